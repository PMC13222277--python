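from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from panelrank import SurveyPanel

settings.register_profile(
    "ci", derandomize=True, max_examples=200, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_panel(
    ratings: dict[str, dict[str, list[int]]],
    involvement: list[int] | None = None,
) -> SurveyPanel:
    """Build a panel from {criterion: {dimension: [rating per expert]}}."""
    n = len(next(iter(next(iter(ratings.values())).values())))
    experts = [f"E{i + 1:02d}" for i in range(n)]
    inv = involvement if involvement is not None else [3] * n
    rows = [
        (experts[j], code, dim, levels[j])
        for code, dims in ratings.items()
        for dim, levels in dims.items()
        for j in range(n)
    ]
    return SurveyPanel(
        pd.DataFrame({"expert_id": experts, "involvement": inv}),
        pd.DataFrame(rows, columns=["expert_id", "criterion", "dimension", "rating"]),
    )


def random_panel(rng: np.random.Generator, n_criteria: int, n_experts: int) -> SurveyPanel:
    codes = [f"C{i + 1}" for i in range(n_criteria)]
    ratings = {
        c: {
            "relevance": list(rng.integers(1, 6, n_experts)),
            "applicability": list(rng.integers(1, 6, n_experts)),
        }
        for c in codes
    }
    involvement = list(rng.integers(1, 6, n_experts))
    return make_panel(ratings, involvement)


@pytest.fixture
def two_expert_panel() -> SurveyPanel:
    return make_panel(
        {
            "C1": {"relevance": [5, 5], "applicability": [4, 4]},
            "C2": {"relevance": [3, 4], "applicability": [2, 3]},
        },
        involvement=[5, 2],
    )
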