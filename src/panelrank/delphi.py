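"""Fuzzy Delphi screening: aggregation, defuzzification, cut-off, quadrants.

For each criterion and each dimension (relevance, applicability) the
panel's Likert ratings are mapped to TFNs and aggregated into a single
TFN ``(L, M, U)`` where ``L`` is the minimum lower bound, ``M`` the
geometric mean of the modal values, and ``U`` the maximum upper bound
across experts.  Centroid defuzzification yields the representative
score ``G`` per criterion; the arithmetic mean of the ``G`` values of a
dimension is that dimension's cut-off ``alpha``.  A criterion counts as
"above" a cut-off only when ``G > alpha`` strictly; ties fall below.

Criteria are then placed in a quadrant diagram (relevance on x,
applicability on y, cut-offs as reference lines):

* Q1 — above both cut-offs: retained;
* Q2 — below on relevance, above on applicability: retained with caution;
* Q3 — below both: excluded from all downstream stages;
* Q4 — above on relevance, below on applicability: retained with caution.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzy import LinguisticScale, TriangularFuzzyNumber, defuzzify_centroid, tfn_from_likert
from .panel import DIMENSIONS, SurveyPanel, code_sort_key

__all__ = [
    "FdmResult",
    "ScreeningOutcome",
    "aggregate_panel",
    "aggregate_all",
    "compute_cutoff",
    "screen_criteria",
    "screen_panel",
    "QUADRANT_DECISIONS",
]

#: Decision attached to each quadrant of the relevance/applicability plane.
QUADRANT_DECISIONS = {
    "Q1": "retain",
    "Q2": "retain_with_caution",
    "Q3": "exclude",
    "Q4": "retain_with_caution",
}


@dataclass(frozen=True)
class FdmResult:
    """Aggregated panel judgment for one criterion on one dimension."""

    criterion: str
    dimension: str
    aggregate: TriangularFuzzyNumber
    g: float


def aggregate_panel(
    panel: SurveyPanel,
    criterion: str,
    dimension: str,
    scale: LinguisticScale,
) -> FdmResult:
    """Aggregate one criterion's panel ratings into a TFN and its centroid.

    The aggregate is ``(min_j l_j, geomean_j m_j, max_j u_j)`` over the
    experts' mapped TFNs.  Because every scale value is >= 1 the
    geometric mean of the modal components always lies within
    ``[min l, max u]``, so the aggregate is a valid TFN.
    """
    ratings = panel.criterion_ratings(criterion, dimension)
    if ratings.isna().any():
        missing = list(ratings[ratings.isna()].index)
        raise ValueError(
            f"criterion {criterion}/{dimension}: missing ratings for experts {missing}"
        )
    if len(ratings) < 2:
        raise ValueError(
            f"criterion {criterion}/{dimension}: need at least 2 experts, got {len(ratings)}"
        )
    tfns = [tfn_from_likert(int(r), scale) for r in ratings]
    lo = min(t.l for t in tfns)
    hi = max(t.u for t in tfns)
    modes = [t.m for t in tfns]
    mode = float(np.exp(np.mean(np.log(modes))))
    # the geometric mean lies in [min m, max m] exactly; clamp float drift
    mode = min(max(mode, min(modes)), max(modes))
    agg = TriangularFuzzyNumber(lo, mode, hi)
    return FdmResult(criterion, dimension, agg, defuzzify_centroid(agg))


def aggregate_all(
    panel: SurveyPanel,
    criteria: Sequence[str],
    dimension: str,
    scale: LinguisticScale,
) -> list[FdmResult]:
    """Aggregate every listed criterion for one dimension (panel must be complete)."""
    panel.require_complete(criteria)
    return [aggregate_panel(panel, c, dimension, scale) for c in criteria]


def compute_cutoff(results: Iterable[FdmResult] | Iterable[float]) -> float:
    """Cut-off ``alpha``: arithmetic mean of the defuzzified scores, full precision."""
    gs = [r.g if isinstance(r, FdmResult) else float(r) for r in results]
    if not gs:
        raise ValueError("cannot compute a cut-off from an empty result list")
    return fmean(gs)


def _as_g_map(results) -> dict[str, float]:
    if isinstance(results, Mapping):
        return {str(k): float(v) for k, v in results.items()}
    out = {}
    for r in results:
        if not isinstance(r, FdmResult):
            raise TypeError(f"expected FdmResult or mapping, got {type(r).__name__}")
        out[r.criterion] = r.g
    return out


@dataclass(frozen=True)
class ScreeningOutcome:
    """Quadrant classification of every criterion, with the cut-offs used.

    ``table`` is indexed by criterion code with columns ``g_relevance``,
    ``g_applicability``, ``quadrant`` and ``decision``.
    """

    alpha_relevance: float
    alpha_applicability: float
    table: pd.DataFrame

    @property
    def excluded(self) -> list[str]:
        return list(self.table.index[self.table["decision"] == "exclude"])

    @property
    def retained_with_caution(self) -> list[str]:
        return list(self.table.index[self.table["decision"] == "retain_with_caution"])

    @property
    def retained_q1(self) -> list[str]:
        return list(self.table.index[self.table["decision"] == "retain"])

    @property
    def retained(self) -> list[str]:
        """Everything that proceeds to ranking: Q1 plus the caution set."""
        return list(self.table.index[self.table["decision"] != "exclude"])

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df.insert(0, "criterion", df.index)
        return df.reset_index(drop=True)


def screen_criteria(
    relevance: Iterable[FdmResult] | Mapping[str, float],
    applicability: Iterable[FdmResult] | Mapping[str, float],
    alpha_relevance: float,
    alpha_applicability: float,
) -> ScreeningOutcome:
    """Classify criteria into quadrants given per-dimension scores and cut-offs.

    Retention requires ``G`` strictly above the cut-off; a criterion
    sitting exactly at a cut-off counts as below it on that dimension.
    """
    g_rel = _as_g_map(relevance)
    g_app = _as_g_map(applicability)
    if set(g_rel) != set(g_app):
        only_rel = sorted(set(g_rel) - set(g_app), key=code_sort_key)
        only_app = sorted(set(g_app) - set(g_rel), key=code_sort_key)
        raise ValueError(
            "relevance and applicability cover different criteria: "
            f"relevance-only={only_rel}, applicability-only={only_app}"
        )
    codes = sorted(g_rel, key=code_sort_key)
    rows = []
    for c in codes:
        hi_rel = g_rel[c] > alpha_relevance
        hi_app = g_app[c] > alpha_applicability
        quadrant = {(True, True): "Q1", (False, True): "Q2",
                    (False, False): "Q3", (True, False): "Q4"}[(hi_rel, hi_app)]
        rows.append((c, g_rel[c], g_app[c], quadrant, QUADRANT_DECISIONS[quadrant]))
    table = pd.DataFrame(
        rows, columns=["criterion", "g_relevance", "g_applicability", "quadrant", "decision"]
    ).set_index("criterion")
    return ScreeningOutcome(alpha_relevance, alpha_applicability, table)


def screen_panel(
    panel: SurveyPanel,
    criteria: Sequence[str],
    scales: Mapping[str, LinguisticScale],
) -> tuple[dict[str, list[FdmResult]], ScreeningOutcome]:
    """Full Delphi stage: aggregate both dimensions, derive cut-offs, screen.

    Returns the per-dimension aggregation results and the screening
    outcome.  Cut-offs are computed per dimension over the full catalog,
    before any exclusion.
    """
    results = {
        dim: aggregate_all(panel, criteria, dim, scales[dim]) for dim in DIMENSIONS
    }
    alphas = {dim: compute_cutoff(results[dim]) for dim in DIMENSIONS}
    outcome = screen_criteria(
        results["relevance"],
        results["applicability"],
        alphas["relevance"],
        alphas["applicability"],
    )
    return results, outcome
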