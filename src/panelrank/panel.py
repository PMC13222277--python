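"""Criteria catalog descriptors and the expert survey panel container.

A :class:`SurveyPanel` holds the long-format ratings table (one row per
expert x criterion x dimension) plus each expert's self-reported
involvement level.  Every pipeline stage consumes panels through this
container, which enforces completeness — each expert must rate every
catalog criterion on both dimensions — before any aggregation runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DIMENSIONS",
    "AXES",
    "ASPECTS",
    "CriterionDescriptor",
    "SurveyPanel",
    "PanelValidationError",
    "code_sort_key",
]

DIMENSIONS = ("relevance", "applicability")
AXES = ("etiology", "consequence", "adherence")
ASPECTS = ("behavioral", "psychological", "biological", "environmental", "aggregated")
GRANULARITIES = ("individual", "aggregated")


def code_sort_key(code: str) -> tuple:
    """Natural ordering for criterion codes: C2 sorts before C10."""
    m = re.fullmatch(r"([A-Za-z]*)(\d+)", code)
    if m:
        return (m.group(1), int(m.group(2)))
    return (code, -1)


@dataclass(frozen=True)
class CriterionDescriptor:
    """One catalog entry: a candidate criterion for obesity management.

    ``axis`` places the criterion in the framework layer it belongs to
    (etiology, consequence of obesity, or treatment adherence);
    ``aspect`` is the thematic domain within that layer; ``granularity``
    records whether the panel rated it individually or as an aggregated
    construct.
    """

    code: str
    label: str
    axis: str
    aspect: str
    granularity: str

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"{self.code}: unknown axis {self.axis!r}")
        if self.aspect not in ASPECTS:
            raise ValueError(f"{self.code}: unknown aspect {self.aspect!r}")
        if self.granularity not in GRANULARITIES:
            raise ValueError(f"{self.code}: unknown granularity {self.granularity!r}")


class PanelValidationError(ValueError):
    """Raised when a survey panel violates the input contract.

    Carries the full list of problems so a malformed file is reported
    in one pass rather than one error at a time.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        msg = f"{len(self.problems)} survey validation problem(s):\n" + "\n".join(
            f"  - {p}" for p in self.problems
        )
        super().__init__(msg)


@dataclass
class SurveyPanel:
    """Expert ratings in long format plus per-expert involvement levels.

    Parameters
    ----------
    experts
        DataFrame with columns ``expert_id`` and ``involvement`` (Likert
        1..5); one row per expert, ids unique.
    ratings
        DataFrame with columns ``expert_id``, ``criterion``,
        ``dimension`` and ``rating`` (Likert 1..5).
    """

    experts: pd.DataFrame
    ratings: pd.DataFrame

    def __post_init__(self) -> None:
        self.experts = self.experts.reset_index(drop=True)
        self.ratings = self.ratings.reset_index(drop=True)
        problems: list[str] = []
        dup = self.experts["expert_id"][self.experts["expert_id"].duplicated()]
        for e in dup.unique():
            problems.append(f"duplicate expert id {e!r}")
        for _, row in self.experts.iterrows():
            inv = row["involvement"]
            if not _is_likert(inv):
                problems.append(
                    f"expert {row['expert_id']!r}: involvement {inv!r} is not an integer in 1..5"
                )
        bad = self.ratings[~self.ratings["dimension"].isin(DIMENSIONS)]
        for _, row in bad.iterrows():
            problems.append(
                f"expert {row['expert_id']!r}, criterion {row['criterion']!r}: "
                f"unknown dimension {row['dimension']!r}"
            )
        for _, row in self.ratings.iterrows():
            if not _is_likert(row["rating"]):
                problems.append(
                    f"expert {row['expert_id']!r}, criterion {row['criterion']!r}, "
                    f"{row['dimension']}: rating {row['rating']!r} is not an integer in 1..5"
                )
        dup_cells = self.ratings.duplicated(
            subset=["expert_id", "criterion", "dimension"], keep=False
        )
        if dup_cells.any():
            cells = self.ratings.loc[
                dup_cells, ["expert_id", "criterion", "dimension"]
            ].drop_duplicates()
            for _, row in cells.iterrows():
                problems.append(
                    f"duplicate rating cell (expert {row['expert_id']!r}, "
                    f"{row['criterion']}, {row['dimension']})"
                )
        if problems:
            raise PanelValidationError(problems)
        self.ratings["rating"] = self.ratings["rating"].astype(int)
        self.experts["involvement"] = self.experts["involvement"].astype(int)

    # -- accessors ---------------------------------------------------------

    @property
    def expert_ids(self) -> list:
        return list(self.experts["expert_id"])

    @property
    def n_experts(self) -> int:
        return len(self.experts)

    @property
    def criteria(self) -> list[str]:
        return sorted(self.ratings["criterion"].unique(), key=code_sort_key)

    def involvement_levels(self) -> pd.Series:
        """Involvement Likert level per expert, indexed by expert id."""
        return self.experts.set_index("expert_id")["involvement"]

    def rating_matrix(self, dimension: str, criteria: Sequence[str] | None = None) -> pd.DataFrame:
        """Criteria x experts matrix of Likert ratings for one dimension."""
        if dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {dimension!r}")
        sub = self.ratings[self.ratings["dimension"] == dimension]
        mat = sub.pivot(index="criterion", columns="expert_id", values="rating")
        mat = mat.reindex(columns=self.expert_ids)
        codes = self.criteria if criteria is None else list(criteria)
        mat = mat.reindex(index=codes)
        return mat

    def criterion_ratings(self, criterion: str, dimension: str) -> pd.Series:
        """One criterion's ratings across the panel, indexed by expert id."""
        sub = self.ratings[
            (self.ratings["criterion"] == criterion)
            & (self.ratings["dimension"] == dimension)
        ]
        return sub.set_index("expert_id")["rating"].reindex(self.expert_ids)

    # -- validation --------------------------------------------------------

    def require_complete(self, criteria: Iterable[str]) -> None:
        """Check every expert rated every listed criterion on both dimensions.

        Raises :class:`PanelValidationError` listing each missing
        (expert, criterion, dimension) cell.
        """
        codes = list(criteria)
        have = set(
            zip(self.ratings["expert_id"], self.ratings["criterion"], self.ratings["dimension"])
        )
        missing = [
            f"missing rating: expert {e!r}, criterion {c}, dimension {d}"
            for e in self.expert_ids
            for c in codes
            for d in DIMENSIONS
            if (e, c, d) not in have
        ]
        if missing:
            raise PanelValidationError(missing)

    def subset(self, criteria: Sequence[str]) -> "SurveyPanel":
        """Panel restricted to the given criteria (experts unchanged)."""
        keep = self.ratings[self.ratings["criterion"].isin(set(criteria))]
        return SurveyPanel(self.experts.copy(), keep.copy())


def _is_likert(v) -> bool:
    if isinstance(v, bool):
        return False
    try:
        f = float(v)
    except (TypeError, ValueError):
        return False
    return f.is_integer() and 1 <= f <= 5
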