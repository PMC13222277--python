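"""Involvement-weighted fuzzy TOPSIS over the retained criteria.

The decision matrix has retained criteria as rows (alternatives) and
experts as columns; each cell is the TFN image of that expert's Likert
rating on the dimension being ranked.  Because every criterion is
benefit-type, the matrix is normalized per expert column by the column's
maximum upper bound.  Each expert column is then weighted by the
expert's involvement TFN, normalized component-wise so that each
component family (L, M, U) sums to one across experts — experts more
involved in obesity management pull the ranking harder.

Distances of each weighted row to the fuzzy positive and negative ideal
solutions are summed over expert columns with the vertex metric, and the
closeness coefficient ``CC_i = D_i^- / (D_i^+ + D_i^-)`` orders the
criteria: 1 at the positive ideal, 0 at the negative ideal.

Two ideal-solution conventions are supported and stamped into every
result:

* ``per_column`` (default) — ``A+_j`` is the column's maximum upper
  bound and ``A-_j`` the column's minimum lower bound, each replicated
  as a degenerate TFN;
* ``chen_fixed`` — ``A+_j = (1, 1, 1)`` and ``A-_j = (0, 0, 0)`` for
  every column, the classical fixed-anchor variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzy import INVOLVEMENT_SCALE, LinguisticScale, tfn_from_likert
from .panel import SurveyPanel, code_sort_key

__all__ = [
    "FuzzyDecisionMatrix",
    "WeightVector",
    "IdealSolutions",
    "TopsisResult",
    "CONVENTIONS",
    "build_decision_matrix",
    "normalize_benefit",
    "normalize_weights",
    "weights_from_panel",
    "apply_weights",
    "ideal_solutions",
    "closeness",
    "rank_criteria",
]

CONVENTIONS = ("per_column", "chen_fixed")

log = logging.getLogger("panelrank.topsis")

# whether the routine weighted-cell re-ordering repair has been reported yet
_reorder_reported = False


@dataclass(frozen=True)
class FuzzyDecisionMatrix:
    """Dense criteria x experts matrix of TFN cells for one dimension.

    ``values`` has shape ``(m, n, 3)`` with the last axis holding
    ``(l, m, u)``.
    """

    dimension: str
    criteria: tuple[str, ...]
    experts: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.criteria), len(self.experts), 3):
            raise ValueError(
                f"matrix shape {v.shape} inconsistent with "
                f"{len(self.criteria)} criteria x {len(self.experts)} experts"
            )
        if np.any(v < 0):
            raise ValueError("decision matrix cells must be non-negative")
        if np.any(v[..., 0] > v[..., 1]) or np.any(v[..., 1] > v[..., 2]):
            raise ValueError("decision matrix cells must satisfy l <= m <= u")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.criteria), len(self.experts))


@dataclass(frozen=True)
class WeightVector:
    """Per-expert involvement TFNs and their component-wise normalization.

    Normalization divides each component family by its own sum, so each
    of the L, M and U families sums to one across experts.  For skewed
    panels this printed formula can yield triples with ``l' > m'``; such
    triples are kept as-is (they are weights, not TFN-validated values)
    and any ordering violation they induce in the weighted matrix is
    repaired and reported downstream in :func:`apply_weights`.
    """

    experts: tuple
    raw: np.ndarray         # (n, 3)
    normalized: np.ndarray  # (n, 3), each column sums to 1

    def __post_init__(self) -> None:
        if self.raw.shape != (len(self.experts), 3):
            raise ValueError("weight vector shape inconsistent with expert count")
        sums = self.normalized.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"normalized weight components must sum to 1, got {sums}")


@dataclass(frozen=True)
class IdealSolutions:
    """Per-expert-column fuzzy positive/negative ideal solutions."""

    convention: str
    a_plus: np.ndarray   # (n, 3)
    a_minus: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        if np.any(self.a_minus > self.a_plus):
            raise ValueError("FNIS must not exceed FPIS component-wise")


@dataclass(frozen=True)
class TopsisResult:
    """Closeness coefficients and ranks for one dimension.

    ``table`` is indexed by criterion with columns ``d_plus``,
    ``d_minus``, ``cc`` and ``rank`` (1 = closest to the positive
    ideal); ``convention`` records the ideal-solution variant used.
    """

    dimension: str
    convention: str
    table: pd.DataFrame

    def cc_map(self) -> dict[str, float]:
        return self.table["cc"].to_dict()


def build_decision_matrix(
    panel: SurveyPanel,
    retained: Sequence[str],
    dimension: str,
    scale: LinguisticScale,
) -> FuzzyDecisionMatrix:
    """Map the panel's ratings on ``retained`` criteria to a TFN matrix."""
    codes = list(retained)
    if not codes:
        raise ValueError("retained criterion set is empty")
    unknown = sorted(set(codes) - set(panel.criteria), key=code_sort_key)
    if unknown:
        raise ValueError(f"criteria not present in the panel: {unknown}")
    ratings = panel.rating_matrix(dimension, codes)
    if ratings.isna().any().any():
        missing = [
            f"({c}, {e})"
            for c in ratings.index
            for e in ratings.columns
            if pd.isna(ratings.loc[c, e])
        ]
        raise ValueError(f"incomplete panel for {dimension}: missing cells {missing}")
    values = np.empty((len(codes), panel.n_experts, 3), dtype=float)
    for i, c in enumerate(codes):
        for j, e in enumerate(ratings.columns):
            values[i, j, :] = tfn_from_likert(int(ratings.loc[c, e]), scale).astuple()
    return FuzzyDecisionMatrix(dimension, tuple(codes), tuple(ratings.columns), values)


def normalize_benefit(matrix: FuzzyDecisionMatrix) -> FuzzyDecisionMatrix:
    """Benefit-type linear normalization per expert column.

    Each cell is divided by the column's maximum upper bound
    ``u_j^+ = max_i u_ij``, so all components land in ``(0, 1]`` and the
    largest upper component of every column becomes exactly 1.
    """
    u_plus = matrix.values[..., 2].max(axis=0)  # (n,)
    if np.any(u_plus <= 0):
        bad = [matrix.experts[j] for j in np.flatnonzero(u_plus <= 0)]
        raise ValueError(f"zero column maximum for experts {bad}; cannot normalize")
    return FuzzyDecisionMatrix(
        matrix.dimension,
        matrix.criteria,
        matrix.experts,
        matrix.values / u_plus[None, :, None],
    )


def normalize_weights(
    involvements: Sequence, experts: Sequence | None = None
) -> WeightVector:
    """Component-wise normalization of the expert involvement TFNs.

    ``w_j^c' = w_j^c / sum_j w_j^c`` independently for each component
    ``c in {L, M, U}``.
    """
    raw = np.asarray([tuple(t) for t in involvements], dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 3 or raw.shape[0] < 1:
        raise ValueError("involvements must be a non-empty sequence of TFNs")
    sums = raw.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError(f"zero component sum in weight vector: {sums}")
    ids = tuple(experts) if experts is not None else tuple(range(raw.shape[0]))
    if len(ids) != raw.shape[0]:
        raise ValueError("expert id count does not match involvement count")
    return WeightVector(ids, raw, raw / sums[None, :])


def weights_from_panel(
    panel: SurveyPanel, scale: LinguisticScale = INVOLVEMENT_SCALE
) -> WeightVector:
    """Weight vector from the panel's involvement levels via the involvement scale."""
    levels = panel.involvement_levels()
    tfns = [tfn_from_likert(int(lv), scale) for lv in levels]
    return normalize_weights(tfns, experts=levels.index)


def apply_weights(matrix: FuzzyDecisionMatrix, weights: WeightVector) -> FuzzyDecisionMatrix:
    """Multiply each normalized column by its expert's normalized weight triple.

    The normalized weight triple is applied as a component-wise product.
    For experts whose raw weight components exceed the component-family
    average, the printed normalization yields triples with ``l' > m'``,
    which breaks the component ordering of the weighted cells; such
    cells are re-sorted to restore ``l <= m <= u`` and the repair is
    logged (routine for any panel with heterogeneous involvement, so it
    is reported at warning level only once per process).
    """
    if len(weights.experts) != len(matrix.experts):
        raise ValueError(
            f"weight count {len(weights.experts)} does not match "
            f"expert column count {len(matrix.experts)}"
        )
    weighted = matrix.values * weights.normalized[None, :, :]
    disordered = np.any(
        (weighted[..., 0] > weighted[..., 1]) | (weighted[..., 1] > weighted[..., 2])
    )
    if disordered:
        msg = (
            "component-wise weight normalization produced mis-ordered weighted "
            "cells; components re-sorted to restore l <= m <= u"
        )
        global _reorder_reported
        if not _reorder_reported:
            log.warning(msg)
            _reorder_reported = True
        else:
            log.debug(msg)
        weighted = np.sort(weighted, axis=2)
    return FuzzyDecisionMatrix(matrix.dimension, matrix.criteria, matrix.experts, weighted)


def ideal_solutions(matrix: FuzzyDecisionMatrix, convention: str = "per_column") -> IdealSolutions:
    """Fuzzy positive/negative ideal solutions per expert column."""
    if convention == "per_column":
        hi = matrix.values[..., 2].max(axis=0)  # (n,)
        lo = matrix.values[..., 0].min(axis=0)
        a_plus = np.repeat(hi[:, None], 3, axis=1)
        a_minus = np.repeat(lo[:, None], 3, axis=1)
    elif convention == "chen_fixed":
        n = len(matrix.experts)
        a_plus = np.ones((n, 3))
        a_minus = np.zeros((n, 3))
    else:
        raise ValueError(f"unknown ideal-solution convention {convention!r}; "
                         f"choose one of {CONVENTIONS}")
    return IdealSolutions(convention, a_plus, a_minus)


def closeness(matrix: FuzzyDecisionMatrix, ideals: IdealSolutions) -> TopsisResult:
    """Vertex distances to both ideals, closeness coefficients and ranks.

    ``D_i^+/- = sum_j d_v(v_ij, A^+/-_j)`` and
    ``CC_i = D_i^- / (D_i^+ + D_i^-)``.  Ranks descend in ``CC`` with
    ties broken by ascending criterion code.
    """
    if ideals.a_plus.shape[0] != len(matrix.experts):
        raise ValueError("ideal solutions do not match the matrix's expert columns")
    diff_p = matrix.values - ideals.a_plus[None, :, :]
    diff_m = matrix.values - ideals.a_minus[None, :, :]
    d_plus = np.sqrt((diff_p**2).mean(axis=2)).sum(axis=1)
    d_minus = np.sqrt((diff_m**2).mean(axis=2)).sum(axis=1)
    denom = d_plus + d_minus
    if np.any(denom == 0):
        bad = [matrix.criteria[i] for i in np.flatnonzero(denom == 0)]
        raise ValueError(
            f"degenerate closeness for criteria {bad}: D+ + D- = 0 "
            "(positive and negative ideals coincide)"
        )
    cc = d_minus / denom
    order = sorted(
        range(len(matrix.criteria)),
        key=lambda i: (-cc[i], code_sort_key(matrix.criteria[i])),
    )
    rank = np.empty(len(order), dtype=int)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    table = pd.DataFrame(
        {"d_plus": d_plus, "d_minus": d_minus, "cc": cc, "rank": rank},
        index=pd.Index(matrix.criteria, name="criterion"),
    )
    return TopsisResult(matrix.dimension, ideals.convention, table)


def rank_criteria(
    panel: SurveyPanel,
    retained: Sequence[str],
    dimension: str,
    scale: LinguisticScale,
    involvement_scale: LinguisticScale = INVOLVEMENT_SCALE,
    convention: str = "per_column",
) -> TopsisResult:
    """Full TOPSIS stage for one dimension: build, normalize, weight, rank."""
    matrix = build_decision_matrix(panel, retained, dimension, scale)
    normalized = normalize_benefit(matrix)
    weights = weights_from_panel(panel, involvement_scale)
    weighted = apply_weights(normalized, weights)
    ideals = ideal_solutions(weighted, convention)
    return closeness(weighted, ideals)
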