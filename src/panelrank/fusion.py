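"""Fusion of the relevance and applicability rankings into a unified priority.

The two TOPSIS closeness coefficients of each criterion are averaged
into the unified priority ``mu = (cc_relevance + cc_applicability) / 2``
and the criteria re-ranked on ``mu``.  The relevance closeness
coefficient doubles as the criterion's priority value ``p`` in the
criteria-prioritization framework annotation, which lays the retained
criteria out by axis (etiology, consequences, adherence) for machine
consumption.

Report values are rounded half-up to two decimals; ranking always uses
full precision.  Ties in ``mu`` are broken by higher relevance closeness
first (relevance is the designated primary weight), then ascending
criterion code.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .delphi import ScreeningOutcome
from .panel import CriterionDescriptor, code_sort_key
from .topsis import TopsisResult

__all__ = ["UnifiedRanking", "round_half_up", "unify", "annotate_framework"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.665 -> 0.67), robust to float representation.

    The value is first snapped to ``ndigits + 6`` decimals so that a
    float sitting a few ulps below an exact half (e.g. the double
    nearest 0.665) still rounds up.
    """
    snapped = Decimal(repr(float(x))).quantize(
        Decimal(1).scaleb(-(ndigits + 6)), rounding=ROUND_HALF_UP
    )
    q = snapped.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
    return float(q)


def _as_cc_map(result: TopsisResult | Mapping[str, float]) -> dict[str, float]:
    if isinstance(result, TopsisResult):
        return result.cc_map()
    return {str(k): float(v) for k, v in result.items()}


def _dense_rank(codes: Sequence[str], key) -> dict[str, int]:
    order = sorted(codes, key=key)
    return {c: i + 1 for i, c in enumerate(order)}


@dataclass(frozen=True)
class UnifiedRanking:
    """Per-criterion closeness coefficients, unified priority and ranks.

    ``table`` is indexed by criterion with full-precision columns
    ``cc_relevance``, ``cc_applicability``, ``mu`` and the three rank
    columns; :meth:`report` adds the half-up 2-decimal presentation.
    """

    table: pd.DataFrame

    def report(self, ndigits: int = 2) -> pd.DataFrame:
        """Presentation table with half-up rounded values, ordered by unified rank."""
        df = self.table.copy()
        for col in ("cc_relevance", "cc_applicability", "mu"):
            df[col] = df[col].map(lambda v: round_half_up(v, ndigits))
        df = df.sort_values("rank_unified")
        df.insert(0, "criterion", df.index)
        return df.reset_index(drop=True)

    def mu_map(self) -> dict[str, float]:
        return self.table["mu"].to_dict()


def unify(
    relevance: TopsisResult | Mapping[str, float],
    applicability: TopsisResult | Mapping[str, float],
) -> UnifiedRanking:
    """Average the two dimensions' closeness coefficients into ``mu`` and rank.

    Accepts full TOPSIS results from an end-to-end run, or plain
    ``{criterion: cc}`` mappings when reproducing a ranking from
    published closeness coefficients.
    """
    cc_rel = _as_cc_map(relevance)
    cc_app = _as_cc_map(applicability)
    if set(cc_rel) != set(cc_app):
        raise ValueError(
            "relevance and applicability rankings cover different criteria: "
            f"{sorted(set(cc_rel) ^ set(cc_app), key=code_sort_key)}"
        )
    codes = sorted(cc_rel, key=code_sort_key)
    mu = {c: (cc_rel[c] + cc_app[c]) / 2.0 for c in codes}
    r_rel = _dense_rank(codes, lambda c: (-cc_rel[c], code_sort_key(c)))
    r_app = _dense_rank(codes, lambda c: (-cc_app[c], code_sort_key(c)))
    r_uni = _dense_rank(codes, lambda c: (-mu[c], -cc_rel[c], code_sort_key(c)))
    table = pd.DataFrame(
        {
            "cc_relevance": [cc_rel[c] for c in codes],
            "rank_relevance": [r_rel[c] for c in codes],
            "cc_applicability": [cc_app[c] for c in codes],
            "rank_applicability": [r_app[c] for c in codes],
            "mu": [mu[c] for c in codes],
            "rank_unified": [r_uni[c] for c in codes],
        },
        index=pd.Index(codes, name="criterion"),
    )
    return UnifiedRanking(table)


def annotate_framework(
    catalog: Sequence[CriterionDescriptor],
    screening: ScreeningOutcome,
    unified: UnifiedRanking,
) -> dict:
    """Machine-readable framework annotation: layers, priorities, exclusions.

    Retained criteria are grouped by axis, each carrying its priority
    value ``p`` (the relevance closeness coefficient), unified ``mu``,
    ranks and screening decision; excluded criteria are listed in an
    appendix with the quadrant that motivated their exclusion.
    """
    by_code = {d.code: d for d in catalog}
    missing = [c for c in unified.table.index if c not in by_code]
    if missing:
        raise ValueError(f"ranked criteria missing from the catalog: {missing}")
    not_ranked = [
        c for c in screening.retained if c not in set(unified.table.index)
    ]
    if not_ranked:
        raise ValueError(
            f"screening retained criteria absent from the unified ranking: {not_ranked}"
        )
    layers: dict[str, list] = {"etiology": [], "consequence": [], "adherence": []}
    for code, row in unified.table.sort_values("rank_unified").iterrows():
        d = by_code[code]
        layers[d.axis].append(
            {
                "code": code,
                "label": d.label,
                "aspect": d.aspect,
                "p": round_half_up(float(row["cc_relevance"])),
                "mu": round_half_up(float(row["mu"])),
                "rank_unified": int(row["rank_unified"]),
                "decision": str(screening.table.loc[code, "decision"]),
            }
        )
    excluded = [
        {
            "code": code,
            "label": by_code[code].label if code in by_code else None,
            "quadrant": str(screening.table.loc[code, "quadrant"]),
        }
        for code in screening.excluded
    ]
    return {
        "priority_key": "p = relevance closeness coefficient",
        "layers": layers,
        "excluded": excluded,
    }
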