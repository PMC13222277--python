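"""Quadrant scatter of defuzzified relevance vs applicability scores."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .delphi import ScreeningOutcome

__all__ = ["quadrant_scatter"]

_DECISION_STYLE = {
    "retain": ("tab:green", "o"),
    "retain_with_caution": ("tab:orange", "s"),
    "exclude": ("tab:red", "x"),
}


def quadrant_scatter(outcome: ScreeningOutcome, path: str | Path) -> Path:
    """Plot criteria on the relevance (x) / applicability (y) plane.

    Cut-off reference lines split the plane into the four screening
    quadrants; marker style encodes the decision.  Output format follows
    the file extension (PNG or SVG).
    """
    fig, ax = plt.subplots(figsize=(7, 6))
    for decision, (color, marker) in _DECISION_STYLE.items():
        sub = outcome.table[outcome.table["decision"] == decision]
        ax.scatter(
            sub["g_relevance"],
            sub["g_applicability"],
            c=color,
            marker=marker,
            label=decision.replace("_", " "),
            zorder=3,
        )
        for code, row in sub.iterrows():
            ax.annotate(
                code,
                (row["g_relevance"], row["g_applicability"]),
                textcoords="offset points",
                xytext=(4, 4),
                fontsize=8,
            )
    ax.axvline(outcome.alpha_relevance, color="grey", ls="--", lw=1)
    ax.axhline(outcome.alpha_applicability, color="grey", ls="--", lw=1)
    ax.set_xlabel("defuzzified relevance score G")
    ax.set_ylabel("defuzzified applicability score G")
    ax.set_title(
        f"Criteria screening quadrants "
        f"(α_rel={outcome.alpha_relevance:.3f}, α_app={outcome.alpha_applicability:.3f})"
    )
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
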