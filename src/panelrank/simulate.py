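"""Synthetic expert panels for exercising and validating the pipeline.

The survey behind the published criteria prioritization is not
released, so this module generates panels with the statistical
structure the analysis assumes: each criterion has a latent true score
per dimension on the 1-5 Likert scale, each expert reports that score
plus Gaussian noise, and the report is discretized by rounding to the
nearest level and clipping to [1, 5].  Involvement levels are assigned
from a fixed count distribution; by default the generated panel mirrors
the study panel of 25 experts (9 specialists, 9 high, 6 moderate, 1 low
involvement).

The generator is a stand-in for real survey data, and every panel it
emits is synthetic: it does not model inter-expert correlation,
questionnaire fatigue, or response styles, and it is deliberately not
calibrated to reproduce the published aggregate scores (those are
under-determined by the printed tables).

:func:`recovery_experiment` closes the loop: it runs the full screening
+ ranking + fusion pipeline on replicate panels and measures how well
the recovered relevance ranking and screening decisions track the
latent truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .delphi import screen_panel
from .fuzzy import DEFAULT_SCALES, LinguisticScale
from .fusion import unify
from .panel import DIMENSIONS, SurveyPanel, code_sort_key
from .topsis import rank_criteria

__all__ = ["PanelConfig", "generate_panel", "recovery_experiment"]

#: Involvement Likert level -> expert count, mirroring the study panel.
DEFAULT_INVOLVEMENT_COUNTS = {5: 9, 4: 9, 3: 6, 2: 1}


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of a synthetic panel draw.

    Parameters
    ----------
    true_scores
        Mapping ``criterion -> {dimension -> latent score}`` with scores
        in [1, 5]; both dimensions must be present for every criterion.
    n_experts
        Panel size; involvement counts must sum to it.
    noise_sd
        Standard deviation of the Gaussian reporting noise, in latent
        Likert units.  0 makes every expert reproduce the (rounded)
        true scores exactly.
    involvement_counts
        Mapping involvement level (1..5) -> number of experts.
    expertise_bias
        Optional coupling between involvement and precision, in [0, 1]:
        an expert at involvement level ``k`` has noise standard
        deviation ``noise_sd * (1 - expertise_bias * (k - 1) / 4)``,
        so 0 (default) decouples involvement from rating behavior and
        1 makes specialists noise-free.
    seed
        Seed for the single pseudo-random stream used for the whole
        draw.
    """

    true_scores: Mapping[str, Mapping[str, float]]
    n_experts: int = 25
    noise_sd: float = 0.5
    involvement_counts: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_INVOLVEMENT_COUNTS)
    )
    expertise_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise ValueError(f"need at least 2 experts, got {self.n_experts}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 <= self.expertise_bias <= 1:
            raise ValueError(f"expertise_bias must be in [0, 1], got {self.expertise_bias}")
        total = sum(self.involvement_counts.values())
        if total != self.n_experts:
            raise ValueError(
                f"involvement counts sum to {total}, expected n_experts={self.n_experts}"
            )
        for level, count in self.involvement_counts.items():
            if level not in (1, 2, 3, 4, 5) or count < 0:
                raise ValueError(f"invalid involvement count entry {level!r}: {count!r}")
        if not self.true_scores:
            raise ValueError("true_scores must cover at least one criterion")
        for code, dims in self.true_scores.items():
            for dim in DIMENSIONS:
                if dim not in dims:
                    raise ValueError(f"criterion {code}: missing true score for {dim}")
                v = dims[dim]
                if not 1 <= v <= 5:
                    raise ValueError(
                        f"criterion {code}/{dim}: true score {v} outside [1, 5]"
                    )

    @property
    def criteria(self) -> list[str]:
        return sorted(self.true_scores, key=code_sort_key)


def generate_panel(config: PanelConfig) -> SurveyPanel:
    """Draw one synthetic panel; identical config + seed gives an identical panel."""
    rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_experts)))
    expert_ids = [f"E{i + 1:0{width}d}" for i in range(config.n_experts)]
    levels = np.repeat(
        [lv for lv in sorted(config.involvement_counts)],
        [config.involvement_counts[lv] for lv in sorted(config.involvement_counts)],
    )
    rng.shuffle(levels)
    experts = pd.DataFrame({"expert_id": expert_ids, "involvement": levels.astype(int)})

    codes = config.criteria
    per_expert_sd = np.array(
        [
            config.noise_sd * (1.0 - config.expertise_bias * (lv - 1) / 4.0)
            for lv in levels
        ]
    )
    rows = []
    for code in codes:
        for dim in DIMENSIONS:
            true = config.true_scores[code][dim]
            latent = true + rng.normal(0.0, 1.0, size=config.n_experts) * per_expert_sd
            rating = np.clip(np.rint(latent), 1, 5).astype(int)
            rows.extend(
                (expert_ids[j], code, dim, int(rating[j]))
                for j in range(config.n_experts)
            )
    ratings = pd.DataFrame(rows, columns=["expert_id", "criterion", "dimension", "rating"])
    return SurveyPanel(experts, ratings)


def _run_pipeline_once(
    panel: SurveyPanel,
    criteria: Sequence[str],
    scales: Mapping[str, LinguisticScale],
    convention: str,
):
    _, outcome = screen_panel(panel, criteria, scales)
    retained = outcome.retained
    if len(retained) < 2:
        return outcome, None, None
    rel = rank_criteria(panel, retained, "relevance", scales["relevance"], convention=convention)
    app = rank_criteria(
        panel, retained, "applicability", scales["applicability"], convention=convention
    )
    return outcome, rel, unify(rel, app)


def recovery_experiment(
    config: PanelConfig,
    replicates: int,
    scales: Mapping[str, LinguisticScale] | None = None,
    convention: str = "per_column",
) -> dict:
    """Monte-Carlo check that the pipeline recovers a known priority order.

    Per replicate the full screening + ranking + fusion pipeline runs on
    a fresh panel and two quantities are measured:

    * the Spearman correlation between the latent relevance scores of
      the criteria that survive screening and their recovered relevance
      closeness coefficients;
    * the false-exclusion rate — the fraction of criteria whose latent
      scores exceed the latent mean on *both* dimensions yet end up
      excluded by the screening stage.

    Returns a summary dict with the median and mean Spearman, the mean
    false-exclusion rate, and the per-replicate values.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    rel_true = {c: config.true_scores[c]["relevance"] for c in config.criteria}
    if len(set(rel_true.values())) != len(rel_true):
        app_true = {c: config.true_scores[c]["applicability"] for c in config.criteria}
        if len(set(app_true.values())) != len(app_true):
            raise ValueError(
                "true scores must define a strict priority order on at least one dimension"
            )
    scales = dict(DEFAULT_SCALES) if scales is None else dict(scales)
    codes = config.criteria
    means = {
        dim: float(np.mean([config.true_scores[c][dim] for c in codes]))
        for dim in DIMENSIONS
    }
    should_retain = [
        c
        for c in codes
        if all(config.true_scores[c][dim] > means[dim] for dim in DIMENSIONS)
    ]

    child_seeds = np.random.SeedSequence(config.seed).spawn(replicates)
    spearmans: list[float] = []
    false_exclusion: list[float] = []
    for child in child_seeds:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        rep_config = PanelConfig(
            true_scores=config.true_scores,
            n_experts=config.n_experts,
            noise_sd=config.noise_sd,
            involvement_counts=dict(config.involvement_counts),
            expertise_bias=config.expertise_bias,
            seed=rep_seed,
        )
        panel = generate_panel(rep_config)
        outcome, rel, _ = _run_pipeline_once(panel, codes, scales, convention)
        if should_retain:
            excluded = set(outcome.excluded)
            false_exclusion.append(
                sum(1 for c in should_retain if c in excluded) / len(should_retain)
            )
        else:
            false_exclusion.append(0.0)
        if rel is None:
            spearmans.append(float("nan"))
            continue
        kept = list(rel.table.index)
        truth = [rel_true[c] for c in kept]
        recovered = [float(rel.table.loc[c, "cc"]) for c in kept]
        if len(kept) < 2 or len(set(truth)) < 2:
            spearmans.append(float("nan"))
        else:
            rho = spearmanr(truth, recovered).statistic
            spearmans.append(float(rho))
    arr = np.asarray(spearmans, dtype=float)
    valid = arr[~np.isnan(arr)]
    return {
        "replicates": replicates,
        "median_spearman": float(np.median(valid)) if valid.size else float("nan"),
        "mean_spearman": float(np.mean(valid)) if valid.size else float("nan"),
        "false_exclusion_rate": float(np.mean(false_exclusion)),
        "spearman_per_replicate": spearmans,
        "false_exclusion_per_replicate": false_exclusion,
    }
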