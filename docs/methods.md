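# Methods

## Linguistic scales and fuzzy ratings

All three elicitation scales — relevance, applicability, and professional
involvement — are five-point Likert scales mapped to triangular fuzzy
numbers (TFNs) on a 1–9 magnitude scale:

| level | TFN (l, m, u) |
|------:|---------------|
| 1 | (1, 1, 1) |
| 2 | (1, 3, 5) |
| 3 | (3, 5, 7) |
| 4 | (5, 7, 9) |
| 5 | (7, 9, 9) |

The three scales share this numeric mapping but are kept as distinct named
objects (`RELEVANCE_SCALE`, `APPLICABILITY_SCALE`, `INVOLVEMENT_SCALE`): the
coincidence is data, not structure, and an alternative calibration for one
dimension can be swapped in without touching the others. Scales serialize to
YAML/JSON.

TFNs are immutable value objects validated at construction (`0 ≤ l ≤ m ≤ u`);
a mis-ordered triple is rejected rather than silently re-sorted, because
re-sorting would mask upstream bugs. All stage outputs carry full precision;
rounding happens only at report time.

## Fuzzy Delphi screening

For each criterion and dimension, the panel's mapped TFNs aggregate to
`(min_j l_j, geomean_j m_j, max_j u_j)`. The aggregation statistic applied to
the modal components is deliberately the geometric mean of the *mapped* TFN
modes rather than of the raw Likert levels: since every scale value is ≥ 1,
this keeps the aggregate a valid TFN for any panel, including unanimous
extreme panels, which the raw-level reading does not guarantee. The
geometric mean is clamped into `[min m, max m]` to absorb floating-point
drift from the log-mean-exp evaluation (observed at the last ulp for
unanimous panels).

The representative score is the centroid `G = (L + M + U)/3`. The cut-off α
per dimension is the arithmetic mean of that dimension's G values over the
**full** catalog (27 criteria), computed before any exclusion. Retention
requires `G > α` strictly; a criterion sitting exactly at a cut-off counts as
below it. Quadrants on the relevance (x) / applicability (y) plane:

* Q1 (above/above) → retain;
* Q2 (below relevance, above applicability) → retain with caution;
* Q3 (below/below) → exclude from all downstream stages;
* Q4 (above relevance, below applicability) → retain with caution.

Caution-flagged criteria proceed to ranking alongside Q1 criteria, so the
ranked set is "everything not excluded". A single elicitation round is
modeled; multi-round Delphi iteration is out of scope.

## Fuzzy TOPSIS

Matrix orientation: alternatives (rows) are the retained criteria, columns
are the experts, so the weight vector runs over experts — expert influence,
not criterion importance, is what the involvement weighting modulates. The
method runs separately on the relevance and applicability ratings.

* **Normalization** (benefit-type, per expert column): every cell is divided
  by the column's maximum upper bound `u_j⁺ = max_i u_ij`, landing all
  components in (0, 1].
* **Weights**: each expert's involvement TFN is normalized component-wise,
  `w_j^c′ = w_j^c / Σ_j w_j^c` independently for c ∈ {L, M, U}. This printed
  formula is implemented exactly as stated even though it yields decreasing
  triples (`l′ > m′ > u′`) for experts whose components exceed the
  component-family average — e.g. a specialist (7,9,9) in a 25-expert panel
  with component sums (127, 177, 209) gets (0.0551, 0.0508, 0.0431). Such
  triples are stored as ordering-exempt weight triples, not TFN-validated.
* **Weighting**: cells are multiplied component-wise by their column's
  normalized weight triple. Where a decreasing weight triple breaks a cell's
  component ordering, the components are re-sorted to restore `l ≤ m ≤ u`
  and the repair is logged (once per process at warning level — it is
  routine for any panel with heterogeneous involvement, not an anomaly).
* **Ideal solutions**: configurable, stamped into every result.
  `per_column` (default): `A⁺_j` is the column's maximum upper bound and
  `A⁻_j` its minimum lower bound, each replicated as a degenerate TFN —
  ideals defined per column from the data. `chen_fixed`: `A⁺_j = (1,1,1)`,
  `A⁻_j = (0,0,0)`, the classical fixed anchors. No intermediate quantity of
  the reference analysis is published, so neither convention can be anchored
  numerically; both are first-class and the default is the per-column
  reading. The ideal-solution convention, scales and rounding mode are
  recorded in the run manifest of every pipeline run.
* **Closeness**: `D_i^± = Σ_j d_v(ṽ_ij, A^±_j)` with the vertex (RMS)
  distance; `CC_i = D_i⁻/(D_i⁺ + D_i⁻)`. Coincident ideals (possible only
  for a single-criterion matrix under `per_column`) raise an error naming
  the degenerate column. Ranks descend in CC with ties broken by ascending
  criterion code (natural order, C2 before C10).

## Fusion and framework annotation

The unified priority is the plain arithmetic mean
`μ = (CC_rel + CC_app)/2`. Ranks are computed on full-precision values;
ties in μ are broken by higher relevance CC (relevance is the designated
primary weight), then ascending code.

Report rounding is decimal **round-half-up** to 2 decimals (0.665 → 0.67),
with the float first snapped to 8 decimals so a double one ulp below an
exact half still rounds up. Half-up is used because banker's rounding would
contradict the reference ranking's printed μ values on the many rows whose
2-dp inputs average to an exact half.

When the pipeline runs end-to-end, μ comes from full-precision closeness
coefficients; when reproducing the reference ranking from the packaged
fixture, the inputs are the printed 2-dp coefficients, and recomputed
per-dimension ranks can then differ from the printed ranks among criteria
tied at 2 dp (the reference ranking was evidently computed on unrounded
values that are not public). The μ column, not the per-dimension rank
column, is therefore the reproduction anchor.

The framework annotation groups retained criteria by axis (etiology,
consequences, adherence) with each criterion's priority `p` (relevance CC),
μ, unified rank and screening decision; excluded criteria appear only in an
exclusion appendix with their quadrant.

## Packaged reference fixtures

The reference study's survey (25 experts × 27 criteria × 2 dimensions) is
not public. The package therefore ships, as data fixtures: the 27-criterion
catalog (codes, labels, axis/aspect/granularity), the published
per-criterion defuzzified scores for both dimensions, the published
closeness coefficients and ranks for the 21 ranked criteria, and the
involvement scale. Downstream stages (cut-offs, screening partition, fusion)
are recomputed from these; upstream stages (aggregation, TOPSIS distances)
cannot be anchored to published numbers and are validated by unit oracles
and property tests instead. Using printed 3-dp scores as inputs leaves a
small rounding drift: the recomputed applicability cut-off is 5.2034 against
a published 5.204.

## Synthetic panel generator

The generator emulates the study conditions: 25 experts by default with the
study's involvement distribution (9 specialists, 9 high, 6 moderate, 1 low),
rating criteria on both dimensions. Response model: each criterion has a
latent true score per dimension in [1, 5]; an expert's rating is
`clip(round(true + N(0, noise_sd)), 1, 5)`. This is the simplest model with
a single controllable consensus parameter; no response-model information
exists for the reference panel, so the generator is a stand-in, and it does
**not** emulate inter-expert correlation, response styles, questionnaire
fatigue, or any coupling between the two dimensions. Passing recovery tests
therefore show the pipeline's internal consistency under the assumed model,
not its behavior on real panels. The generator is deliberately not
calibrated to reproduce the published aggregate scores (under-determined
from printed data).

Defaults: `noise_sd = 0.5` latent-Likert units, chosen as a
moderate-consensus level (roughly one half-step of reporting scatter, which
keeps a 25-expert panel's aggregate stable without making recovery trivial).
Involvement is independent of rating behavior by default; the optional
`expertise_bias ∈ [0, 1]` hook scales expert noise by
`1 − bias·(level − 1)/4` so the effect of involvement weighting can be
studied in isolation. One seeded generator drives the entire draw, so a
config plus seed reproduces a panel byte-for-byte.

The rank-recovery experiment runs the full pipeline per replicate and
reports (a) the Spearman correlation between the latent relevance scores of
the criteria that survive screening and their recovered closeness
coefficients, and (b) the false-exclusion rate: the fraction of criteria
above the latent mean on both dimensions that screening nevertheless
excludes. Replicate seeds are spawned from the master seed via
`SeedSequence`. The standard stochastic setting (21 criteria with latent
scores equally spaced 2.0–4.5 on both dimensions, `noise_sd = 0.5`,
25 experts, 200 replicates) yields a median Spearman around 0.96; the
recovery test asserts ≥ 0.9, a threshold fixed by a Monte-Carlo run of this
setting before the suite was frozen. The acceptance script uses the same
sizes (27-criterion fixture stages, 200-replicate recovery), which complete
in well under a minute.

## Degenerate inputs and numerical choices

* Panels need ≥ 2 experts per criterion; incomplete panels are rejected with
  the full list of missing (expert, criterion, dimension) cells.
* Survey validation collects all problems (bad header, out-of-range or
  non-integer ratings, unknown dimensions, duplicate cells, inconsistent
  involvement) into one structured error citing row numbers.
* All distances and coefficients are computed in double precision;
  comparisons in tests use 1e-12 for algebraic identities and the printed
  precision for fixture reproductions.
* Pipeline reports are staged in a temporary directory and moved into place
  only on success, so a failing stage leaves no partial outputs.

## Known limitations

* The TOPSIS stage has no published intermediate values to reproduce, so the
  choice between ideal-solution conventions rests on the per-column reading
  of the reference procedure, not on a numeric anchor.
* Only component-wise product arithmetic is applied to TFNs; no alpha-cut or
  extension-principle machinery is provided.
* The synthetic generator's independence assumptions (across experts,
  criteria and dimensions) are optimistic; real panels exhibit halo effects
  and correlated severity that would lower recovery performance.
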