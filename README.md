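# panelrank

Expert-panel criteria screening and prioritization with fuzzy multi-criteria
decision analysis, built for clinical decision-support work in longitudinal
obesity management.

Clinicians designing data-driven obesity care need to decide *which* patient
criteria — dietary patterns, psychological factors, biological mechanisms,
environmental exposures, treatment-adherence barriers — are worth collecting
and weighting. `panelrank` implements the full elicitation-analysis pipeline
used to answer that question from a multidisciplinary expert panel:

1. **Fuzzy Delphi screening.** Each expert rates every candidate criterion on
   two five-point Likert dimensions, *relevance* (clinical importance) and
   *applicability* (feasibility of routine data collection). Ratings map to
   triangular fuzzy numbers (TFNs) on a 1–9 scale — level *k* ↦ (1,1,1),
   (1,3,5), (3,5,7), (5,7,9), (7,9,9) — and the panel's judgment of criterion
   *i* aggregates to

   (Lᵢ, Mᵢ, Uᵢ) = (min over experts of l, geometric mean of m, max of u),

   defuzzified by the centroid Gᵢ = (Lᵢ + Mᵢ + Uᵢ)/3. The mean of the Gᵢ
   per dimension is that dimension's cut-off α; criteria with Gᵢ > α on both
   dimensions are retained (quadrant Q1), on neither excluded (Q3), and on
   exactly one retained with caution (Q2/Q4).

2. **Involvement-weighted fuzzy TOPSIS.** Over the retained criteria, a
   criteria × experts fuzzy decision matrix is normalized per expert column
   (benefit-type: divide by the column max upper bound), weighted by each
   expert's professional-involvement TFN (normalized component-wise so each
   component family sums to 1), and scored by summed vertex distances

   d(x̃, z̃) = √(⅓[(l_x−l_z)² + (m_x−m_z)² + (u_x−u_z)²])

   to the fuzzy positive and negative ideal solutions, giving the closeness
   coefficient CCᵢ = Dᵢ⁻/(Dᵢ⁺ + Dᵢ⁻) ∈ [0, 1] per dimension.

3. **Fusion.** The unified priority is the arithmetic mean
   μᵢ = (CCᵢ_relevance + CCᵢ_applicability)/2; the relevance CC doubles as the
   priority value *p* attached to each criterion in the machine-readable
   framework annotation.

The package also ships a synthetic-panel generator (latent true scores +
Gaussian reporting noise, study-matched involvement distribution) so the whole
pipeline can be exercised and validated by rank-recovery experiments, and
packaged reference fixtures — the 27-criterion catalog, the reference study's
published per-criterion Gᵢ scores and closeness coefficients — so the
screening and fusion stages can be reproduced even though the underlying
25-expert survey is not public.

## Worked example

Reproduce the screening and unified ranking from the packaged reference
fixtures:

```sh
panelrank reproduce --out reports/
```

prints

```json
{
  "alpha": {
    "relevance": 6.255111111111112,
    "applicability": 5.203444444444444
  },
  "excluded": ["C11", "C12", "C14", "C15", "C18", "C20"],
  "retained_with_caution": ["C4", "C9", "C13", "C25", "C26"],
  "n_retained_q1": 16
}
```

i.e. the relevance cut-off is α = 6.255 and the applicability cut-off
α = 5.203; six criteria (genetics, hormonal imbalances, metabolic
alterations, epigenetics, endocrine disruptors, urban infrastructure) fall
below both cut-offs and are excluded; five show a relevance/applicability
asymmetry and are retained with caution; the remaining sixteen are retained
outright. The written `reports/unified_ranking.csv` starts

```
criterion,cc_relevance,rank_relevance,cc_applicability,rank_applicability,mu,rank_unified
C21,0.73,5,0.67,1,0.7,1
C23,0.72,8,0.65,2,0.69,2
C2,0.75,1,0.61,4,0.68,3
```

— biological consequences of obesity (C21, μ = 0.70) head the unified
priority list, followed by behavioral consequences (C23, μ = 0.69) and
ultra-processed-food-heavy diet (C2, μ = 0.68).

Running the pipeline end-to-end on your own (or synthetic) survey data:

```sh
panelrank simulate --config panel.yaml --seed 42 --out survey.csv
panelrank run survey.csv --out reports/
```

writes per-stage CSV/JSON reports, the relevance-vs-applicability quadrant
plot, and a run manifest recording the input hash, linguistic scales,
ideal-solution convention and rounding mode. Every stage (`validate`, `fdm`,
`screen`, `topsis`, `rank`) is also invocable on its own; the same
functionality is available as a library (`panelrank.screen_panel`,
`panelrank.rank_criteria`, `panelrank.unify`, ...).

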