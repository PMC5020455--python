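# smsfreq

How often do you need to measure a recovering pain cohort?

`smsfreq` studies that question for weekly patient-reported outcomes of
the kind collected by SMS: each week, subjects with an episode of
non-specific low back pain report the **Number of Bothersome Days**
(NBD, an integer 0–7) over 26 weeks. Most such patients improve and
then settle into a steady state, so a *measurement-frequency design* —
the subset of the 26 weeks at which you actually ask — determines how
well you can recover the subgroups, trajectories and risk estimates
that the full weekly schedule would give. The package is written for
biostatisticians and epidemiologists planning longitudinal follow-up
schedules with repeated count outcomes.

## What it computes

Six designs are compared: **A** all 26 weeks (reference), **B** first
8, **C** first 13, **D** first 8 + every 4th week + week 26 (13),
**E** every other week + week 26 (14), **F** first 18.

1. **Trajectory model.** Each subject's course is a continuous
   two-phase linear spline with a free knot,

   `y(t) = β₀ + β₁ (t − t₀) + (β₂ − β₁) max(0, t − κ)`,

   fitted by exhaustive search over integer candidate knots κ with
   ordinary least squares per candidate. The four parameters
   (β₀, β₁, β₂, κ) summarise intercept, early slope, late slope and
   the week of the trend break.
2. **Clustering.** The standardized parameters are grouped by Ward's
   minimum-variance hierarchical clustering, consolidated by K-means
   seeded at the Ward centroids; the Calinski–Harabasz pseudo-F
   selects the number of clusters when k is free.
3. **Agreement.** Each reduced design's forced 4-cluster solution is
   cross-tabulated against the reference design's, rows matched by
   optimal assignment, and scored with Cohen's κ and the
   quadratic-weighted κ (weights `1 − (i−j)²/(k−1)²`, clusters ranked
   from fastest to no improvement). Landis–Koch bands: >0.75
   excellent, 0.40–0.75 fair to good, <0.40 poor.
4. **Trajectory extrapolation.** Cluster mean trajectories under each
   design are extended to week 26 along the members' fitted post-knot
   lines, exposing what short schedules miss.
5. **Weekly relative risk.** For every measured week a log-binomial
   GLM (`NBD ~ Binomial(7, p)`, `log p = α + β·duration`) estimates
   the relative risk of a bothersome day for subjects with >30 days of
   pain in the prior year vs ≤30 days.

Because weekly SMS pain series of this kind are not publicly
deposited, the package ships a synthetic-cohort generator
(`smsfreq.synthetic`) that emulates the assumed structure: a
four-archetype mixture of piecewise-linear trajectories (fast, normal
and slow improvers plus an indifferent group), Binomial(7, p_t) weekly
counts, ~3 % missing replies, occasional constant repliers, and a
duration covariate associated with recovery speed. The published 4×4
agreement tables from the original weekly-SMS study are shipped as
in-repo reference data and are reproduced exactly.

## Worked example

```sh
$ smsfreq kappa-verify
design  kappa  weighted_kappa interpretation  printed_kappa  printed_weighted_kappa
     B  0.272           0.548   fair-to-good          0.272                   0.548
     C  0.348           0.611   fair-to-good          0.348                   0.611
     D  0.618           0.720   fair-to-good          0.618                   0.720
     E  0.642           0.823      excellent          0.642                   0.823
     F  0.611           0.708   fair-to-good          0.611                   0.708
all published kappa values reproduced to 3 decimals
```

Each row recomputes, from the published contingency table alone, how
well that design's forced four clusters agree with the full-data
clusters: measuring every other week (E) reaches weighted κ = 0.823 —
excellent agreement — while stopping at week 8 (B) falls to 0.548.

The full pipeline on a synthetic cohort:

```sh
$ smsfreq run --seed 1 --out study_out
```

or, as a Python library:

```python
import smsfreq as sf

report = sf.run_study(sf.RunConfig(cohort_spec=sf.CohortSpec(), seed=1))
print(report.agreement_frame())   # κ / weighted κ per design vs A
print(report.optimal_k_frame())   # free Calinski-Harabasz search
```

The numbered scripts under `analysis/` run the same steps as a
narrative: `01` simulates the cohort (129 subjects, 2.6 % missing at
seed 1), `02` cleans and imputes (120 kept, 67 cells imputed), `03`
fits the splines (mean fitted knots 3.2 / 8.6 / 14.3 weeks for the
fast / normal / slow archetypes), `04` clusters all designs and scores
agreement, `05` extrapolates trajectories, `06` estimates weekly RR
(1.14 at week 1 rising to a plateau of 2.69 — the long-duration group
stays bothered while short-duration subjects recover), and `07`
verifies the published κ values. Outputs land in `results/`.

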