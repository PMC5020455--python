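"""Simulate the study cohort.

Generates the default synthetic cohort — 129 subjects over 26 weeks,
four trajectory archetypes (fast/normal/slow improvers + indifferent),
Binomial(7, p_t) weekly bothersome-day counts, ~2.9% missing replies,
a few constant repliers, and a prior-pain-duration covariate linked to
recovery speed — and writes it as the long-format series CSV plus the
covariates CSV.
"""

from pathlib import Path

from smsfreq import CohortSpec, generate_cohort, write_cohort_csv

SEED = 1
OUT = Path("results/cohort")


def main() -> None:
    spec = CohortSpec(seed=SEED)
    cohort = generate_cohort(spec)
    OUT.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(cohort, OUT / "series.csv", OUT / "covariates.csv")

    n_missing = sum((~s.observed).sum() for s in cohort)
    n_cells = sum(len(s.weeks) for s in cohort)
    print(f"cohort: {cohort.n_subjects} subjects x {spec.n_weeks} weeks (seed {SEED})")
    print(f"missing replies: {n_missing}/{n_cells} ({100 * n_missing / n_cells:.1f}%)")
    print("archetype sizes:")
    print(cohort.covariates["true_archetype"].value_counts().to_string())
    print(f"wrote {OUT}/series.csv and {OUT}/covariates.csv")


if __name__ == "__main__":
    main()
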