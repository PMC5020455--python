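"""Apply the eligibility, imputation and constant-replier rules.

Subjects need >= 24 of 26 weekly replies and a complete duration
covariate; remaining missing weeks are imputed from the nearest
observations before and after; zero-variance repliers are removed.
Writes the cleaned cohort and the exclusion log.
"""

from pathlib import Path

from smsfreq import clean_cohort, read_cohort, write_cohort_csv
from smsfreq.ingest import exclusions_frame

IN = Path("results/cohort")
OUT = Path("results/clean")


def main() -> None:
    if not (IN / "series.csv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cohort = read_cohort(IN / "series.csv", IN / "covariates.csv")
    cleaned, log = clean_cohort(cohort)

    OUT.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(cleaned, OUT / "series.csv", OUT / "covariates.csv")
    exclusions_frame(log).to_csv(OUT / "exclusions.csv", index=False)

    n_imputed = sum(s.imputed.sum() for s in cleaned)
    n_cells = sum(len(s.weeks) for s in cleaned)
    print(f"kept {cleaned.n_subjects}/{cohort.n_subjects} subjects; "
          f"excluded {len(log)} (see {OUT}/exclusions.csv)")
    print(f"imputed {n_imputed} cells ({100 * n_imputed / n_cells:.1f}%)")


if __name__ == "__main__":
    main()
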