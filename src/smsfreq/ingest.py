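"""Cohort ingestion, eligibility filtering and imputation.

The cleaning rules mirror the source study's protocol: subjects need at
least 24 of 26 weekly replies and a complete set of baseline covariates;
missing weekly values are imputed from the observations closest in time
before and after the gap; and constant repliers (zero within-subject
variance, e.g. NBD = 7 every week) are removed because the per-subject
spline regression needs variability.

Operation order is eligibility filter -> impute -> remove constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MAX_NBD, Cohort, SubjectSeries

MIN_REPLIES_DEFAULT = 24


@dataclass
class Exclusion:
    subject_id: str
    reason: str


def read_cohort(series_path, covariates_path) -> Cohort:
    """Read a long-format series CSV plus a covariates CSV.

    Expected headers: ``subject_id,week,nbd`` (week 1-based, blank nbd =
    missing) and ``subject_id,duration_gt30[,...]``.  Raw nbd values
    must be integers in [0, 7]; duplicate (subject, week) rows and
    out-of-range values are rejected with the offending row number.
    """
    long = pd.read_csv(series_path, dtype={"subject_id": str})
    need = {"subject_id", "week", "nbd"}
    if not need.issubset(long.columns):
        raise ValueError(f"series CSV must have columns {sorted(need)}")

    nbd = pd.to_numeric(long["nbd"], errors="coerce")
    bad = long.index[long["nbd"].notna() & nbd.isna()]
    if len(bad):
        raise ValueError(f"non-numeric nbd at data row {bad[0] + 2}")
    observed = nbd.notna()
    vals = nbd[observed]
    offgrid = vals.index[(vals < 0) | (vals > MAX_NBD) | (vals != vals.round())]
    if len(offgrid):
        raise ValueError(
            f"nbd outside integer range [0, {MAX_NBD}] at data row {offgrid[0] + 2}"
        )
    dup = long.duplicated(subset=["subject_id", "week"])
    if dup.any():
        raise ValueError(f"duplicate (subject_id, week) at data row {dup.idxmax() + 2}")

    covariates = pd.read_csv(covariates_path, dtype={"subject_id": str}).set_index(
        "subject_id"
    )
    series_ids = list(dict.fromkeys(long["subject_id"]))
    unknown = set(covariates.index) - set(series_ids)
    if unknown:
        warnings.warn(
            f"covariates for unknown subject_id(s) ignored: {sorted(unknown)}",
            stacklevel=2,
        )

    all_weeks = np.arange(1, int(long["week"].max()) + 1)
    series = []
    for sid, grp in long.assign(nbd=nbd).groupby("subject_id", sort=False):
        row = grp.set_index("week")["nbd"].reindex(all_weeks)
        values = row.to_numpy(dtype=float)
        series.append(
            SubjectSeries(
                subject_id=sid,
                weeks=all_weeks,
                values=values,
                observed=np.isfinite(values),
            )
        )
    covariates = covariates.reindex([s.subject_id for s in series])
    return Cohort(series=series, covariates=covariates)


def eligibility_filter(
    cohort: Cohort,
    min_replies: int = MIN_REPLIES_DEFAULT,
    required_covariates: tuple[str, ...] = ("duration_gt30",),
) -> tuple[Cohort, list[Exclusion]]:
    """Keep subjects with enough observed weeks and full covariates."""
    n_weeks = max(len(s.weeks) for s in cohort.series)
    if min_replies > n_weeks:
        raise ValueError("min_replies exceeds the number of study weeks")
    kept, log = [], []
    for s in cohort.series:
        if s.n_observed < min_replies:
            log.append(Exclusion(s.subject_id, f"replies {s.n_observed} < {min_replies}"))
            continue
        cov = (
            cohort.covariates.loc[s.subject_id]
            if s.subject_id in cohort.covariates.index
            else None
        )
        missing_cov = [
            c
            for c in required_covariates
            if cov is None or c not in cov.index or pd.isna(cov[c])
        ]
        if missing_cov:
            log.append(Exclusion(s.subject_id, f"missing covariate {missing_cov[0]}"))
            continue
        kept.append(s.copy())
    if not kept:
        raise ValueError("eligibility filter excluded every subject")
    return _subset(cohort, kept), log


def remove_constant(cohort: Cohort) -> tuple[Cohort, list[Exclusion]]:
    """Drop subjects whose complete series has zero variance."""
    kept, log = [], []
    for s in cohort.series:
        if s.is_constant:
            log.append(Exclusion(s.subject_id, "constant reply"))
        else:
            kept.append(s.copy())
    return _subset(cohort, kept), log


def impute(series: SubjectSeries) -> SubjectSeries:
    """Fill missing weeks from the observations closest in time.

    An interior gap takes the mean of the nearest observed values before
    and after it — realised as linear interpolation between the flanking
    observations, which coincides with the two-sided mean for one-week
    gaps.  Missing weeks at either end copy the nearest observed value.
    Imputed values may be fractional.
    """
    if series.n_observed == 0:
        raise ValueError(f"{series.subject_id}: cannot impute an all-missing series")
    out = series.copy()
    if out.is_complete:
        return out
    obs = np.isfinite(out.values)
    filled = np.interp(
        out.weeks.astype(float), out.weeks[obs].astype(float), out.values[obs]
    )
    out.imputed = out.imputed | ~obs
    out.values = np.where(obs, out.values, filled)
    return out


def impute_cohort(cohort: Cohort) -> Cohort:
    return _subset(cohort, [impute(s) for s in cohort.series])


def clean_cohort(
    cohort: Cohort,
    min_replies: int = MIN_REPLIES_DEFAULT,
    required_covariates: tuple[str, ...] = ("duration_gt30",),
) -> tuple[Cohort, list[Exclusion]]:
    """Full cleaning pass: eligibility -> imputation -> constants."""
    kept, log = eligibility_filter(cohort, min_replies, required_covariates)
    kept = impute_cohort(kept)
    kept, log2 = remove_constant(kept)
    return kept, log + log2


def rounded_values(series: SubjectSeries) -> np.ndarray:
    """Integer NBD for the binomial risk model: ties round away from zero."""
    return np.clip(np.floor(series.values + 0.5), 0, MAX_NBD)


def exclusions_frame(log: list[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.subject_id, e.reason) for e in log], columns=["subject_id", "reason"]
    )


def _subset(cohort: Cohort, series: list[SubjectSeries]) -> Cohort:
    ids = [s.subject_id for s in series]
    return Cohort(series=series, covariates=cohort.covariates.reindex(ids))
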