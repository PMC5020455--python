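"""Week-wise relative risk of a bothersome day from a log-binomial GLM.

Each study week is modelled separately: a subject's NBD that week is
Binomial(7, p), and ``log p`` is regressed on a single binary factor —
prior pain duration >30 days (index) vs <=30 days (reference).  The
exponentiated coefficient is the relative risk (RR) of a bothersome day
for the index group.

With one binary covariate the maximum-likelihood RR has a closed form,
the ratio of the two group mean proportions; the iteratively reweighted
least squares fit must agree with it to high precision, which doubles
as an internal consistency check.  Wald 95% intervals on the log scale
are reported alongside (the point estimates are the primary output).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .cohort import MAX_NBD, Cohort
from .designs import DesignOption
from .ingest import rounded_values

Z975 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class WeeklyRR:
    week: int
    rr: float
    ci_low: float
    ci_high: float
    converged: bool
    n_index: int
    n_ref: int
    note: str = ""


def _week_counts(cohort: Cohort, week: int, group) -> tuple[np.ndarray, np.ndarray]:
    """Integer NBD at one week, split by the binary group factor."""
    if isinstance(group, str):
        group = cohort.covariates[group]
    g = np.asarray(pd.Series(group).reindex(cohort.subject_ids)
                   if isinstance(group, pd.Series) else group, dtype=float)
    if g.shape[0] != cohort.n_subjects or not np.isin(g, (0, 1)).all():
        raise ValueError("group must be a 0/1 factor aligned with the cohort")
    counts = np.array(
        [rounded_values(s)[np.where(s.weeks == week)[0][0]] for s in cohort.series]
    )
    return counts[g == 1], counts[g == 0]


def closed_form_rr(index_counts: np.ndarray, ref_counts: np.ndarray) -> float:
    """ML relative risk for a single binary covariate: ratio of group
    mean proportions (equivalently of group mean NBD)."""
    ref_mean = ref_counts.mean()
    if ref_mean == 0:
        raise ZeroDivisionError("reference group mean is 0: RR undefined")
    return float(index_counts.mean() / ref_mean)


def weekly_rr(
    cohort: Cohort,
    group,
    week: int,
    continuity_correction: bool = False,
) -> WeeklyRR:
    """Log-binomial GLM for one week; see module docstring.

    A zero-mean reference group makes the RR undefined (flagged, not
    corrected); ``continuity_correction=True`` instead adds 0.5 events
    and 0.5 non-events to each group before estimation.
    """
    idx, ref = _week_counts(cohort, week, group)
    if idx.size == 0 or ref.size == 0:
        raise ValueError("both duration groups must be non-empty")
    n_index, n_ref = int(idx.size), int(ref.size)

    s_idx, n_idx_tr = float(idx.sum()), MAX_NBD * n_index
    s_ref, n_ref_tr = float(ref.sum()), MAX_NBD * n_ref
    if continuity_correction:
        s_idx, n_idx_tr = s_idx + 0.5, n_idx_tr + 1.0
        s_ref, n_ref_tr = s_ref + 0.5, n_ref_tr + 1.0

    if s_ref == 0:
        return WeeklyRR(week, float("nan"), float("nan"), float("nan"),
                        False, n_index, n_ref, note="reference mean 0: RR undefined")
    if s_idx == 0:
        return WeeklyRR(week, 0.0, 0.0, float("nan"),
                        False, n_index, n_ref, note="index mean 0: RR at boundary")

    if continuity_correction:
        # The corrected estimate is the closed form on adjusted totals.
        rr, lo, hi = _wald_from_totals(s_idx, n_idx_tr, s_ref, n_ref_tr)
        return WeeklyRR(week, rr, lo, hi, True, n_index, n_ref,
                        note="continuity-corrected")
    rr, lo, hi, converged, note = _fit_log_binomial(idx, ref, s_idx, n_idx_tr, s_ref, n_ref_tr)
    return WeeklyRR(week, rr, lo, hi, converged, n_index, n_ref, note=note)


def _wald_from_totals(
    s_idx: float, n_idx: float, s_ref: float, n_ref: float
) -> tuple[float, float, float]:
    p_idx, p_ref = s_idx / n_idx, s_ref / n_ref
    b1 = np.log(p_idx) - np.log(p_ref)
    se = np.sqrt((1 - p_idx) / (n_idx * p_idx) + (1 - p_ref) / (n_ref * p_ref))
    return float(np.exp(b1)), float(np.exp(b1 - Z975 * se)), float(np.exp(b1 + Z975 * se))


def _fit_log_binomial(
    idx: np.ndarray, ref: np.ndarray,
    s_idx: float, n_idx: float, s_ref: float, n_ref: float,
) -> tuple[float, float, float, bool, str]:
    """IRLS fit of log p ~ group on per-subject binomial counts, with a
    closed-form fallback (exact here because the covariate is binary)."""
    counts = np.concatenate([ref, idx]).astype(float)
    endog = np.column_stack([counts, MAX_NBD - counts])
    exog = sm.add_constant(
        np.concatenate([np.zeros(ref.size), np.ones(idx.size)]), prepend=True
    )
    p_pool = (s_ref + s_idx) / (n_ref + n_idx)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, exog, family=sm.families.Binomial(sm.families.links.Log())).fit(
                start_params=[np.log(p_pool), 0.0], maxiter=200, tol=1e-10
            )
        if not res.converged or not np.isfinite(res.params).all():
            raise RuntimeError("IRLS did not converge")
        b1 = float(res.params[1])
        se = float(res.bse[1])
        return float(np.exp(b1)), float(np.exp(b1 - Z975 * se)), float(np.exp(b1 + Z975 * se)), True, ""
    except Exception as err:  # fall back to the exact closed form
        rr, lo, hi = _wald_from_totals(s_idx, n_idx, s_ref, n_ref)
        return rr, lo, hi, False, f"closed-form fallback: {err}"


def rr_profile(
    cohort: Cohort,
    group,
    option: DesignOption,
    continuity_correction: bool = False,
) -> list[WeeklyRR]:
    """Weekly RR at every week the design measures, in week order.

    Non-converged weeks are carried through with their flags set, never
    dropped.
    """
    return [
        weekly_rr(cohort, group, int(w), continuity_correction=continuity_correction)
        for w in option.weeks
    ]


def profile_frame(design: str, profile: list[WeeklyRR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "design": design,
                "week": r.week,
                "rr": r.rr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "converged": r.converged,
                "n_index": r.n_index,
                "n_ref": r.n_ref,
            }
            for r in profile
        ]
    )
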