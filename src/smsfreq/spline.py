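"""Per-subject two-phase linear spline regression with a free knot.

Each subject's pain course is summarised by a continuous piecewise-
linear model with one break:

    value(t) = intercept + slope1 * (t - t0) + (slope2 - slope1) * max(0, t - knot)

where ``t0`` is the first fitted week.  The four parameters (intercept,
pre-knot slope, post-knot slope, knot week) feed the trajectory
clustering.  The knot is estimated by an exhaustive search over integer
candidate weeks, with ordinary least squares for the segment
coefficients at each candidate — deterministic, reproducible, and exact
when the true knot lies on the candidate grid.  Weekly data do not
identify sub-week knot positions, so nothing is lost by the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

MIN_POINTS = 5


@dataclass(frozen=True)
class SplineFit:
    """Fitted trajectory parameters for one subject."""

    subject_id: str
    intercept: float  # fitted NBD at the first fitted week (days)
    slope1: float  # pre-knot slope (days/week)
    slope2: float  # post-knot slope (days/week)
    knot: float  # estimated break week
    sse: float  # residual sum of squares (days^2)
    n_obs: int
    first_week: int

    def predict(self, week) -> np.ndarray | float:
        """Evaluate the piecewise-linear model at any week.

        Weeks beyond the fitted range extrapolate along the post-knot
        line (the "steady state" continuation).
        """
        t = np.asarray(week, dtype=float)
        out = (
            self.intercept
            + self.slope1 * (t - self.first_week)
            + (self.slope2 - self.slope1) * np.maximum(0.0, t - self.knot)
        )
        return out if out.ndim else float(out)


def _knot_candidates(weeks: np.ndarray) -> np.ndarray:
    """Integer candidate knots: first_week+2 .. last_week-2.

    The margin keeps at least three measured points on each side for
    every design considered here (the shortest spans weeks 1..8).
    Candidates need not themselves be measured weeks, so designs with
    gaps (e.g. every other week) still search the full interior.
    """
    lo, hi = int(weeks[0]) + 2, int(weeks[-1]) - 2
    return np.arange(lo, hi + 1)


def fit_spline(
    weeks, values, subject_id: str = "", allow_constant: bool = False
) -> SplineFit:
    """Least-squares fit of the one-knot linear spline.

    The candidate knot minimising the residual sum of squares wins;
    SSE ties break to the earliest candidate, so a series that is a
    single straight line returns slope1 == slope2 deterministically.

    A constant series is rejected by default (constant repliers are
    removed upstream and carry no trajectory information).  With
    ``allow_constant=True`` — used when a design's week subset makes an
    otherwise-varying subject locally flat — the exact degenerate
    solution is returned: both slopes 0, knot at the earliest
    candidate, SSE 0.
    """
    weeks = np.asarray(weeks, dtype=float)
    values = np.asarray(values, dtype=float)
    if weeks.ndim != 1 or weeks.shape != values.shape:
        raise ValueError("weeks and values must be 1-D and equal length")
    if len(weeks) < MIN_POINTS:
        raise ValueError(f"need >= {MIN_POINTS} points, got {len(weeks)}")
    if np.unique(weeks).size < len(weeks) or not np.all(np.diff(weeks) > 0):
        raise ValueError("weeks must be strictly increasing")
    if np.allclose(values, values[0]):
        if not allow_constant:
            raise ValueError("constant series: spline fit is degenerate")
        return SplineFit(
            subject_id=subject_id,
            intercept=float(values[0]),
            slope1=0.0,
            slope2=0.0,
            knot=float(_knot_candidates(weeks)[0]),
            sse=0.0,
            n_obs=len(weeks),
            first_week=int(weeks[0]),
        )

    t0 = weeks[0]
    best: tuple[float, float, np.ndarray] | None = None  # (sse, knot, coef)
    for knot in _knot_candidates(weeks):
        X = np.column_stack(
            [np.ones_like(weeks), weeks - t0, np.maximum(0.0, weeks - knot)]
        )
        coef, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
        resid = values - X @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(knot), coef)
    assert best is not None
    sse, knot, coef = best
    return SplineFit(
        subject_id=subject_id,
        intercept=float(coef[0]),
        slope1=float(coef[1]),
        slope2=float(coef[1] + coef[2]),
        knot=knot,
        sse=max(sse, 0.0),
        n_obs=len(weeks),
        first_week=int(t0),
    )


def fit_cohort(cohort, allow_constant: bool = False) -> list[SplineFit]:
    """Fit every subject in a (complete, post-imputation) cohort."""
    return [
        fit_spline(s.weeks, s.values, subject_id=s.subject_id,
                   allow_constant=allow_constant)
        for s in cohort
    ]


def parameter_matrix(fits: list[SplineFit], standardize: bool = True) -> np.ndarray:
    """Subjects x 4 matrix (intercept, slope1, slope2, knot).

    The four parameters mix units (days, days/week, weeks), so each
    column is centred and scaled to unit variance by default before
    clustering.  A zero-variance column is left centred with scale 1.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits")
    mat = np.array([[f.intercept, f.slope1, f.slope2, f.knot] for f in fits])
    if not standardize:
        return mat
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance parameter column(s) {np.flatnonzero(flat).tolist()}: "
            "left centred, scale 1",
            stacklevel=2,
        )
        sd = np.where(flat, 1.0, sd)
    return (mat - mean) / sd


def fits_frame(fits: list[SplineFit]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject_id": f.subject_id,
                "intercept": f.intercept,
                "slope1": f.slope1,
                "slope2": f.slope2,
                "knot": f.knot,
                "sse": f.sse,
                "n_obs": f.n_obs,
            }
            for f in fits
        ]
    )
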