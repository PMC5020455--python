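"""Per-cluster mean trajectories and extrapolation to week 26.

For each cluster under a reduced design, the trajectory over the
measured weeks is the plain mean of the member subjects' (imputed)
weekly values.  Beyond the design's last measured week, each member's
fitted post-knot line is evaluated and the member-level predictions
averaged, continuing every subject's own steady-state trend rather than
refitting the cluster mean.  Extrapolated means are clamped to the
valid NBD range [0, 7]; clamp events are logged because they signal
trajectories leaving the plausible range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MAX_NBD, Cohort
from .designs import DesignOption, N_WEEKS
from .spline import SplineFit

logger = logging.getLogger(__name__)


@dataclass
class ClusterTrajectory:
    """Weekly mean NBD for one cluster, with extrapolation flags."""

    cluster: int
    weeks: np.ndarray
    mean_nbd: np.ndarray
    is_extrapolated: np.ndarray


def cluster_mean_trajectory(
    cohort: Cohort, labels: np.ndarray, cluster: int, option: DesignOption
) -> ClusterTrajectory:
    """Mean of member series at each measured week (no extrapolation)."""
    members = _member_ids(cohort, labels, cluster)
    weeks = option.week_array()
    mat = cohort.value_matrix().loc[members, weeks]
    return ClusterTrajectory(
        cluster=cluster,
        weeks=weeks,
        mean_nbd=mat.mean(axis=0).to_numpy(),
        is_extrapolated=np.zeros(len(weeks), dtype=bool),
    )


def extrapolate(
    cohort: Cohort,
    fits: list[SplineFit],
    labels: np.ndarray,
    cluster: int,
    option: DesignOption,
    n_weeks: int = N_WEEKS,
) -> ClusterTrajectory:
    """Full 1..n_weeks trajectory: measured means, then averaged
    member-level post-knot extrapolation."""
    members = set(_member_ids(cohort, labels, cluster))
    measured = cluster_mean_trajectory(cohort, labels, cluster, option)
    last = int(option.weeks[-1])
    extra_weeks = np.arange(last + 1, n_weeks + 1)
    if extra_weeks.size == 0:
        return measured

    member_fits = [f for f in fits if f.subject_id in members]
    if not member_fits:
        raise ValueError(f"cluster {cluster} has no fitted members")
    preds = np.stack([np.asarray(f.predict(extra_weeks)) for f in member_fits])
    mean_extra = preds.mean(axis=0)
    clamped = np.clip(mean_extra, 0.0, MAX_NBD)
    n_clamped = int(np.sum(clamped != mean_extra))
    if n_clamped:
        logger.warning(
            "cluster %d: clamped %d extrapolated week(s) into [0, %d]",
            cluster, n_clamped, MAX_NBD,
        )
    return ClusterTrajectory(
        cluster=cluster,
        weeks=np.concatenate([measured.weeks, extra_weeks]),
        mean_nbd=np.concatenate([measured.mean_nbd, clamped]),
        is_extrapolated=np.concatenate(
            [measured.is_extrapolated, np.ones(extra_weeks.size, dtype=bool)]
        ),
    )


def design_trajectories(
    cohort: Cohort,
    fits: list[SplineFit],
    labels: np.ndarray,
    option: DesignOption,
    n_weeks: int = N_WEEKS,
) -> list[ClusterTrajectory]:
    """Extrapolated trajectory for every cluster, ascending label."""
    return [
        extrapolate(cohort, fits, labels, c, option, n_weeks=n_weeks)
        for c in sorted(np.unique(np.asarray(labels, dtype=int)))
    ]


def trajectories_frame(design: str, trajectories: list[ClusterTrajectory]) -> pd.DataFrame:
    rows = [
        {
            "design": design,
            "cluster": t.cluster,
            "week": int(w),
            "mean_nbd": float(m),
            "is_extrapolated": bool(e),
        }
        for t in trajectories
        for w, m, e in zip(t.weeks, t.mean_nbd, t.is_extrapolated)
    ]
    return pd.DataFrame(rows)


def _member_ids(cohort: Cohort, labels: np.ndarray, cluster: int) -> list[str]:
    labels = np.asarray(labels, dtype=int)
    ids = np.asarray(cohort.subject_ids)
    if labels.shape[0] != ids.shape[0]:
        raise ValueError("labels length must match cohort size")
    members = ids[labels == cluster].tolist()
    if not members:
        raise ValueError(f"cluster {cluster} is empty")
    return members
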