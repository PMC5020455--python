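"""In-memory containers for weekly pain-course cohorts.

The repeated outcome is the Number of Bothersome Days (NBD): for each
study week a subject reports on how many of the past 7 days their low
back pain affected daily activities, an integer count in [0, 7].  A
cohort bundles one weekly series per subject with per-subject baseline
covariates (at minimum the binary prior-pain-duration factor,
``duration_gt30``: more than 30 days of pain in the previous year).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

N_WEEKS_DEFAULT = 26
MAX_NBD = 7


@dataclass
class SubjectSeries:
    """One subject's weekly NBD counts with missingness bookkeeping.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    weeks : ndarray of int
        Strictly increasing 1-based week indices.
    values : ndarray of float
        NBD per week; ``nan`` marks a missing reply.  Fractional values
        appear only after imputation.
    observed : ndarray of bool
        True where the subject actually replied.
    imputed : ndarray of bool
        True where a value was filled in by imputation.
    """

    subject_id: str
    weeks: np.ndarray
    values: np.ndarray
    observed: np.ndarray
    imputed: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros_like(self.observed)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if not np.all(np.diff(self.weeks) > 0):
            raise ValueError(f"{self.subject_id}: weeks must be strictly increasing")
        if len({len(self.weeks), len(self.values), len(self.observed), len(self.imputed)}) != 1:
            raise ValueError(f"{self.subject_id}: field lengths differ")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > MAX_NBD):
            raise ValueError(f"{self.subject_id}: NBD values outside [0, {MAX_NBD}]")
        if np.any(self.imputed & self.observed):
            raise ValueError(f"{self.subject_id}: a week cannot be both observed and imputed")

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def is_complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    @property
    def is_constant(self) -> bool:
        """All available values identical (judged on the complete series)."""
        finite = self.values[np.isfinite(self.values)]
        return finite.size > 0 and bool(np.all(finite == finite[0]))

    def restrict(self, weeks: np.ndarray) -> "SubjectSeries":
        """Return a copy keeping only the given weeks (order preserved)."""
        idx = np.isin(self.weeks, weeks)
        return SubjectSeries(
            subject_id=self.subject_id,
            weeks=self.weeks[idx],
            values=self.values[idx].copy(),
            observed=self.observed[idx].copy(),
            imputed=self.imputed[idx].copy(),
        )

    def copy(self) -> "SubjectSeries":
        return replace(
            self,
            weeks=self.weeks.copy(),
            values=self.values.copy(),
            observed=self.observed.copy(),
            imputed=self.imputed.copy(),
        )


@dataclass
class Cohort:
    """An ordered collection of subject series plus baseline covariates.

    ``covariates`` is indexed by ``subject_id`` and carries at least
    ``duration_gt30`` (0/1); synthetic cohorts additionally carry the
    generating ``true_archetype`` label for recovery tests.
    """

    series: list[SubjectSeries] = field(default_factory=list)
    covariates: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=pd.Index([], name="subject_id"))
        ids = self.subject_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in cohort")

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.series]

    @property
    def n_subjects(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def __getitem__(self, subject_id: str) -> SubjectSeries:
        for s in self.series:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def value_matrix(self) -> pd.DataFrame:
        """Subjects x weeks matrix of NBD values (nan = missing)."""
        frames = {s.subject_id: pd.Series(s.values, index=s.weeks) for s in self.series}
        mat = pd.DataFrame(frames).T
        mat.index.name = "subject_id"
        mat.columns.name = "week"
        return mat.loc[self.subject_ids]

    def to_long(self) -> pd.DataFrame:
        """Long-format table: subject_id, week, nbd (NaN when missing)."""
        rows = [
            (s.subject_id, int(w), v)
            for s in self.series
            for w, v in zip(s.weeks, s.values)
        ]
        return pd.DataFrame(rows, columns=["subject_id", "week", "nbd"])

    def copy(self) -> "Cohort":
        return Cohort(
            series=[s.copy() for s in self.series],
            covariates=self.covariates.copy(),
        )
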