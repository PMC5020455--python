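"""Synthetic weekly pain-course cohorts.

Real SMS follow-up data of this kind are rarely shareable, so the
pipeline ships a generator that reproduces the statistical structure the
analysis assumes: a small number of trajectory archetypes (fast, normal
and slow improvers plus an indifferent, non-improving group), each a
continuous piecewise-linear mean NBD curve with at most one trend break
(knot); weekly counts drawn Binomial(7, p_t) around the mean curve;
a few percent of replies missing at random; occasional constant
repliers; and a prior-pain-duration covariate associated with the
slower archetypes.

Everything is driven by :func:`numpy.random.default_rng`; the same seed
yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MAX_NBD, Cohort, SubjectSeries


@dataclass(frozen=True)
class ArchetypeSpec:
    """A piecewise-linear mean trajectory for one subject group.

    The expected NBD runs linearly from ``start_level`` at week 1 to
    ``end_level`` at ``knot_week`` and stays at ``end_level`` thereafter
    (the "steady state").  ``knot_week=None`` gives a flat course at
    ``start_level``.
    """

    name: str
    start_level: float
    knot_week: int | None
    end_level: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_level <= MAX_NBD:
            raise ValueError(f"start_level must be in [0, {MAX_NBD}]")
        if not 0 <= self.end_level <= MAX_NBD:
            raise ValueError(f"end_level must be in [0, {MAX_NBD}]")
        if self.knot_week is not None and not 2 <= self.knot_week <= 25:
            raise ValueError("knot_week must lie in [2, 25]")

    def mean_curve(self, weeks: np.ndarray) -> np.ndarray:
        """Expected NBD at each week (piecewise-linear, continuous)."""
        weeks = np.asarray(weeks, dtype=float)
        if self.knot_week is None:
            return np.full_like(weeks, float(self.start_level))
        slope = (self.end_level - self.start_level) / (self.knot_week - 1.0)
        mean = self.start_level + slope * (weeks - 1.0)
        return np.where(weeks >= self.knot_week, float(self.end_level), mean)


#: Default archetypes: start level / knot week / steady-state level.
#: Chosen to emulate a care-seeking low back pain cohort in which most
#: subjects improve, at different speeds, and a minority do not.
DEFAULT_ARCHETYPES: tuple[ArchetypeSpec, ...] = (
    ArchetypeSpec("fast", start_level=5.0, knot_week=3, end_level=1.0),
    ArchetypeSpec("normal", start_level=5.0, knot_week=8, end_level=1.0),
    ArchetypeSpec("slow", start_level=6.0, knot_week=15, end_level=2.0),
    ArchetypeSpec("indifferent", start_level=6.0, knot_week=None, end_level=6.0),
)

#: Archetypes counted as "slow recovery" for the duration covariate.
SLOW_ARCHETYPES = frozenset({"slow", "indifferent"})


@dataclass
class CohortSpec:
    """Configuration of a synthetic cohort.

    Parameters
    ----------
    n_subjects : int
        Cohort size before any exclusion.
    n_weeks : int
        Follow-up length in weeks.
    archetypes : tuple of ArchetypeSpec
        Trajectory groups.
    mixture : tuple of float
        Group proportions, same order as ``archetypes``; must sum to 1.
    missing_rate : float
        Probability that any single weekly reply is absent.
    constant_rate : float
        Probability that a subject replies one constant value all weeks.
    duration_assoc : (float, float)
        P(duration_gt30 = 1) for subjects in a slow/indifferent
        archetype and for subjects in a fast/normal archetype.
    overdispersion : float
        Beta-binomial overdispersion rho in [0, 1); 0 (default) gives
        plain binomial weekly counts.
    seed : int
        RNG seed; identical seeds give bit-identical cohorts.
    """

    n_subjects: int = 129
    n_weeks: int = 26
    archetypes: tuple[ArchetypeSpec, ...] = DEFAULT_ARCHETYPES
    mixture: tuple[float, ...] = (0.13, 0.49, 0.18, 0.20)
    missing_rate: float = 0.029
    constant_rate: float = 0.03
    duration_assoc: tuple[float, float] = (0.9, 0.25)
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_weeks < 2:
            raise ValueError("n_weeks must be >= 2")
        mix = np.asarray(self.mixture, dtype=float)
        if len(mix) != len(self.archetypes):
            raise ValueError("mixture length must match number of archetypes")
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("mixture must be non-negative and sum to 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.constant_rate <= 1:
            raise ValueError("constant_rate must be in [0, 1]")
        if not 0 <= self.overdispersion < 1:
            raise ValueError("overdispersion must be in [0, 1)")
        for p in self.duration_assoc:
            if not 0 <= p <= 1:
                raise ValueError("duration_assoc probabilities must be in [0, 1]")


def _draw_weekly_counts(
    p: np.ndarray, rng: np.random.Generator, overdispersion: float
) -> np.ndarray:
    """Binomial(7, p_t) counts; beta-binomial if overdispersion > 0."""
    if overdispersion > 0.0:
        # Beta(a, b) with mean p and intra-class correlation rho.
        s = (1.0 - overdispersion) / overdispersion
        pc = np.clip(p, 1e-12, 1 - 1e-12)
        p = rng.beta(pc * s, (1.0 - pc) * s)
    return rng.binomial(MAX_NBD, p)


def generate_subject(
    archetype: ArchetypeSpec,
    n_weeks: int,
    rng: np.random.Generator,
    subject_id: str = "S1",
    overdispersion: float = 0.0,
) -> SubjectSeries:
    """Draw one subject's weekly NBD counts around the archetype mean.

    Week ``t`` is Binomial(7, p_t) with ``7 * p_t`` the archetype's
    piecewise-linear mean curve.  No missingness is applied here.
    """
    if n_weeks < 2:
        raise ValueError("n_weeks must be >= 2")
    weeks = np.arange(1, n_weeks + 1)
    p = archetype.mean_curve(weeks) / MAX_NBD
    values = _draw_weekly_counts(p, rng, overdispersion).astype(float)
    return SubjectSeries(
        subject_id=subject_id,
        weeks=weeks,
        values=values,
        observed=np.ones(n_weeks, dtype=bool),
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort from a :class:`CohortSpec`.

    Archetype membership is multinomial with the spec's mixture, the
    duration covariate is Bernoulli with the archetype-dependent rate,
    constant repliers repeat a single week-1 draw for all weeks, and
    missingness is injected at ``spec.missing_rate``.  The generating
    archetype is retained in the covariates as ``true_archetype``.
    """
    rng = np.random.default_rng(spec.seed)
    weeks = np.arange(1, spec.n_weeks + 1)
    groups = rng.choice(len(spec.archetypes), size=spec.n_subjects, p=spec.mixture)
    width = len(str(spec.n_subjects))

    series: list[SubjectSeries] = []
    cov_rows = []
    p_slow, p_fast = spec.duration_assoc
    for i, g in enumerate(groups):
        arch = spec.archetypes[g]
        sid = f"S{i + 1:0{width}d}"
        s = generate_subject(arch, spec.n_weeks, rng, subject_id=sid,
                             overdispersion=spec.overdispersion)
        if rng.random() < spec.constant_rate:
            # Constant replier: one draw at the starting level, repeated.
            const = rng.binomial(MAX_NBD, arch.mean_curve(weeks[:1])[0] / MAX_NBD)
            s.values[:] = float(const)
        p_dur = p_slow if arch.name in SLOW_ARCHETYPES else p_fast
        cov_rows.append(
            {
                "subject_id": sid,
                "duration_gt30": int(rng.random() < p_dur),
                "true_archetype": arch.name,
            }
        )
        series.append(s)

    covariates = pd.DataFrame(cov_rows).set_index("subject_id")
    cohort = Cohort(series=series, covariates=covariates)
    if spec.missing_rate > 0:
        cohort = inject_missingness(cohort, spec.missing_rate, rng)
    return cohort


def inject_missingness(
    cohort: Cohort, missing_rate: float, rng: np.random.Generator
) -> Cohort:
    """Mask each observed cell independently with the given probability."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    out = cohort.copy()
    for s in out.series:
        mask = rng.random(len(s.weeks)) < missing_rate
        s.values[mask] = np.nan
        s.observed[mask] = False
        s.imputed[mask] = False
    return out


def write_cohort_csv(cohort: Cohort, series_path, covariates_path) -> None:
    """Write the long-format series CSV and the covariates CSV.

    Series columns: ``subject_id, week, nbd`` with nbd blank when
    missing; covariates: ``subject_id, duration_gt30`` plus
    ``true_archetype`` when present.
    """
    long = cohort.to_long()
    # Integer-valued cells print as integers so a write/read round-trip
    # is exact on raw (pre-imputation) cohorts.
    def _fmt(v: float) -> str:
        if not np.isfinite(v):
            return ""
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    long["nbd"] = long["nbd"].map(_fmt)
    long.to_csv(series_path, index=False)
    cohort.covariates.to_csv(covariates_path)
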