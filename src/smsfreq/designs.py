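"""Measurement-frequency designs: which of the 26 weeks are measured.

Six named options are compared against the full weekly schedule:

- A: all 26 weekly measures (the reference),
- B: the first 8 weeks only,
- C: the first 13 weeks only,
- D: the first 8 weeks, then every fourth week (12, 16, 20, 24) plus
  the final week 26 — 13 measures in all,
- E: every other week (1, 3, ..., 25) plus the final week 26 — 14
  measures,
- F: the first 18 weeks.

Novel designs can be screened by constructing a :class:`DesignOption`
with an explicit week list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort

N_WEEKS = 26


@dataclass(frozen=True)
class DesignOption:
    """A named, ordered subset of the study weeks."""

    name: str
    weeks: tuple[int, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weeks, dtype=int)
        if w.size == 0:
            raise ValueError("week set must be non-empty")
        if not np.all(np.diff(w) > 0):
            raise ValueError("weeks must be strictly increasing")
        if w[0] < 1 or w[-1] > N_WEEKS:
            raise ValueError(f"weeks must lie in 1..{N_WEEKS}")

    @property
    def n_weeks(self) -> int:
        return len(self.weeks)

    def week_array(self) -> np.ndarray:
        return np.asarray(self.weeks, dtype=int)


_WEEK_SETS: dict[str, tuple[int, ...]] = {
    "A": tuple(range(1, 27)),
    "B": tuple(range(1, 9)),
    "C": tuple(range(1, 14)),
    "D": tuple(range(1, 9)) + (12, 16, 20, 24, 26),
    "E": tuple(range(1, 26, 2)) + (26,),
    "F": tuple(range(1, 19)),
}

DESIGN_NAMES = tuple(_WEEK_SETS)


def week_set(name: str) -> DesignOption:
    """Return the named design option (A-F)."""
    try:
        return DesignOption(name=name, weeks=_WEEK_SETS[name.upper()])
    except KeyError:
        raise ValueError(f"unknown design {name!r}; expected one of {DESIGN_NAMES}") from None


def all_designs() -> list[DesignOption]:
    return [week_set(n) for n in DESIGN_NAMES]


def subsample(cohort: Cohort, option: DesignOption) -> Cohort:
    """Restrict every subject's series to the design's weeks.

    The subject set is unchanged; values at shared weeks are identical
    to the full cohort's.
    """
    series = [s.restrict(option.week_array()) for s in cohort.series]
    return Cohort(series=series, covariates=cohort.covariates.copy())
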