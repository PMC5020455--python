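"""Shared test construction helpers."""

import numpy as np
import pandas as pd

from smsfreq.cohort import Cohort, SubjectSeries
from smsfreq.risk import _week_counts


def random_one_week_cohort(rng):
    """Random small cohort (constant across 5 weeks) with a random
    binary group; returns (cohort, index_counts, ref_counts)."""
    n = int(rng.integers(10, 40))
    counts = rng.binomial(7, rng.uniform(0.1, 0.9), size=n)
    groups = rng.integers(0, 2, size=n)
    if groups.sum() == 0:
        groups[0] = 1
    if groups.sum() == n:
        groups[0] = 0
    series = [
        SubjectSeries(
            subject_id=f"S{i+1}",
            weeks=np.arange(1, 6),
            values=np.full(5, float(c)),
            observed=np.ones(5, bool),
        )
        for i, c in enumerate(counts)
    ]
    cov = pd.DataFrame(
        {"duration_gt30": groups},
        index=pd.Index([s.subject_id for s in series], name="subject_id"),
    )
    cohort = Cohort(series=series, covariates=cov)
    idx, ref = _week_counts(cohort, 1, "duration_gt30")
    return cohort, idx, ref
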