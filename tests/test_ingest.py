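"""Ingestion, eligibility, constant removal and imputation rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import smsfreq as sf
from smsfreq.cohort import SubjectSeries
from smsfreq.ingest import exclusions_frame, rounded_values


def make_series(values, subject_id="S1"):
    values = np.asarray(values, dtype=float)
    return SubjectSeries(
        subject_id=subject_id,
        weeks=np.arange(1, len(values) + 1),
        values=values,
        observed=np.isfinite(values),
    )


def cohort_from_values(rows, durations=None):
    series = [make_series(v, f"S{i+1}") for i, v in enumerate(rows)]
    ids = [s.subject_id for s in series]
    cov = pd.DataFrame(
        {"duration_gt30": durations if durations is not None else [0] * len(ids)},
        index=pd.Index(ids, name="subject_id"),
    )
    return sf.Cohort(series=series, covariates=cov)


class TestReadCohort:
    def test_round_trip_preserves_cohort(self, tmp_path, default_cohort):
        sp, cp = tmp_path / "series.csv", tmp_path / "cov.csv"
        sf.write_cohort_csv(default_cohort, sp, cp)
        back = sf.read_cohort(sp, cp)
        assert back.subject_ids == default_cohort.subject_ids
        np.testing.assert_array_equal(
            back.value_matrix().to_numpy(), default_cohort.value_matrix().to_numpy()
        )
        pd.testing.assert_series_equal(
            back.covariates["duration_gt30"].astype(int),
            default_cohort.covariates["duration_gt30"].astype(int),
        )

    def test_blank_nbd_flags_week_missing(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "subject_id,week,nbd\nS1,1,2\nS1,2,\nS1,3,4\n"
        )
        (tmp_path / "c.csv").write_text("subject_id,duration_gt30\nS1,1\n")
        cohort = sf.read_cohort(tmp_path / "s.csv", tmp_path / "c.csv")
        s = cohort["S1"]
        assert not s.observed[1] and s.observed[0] and s.observed[2]

    def test_absent_weeks_recorded_missing(self, tmp_path):
        (tmp_path / "s.csv").write_text("subject_id,week,nbd\nS1,1,2\nS1,4,3\n")
        (tmp_path / "c.csv").write_text("subject_id,duration_gt30\nS1,0\n")
        s = sf.read_cohort(tmp_path / "s.csv", tmp_path / "c.csv")["S1"]
        assert s.n_observed == 2 and len(s.weeks) == 4

    @pytest.mark.parametrize(
        "row,msg",
        [("S1,2,9", "range"), ("S1,2,3.5", "range"), ("S1,1,abc", "non-numeric")],
    )
    def test_bad_values_rejected_with_row(self, tmp_path, row, msg):
        (tmp_path / "s.csv").write_text(f"subject_id,week,nbd\nS1,1,2\n{row}\n")
        (tmp_path / "c.csv").write_text("subject_id,duration_gt30\nS1,0\n")
        with pytest.raises(ValueError, match=msg):
            sf.read_cohort(tmp_path / "s.csv", tmp_path / "c.csv")

    def test_duplicate_subject_week_rejected(self, tmp_path):
        (tmp_path / "s.csv").write_text("subject_id,week,nbd\nS1,1,2\nS1,1,3\n")
        (tmp_path / "c.csv").write_text("subject_id,duration_gt30\nS1,0\n")
        with pytest.raises(ValueError, match="duplicate"):
            sf.read_cohort(tmp_path / "s.csv", tmp_path / "c.csv")

    def test_unknown_covariate_subject_warns(self, tmp_path):
        (tmp_path / "s.csv").write_text("subject_id,week,nbd\nS1,1,2\n")
        (tmp_path / "c.csv").write_text("subject_id,duration_gt30\nS1,0\nS9,1\n")
        with pytest.warns(UserWarning, match="S9"):
            sf.read_cohort(tmp_path / "s.csv", tmp_path / "c.csv")


class TestEligibility:
    def test_23_of_26_excluded_24_kept(self):
        v23 = [3.0] * 23 + [np.nan] * 3
        v24 = [np.nan, np.nan] + [3.0] * 23 + [1.0]
        cohort = cohort_from_values([v23, v24])
        kept, log = sf.eligibility_filter(cohort, min_replies=24)
        assert kept.subject_ids == ["S2"]
        assert log[0].subject_id == "S1" and "23" in log[0].reason

    def test_missing_covariate_excludes(self):
        cohort = cohort_from_values([[3.0] * 26, [4.0] * 26], durations=[np.nan, 1])
        kept, log = sf.eligibility_filter(cohort)
        assert kept.subject_ids == ["S2"] and "covariate" in log[0].reason

    def test_fully_observed_cohort_unchanged(self, noise_free_cohort):
        kept, log = sf.eligibility_filter(noise_free_cohort)
        assert kept.subject_ids == noise_free_cohort.subject_ids and log == []

    def test_count_conservation_and_idempotence(self, default_cohort):
        kept, log = sf.eligibility_filter(default_cohort)
        assert kept.n_subjects + len(log) == default_cohort.n_subjects
        again, log2 = sf.eligibility_filter(kept)
        assert again.subject_ids == kept.subject_ids and log2 == []

    def test_empty_result_is_an_error(self):
        cohort = cohort_from_values([[np.nan] * 25 + [3.0]])
        with pytest.raises(ValueError, match="every subject"):
            sf.eligibility_filter(cohort, min_replies=24)


class TestRemoveConstant:
    def test_all_sevens_excluded(self):
        cohort = cohort_from_values([[7.0] * 26, [7.0] * 25 + [6.0]])
        kept, log = sf.remove_constant(cohort)
        assert kept.subject_ids == ["S2"]
        assert log[0].reason == "constant reply"

    def test_no_constants_unchanged_and_idempotent(self, noise_free_cohort):
        kept, log = sf.remove_constant(noise_free_cohort)
        assert kept.subject_ids == noise_free_cohort.subject_ids and log == []


class TestImpute:
    def test_interior_gap_takes_two_sided_mean(self):
        s = sf.impute(make_series([2.0, np.nan, 4.0]))
        assert s.values[1] == 3.0 and s.imputed[1] and not s.imputed[0]

    def test_boundary_copies_nearest_observed(self):
        s = sf.impute(make_series([np.nan, 5.0, 3.0, np.nan]))
        assert s.values[0] == 5.0 and s.values[-1] == 3.0

    def test_long_gap_linear_interpolation(self):
        s = sf.impute(make_series([2.0, np.nan, np.nan, 5.0]))
        np.testing.assert_allclose(s.values, [2.0, 3.0, 4.0, 5.0])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="all-missing"):
            sf.impute(make_series([np.nan, np.nan]))

    @given(st.data())
    def test_imputation_bounded_and_preserves_observed(self, data):
        n = data.draw(st.integers(6, 26), label="n")
        vals = np.array(
            data.draw(
                st.lists(st.integers(0, 7), min_size=n, max_size=n), label="values"
            ),
            dtype=float,
        )
        miss = np.array(
            data.draw(st.lists(st.booleans(), min_size=n, max_size=n), label="missing")
        )
        if miss.all():
            miss[0] = False
        vals[miss] = np.nan
        out = sf.impute(make_series(vals))
        obs = np.isfinite(vals)
        np.testing.assert_array_equal(out.values[obs], vals[obs])
        assert out.values.min() >= vals[obs].min() - 1e-12
        assert out.values.max() <= vals[obs].max() + 1e-12
        assert out.is_complete


class TestRounding:
    def test_half_days_round_away_from_zero(self):
        s = make_series([3.5, 2.4, 6.5, 0.0, 7.0])
        np.testing.assert_array_equal(rounded_values(s), [4, 2, 7, 0, 7])


def test_clean_cohort_order_and_conservation(default_cohort):
    kept, log = sf.clean_cohort(default_cohort)
    assert kept.n_subjects + len(log) == default_cohort.n_subjects
    assert all(s.is_complete for s in kept)
    assert not any(s.is_constant for s in kept)
    frame = exclusions_frame(log)
    assert set(frame.columns) == {"subject_id", "reason"}
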