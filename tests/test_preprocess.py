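"""Cleaning pipeline: CSV I/O, imputation, outlier removal, smoothing, split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from habforecast.preprocess import (
    GridError,
    centred_moving_average,
    chronological_split,
    clean_dataset,
    impute_linear,
    read_sensor_csv,
    remove_outliers,
    split_index,
    write_sensor_csv,
)
from reference_impls import ref_centred_moving_average, ref_outlier_flags

from conftest import make_series


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

class TestCsvIO:
    def test_empty_cell_becomes_missing(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "timestamp,chl470\n"
            "2020-05-01T00:00:00,1.5\n"
            "2020-05-01T00:10:00,\n"
            "2020-05-01T00:20:00,2.5\n"
        )
        ds = read_sensor_csv(p)
        assert ds.channels["chl470"].missing_mask.tolist() == [False, True, False]

    def test_duplicate_timestamp_is_named(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "timestamp,chl470\n"
            "2020-05-01T00:00:00,1\n"
            "2020-05-01T00:10:00,2\n"
            "2020-05-01T00:10:00,3\n"
        )
        with pytest.raises(GridError, match="2020-05-01 00:10:00"):
            read_sensor_csv(p)

    def test_irregular_spacing_names_first_offending_row(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "timestamp,chl470\n"
            "2020-05-01T00:00:00,1\n"
            "2020-05-01T00:10:00,2\n"
            "2020-05-01T00:25:00,3\n"
        )
        with pytest.raises(GridError, match="row 2"):
            read_sensor_csv(p)

    def test_round_trip_identity(self, tmp_path, small_dataset):
        dataset, _ = small_dataset
        p = tmp_path / "rt.csv"
        write_sensor_csv(dataset, p)
        back = read_sensor_csv(p)
        for name in dataset.channel_names:
            np.testing.assert_allclose(
                back.channels[name].values, dataset.channels[name].values,
                rtol=1e-10, equal_nan=True,
            )
        assert back.grid.equals(dataset.grid)
        np.testing.assert_allclose(
            back.dependent.to_numpy(), dataset.dependent.to_numpy(), rtol=1e-10
        )


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

class TestImputeLinear:
    def test_midpoint_is_mean_of_brackets(self):
        s = make_series([2.0, np.nan, 6.0])
        out, rep = impute_linear(s)
        assert out.values[1] == pytest.approx(4.0)
        assert rep.imputed_indices["chl470"].tolist() == [1]

    def test_no_missing_returns_unchanged(self):
        s = make_series([1.0, 2.0, 3.0])
        out, rep = impute_linear(s)
        np.testing.assert_array_equal(out.values, s.values)
        assert len(rep.imputed_indices["chl470"]) == 0

    def test_interior_gap_matches_bracketing_line(self):
        # piecewise-linear signal with a 3-point hole: the fill must lie on
        # the straight line through the bracketing observations
        base = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 3.0, 2.0, 1.0, 0.0, 1.0])
        vals = base.copy()
        vals[3:6] = np.nan
        out, _ = impute_linear(make_series(vals))
        # brute-force line between (2, 2.0) and (6, 2.0)... recompute directly
        x0, y0, x1, y1 = 2, base[2], 6, base[6]
        for t in (3, 4, 5):
            expected = y0 + (y1 - y0) * (t - x0) / (x1 - x0)
            assert out.values[t] == pytest.approx(expected, abs=1e-12)

    def test_exactly_linear_signal_recovered_to_machine_precision(self):
        t = np.arange(50, dtype=float)
        vals = 0.3 * t + 2.0
        holed = vals.copy()
        holed[[4, 5, 6, 20, 33, 34]] = np.nan
        out, _ = impute_linear(make_series(holed))
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    def test_leading_trailing_filled_with_nearest(self):
        out, _ = impute_linear(make_series([np.nan, np.nan, 5.0, 7.0, np.nan]))
        assert out.values.tolist() == [5.0, 5.0, 5.0, 7.0, 7.0]

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError, match="all values missing"):
            impute_linear(make_series([np.nan, np.nan, np.nan]))

    @given(
        st.lists(
            st.one_of(st.floats(-100, 100), st.none()), min_size=5, max_size=40
        ).filter(lambda v: sum(x is not None for x in v) >= 2)
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_idempotent_and_bounded_by_brackets(self, raw):
        vals = np.array([np.nan if v is None else v for v in raw], dtype=float)
        once, _ = impute_linear(make_series(vals))
        twice, _ = impute_linear(once)
        np.testing.assert_array_equal(once.values, twice.values)
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        assert np.all(once.values >= lo - 1e-9) and np.all(once.values <= hi + 1e-9)


# ---------------------------------------------------------------------------
# Outlier removal
# ---------------------------------------------------------------------------

class TestRemoveOutliers:
    def test_single_gross_spike_flagged_exactly(self):
        vals = np.full(60, 3.0)
        vals[:] += 0.01 * np.sin(np.arange(60))  # avoid exactly-zero MAD
        vals[30] = 300.0
        out, rep = remove_outliers(make_series(vals), window=21, k=5.0)
        assert rep.outlier_indices["chl470"].tolist() == [30]
        assert np.isnan(out.values[30])

    def test_constant_series_flags_nothing(self):
        out, rep = remove_outliers(make_series(np.full(30, 2.0)), window=11, k=5.0)
        assert len(rep.outlier_indices["chl470"]) == 0

    def test_monotone_signal_clean_at_k3(self):
        out, rep = remove_outliers(make_series(np.linspace(0, 10, 200)), window=21, k=3.0)
        assert len(rep.outlier_indices["chl470"]) == 0

    def test_injected_spikes_match_brute_force(self):
        rng = np.random.default_rng(11)
        vals = 5.0 + 0.2 * rng.standard_normal(400)
        spikes = [17, 80, 211, 390]
        vals[spikes] += rng.choice([-1, 1], size=len(spikes)) * 8.0
        out, rep = remove_outliers(make_series(vals), window=45, k=5.0)
        expected = ref_outlier_flags(vals, window=45, k=5.0)
        assert rep.outlier_indices["chl470"].tolist() == expected
        assert set(spikes) <= set(expected)

    def test_window_larger_than_series_is_error(self):
        with pytest.raises(ValueError, match="exceeds series length"):
            remove_outliers(make_series(np.ones(5)), window=11)


# ---------------------------------------------------------------------------
# Centred moving average
# ---------------------------------------------------------------------------

class TestCentredMovingAverage:
    def test_constant_unchanged(self):
        out = centred_moving_average(make_series(np.full(40, 3.3)), width=6)
        np.testing.assert_allclose(out.values, 3.3)

    @pytest.mark.parametrize("width", [3, 6, 7])
    def test_linear_ramp_unchanged_everywhere(self, width):
        vals = np.linspace(0.0, 9.9, 100)
        out = centred_moving_average(make_series(vals), width=width)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    @pytest.mark.parametrize("width", [1, 4, 5, 6])
    def test_matches_explicit_windowed_mean(self, width):
        vals = np.random.default_rng(3).standard_normal(120)
        out = centred_moving_average(make_series(vals), width=width)
        np.testing.assert_allclose(
            out.values, ref_centred_moving_average(vals, width), atol=1e-12
        )

    def test_mean_preserved_over_whole_periods(self):
        t = np.arange(24 * 6 * 4)
        vals = 5.0 + np.sin(2 * np.pi * t / 144)
        out = centred_moving_average(make_series(vals), width=6)
        assert out.values.mean() == pytest.approx(vals.mean(), abs=1e-2)

    def test_missing_values_are_rejected(self):
        with pytest.raises(ValueError, match="impute_linear"):
            centred_moving_average(make_series([1.0, np.nan, 2.0]))


# ---------------------------------------------------------------------------
# Chronological split
# ---------------------------------------------------------------------------

class TestSplit:
    @pytest.mark.parametrize(
        "n,f,train_n,test_n",
        [(100, 0.75, 75, 25), (4, 0.5, 2, 2), (22708, 0.75, 17031, 5677)],
    )
    def test_split_sizes(self, n, f, train_n, test_n):
        assert split_index(n, f) == train_n
        assert n - split_index(n, f) == test_n

    def test_dataset_split_is_chronological(self, small_dataset):
        dataset, _ = small_dataset
        train, test = chronological_split(dataset, 0.75)
        assert len(train) == int(np.floor(len(dataset) * 0.75))
        assert train.grid[-1] < test.grid[0]
        if train.dependent is not None and test.dependent is not None:
            assert train.dependent.index.max() < test.grid[0]
            assert test.dependent.index.min() >= test.grid[0]

    def test_degenerate_split_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            split_index(3, 0.1)


def test_clean_dataset_runs_full_order(small_dataset):
    dataset, truth = small_dataset
    cleaned, report = clean_dataset(dataset, outlier_window=145, outlier_k=5.0)
    for name in dataset.channel_names:
        assert not cleaned.channels[name].missing_mask.any()
        flagged = set(report.outlier_indices[name])
        assert set(truth.outlier_indices[name]) <= flagged
        # imputed and outlier index sets stay disjoint in the report
        assert not flagged & set(report.imputed_indices[name])
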