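"""Time-series analyses: averages, summaries, histograms, correlations, flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkatraj import (
    PkaTable,
    average_over_replicas,
    compare_mutant_profiles,
    correlation_scan,
    distribution,
    flag_protonation_sensitive,
    running_average,
    summarize,
)
from pkatraj.timeseries import read_property_series, window_frames_from_time


def _table(columns: dict, model: dict | None = None, times=None) -> PkaTable:
    n = len(next(iter(columns.values())))
    index = pd.Index(
        times if times is not None else np.arange(n, dtype=float) * 100.0,
        name="time_ps", dtype=float,
    )
    return PkaTable(
        data=pd.DataFrame(columns, index=index),
        model_pka=pd.Series(model) if model else None,
    )


class TestRunningAverage:
    def test_centered_shrinking_window(self):
        out = running_average([1, 2, 3, 4, 5], 3)
        np.testing.assert_allclose(out, [1.5, 2, 3, 4, 4.5])

    def test_window_one_is_identity(self):
        np.testing.assert_allclose(running_average([3.0, 1.0, 4.0], 1), [3, 1, 4])

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(running_average([2.0] * 7, 5), [2.0] * 7)

    def test_window_larger_than_series_raises(self):
        with pytest.raises(ValueError):
            running_average([1.0, 2.0], 5)

    def test_even_window_rounded_up_to_odd(self, caplog):
        with caplog.at_level("WARNING", logger="pkatraj"):
            out = running_average([1, 2, 3, 4, 5], 2)
        np.testing.assert_allclose(out, running_average([1, 2, 3, 4, 5], 3))

    @settings(deadline=None, max_examples=40)
    @given(
        series=st.lists(st.floats(-50, 50), min_size=3, max_size=40),
        shift=st.floats(-10, 10),
    )
    def test_shift_equivariance(self, series, shift):
        base = running_average(series, 3)
        shifted = running_average([v + shift for v in series], 3)
        np.testing.assert_allclose(shifted, base + shift, atol=1e-9)

    def test_time_window_conversion(self):
        # 5 ns window at 100 ps/frame -> 51 frames (rounded up to odd)
        assert window_frames_from_time(5000.0, 100.0) == 51


class TestSummarize:
    def test_mean_and_delta_from_model(self):
        table = _table({"ASP 52 A": [4.0, 4.2, 4.4, 3.9, 4.0]}, {"ASP 52 A": 3.8})
        (s,) = summarize(table)
        assert s.mean == pytest.approx(4.1)
        assert s.delta_from_model == pytest.approx(0.3)
        assert s.min <= s.mean <= s.max

    def test_single_frame_sd_zero(self):
        table = _table({"ASP 52 A": [4.5]}, {"ASP 52 A": 3.8})
        (s,) = summarize(table)
        assert s.sd == 0.0
        assert s.delta_from_model == pytest.approx(0.7)

    def test_all_missing_column_marked_undefined(self, caplog):
        table = _table({"ASP 52 A": [np.nan, np.nan]}, {"ASP 52 A": 3.8})
        with caplog.at_level("WARNING", logger="pkatraj"):
            (s,) = summarize(table)
        assert np.isnan(s.mean)


class TestDistribution:
    def test_single_bin_when_all_values_equal(self):
        table = _table({"ASP 52 A": [4.05] * 10})
        hist = distribution(table, bin_width=0.1)
        assert len(hist) == 1
        assert hist.iloc[0]["bin_left"] == pytest.approx(4.0)
        assert hist.iloc[0]["count"] == 10

    def test_adjacent_bins(self):
        table = _table({"ASP 52 A": [3.95, 4.05]})
        hist = distribution(table, bin_width=0.1)
        assert sorted(hist["bin_left"].round(10)) == [3.9, 4.0]
        assert list(hist["count"]) == [1, 1]

    @settings(deadline=None, max_examples=30)
    @given(values=st.lists(st.floats(0, 14), min_size=1, max_size=60))
    def test_counts_conserve_frame_count(self, values):
        table = _table({"GLU 35 A": values}, times=np.arange(len(values), dtype=float))
        hist = distribution(table, bin_width=0.25)
        assert hist["count"].sum() == len(values)


class TestCorrelationScan:
    def test_exact_linear_relations(self):
        x = np.linspace(-1, 1, 50)
        table = _table({"ASP 52 A": 2 * x + 1, "GLU 35 A": -3 * x})
        props = pd.DataFrame({"PC1": x})
        report = correlation_scan(table, props)
        r = dict(zip(report["residue"], report["correlation"]))
        assert r["ASP 52 A"] == pytest.approx(1.0)
        assert r["GLU 35 A"] == pytest.approx(-1.0)

    def test_zero_variance_gives_missing_not_zero(self):
        table = _table({"ASP 52 A": [4.0] * 20})
        props = pd.DataFrame({"PC1": np.arange(20.0)})
        report = correlation_scan(table, props)
        assert np.isnan(report["correlation"].iloc[0])

    def test_recovers_designed_correlation(self):
        rng = np.random.default_rng(11)
        n = 1000
        for rho in (0.0, 0.5, 0.9):
            x = rng.standard_normal(n)
            eps = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * eps
            table = _table({"ASP 52 A": y}, times=np.arange(n, dtype=float))
            report = correlation_scan(table, pd.DataFrame({"PC1": x}))
            assert report["correlation"].iloc[0] == pytest.approx(rho, abs=0.05)

    def test_length_mismatch_without_time_raises(self):
        table = _table({"ASP 52 A": [4.0, 4.1, 4.2]})
        with pytest.raises(ValueError):
            correlation_scan(table, pd.DataFrame({"PC1": [1.0, 2.0]}))

    def test_threshold_flags_pairs(self):
        x = np.linspace(0, 1, 30)
        table = _table({"ASP 52 A": x})
        report = correlation_scan(table, pd.DataFrame({"PC1": x}), threshold=0.5)
        assert bool(report["flagged"].iloc[0])

    def test_spearman_option(self):
        x = np.linspace(0, 1, 30)
        table = _table({"ASP 52 A": np.exp(x)})  # monotone, nonlinear
        report = correlation_scan(table, pd.DataFrame({"PC1": x}), method="spearman")
        assert report["correlation"].iloc[0] == pytest.approx(1.0)


class TestProtonationFlags:
    def test_fraction_of_frames_in_window(self):
        table = _table({"HIS 15 A": [6.5, 7.0, 8.0, 9.0]})
        out = flag_protonation_sensitive(table, reference_ph=7.4, half_width=1.0)
        assert out.iloc[0]["fraction_in_window"] == pytest.approx(0.75)

    def test_residue_outside_window_not_listed(self):
        table = _table({"ASP 52 A": [4.0] * 5})
        out = flag_protonation_sensitive(table, reference_ph=7.4, half_width=1.0)
        assert out.empty

    def test_window_spanning_all_values(self):
        table = _table({"ASP 52 A": [4.0, 5.0, 6.0]})
        out = flag_protonation_sensitive(table, reference_ph=5.0, half_width=10.0)
        assert out.iloc[0]["fraction_in_window"] == 1.0


class TestAverageOverReplicas:
    def test_unweighted_mean_of_replica_means(self):
        r1 = _table({"ASP 52 A": [4.0, 4.0]})
        r2 = _table({"ASP 52 A": [4.2, 4.2]})
        out = average_over_replicas([r1, r2])
        assert out.loc["ASP 52 A", "mean_pka"] == pytest.approx(4.1)

    def test_single_replica_identity(self):
        r1 = _table({"ASP 52 A": [4.0, 4.4]})
        out = average_over_replicas([r1])
        assert out.loc["ASP 52 A", "mean_pka"] == pytest.approx(4.2)

    def test_identical_replicas_equal_single_replica_mean(self):
        r = _table({"GLU 35 A": [4.4, 4.8, 5.0]})
        joint = average_over_replicas([r, r, r])
        single = average_over_replicas([r])
        assert joint.loc["GLU 35 A", "mean_pka"] == single.loc["GLU 35 A", "mean_pka"]

    def test_partial_residue_flagged(self):
        r1 = _table({"ASP 52 A": [4.0], "GLU 35 A": [5.0]})
        r2 = _table({"ASP 52 A": [4.2]})
        out = average_over_replicas([r1, r2])
        assert bool(out.loc["GLU 35 A", "partial"])
        assert out.loc["GLU 35 A", "mean_pka"] == pytest.approx(5.0)

    def test_disjoint_residue_sets_raise(self):
        r1 = _table({"ASP 52 A": [4.0]})
        r2 = _table({"GLU 35 A": [5.0]})
        with pytest.raises(ValueError):
            average_over_replicas([r1, r2])


class TestCompareMutantProfiles:
    def test_uniform_shift(self):
        wild = _table({"ASP 52 A": [4.0, 4.2, 4.4]})
        mutant = _table({"ASP 52 A": [4.5, 4.7, 4.9]})
        cmp = compare_mutant_profiles(wild, mutant, "ASP 52 A")
        assert cmp.mean_shift == pytest.approx(0.5)
        assert cmp.fluctuation_ratio == pytest.approx(1.0)

    def test_flattened_mutant_has_zero_fluctuation_ratio(self):
        wild = _table({"ASP 52 A": [4.0, 4.2, 4.4]})
        mutant = _table({"ASP 52 A": [4.2, 4.2, 4.2]})
        cmp = compare_mutant_profiles(wild, mutant, "ASP 52 A")
        assert cmp.fluctuation_ratio == 0.0

    def test_identity(self):
        wild = _table({"ASP 52 A": [4.0, 4.2, 4.4]})
        cmp = compare_mutant_profiles(wild, wild, "ASP 52 A")
        assert cmp.mean_shift == 0.0
        assert cmp.fluctuation_ratio == pytest.approx(1.0)

    def test_time_axis_mismatch_raises(self):
        wild = _table({"ASP 52 A": [4.0, 4.2]})
        mutant = _table({"ASP 52 A": [4.0, 4.2]}, times=[0.0, 50.0])
        with pytest.raises(ValueError):
            compare_mutant_profiles(wild, mutant, "ASP 52 A")


class TestPropertySeriesReader:
    def test_headerless_whitespace_columns(self, tmp_path):
        path = tmp_path / "proj.dat"
        path.write_text("0.1 1.0\n0.2 2.0\n0.3 3.0\n")
        df = read_property_series(path)
        assert list(df.columns) == ["prop_0", "prop_1"]
        assert len(df) == 3

    def test_csv_with_header(self, tmp_path):
        path = tmp_path / "proj.csv"
        path.write_text("PC1,PC2\n0.1,1.0\n0.2,2.0\n")
        df = read_property_series(path)
        assert list(df.columns) == ["PC1", "PC2"]
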