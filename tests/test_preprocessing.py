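"""Tests of peak-flow binarisation, episode annotation and feature extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plcalds import (
    WindowSpec,
    annotate_temporal_states,
    binarise_peak_flow,
    build_feature_tensor,
    dwt_decompose,
    estimate_window_lag,
    expand_annotation_masks,
    extract_window_features,
)
from plcalds.preprocessing import RICH_FEATURES, NonnegativeScaler
from plcalds.synthetic_cohort import ConfigurationError, ValidationError


class TestBinarisePeakFlow:
    def test_median_rule_hand_example(self):
        out = binarise_peak_flow(pd.Series([300, 320, 310, 280, 290]))
        np.testing.assert_array_equal(out.to_numpy(), [0, 0, 0, 1, 1])

    def test_constant_series_all_zero(self):
        out = binarise_peak_flow(pd.Series([400.0] * 6))
        assert out.sum() == 0

    def test_strictly_decreasing_odd_length(self):
        n = 9
        out = binarise_peak_flow(pd.Series(np.arange(n, 0, -1, dtype=float)))
        np.testing.assert_array_equal(out.to_numpy()[(n + 1) // 2:], 1)
        np.testing.assert_array_equal(out.to_numpy()[: n // 2], 0)

    def test_missing_days_stay_missing(self):
        out = binarise_peak_flow(pd.Series([300, np.nan, 280]))
        assert np.isnan(out.iloc[1]) and out.iloc[2] == 1

    def test_all_missing_raises(self):
        with pytest.raises(ValidationError):
            binarise_peak_flow(pd.Series([np.nan, np.nan]))


class TestEpisodeAnnotation:
    @pytest.mark.parametrize("series,expected", [
        ([0, 1, 1, 1, 1, 0], [(1, [2, 3], 4)]),
        ([0, 1, 0], [(1, [], 1)]),
        ([1, 1, 0, 1], [(0, [], 1), (3, [], 3)]),
        ([0, 0], []),
    ])
    def test_run_segmentation(self, series, expected):
        eps = annotate_temporal_states(series)
        got = [(e.onset_day, e.transient_days, e.offset_day) for e in eps]
        assert got == expected

    def test_mask_expansion_counts(self):
        eps = annotate_temporal_states([0, 1, 1, 1, 1, 0], symptom=0)
        masks = expand_annotation_masks(eps, n_symptoms=1, n_days=6)
        assert masks.sum() == 4  # 1 onset + 2 transient + 1 offset
        assert masks[0, 0, 1] == 1 and masks[0, 2, 4] == 1

    def test_single_day_episode_sets_onset_and_offset(self):
        masks = expand_annotation_masks(annotate_temporal_states([0, 1, 0]), 1, 3)
        assert masks[0, 0, 1] == 1 and masks[0, 2, 1] == 1 and masks[0, 1].sum() == 0

    def test_out_of_axis_annotation_raises(self):
        eps = annotate_temporal_states([0, 1])
        with pytest.raises(ValidationError):
            expand_annotation_masks(eps, n_symptoms=1, n_days=1)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40))
    def test_annotate_expand_collapse_roundtrip(self, series):
        eps = annotate_temporal_states(series)
        masks = expand_annotation_masks(eps, 1, len(series))
        collapsed = masks[0].max(axis=0)
        np.testing.assert_array_equal(collapsed, np.asarray(series))


class TestWindowLag:
    def test_white_noise_gives_lag_one(self):
        rng = np.random.default_rng(0)
        lags, window, _ = estimate_window_lag({"p": rng.normal(size=400)})
        assert lags["p"] == 1 and window == 1

    def test_ar1_lag_matches_band_crossing(self):
        # brute-force check on a simulated AR(1): acf ~ 0.9^k crosses the
        # significance band near log(band)/log(0.9) ~ 22
        lags = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = np.empty(2000)
            x[0] = rng.normal()
            for t in range(1, 2000):
                x[t] = 0.9 * x[t - 1] + np.sqrt(1 - 0.81) * rng.normal()
            lag, _, _ = estimate_window_lag({"p": x}, max_lag=60)
            lags.append(lag["p"])
        assert abs(np.median(lags) - 22) <= 5

    def test_identical_cohort_gives_common_lag(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        lags, window, mean = estimate_window_lag({"a": x, "b": x, "c": x})
        assert window == lags["a"] == round(mean)

    def test_short_series_skipped(self):
        rng = np.random.default_rng(2)
        lags, _, _ = estimate_window_lag(
            {"short": rng.normal(size=10), "ok": rng.normal(size=400)})
        assert "short" not in lags and "ok" in lags


class TestDWT:
    def test_constant_signal_has_zero_details(self):
        bands = dwt_decompose(np.full(64, 3.0), wavelet_order=2, levels=3)
        for detail in bands[1:]:
            assert np.max(np.abs(detail)) < 1e-10

    def test_haar_hand_example(self):
        bands = dwt_decompose([2, 2, 2, 2], wavelet_order=1, levels=1)
        np.testing.assert_allclose(bands[0], [2 * np.sqrt(2)] * 2, atol=1e-12)
        np.testing.assert_allclose(bands[1], [0, 0], atol=1e-12)

    @pytest.mark.parametrize("n", [32, 64, 128])
    def test_parseval_energy_conservation(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        bands = dwt_decompose(x, wavelet_order=2, levels=3)
        energy = sum(float(np.sum(b ** 2)) for b in bands)
        assert abs(energy - float(np.sum(x ** 2))) < 1e-8

    def test_perfect_reconstruction(self):
        import pywt
        rng = np.random.default_rng(5)
        x = rng.normal(size=64)
        bands = dwt_decompose(x, wavelet_order=2, levels=3)
        back = pywt.waverec(bands, "db2", mode="periodization")
        np.testing.assert_allclose(back, x, atol=1e-8)

    def test_short_window_falls_back(self):
        bands = dwt_decompose(np.ones(4), wavelet_order=2, levels=3)
        assert len(bands) == 2  # one level only


class TestWindowFeatures:
    def test_constant_window_conventions(self):
        vec, names, _ = extract_window_features({"NO": np.full(32, 5.0)})
        f = dict(zip(names, vec))
        assert f["NO:variance"] == 0 and f["NO:skewness"] == 0
        assert f["NO:spectral_flux"] == 0

    def test_flux_zero_for_identical_consecutive_windows(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(1, 2, 32)
        _, _, bands = extract_window_features({"NO": w})
        vec, names, _ = extract_window_features({"NO": w}, prev_band_energies=bands)
        assert dict(zip(names, vec))["NO:spectral_flux"] < 1e-12

    def test_centroid_higher_for_alternating_signal(self):
        # alternating sample puts energy in the finest band; an isolated
        # impulse spreads it across bands -> lower centroid
        alternating = np.tile([0.0, 1.0], 16)
        impulse = np.zeros(32)
        impulse[13] = 1.0
        va, na, _ = extract_window_features({"c": alternating})
        vi, ni, _ = extract_window_features({"c": impulse})
        ca = dict(zip(na, va))["c:spectral_centroid"]
        ci = dict(zip(ni, vi))["c:spectral_centroid"]
        assert ca > ci

    def test_average_only_equals_arithmetic_mean(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0, 10, 40)
        vec, names, _ = extract_window_features({"NO": w}, feature_set="average_only")
        assert names == ["NO:average"]
        np.testing.assert_allclose(vec[0], w.mean())

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(ConfigurationError):
            extract_window_features({"NO": np.ones(8)}, feature_set="everything")

    def test_feature_order_is_stable(self):
        w = {"NO": np.arange(16.0), "CO": np.arange(16.0)}
        _, names, _ = extract_window_features(w)
        assert names == [f"{ch}:{f}" for ch in ("NO", "CO") for f in RICH_FEATURES]


class TestFeatureTensor:
    def test_frame_count(self, small_cohort):
        _, cohort = small_cohort
        ft = build_feature_tensor(cohort[0], WindowSpec(8, 1))
        n_days = cohort[0].n_days
        dropped = len(ft.dropped_dates)
        assert ft.n_frames + dropped == n_days - 8 + 1

    def test_ten_days_window_eight_gives_three_frames(self, small_cohort):
        import dataclasses
        _, cohort = small_cohort
        rec = cohort[2]  # full coverage participant
        short = dataclasses.replace(
            rec,
            dates=rec.dates[:10],
            sensor_streams=rec.sensor_streams.iloc[:10 * rec.samples_per_day],
            day_valid=rec.day_valid[:10],
            season_of_day=rec.season_of_day[:10],
            peak_flow=rec.peak_flow.iloc[:10],
            diary=rec.diary.iloc[:10],
        )
        ft = build_feature_tensor(short, WindowSpec(8, 1))
        assert ft.n_frames == 3

    def test_nonnegative_and_energy_definition(self, small_cohort):
        _, cohort = small_cohort
        ft = build_feature_tensor(cohort[1])
        assert np.all(ft.values >= 0) and np.all(np.isfinite(ft.values))
        np.testing.assert_allclose(ft.frame_energy, ft.values.sum(axis=0), atol=1e-9)

    def test_sensor_subsets(self, small_cohort):
        _, cohort = small_cohort
        rec = cohort[2]
        full = build_feature_tensor(rec, sensors_subset="all")
        poll = build_feature_tensor(rec, sensors_subset="pollutants_only")
        pf = build_feature_tensor(rec, sensors_subset="peakflow_only")
        assert {n.split(":")[0] for n in poll.feature_names} == {
            "NO", "CO", "PM1", "PM2.5", "PM10", "RH"}
        assert {n.split(":")[0] for n in pf.feature_names} == {"peak_flow"}
        assert full.values.shape[0] > poll.values.shape[0] > pf.values.shape[0]

    def test_empty_subset_rejected(self, small_cohort):
        import dataclasses
        _, cohort = small_cohort
        rec = dataclasses.replace(cohort[0], peak_flow=None)
        with pytest.raises(ConfigurationError):
            build_feature_tensor(rec, sensors_subset="peakflow_only")

    def test_on_off_coding_splits_deviations(self):
        raw = np.array([[1.0, 2.0, 3.0, 4.0]])
        scaler = NonnegativeScaler.fit(raw, ["c:average"], np.ones(4, bool))
        out = scaler.transform(raw)
        assert out.shape == (2, 4)
        assert np.all(out >= 0)
        # on-row fires above the median, off-row below
        assert out[0, 3] > 0 and out[0, 0] == 0
        assert out[1, 0] > 0 and out[1, 3] == 0
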