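import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import brute_candidate_indices, brute_prominence, make_mag, ten_peak_topology
from stepcount import (
    DynamicThresholdConfig,
    MotionState,
    Peak,
    WalkSpec,
    candidate_peaks,
    detect_peaks,
    dynamic_threshold_filter,
    generate_walk,
    lowpass,
    magnitude,
    peak_prominence,
    profile_for,
    vibration_filter,
)

signal_arrays = arrays(
    np.float64, st.integers(8, 60), elements=st.floats(0.5, 2.0, allow_nan=False)
)


class TestCandidatePeaks:
    def test_monotone_ramp_has_no_peaks(self, mag_factory):
        assert candidate_peaks(mag_factory(np.linspace(0, 1, 50)), 3) == []

    def test_toy_array_d1_and_d2(self, mag_factory):
        mag = mag_factory([1, 1.3, 1, 1.2, 1])
        assert [p.index for p in candidate_peaks(mag, 1)] == [1, 3]
        assert [p.index for p in candidate_peaks(mag, 2)] == [1]

    def test_plateau_keeps_earliest_index(self, mag_factory):
        mag = mag_factory([0, 1, 1, 1, 0, 0])
        assert [p.index for p in candidate_peaks(mag, 2)] == [1]

    def test_too_short_series_is_empty(self, mag_factory):
        assert candidate_peaks(mag_factory([1, 2, 1]), 5) == []

    @settings(derandomize=True, max_examples=60)
    @given(signal_arrays, st.integers(1, 6))
    def test_matches_brute_force(self, acc, d):
        got = [p.index for p in candidate_peaks(make_mag(acc), d)]
        if len(acc) > 2 * d:
            assert got == brute_candidate_indices(acc, d)
        else:
            assert got == []

    def test_peak_count_non_increasing_in_d(self):
        series, _ = generate_walk(WalkSpec(state=MotionState.NORMAL, n_steps=40, seed=3))
        mag = lowpass(magnitude(series))
        counts = [len(candidate_peaks(mag, d)) for d in (5, 14, 20)]
        assert counts[0] >= counts[1] >= counts[2]


class TestPeakProminence:
    def test_global_max_over_full_window(self, mag_factory):
        mag = mag_factory([0.0, 1.0, 0.0])
        p = Peak(index=1, time=0.02, amplitude=1.0)
        assert peak_prominence(mag, p, (0, 2)) == pytest.approx(1.0)

    def test_ten_peak_topology_orders_true_above_false(self, mag_factory):
        y, true_idx, false_idx = ten_peak_topology()
        mag = mag_factory(y)
        n = len(y)
        prom = {
            j: peak_prominence(mag, Peak(index=j, time=j / 50, amplitude=y[j]), (0, n - 1))
            for j in true_idx + false_idx
        }
        assert max(prom[j] for j in false_idx) < min(prom[j] for j in true_idx)

    @settings(derandomize=True, max_examples=40)
    @given(arrays(np.float64, 200, elements=st.floats(0.5, 2.0, allow_nan=False)))
    def test_matches_exhaustive_oracle(self, acc):
        mag = make_mag(acc)
        for p in candidate_peaks(mag, 2):
            lo, hi = max(0, p.index - 12), min(len(acc) - 1, p.index + 12)
            got = peak_prominence(mag, p, (lo, hi))
            assert got == pytest.approx(brute_prominence(acc, p.index, lo, hi), abs=1e-12)

    def test_agrees_with_scipy_on_full_window(self):
        """Independent cross-check against scipy's prominence definition."""
        from scipy.signal import find_peaks, peak_prominences

        rng = np.random.default_rng(7)
        for _ in range(20):
            acc = rng.uniform(0.5, 2.0, size=150)
            idx, _ = find_peaks(acc)
            ours = [
                peak_prominence(
                    make_mag(acc), Peak(index=j, time=j / 50, amplitude=acc[j]), (0, 149)
                )
                for j in idx
            ]
            theirs = peak_prominences(acc, idx)[0]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestDynamicThreshold:
    def _triangle(self, height, period=24, cycles=6):
        # symmetric triangle oscillating around 1 g
        one = np.concatenate(
            [np.linspace(-0.5, 0.5, period // 2, endpoint=False),
             np.linspace(0.5, -0.5, period // 2, endpoint=False)]
        )
        return 1.0 + height * np.tile(one, cycles)

    def test_tall_triangle_kept(self):
        mag = make_mag(self._triangle(0.4))
        peaks = candidate_peaks(mag, 5)
        kept = dynamic_threshold_filter(mag, peaks, DynamicThresholdConfig(0.15, 24))
        assert len(kept) == len(peaks) > 0
        assert all("dynamic_ok" in p.flags for p in kept)

    def test_short_triangle_removed(self):
        mag = make_mag(self._triangle(0.2))
        peaks = candidate_peaks(mag, 5)
        assert dynamic_threshold_filter(mag, peaks, DynamicThresholdConfig(0.15, 24)) == []

    @settings(derandomize=True, max_examples=40)
    @given(arrays(np.float64, 120, elements=st.floats(0.5, 2.0, allow_nan=False)))
    def test_matches_direct_recomputation(self, acc):
        mag = make_mag(acc)
        cfg = DynamicThresholdConfig(th_d=0.15, win_size=24)
        peaks = candidate_peaks(mag, 3)
        kept = {p.index for p in dynamic_threshold_filter(mag, list(peaks), cfg)}
        for p in candidate_peaks(mag, 3):
            lo = max(0, p.index - 12)
            hi = min(len(acc), lo + 24)
            lo = max(0, hi - 24)
            w = acc[lo:hi]
            aver_d = (w.max() + w.min()) / 2.0
            assert (acc[p.index] - aver_d >= 0.15) == (p.index in kept)


class TestVibrationFilter:
    def test_peak_at_gravity_always_removed(self):
        p = Peak(index=5, time=0.1, amplitude=1.0)
        assert vibration_filter([p], 0.01) == []

    def test_normal_state_threshold_arithmetic(self):
        low = Peak(index=5, time=0.1, amplitude=1.09)
        high = Peak(index=30, time=0.6, amplitude=1.11)
        kept = vibration_filter([low, high], 0.1)
        assert [p.amplitude for p in kept] == [1.11]
        assert kept[0].vib_eli == pytest.approx(0.11)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.8, 1.6), min_size=0, max_size=20))
    def test_kept_count_non_increasing_in_threshold(self, amps):
        def count(th):
            peaks = [Peak(index=i, time=i / 50, amplitude=a) for i, a in enumerate(amps)]
            return len(vibration_filter(peaks, th))

        counts = [count(th) for th in (0.05, 0.08, 0.10, 0.15, 0.30)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDetectPeaks:
    def test_constant_signal_yields_nothing(self, mag_factory):
        profile = profile_for(MotionState.NORMAL, 50.0)
        assert detect_peaks(mag_factory(np.ones(300)), profile) == []

    def test_clean_walk_recovers_every_stride(self):
        series, truth = generate_walk(
            WalkSpec(state=MotionState.NORMAL, n_steps=50, noise_sd=0.005, seed=4)
        )
        mag = lowpass(magnitude(series))
        peaks = detect_peaks(mag, profile_for(MotionState.NORMAL, 50.0))
        assert len(peaks) == 50
        assert all(p.flags >= {"distance_ok", "prominence_ok", "dynamic_ok", "vibration_ok"}
                   for p in peaks)

    def test_pure_vibration_segment_rejected(self):
        rng = np.random.default_rng(5)
        acc = 1.0 + 0.05 * np.sin(2 * np.pi * 2.0 * np.arange(600) / 50.0) \
            + rng.normal(0, 0.005, 600)
        peaks = detect_peaks(make_mag(acc), profile_for(MotionState.NORMAL, 50.0))
        assert peaks == []

    def test_each_stage_only_removes_peaks(self):
        series, _ = generate_walk(
            WalkSpec(state=MotionState.NORMAL, n_steps=30, noise_sd=0.05, seed=6)
        )
        mag = lowpass(magnitude(series))
        profile = profile_for(MotionState.NORMAL, 50.0)
        from stepcount import prominence_filter

        c0 = candidate_peaks(mag, profile.d)
        c1 = prominence_filter(mag, list(c0), profile.h, profile.win_size)
        c2 = dynamic_threshold_filter(
            mag, list(c1), DynamicThresholdConfig(0.15, profile.win_size)
        )
        c3 = vibration_filter(list(c2), profile.th_vib)
        ids = lambda peaks: {p.index for p in peaks}
        assert ids(c3) <= ids(c2) <= ids(c1) <= ids(c0)

    @pytest.mark.parametrize("param,values", [
        ("d", (5, 10, 12, 14, 20)),
        ("h", (0.1, 0.2, 0.25, 0.35, 0.5)),
        ("th_vib", (0.05, 0.08, 0.10, 0.15, 0.30)),
    ])
    def test_surviving_count_monotone_in_profile_thresholds(self, param, values):
        series, _ = generate_walk(
            WalkSpec(state=MotionState.NORMAL, n_steps=30, noise_sd=0.05, seed=6)
        )
        mag = lowpass(magnitude(series))
        counts = []
        for v in values:
            profile = profile_for(MotionState.NORMAL, 50.0, {param: v})
            counts.append(len(detect_peaks(mag, profile)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_surviving_count_monotone_in_th_d(self):
        series, _ = generate_walk(
            WalkSpec(state=MotionState.NORMAL, n_steps=30, noise_sd=0.05, seed=6)
        )
        mag = lowpass(magnitude(series))
        profile = profile_for(MotionState.NORMAL, 50.0)
        counts = [
            len(detect_peaks(mag, profile, DynamicThresholdConfig(th, profile.win_size)))
            for th in (0.05, 0.10, 0.15, 0.25, 0.40)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_offset_invariance_of_shape_filters(self):
        """Distance, prominence and dynamic thresholding ignore a DC offset;
        only vibration elimination is anchored to the 1 g baseline."""
        series, _ = generate_walk(
            WalkSpec(state=MotionState.NORMAL, n_steps=30, noise_sd=0.02, seed=8)
        )
        mag = lowpass(magnitude(series))
        shifted = make_mag(mag.acc + 0.2)
        profile = profile_for(MotionState.NORMAL, 50.0)
        from stepcount import prominence_filter

        def shape_chain(m):
            c = candidate_peaks(m, profile.d)
            c = prominence_filter(m, c, profile.h, profile.win_size)
            c = dynamic_threshold_filter(m, c, DynamicThresholdConfig(0.15, profile.win_size))
            return [p.index for p in c]

        assert shape_chain(mag) == shape_chain(shifted)
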