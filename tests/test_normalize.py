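"""Baseline estimation, dF/F and dR/R normalization, bleach correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catrace.model import AcquisitionMeta, Recording, StimulusProtocol
from catrace.normalize import (
    BaselineParams,
    bleach_correct,
    normalize_dff,
    normalize_drr,
    rest_normalize,
    sliding_baseline,
    smooth_reference,
)


def brute_force_baseline(values, params):
    """Per-index sort-and-select oracle for the sliding baseline."""
    values = np.asarray(values, dtype=float)
    n = values.size
    h = (params.window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        win = np.sort(values[max(0, i - h): min(n, i + h + 1)])
        m = win.size
        if params.method == "percentile":
            # linear-interpolation percentile at index p/100 * (m-1)
            pos = params.percentile / 100.0 * (m - 1)
            lo = int(math.floor(pos))
            hi = min(lo + 1, m - 1)
            out[i] = win[lo] + (pos - lo) * (win[hi] - win[lo])
        else:
            k = math.ceil(params.fraction * m)
            out[i] = win[:k].mean()
    return out


class TestSlidingBaseline:
    def test_constant_input_any_params(self):
        for params in (
            BaselineParams(window=5),
            BaselineParams(window=101, method="lowest_fraction"),
        ):
            out = sliding_baseline(np.full(50, 3.7), params)
            np.testing.assert_allclose(out, 3.7)

    def test_percentile_30_of_permuted_1_to_101(self, rng):
        values = rng.permutation(np.arange(1.0, 102.0))
        out = sliding_baseline(values, BaselineParams(window=101, percentile=30))
        # center index sees all 101 values: index 0.30 * 100 = 30 -> value 31
        assert out[50] == pytest.approx(31.0, abs=1e-12)

    def test_lowest_decile_of_permuted_1_to_100(self, rng):
        values = rng.permutation(np.arange(1.0, 101.0))
        out = sliding_baseline(
            values, BaselineParams(window=101, method="lowest_fraction", fraction=0.10)
        )
        # truncated window at the center covers all 100 values: mean(1..10)
        assert out[50] == pytest.approx(5.5, abs=1e-12)

    @pytest.mark.parametrize("method", ["percentile", "lowest_fraction"])
    def test_matches_brute_force_oracle(self, method, rng):
        for _ in range(25):
            n = int(rng.integers(10, 200))
            window = int(rng.choice([3, 11, 51, 101]))
            values = rng.normal(100, 20, size=n)
            params = BaselineParams(window=window, method=method)
            got = sliding_baseline(values, params)
            want = brute_force_baseline(values, params)
            if method == "lowest_fraction":
                np.testing.assert_array_equal(got, want)
            else:
                np.testing.assert_allclose(got, want, atol=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 2**16),
        shift=st.floats(-50, 50, allow_nan=False),
        method=st.sampled_from(["percentile", "lowest_fraction"]),
    )
    def test_shift_equivariance(self, seed, shift, method):
        values = np.random.default_rng(seed).normal(0, 1, size=60)
        params = BaselineParams(window=11, method=method)
        np.testing.assert_allclose(
            sliding_baseline(values + shift, params),
            sliding_baseline(values, params) + shift,
            atol=1e-10,
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sliding_baseline(np.array([1.0, np.inf, 2.0]), BaselineParams(window=3))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BaselineParams(window=4)
        with pytest.raises(ValueError):
            BaselineParams(percentile=0)
        with pytest.raises(ValueError):
            BaselineParams(fraction=0)


class TestNormalizeDff:
    def _recording(self, signal, frame_rate=100.0):
        return Recording(
            meta=AcquisitionMeta(frame_rate=frame_rate), roi_id="r",
            signal=np.asarray(signal, dtype=float),
        )

    def test_flat_trace_gives_zero(self):
        trace = normalize_dff(self._recording(np.full(300, 100.0)))
        np.testing.assert_allclose(trace.values, 0.0)
        np.testing.assert_allclose(trace.baseline, 100.0)

    def test_transient_on_flat_baseline(self):
        signal = np.full(400, 100.0)
        signal[200:205] = 150.0
        trace = normalize_dff(self._recording(signal))
        assert trace.baseline[200] == pytest.approx(100.0)
        assert trace.values.max() == pytest.approx(0.5)
        assert trace.values[0] == pytest.approx(0.0)

    def test_denormalization_round_trip(self, rng):
        signal = 100.0 + rng.normal(0, 5, size=500)
        rec = self._recording(signal)
        trace = normalize_dff(rec)
        recovered = trace.baseline * (1.0 + trace.values)
        np.testing.assert_allclose(recovered, signal, rtol=1e-12)

    def test_nonpositive_baseline_names_frame(self):
        signal = np.full(50, -1.0)
        with pytest.raises(ValueError, match="frame 0"):
            normalize_dff(self._recording(signal))


class TestSmoothReference:
    def test_truncated_window_means(self):
        np.testing.assert_allclose(
            smooth_reference(np.array([0.0, 3.0, 0.0]), 3), [1.5, 1.0, 1.5]
        )

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_array_equal(smooth_reference(x, 1), x)

    def test_constant_invariant(self):
        np.testing.assert_allclose(smooth_reference(np.full(30, 2.5), 8), 2.5)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            smooth_reference(np.ones(5), 0)


class TestNormalizeDrr:
    def _dual(self, signal, reference, frame_rate=118.0):
        return Recording(
            meta=AcquisitionMeta(frame_rate=frame_rate), roi_id="r",
            signal=np.asarray(signal, float), reference=np.asarray(reference, float),
        )

    def test_proportional_channels_give_zero(self, rng):
        ref = 50.0 + rng.uniform(0, 5, size=300)
        trace = normalize_drr(self._dual(2.0 * ref, ref))
        np.testing.assert_allclose(trace.values, 0.0, atol=1e-12)

    def test_common_multiplicative_bleach_cancels(self):
        n = 400
        bleach = 0.9 ** (np.arange(n) / n)
        trace = normalize_drr(self._dual(100.0 * bleach, 40.0 * bleach))
        np.testing.assert_allclose(trace.values, 0.0, atol=1e-12)

    def test_missing_reference_is_config_error(self):
        rec = Recording(
            meta=AcquisitionMeta(frame_rate=100.0), roi_id="r", signal=np.ones(10)
        )
        with pytest.raises(ValueError, match="reference"):
            normalize_drr(rec)

    def test_noiseless_event_peak_recovered(self):
        from catrace.simulate import EventKernel

        # 1 kHz sampling puts a frame on the kernel peak: recovery within 2%
        meta = AcquisitionMeta(frame_rate=1000.0)
        t = meta.times(8000)
        kernel = EventKernel(amplitude=0.4, tau_rise=14.0, tau_decay=99.0)
        ref = np.full(t.size, 80.0)
        signal = 100.0 * (1.0 + 0.4 * kernel.waveform(t - 5000.0))
        trace = normalize_drr(self._dual(signal, ref, frame_rate=1000.0))
        assert trace.values.max() == pytest.approx(0.4, rel=0.02)


class TestBleachCorrect:
    def _protocol(self, n=10, first=1000.0):
        return StimulusProtocol.from_block_specs(
            [{"label": "1Hz", "frequency_hz": 1, "n_stimuli": n,
              "first_stimulus_ms": first}]
        )

    def test_recovers_injected_linear_slope(self):
        meta = AcquisitionMeta(frame_rate=100.0)
        t = meta.times(1200)
        rec = Recording(meta=meta, roi_id="r", signal=100.0 - 0.5 * (t / 1000.0))
        corrected, fit = bleach_correct(rec, self._protocol())
        assert fit.slope * 1000.0 == pytest.approx(-0.5, rel=1e-9)
        assert np.ptp(corrected.signal) == pytest.approx(0.0, abs=1e-9)
        # anchored at the first window center: corrected trace sits at the
        # original trace's value there (center 950 ms for a stimulus at 1 s)
        assert corrected.signal[0] == pytest.approx(100.0 - 0.5 * 0.95, rel=1e-12)

    def test_noisy_slope_recovery_within_one_percent(self):
        meta = AcquisitionMeta(frame_rate=100.0)
        t = meta.times(2000)
        slopes = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            signal = 100.0 - 0.8 * (t / 1000.0) + rng.normal(0, 1.0, size=t.size)
            rec = Recording(meta=meta, roi_id="r", signal=signal)
            _, fit = bleach_correct(rec, self._protocol(n=15))
            slopes.append(fit.slope * 1000.0)
        assert np.mean(slopes) == pytest.approx(-0.8, rel=0.01)

    def test_constant_trace_unchanged(self):
        meta = AcquisitionMeta(frame_rate=100.0)
        rec = Recording(meta=meta, roi_id="r", signal=np.full(1200, 42.0))
        corrected, fit = bleach_correct(rec, self._protocol())
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(corrected.signal, 42.0)

    def test_single_stimulus_is_error(self):
        meta = AcquisitionMeta(frame_rate=100.0)
        rec = Recording(meta=meta, roi_id="r", signal=np.full(1200, 42.0))
        with pytest.raises(ValueError, match="2"):
            bleach_correct(rec, self._protocol(n=1))


class TestRestNormalize:
    def test_basic_fractional_change(self):
        meta = AcquisitionMeta(frame_rate=100.0)
        signal = np.full(300, 100.0)
        signal[150] = 120.0
        rec = Recording(meta=meta, roi_id="r", signal=signal)
        trace = rest_normalize(rec, first_stim_time=1000.0)
        assert trace.values[150] == pytest.approx(0.2)
        assert trace.values[0] == pytest.approx(0.0)

    def test_rest_window_is_half_open(self):
        # the frame at exactly the stimulus time must not enter F_rest
        meta = AcquisitionMeta(frame_rate=100.0)
        signal = np.full(200, 100.0)
        signal[100] = 999.0  # frame at t = 1000 ms
        rec = Recording(meta=meta, roi_id="r", signal=signal)
        trace = rest_normalize(rec, first_stim_time=1000.0)
        np.testing.assert_allclose(trace.baseline, 100.0)

    def test_empty_rest_window_is_error(self):
        meta = AcquisitionMeta(frame_rate=100.0)
        rec = Recording(meta=meta, roi_id="r", signal=np.full(100, 50.0))
        with pytest.raises(ValueError, match="rest window"):
            rest_normalize(rec, first_stim_time=-500.0)
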