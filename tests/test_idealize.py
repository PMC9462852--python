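import numpy as np
import pytest

from scpopen.errors import ConfigurationError
from scpopen.filtering import apply_gaussian, gaussian_kernel
from scpopen.idealize import (
    IdealizationSettings,
    detect_double_openings,
    gaussian_filter,
    resample,
    threshold_idealize,
)
from scpopen.simulate import OPEN, SHUT, Dwell, IdealizedRecord, SampledTrace, render_trace
from tests.conftest import match_open_events


def square_pulse_trace(width_ms=10.0, pad_ms=20.0, fs=100_000.0, amp=5.0, fc=10_000.0):
    n_pad = int(pad_ms / 1000.0 * fs)
    n_pulse = int(width_ms / 1000.0 * fs)
    x = np.concatenate([np.zeros(n_pad), amp * np.ones(n_pulse), np.zeros(n_pad)])
    return SampledTrace(samples=x, fs=fs, fc=fc, baseline=0.0, amp=amp)


class TestGaussianFilter:
    def test_dc_gain_is_one(self):
        tr = SampledTrace(samples=np.full(5000, 3.7), fs=50_000.0, fc=10_000.0)
        out = gaussian_filter(tr, 3000.0)
        assert np.allclose(out.samples, 3.7)
        assert out.samples.size == tr.samples.size

    def test_kernel_is_normalized_and_impulse_response(self):
        fs, fc = 50_000.0, 3000.0
        k = gaussian_kernel(fc, fs)
        assert abs(k.sum() - 1.0) < 1e-9
        x = np.zeros(4001)
        x[2000] = 1.0
        out = apply_gaussian(x, fc, fs)
        half = len(k) // 2
        assert np.allclose(out[2000 - half : 2000 + half + 1], k, atol=1e-12)

    def test_white_noise_sd_follows_l2_norm(self):
        fs, fc = 100_000.0, 3000.0
        rng = np.random.default_rng(5)
        tr = SampledTrace(samples=rng.normal(0, 1, 10**6), fs=fs, fc=30_000.0)
        out = gaussian_filter(tr, fc)
        # the composed 30k*3k cutoff is ~fc; predict from the applied kernel
        expected = np.sqrt(np.sum(gaussian_kernel(fc, fs) ** 2))
        assert abs(out.samples.std() - expected) / expected < 0.05

    def test_records_composed_cutoff(self):
        tr = SampledTrace(samples=np.zeros(100), fs=100_000.0, fc=10_000.0)
        out = gaussian_filter(tr, 3000.0)
        assert out.fc == pytest.approx(1.0 / np.sqrt(1 / 10_000.0**2 + 1 / 3000.0**2))

    def test_cutoff_at_nyquist_rejected(self):
        tr = SampledTrace(samples=np.zeros(100), fs=10_000.0, fc=2000.0)
        with pytest.raises(ConfigurationError):
            gaussian_filter(tr, 5000.0)


class TestResample:
    def test_constant_trace_shrinks_by_ratio(self):
        tr = SampledTrace(samples=np.full(99_999, 2.0), fs=100_000.0, fc=3000.0)
        out = resample(tr, 33_333.0)
        assert np.allclose(out.samples, 2.0)
        assert out.samples.size == pytest.approx(tr.samples.size / 3, abs=2)

    def test_pulse_width_preserved(self):
        tr = square_pulse_trace(width_ms=10.0, fc=3000.0)
        out = resample(gaussian_filter(tr, 3000.0), 33_333.0)
        rec = threshold_idealize(out)
        opens = [d for d in rec.dwells if d.conducting]
        assert len(opens) == 1
        assert abs(opens[0].duration_ms - 10.0) <= 1000.0 / out.fs

    def test_near_identity_limit(self):
        # fs_out = fs/1.0001: linear interpolation error on a smooth input
        fs, freq = 100_000.0, 20.0
        t_in = (np.arange(50_000) + 0.5) / fs
        tr = SampledTrace(samples=np.sin(2 * np.pi * freq * t_in), fs=fs, fc=10_000.0)
        out = resample(tr, fs / 1.0001)
        t_out = (np.arange(out.samples.size) + 0.5) / out.fs
        inner = slice(10, -10)
        assert np.max(np.abs(out.samples[inner] - np.sin(2 * np.pi * freq * t_out[inner]))) < 1e-6

    def test_upsampling_rejected(self):
        tr = SampledTrace(samples=np.zeros(100), fs=10_000.0, fc=2000.0)
        with pytest.raises(ConfigurationError):
            resample(tr, 20_000.0)


class TestThresholdIdealize:
    def test_noiseless_alternation_recovered_exactly(self):
        dwells = [
            Dwell(OPEN if i % 2 == 0 else SHUT, 10.0, 5.0 if i % 2 == 0 else 0.0)
            for i in range(10)
        ]
        rec = IdealizedRecord(dwells=dwells)
        tr = render_trace(rec, fs=100_000.0, amp=5.0, noise_sd=0.0, fc=10_000.0)
        ideal = threshold_idealize(tr)
        assert [d.state for d in ideal.dwells] == [d.state for d in dwells]
        durs = np.array([d.duration_ms for d in ideal.dwells])
        assert np.all(np.abs(durs - 10.0) <= 1000.0 / tr.fs)

    def test_all_baseline_trace_is_single_censored_shut_dwell(self):
        tr = SampledTrace(samples=np.zeros(1000), fs=10_000.0, fc=2000.0, amp=5.0)
        rec = threshold_idealize(tr)
        assert len(rec.dwells) == 1 and rec.dwells[0].state == SHUT
        assert rec.censored_start and rec.censored_end

    def test_dwell_durations_sum_to_trace_duration(self):
        tr = square_pulse_trace()
        rec = threshold_idealize(tr)
        assert sum(d.duration_ms for d in rec.dwells) == pytest.approx(
            tr.duration_ms, abs=1000.0 / tr.fs
        )

    def test_noisy_events_recovered(self, well_resolved_record):
        tr = render_trace(well_resolved_record, fs=100_000.0, amp=5.0, noise_sd=0.5, fc=10_000.0, seed=1)
        ideal = threshold_idealize(resample(gaussian_filter(tr, 3000.0), 33_333.0))
        n_true, n_rec, errors = match_open_events(well_resolved_record, ideal, 33_333.0)
        assert n_rec / n_true >= 0.99
        assert np.mean(errors <= 2.0) >= 0.99

    def test_recovery_does_not_improve_with_more_noise(self, well_resolved_record):
        fractions = []
        for noise in (0.25, 1.0, 2.0):  # in pA, amp = 5
            tr = render_trace(
                well_resolved_record, fs=100_000.0, amp=5.0, noise_sd=noise, fc=10_000.0, seed=3
            )
            ideal = threshold_idealize(resample(gaussian_filter(tr, 3000.0), 33_333.0))
            n_true, n_rec, errors = match_open_events(well_resolved_record, ideal, 33_333.0)
            fractions.append(np.sum(errors <= 2.0) / n_true)
        assert fractions[0] >= fractions[1] >= fractions[2]

    def test_idealization_is_idempotent_on_noiseless_reconstruction(self):
        dwells = [
            Dwell(OPEN if i % 2 == 0 else SHUT, 5.0 + i, 5.0 if i % 2 == 0 else 0.0)
            for i in range(8)
        ]
        fs = 50_000.0
        tr = render_trace(IdealizedRecord(dwells=dwells), fs=fs, amp=5.0, noise_sd=0.0, fc=10_000.0)
        first = threshold_idealize(tr)
        tr2 = render_trace(first, fs=fs, amp=5.0, noise_sd=0.0, fc=10_000.0)
        second = threshold_idealize(tr2)
        assert [d.state for d in first.dwells] == [d.state for d in second.dwells]
        d1 = np.array([d.duration_ms for d in first.dwells])
        d2 = np.array([d.duration_ms for d in second.dwells])
        assert np.all(np.abs(d1 - d2) <= 1000.0 / fs)


class TestDoubleOpenings:
    def test_single_channel_trace_is_clean(self):
        tr = square_pulse_trace()
        assert detect_double_openings(tr) == []

    def test_stacked_opening_flagged_once(self):
        fs, amp = 100_000.0, 5.0
        x = np.zeros(int(0.05 * fs))
        x[2000:2500] = amp  # normal opening
        x[3000:3500] = 2 * amp  # 5 ms double opening
        tr = SampledTrace(samples=x, fs=fs, fc=10_000.0, amp=amp)
        flagged = detect_double_openings(tr)
        assert len(flagged) == 1
        lo, hi = flagged[0]
        assert lo <= 30.0 < 35.0 <= hi + 1e-6

    def test_excursion_shorter_than_rise_time_ignored(self):
        fs, amp = 100_000.0, 5.0
        x = np.zeros(int(0.01 * fs))
        x[500:502] = 2 * amp  # 20 us blip << rise time at 10 kHz (33 us)
        tr = SampledTrace(samples=x, fs=fs, fc=10_000.0, amp=amp)
        assert detect_double_openings(tr) == []


def test_invalid_settings_rejected():
    with pytest.raises(ConfigurationError):
        IdealizationSettings(threshold_frac=1.5)
    with pytest.raises(ConfigurationError):
        IdealizationSettings(double_open_frac=0.9)
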