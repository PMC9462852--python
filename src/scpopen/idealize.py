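"""Threshold-crossing idealization of sampled single-channel traces.

The analysis chain mirrors standard practice for cell-attached recordings:
the acquired trace is low-pass filtered with a 3 kHz Gaussian filter,
resampled to 33.3 kHz, and open/shut dwells are detected by half-amplitude
threshold crossing.  Samples whose current exceeds a configurable multiple
of the unitary amplitude for longer than one filter rise time flag
superimposed (double) openings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .filtering import apply_gaussian, composed_cutoff, rise_time
from .simulate import OPEN, SHUT, Dwell, IdealizedRecord, SampledTrace


@dataclass(frozen=True)
class IdealizationSettings:
    """Settings for the filter/resample/threshold chain.

    ``threshold_frac`` is the open/shut discrimination level as a fraction
    of the unitary amplitude (0.5 = half-amplitude crossing, the field
    standard).  ``double_open_frac`` is the level, in units of the unitary
    amplitude, above which a sample indicates superimposed openings.
    ``min_event_ms`` optionally drops events shorter than a dead time
    (default off: 0).
    """

    fc_post: float = 3000.0
    fs_out: float = 33_333.0
    threshold_frac: float = 0.5
    double_open_frac: float = 1.5
    min_event_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_frac < 1.0:
            raise ConfigurationError(
                f"threshold_frac must be in (0, 1), got {self.threshold_frac!r}"
            )
        if self.double_open_frac <= 1.0:
            raise ConfigurationError(
                f"double_open_frac must exceed 1, got {self.double_open_frac!r}"
            )


def gaussian_filter(trace: SampledTrace, fc_post: float) -> SampledTrace:
    """Post-hoc Gaussian filtering; records the composed effective cutoff."""
    if fc_post >= trace.fs / 2.0:
        raise ConfigurationError(
            f"fc_post {fc_post} Hz must be below Nyquist {trace.fs / 2.0} Hz"
        )
    out = apply_gaussian(trace.samples, fc_post, trace.fs)
    return SampledTrace(
        samples=out,
        fs=trace.fs,
        fc=composed_cutoff(trace.fc, fc_post),
        baseline=trace.baseline,
        amp=trace.amp,
    )


def resample(trace: SampledTrace, fs_out: float) -> SampledTrace:
    """Decimate by linear interpolation onto a uniform ``fs_out`` grid."""
    if fs_out >= trace.fs:
        raise ConfigurationError(
            f"fs_out {fs_out} Hz must be below the source rate {trace.fs} Hz"
        )
    if fs_out <= 2.0 * trace.fc:
        raise ConfigurationError(
            f"fs_out {fs_out} Hz must exceed twice the effective cutoff {trace.fc} Hz"
        )
    n_in = trace.samples.size
    duration_s = n_in / trace.fs
    n_out = max(1, int(round(duration_s * fs_out)))
    t_in = (np.arange(n_in) + 0.5) / trace.fs
    t_out = (np.arange(n_out) + 0.5) / fs_out
    out = np.interp(t_out, t_in, trace.samples)
    return SampledTrace(
        samples=out, fs=fs_out, fc=trace.fc, baseline=trace.baseline, amp=trace.amp
    )


def threshold_idealize(
    trace: SampledTrace, settings: IdealizationSettings | None = None
) -> IdealizedRecord:
    """Classify samples by threshold crossing and merge runs into dwells.

    A sample is open when ``|current - baseline| >= threshold_frac * |amp|``.
    Dwell duration is the run length over the sampling rate.  The first and
    last dwells are truncated by the observation window and the record is
    flagged censored at both ends.
    """
    settings = settings or IdealizationSettings()
    if trace.amp == 0:
        raise DataError("unitary amplitude is zero; cannot set a threshold")
    x = np.abs(trace.samples - trace.baseline)
    is_open = x >= settings.threshold_frac * abs(trace.amp)

    # run-length encode the boolean classification
    change = np.flatnonzero(np.diff(is_open.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [is_open.size]])
    dt_ms = 1000.0 / trace.fs

    dwells = [
        Dwell(
            OPEN if is_open[s] else SHUT,
            (e - s) * dt_ms,
            trace.baseline + trace.amp if is_open[s] else trace.baseline,
        )
        for s, e in zip(starts, ends)
    ]
    if settings.min_event_ms > 0:
        dwells = _drop_short_events(dwells, settings.min_event_ms)
    return IdealizedRecord(
        dwells=dwells,
        sample_interval_ms=dt_ms,
        censored_start=True,
        censored_end=True,
    )


def _drop_short_events(dwells: list[Dwell], min_ms: float) -> list[Dwell]:
    """Merge events shorter than ``min_ms`` into their neighbours."""
    out: list[Dwell] = []
    for d in dwells:
        if out and (d.duration_ms < min_ms or out[-1].state == d.state):
            prev = out[-1]
            if d.duration_ms < min_ms:
                out[-1] = Dwell(prev.state, prev.duration_ms + d.duration_ms, prev.amplitude_pA)
            else:
                out[-1] = Dwell(d.state, prev.duration_ms + d.duration_ms, d.amplitude_pA)
        else:
            out.append(d)
    return out


def detect_double_openings(
    trace: SampledTrace, settings: IdealizationSettings | None = None
) -> list[tuple[float, float]]:
    """Maximal intervals (ms) where the current exceeds the double-opening level.

    Only excursions persisting for more than one filter rise time are
    reported; briefer ones are indistinguishable from filtered noise peaks.
    """
    settings = settings or IdealizationSettings()
    if trace.amp == 0:
        raise DataError("unitary amplitude is zero; cannot set a threshold")
    level = settings.double_open_frac * abs(trace.amp)
    above = np.abs(trace.samples - trace.baseline) >= level
    min_samples = rise_time(trace.fc) * trace.fs

    change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [above.size]])
    dt_ms = 1000.0 / trace.fs
    return [
        (s * dt_ms, e * dt_ms)
        for s, e in zip(starts, ends)
        if above[s] and (e - s) > min_samples
    ]
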