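"""Gaussian low-pass filtering in the single-channel convention.

The filter is specified by its -3 dB cutoff frequency ``fc``.  For a
Gaussian impulse response the corresponding time-domain standard deviation
is ``sigma_t = 0.1325 / fc`` (the standard single-channel analysis
convention); the kernel is truncated at +/- 4 sigma and renormalized to
unit sum so the DC gain is exactly 1.
"""

from __future__ import annotations

import numpy as np

#: sigma_t * fc for a Gaussian filter specified by its -3 dB cutoff.
SIGMA_FC = 0.1325

#: 10-90% rise time * fc for the same filter.
RISE_TIME_FC = 0.3321


def gaussian_kernel(fc: float, fs: float) -> np.ndarray:
    """Unit-sum Gaussian kernel with -3 dB cutoff ``fc`` at sampling rate ``fs``.

    Both frequencies are in hertz.  The kernel has an odd number of taps,
    ``2*ceil(4*sigma)+1`` with ``sigma = 0.1325*fs/fc`` samples.
    """
    sigma = SIGMA_FC * fs / fc
    half = int(np.ceil(4.0 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def apply_gaussian(samples: np.ndarray, fc: float, fs: float) -> np.ndarray:
    """Filter ``samples`` with the Gaussian kernel, symmetric edge padding.

    Output length equals input length.
    """
    k = gaussian_kernel(fc, fs)
    half = len(k) // 2
    if half == 0:
        return np.asarray(samples, dtype=float).copy()
    padded = np.pad(np.asarray(samples, dtype=float), half, mode="edge")
    return np.convolve(padded, k, mode="valid")


def rise_time(fc: float) -> float:
    """10-90% rise time (seconds) of the Gaussian filter with cutoff ``fc`` Hz."""
    return RISE_TIME_FC / fc


def composed_cutoff(fc1: float, fc2: float) -> float:
    """Effective cutoff of two cascaded Gaussian filters: 1/fc^2 adds."""
    return 1.0 / np.sqrt(1.0 / fc1**2 + 1.0 / fc2**2)
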