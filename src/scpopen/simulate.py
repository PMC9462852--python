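"""Synthetic cell-attached single-channel recordings with known ground truth.

The generator emulates the structure that the downstream analysis assumes:
one-channel clusters of alternating open/shut dwells with exponential dwell
times, separated by long desensitized shut periods.  It deliberately uses
the minimal open<->shut scheme with geometric cluster termination into a
desensitized state: that reproduces exactly the observable the analysis
consumes (the within-cluster open probability) without claiming any
activation mechanism.

Rates follow the usual convention: ``alpha`` is the closing rate (so the
mean open dwell is ``1/alpha``) and ``beta`` the opening rate (mean shut
dwell ``1/beta``); the within-cluster equilibrium open probability is
``beta / (alpha + beta)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DataError, ParameterError
from .filtering import apply_gaussian

OPEN = "open"
SHUT = "shut"
DESENSITIZED = "desensitized"

#: states that carry no current
_NONCONDUCTING = (SHUT, DESENSITIZED)


@dataclass(frozen=True)
class GatingParams:
    """Parameters of the reduced open/shut/desensitized gating scheme.

    Parameters
    ----------
    alpha
        Channel closing rate, per second (mean open dwell ``1/alpha``).
    beta
        Channel opening rate, per second (mean shut dwell ``1/beta``).
    desens_prob
        Probability that a shut dwell terminates the cluster into the
        desensitized state (geometric cluster termination).
    mean_desens
        Mean desensitized dwell, in seconds.
    n_clusters
        Number of clusters to generate.
    seed
        RNG seed; fixed seed gives bitwise-identical dwell lists.
    """

    alpha: float = 100.0
    beta: float = 2400.0
    desens_prob: float = 0.01
    mean_desens: float = 2.0
    n_clusters: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be a positive rate, got {getattr(self, name)!r}")
        if not 0.0 < self.desens_prob <= 1.0:
            raise ParameterError(f"desens_prob must be in (0, 1], got {self.desens_prob!r}")
        if not np.isfinite(self.mean_desens) or self.mean_desens <= 0:
            raise ParameterError(f"mean_desens must be positive seconds, got {self.mean_desens!r}")
        if self.n_clusters < 1:
            raise ParameterError(f"n_clusters must be >= 1, got {self.n_clusters!r}")

    @property
    def popen(self) -> float:
        """Within-cluster equilibrium open probability beta/(alpha+beta)."""
        return self.beta / (self.alpha + self.beta)


@dataclass(frozen=True)
class Dwell:
    """One idealized dwell: state label, duration (ms), amplitude (pA)."""

    state: str
    duration_ms: float
    amplitude_pA: float

    @property
    def conducting(self) -> bool:
        return self.state == OPEN


@dataclass
class IdealizedRecord:
    """A sequence of alternating conducting/non-conducting dwells.

    ``sample_interval_ms`` is ``None`` for an exact event list (e.g. from
    the simulator) or the output sample spacing for threshold-idealized
    traces.  ``truth`` optionally carries ground-truth state labels.
    ``censored_start``/``censored_end`` flag dwells truncated by the
    observation window.
    """

    dwells: list[Dwell]
    sample_interval_ms: float | None = None
    truth: list[str] | None = None
    censored_start: bool = False
    censored_end: bool = False
    record_id: str = "rec0"

    @property
    def duration_ms(self) -> float:
        return float(sum(d.duration_ms for d in self.dwells))

    def open_dwells(self) -> list[Dwell]:
        return [d for d in self.dwells if d.conducting]


@dataclass
class SampledTrace:
    """A uniformly sampled current trace with its recording metadata."""

    samples: np.ndarray
    fs: float  # Hz
    fc: float  # effective -3 dB cutoff, Hz
    baseline: float = 0.0  # pA, shut level
    amp: float = 5.0  # pA, unitary open-channel step

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise DataError("trace must contain at least one sample")
        if not self.fs > 2.0 * self.fc:
            raise ConfigurationError(
                f"sampling rate {self.fs} Hz must exceed twice the cutoff {self.fc} Hz"
            )

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.fs


def simulate_dwells(params: GatingParams, amp: float = 5.0) -> IdealizedRecord:
    """Draw a dwell sequence with exactly ``params.n_clusters`` clusters.

    Each cluster is a run of alternating open/shut dwells that begins and
    ends with an opening; after every opening the cluster terminates into a
    desensitized dwell with probability ``desens_prob``.  Dwell durations
    are exponential with means ``1/alpha`` (open), ``1/beta`` (shut) and
    ``mean_desens`` (desensitized).
    """
    rng = np.random.default_rng(params.seed)
    mean_open_ms = 1000.0 / params.alpha
    mean_shut_ms = 1000.0 / params.beta
    mean_desens_ms = 1000.0 * params.mean_desens

    dwells: list[Dwell] = []
    for _ in range(params.n_clusters):
        while True:
            dwells.append(Dwell(OPEN, float(rng.exponential(mean_open_ms)), amp))
            if rng.random() < params.desens_prob:
                break
            dwells.append(Dwell(SHUT, float(rng.exponential(mean_shut_ms)), 0.0))
        dwells.append(Dwell(DESENSITIZED, float(rng.exponential(mean_desens_ms)), 0.0))
    truth = [d.state for d in dwells]
    return IdealizedRecord(dwells=dwells, sample_interval_ms=None, truth=truth)


def render_trace(
    record: IdealizedRecord,
    fs: float = 100_000.0,
    amp: float = 5.0,
    noise_sd: float = 0.0,
    fc: float = 10_000.0,
    seed: int = 0,
    baseline: float = 0.0,
) -> SampledTrace:
    """Render a dwell sequence as a noisy, filtered sampled trace.

    The piecewise-constant two-level signal (open = baseline + amp, shut =
    baseline) first receives additive white Gaussian noise of SD
    ``noise_sd`` and is then filtered with the Gaussian kernel of -3 dB
    cutoff ``fc``, emulating the recording chain (noise enters before the
    analog filter, so the rendered per-level SD is ``noise_sd`` times the
    kernel's l2 norm).
    """
    if not record.dwells:
        raise DataError("cannot render an empty dwell list")
    if not fs > 2.0 * fc:
        raise ConfigurationError(f"fs {fs} Hz must exceed twice fc {fc} Hz")
    if amp == 0:
        raise ConfigurationError("unitary amplitude amp must be nonzero")

    durations = np.array([d.duration_ms for d in record.dwells]) / 1000.0  # s
    levels = np.array(
        [baseline + amp if d.conducting else baseline for d in record.dwells]
    )
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    n = max(1, int(round(edges[-1] * fs)))
    t = (np.arange(n) + 0.5) / fs
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(levels) - 1)
    signal = levels[idx]

    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    filtered = apply_gaussian(signal, fc, fs)
    return SampledTrace(samples=filtered, fs=fs, fc=fc, baseline=baseline, amp=amp)


def beta_for_popen(alpha: float, target_popen: float) -> float:
    """Opening rate that gives a within-cluster Popen of ``target_popen``."""
    if not 0.0 < target_popen < 1.0:
        raise ParameterError(f"target Popen must be in (0, 1), got {target_popen!r}")
    return alpha * target_popen / (1.0 - target_popen)


def alpha_for_popen(beta: float, target_popen: float) -> float:
    """Closing rate that gives ``target_popen`` at a fixed opening rate.

    Fixing ``beta`` keeps the within-cluster shut times short for every
    agonist, so weak agonists are emulated with brief openings rather than
    very long closures — the pattern seen in real recordings, and the one
    that keeps shut times well below any sensible tcrit.
    """
    if not 0.0 < target_popen < 1.0:
        raise ParameterError(f"target Popen must be in (0, 1), got {target_popen!r}")
    return beta * (1.0 - target_popen) / target_popen


def make_agonist_dataset(
    targets: dict[str, float],
    kinetics: GatingParams | None = None,
    seed: int = 0,
    min_duration_ms: float = 100.0,
):
    """Simulate per-agonist cluster sets with known target open probabilities.

    For each agonist the opening rate ``beta`` is chosen (given the
    template's ``alpha``) so that ``beta/(alpha+beta)`` equals the target;
    the record is idealized trivially via its ground-truth labels and the
    recording protocol's cluster acceptance (duration >= ``min_duration_ms``)
    is applied before collecting per-cluster Popen values.

    Returns a dict mapping agonist name to
    :class:`scpopen.clusters.AgonistClusterSet`.
    """
    from .clusters import AgonistClusterSet, cluster_popen, segment_by_truth

    if kinetics is None:
        kinetics = GatingParams()
    out: dict[str, AgonistClusterSet] = {}
    # the global seed derives per-agonist seeds by fixed offsets
    for i, (agonist, target) in enumerate(sorted(targets.items())):
        params = replace(
            kinetics,
            beta=beta_for_popen(kinetics.alpha, target),
            seed=(seed + 1 + i) % 2**31,
        )
        record = simulate_dwells(params)
        # Trivial idealization: clusters are cut at the ground-truth
        # desensitized dwells, so tcrit plays no role here.
        clusters = segment_by_truth(record)
        kept = [c for c in clusters if c.duration_ms >= min_duration_ms]
        out[agonist] = AgonistClusterSet(
            agonist=agonist,
            popens=[cluster_popen(c) for c in kept],
            n_patches=1,
            n_clusters=len(kept),
        )
    return out
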