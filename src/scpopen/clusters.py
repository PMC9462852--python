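"""Cluster segmentation, acceptance filters, and open-probability statistics.

At high agonist concentrations single-channel activity occurs in clusters:
stretches of high open probability separated by long desensitized shut
periods.  A shut time longer than a critical duration ``tcrit`` marks a
desensitized gap; anything shorter is a within-cluster closure.  Each
cluster's open probability is the ratio of its total open time to its
duration, and per-agonist sets of cluster Popen values are the raw material
for the efficacy analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .simulate import DESENSITIZED, Dwell, IdealizedRecord


@dataclass
class Cluster:
    """A contiguous stretch of channel activity bounded by long shut times."""

    dwells: list[Dwell]
    start_ms: float = 0.0
    too_short: bool = False
    has_double_opening: bool = False
    censored_edge: bool = False

    @property
    def duration_ms(self) -> float:
        return float(sum(d.duration_ms for d in self.dwells))

    @property
    def open_time_ms(self) -> float:
        return float(sum(d.duration_ms for d in self.dwells if d.conducting))

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms

    @property
    def popen(self) -> float:
        return cluster_popen(self)


@dataclass
class AgonistClusterSet:
    """Per-cluster open probabilities for one agonist condition."""

    agonist: str
    popens: list[float]
    n_patches: int = 1
    n_clusters: int = 0
    concentration_mM: float | None = None
    pH: float | None = None

    def __post_init__(self) -> None:
        if self.n_clusters == 0:
            self.n_clusters = len(self.popens)
        if self.n_clusters != len(self.popens):
            raise DataError(
                f"{self.agonist}: n_clusters={self.n_clusters} does not match "
                f"{len(self.popens)} popen values"
            )
        bad = [p for p in self.popens if not 0.0 <= p <= 1.0]
        if bad:
            raise DataError(f"{self.agonist}: popen values outside [0, 1]: {bad[:3]}")


def segment_clusters(record: IdealizedRecord, tcrit_ms: float = 100.0) -> list[Cluster]:
    """Split a record into clusters at shut dwells of duration >= ``tcrit_ms``.

    Clusters are trimmed to begin and end with an opening; shut time flanking
    a cluster belongs to the inter-cluster gap.  A record with no openings
    yields an empty list.  Clusters that include a censored first/last dwell
    of the record are flagged ``censored_edge``.
    """
    if tcrit_ms <= 0:
        raise ParameterError(f"tcrit must be positive, got {tcrit_ms!r}")
    if not record.dwells:
        raise DataError("cannot segment an empty record")

    clusters: list[Cluster] = []
    current: list[Dwell] = []
    t = 0.0
    start = 0.0
    for d in record.dwells:
        is_gap = (not d.conducting) and d.duration_ms >= tcrit_ms
        if is_gap:
            if current:
                clusters.append(_trim(current, start))
                current = []
        else:
            if not current:
                start = t
            current.append(d)
        t += d.duration_ms
    if current:
        clusters.append(_trim(current, start))
    clusters = [c for c in clusters if c is not None]

    if clusters:
        if record.censored_start and clusters[0].start_ms == 0.0:
            clusters[0].censored_edge = True
        if record.censored_end and abs(clusters[-1].end_ms - record.duration_ms) < 1e-9:
            clusters[-1].censored_edge = True
    return clusters


def _trim(dwells: list[Dwell], start_ms: float) -> Cluster | None:
    """Trim leading/trailing shut dwells so the cluster starts/ends open."""
    i = 0
    while i < len(dwells) and not dwells[i].conducting:
        start_ms += dwells[i].duration_ms
        i += 1
    j = len(dwells)
    while j > i and not dwells[j - 1].conducting:
        j -= 1
    if j <= i:
        return None
    return Cluster(dwells=list(dwells[i:j]), start_ms=start_ms)


def segment_by_truth(record: IdealizedRecord) -> list[Cluster]:
    """Cut clusters at ground-truth desensitized dwells (simulator records)."""
    if record.truth is None:
        raise DataError("record carries no ground-truth labels")
    clusters: list[Cluster] = []
    current: list[Dwell] = []
    t = 0.0
    start = 0.0
    for d, label in zip(record.dwells, record.truth):
        if label == DESENSITIZED:
            if current:
                c = _trim(current, start)
                if c is not None:
                    clusters.append(c)
                current = []
        else:
            if not current:
                start = t
            current.append(d)
        t += d.duration_ms
    if current:
        c = _trim(current, start)
        if c is not None:
            clusters.append(c)
    return clusters


def flag_double_openings(
    clusters: list[Cluster], intervals_ms: list[tuple[float, float]]
) -> None:
    """Mark clusters that overlap any flagged double-opening interval."""
    for c in clusters:
        for lo, hi in intervals_ms:
            if lo < c.end_ms and hi > c.start_ms:
                c.has_double_opening = True
                break


def filter_clusters(
    clusters: list[Cluster],
    min_duration_ms: float = 100.0,
    exclude_double: bool = True,
    exclude_censored: bool = True,
) -> tuple[list[Cluster], list[tuple[Cluster, str]]]:
    """Apply the acceptance criteria; return (accepted, rejected-with-reason).

    Default thresholds follow the recording protocol: clusters must be at
    least 100 ms long and contain no double openings.
    """
    if min_duration_ms < 0:
        raise ParameterError(f"min_duration must be >= 0, got {min_duration_ms!r}")
    kept: list[Cluster] = []
    audit: list[tuple[Cluster, str]] = []
    for c in clusters:
        if c.duration_ms < min_duration_ms:
            c.too_short = True
            audit.append((c, "too_short"))
        elif exclude_double and c.has_double_opening:
            audit.append((c, "has_double_opening"))
        elif exclude_censored and c.censored_edge:
            audit.append((c, "censored_edge"))
        else:
            kept.append(c)
    return kept, audit


def cluster_popen(cluster: Cluster) -> float:
    """Open probability: total open time over cluster duration."""
    dur = cluster.duration_ms
    if dur <= 0:
        raise DataError("cluster has zero duration")
    return cluster.open_time_ms / dur


def summarize(cluster_set: AgonistClusterSet) -> dict:
    """Mean, sample SD (n-1), median (midpoint convention) and count."""
    if not cluster_set.popens:
        raise DataError(f"{cluster_set.agonist}: empty cluster set")
    p = np.asarray(cluster_set.popens, dtype=float)
    return {
        "agonist": cluster_set.agonist,
        "mean": float(np.mean(p)),
        "sd": float(np.std(p, ddof=1)) if p.size > 1 else 0.0,
        "median": float(np.median(p)),
        "n_clusters": int(p.size),
        "n_patches": cluster_set.n_patches,
    }
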