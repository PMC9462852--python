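"""Nonparametric inference: randomization test and bootstrap utilities.

The randomization (permutation) test for two independent groups uses the
absolute difference of group means as its statistic.  When the number of
distinct label assignments is small enough the test enumerates them all and
the p-value is exact; otherwise labels are shuffled ``n_iter`` times and
the Monte Carlo p-value uses the add-one convention
``p = (1 + #{permuted >= observed}) / (n_iter + 1)``, which can never reach
zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .errors import DataError


@dataclass(frozen=True)
class RandTestResult:
    observed_stat: float
    p_value: float
    n_iter: int
    seed: int | None
    exhaustive: bool

    def to_dict(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "p_value": self.p_value,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
        }


def _group_stat(pooled: np.ndarray, n_a: int, statistic: str) -> float:
    if statistic == "mean":
        return abs(float(pooled[:n_a].mean() - pooled[n_a:].mean()))
    if statistic == "median":
        return abs(float(np.median(pooled[:n_a]) - np.median(pooled[n_a:])))
    raise DataError(f"statistic must be 'mean' or 'median', got {statistic!r}")


def randomization_test(
    group_a,
    group_b,
    n_iter: int = 50_000,
    seed: int = 0,
    statistic: str = "mean",
) -> RandTestResult:
    """Two-tailed, non-paired randomization test on two groups of values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    if n_iter < 1:
        raise DataError(f"n_iter must be >= 1, got {n_iter!r}")

    pooled = np.concatenate([a, b])
    n_a, n = a.size, a.size + b.size
    observed = _group_stat(pooled, n_a, statistic)

    n_splits = comb(n, n_a)
    if n_splits <= n_iter:
        count = 0
        for chosen in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(chosen)] = True
            stat = _group_stat(np.concatenate([pooled[mask], pooled[~mask]]), n_a, statistic)
            if stat >= observed - 1e-12:
                count += 1
        return RandTestResult(observed, count / n_splits, n_splits, seed, True)

    rng = np.random.default_rng(seed)
    if statistic == "mean":
        # vectorized: permute rows of a tiled pool; the mean difference only
        # needs the sum of the first n_a entries of each permutation
        total = pooled.sum()
        perms = rng.permuted(np.tile(pooled, (n_iter, 1)), axis=1)
        sum_a = perms[:, :n_a].sum(axis=1)
        stats = np.abs(sum_a / n_a - (total - sum_a) / (n - n_a))
    else:
        perms = rng.permuted(np.tile(pooled, (n_iter, 1)), axis=1)
        stats = np.abs(
            np.median(perms[:, :n_a], axis=1) - np.median(perms[:, n_a:], axis=1)
        )
    count = int(np.sum(stats >= observed - 1e-12))
    p = (1 + count) / (n_iter + 1)
    return RandTestResult(observed, p, n_iter, seed, False)


def _resample_indices(rng: np.random.Generator, n: int, n_boot: int) -> np.ndarray:
    """(n_boot, n) bootstrap index matrix drawn with replacement."""
    return rng.integers(0, n, size=(n_boot, n))


def bootstrap_sd(
    values, statistic: str = "mean", n_boot: int = 10_000, seed: int = 0
) -> dict:
    """Bootstrap SD of a statistic: resample with replacement ``n_boot`` times.

    Returns ``{"sd": ..., "distribution": replicate array}`` with the SD
    using the n-1 denominator.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DataError("values must be non-empty")
    if n_boot < 1:
        raise DataError(f"n_boot must be >= 1, got {n_boot!r}")
    rng = np.random.default_rng(seed)
    draws = x[_resample_indices(rng, x.size, n_boot)]
    if statistic == "mean":
        reps = draws.mean(axis=1)
    elif statistic == "median":
        reps = np.median(draws, axis=1)
    else:
        raise DataError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    sd = float(np.std(reps, ddof=1)) if n_boot > 1 else 0.0
    return {"sd": sd, "distribution": reps}
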