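"""Gating equilibrium constants and thermodynamic-cycle analysis of efficacy.

The maximum open probability within a cluster relates to the overall gating
equilibrium constant E_eff (lumping pre-open flipping/priming and opening
steps) by

    maxPopen = E_eff / (E_eff + 1),    i.e.    E_eff = p / (1 - p).

Two independent structural modifications of the agonist — lengthening the
backbone by one methylene (glycine→β-alanine, AMS→taurine) and swapping the
carboxylate for a sulfonate (glycine→AMS, β-alanine→taurine) — arrange the
four agonists on a thermodynamic cycle.  Each edge carries the gating free
energy change

    ΔG = -RT ln(E_eff,modified / E_eff,reference)

and the coupling energy ΔΔG_int = ΔG1 - ΔG1' measures the deviation from
additivity of the two modifications: zero means the combined effect is the
sum of the individual effects.  Closure, ΔG1 + ΔG2' = ΔG2 + ΔG1', holds as
an algebraic identity.  Uncertainty comes from bootstrapping the
per-cluster E_eff values of each corner.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .clusters import AgonistClusterSet
from .errors import DataError
from .resampling import _resample_indices


@dataclass(frozen=True)
class EfficacyConstants:
    """Thermodynamic constants: R in cal/K/mol, T in kelvin."""

    R: float = 1.987
    T: float = 295.0

    @property
    def RT_cal(self) -> float:
        return self.R * self.T

    @property
    def RT_kcal(self) -> float:
        """RT in kcal/mol (energies are reported in kcal/mol throughout)."""
        return self.R * self.T * 1e-3


@dataclass
class CycleSpec:
    """The four corners of the agonist cycle, in fixed roles.

    reference: the short carboxylate agonist (glycine);
    lengthened: one extra methylene (β-alanine);
    swapped: sulfonate for carboxylate (AMS);
    both: both modifications (taurine).

    Edge semantics: ΔG1 reference→lengthened, ΔG1' swapped→both,
    ΔG2 reference→swapped, ΔG2' lengthened→both.
    """

    reference: AgonistClusterSet
    lengthened: AgonistClusterSet
    swapped: AgonistClusterSet
    both: AgonistClusterSet

    def corners(self) -> dict[str, AgonistClusterSet]:
        return {
            "reference": self.reference,
            "lengthened": self.lengthened,
            "swapped": self.swapped,
            "both": self.both,
        }


@dataclass
class ThermoCycleResult:
    """Point estimates, closure residual, coupling energy and bootstrap SDs."""

    eeff_point: dict[str, float]
    dG1: float
    dG2: float
    dG1p: float
    dG2p: float
    ddG_int: float
    closure_residual: float
    estimator: str = "mean"
    n_excluded: dict[str, int] = field(default_factory=dict)
    sd_dG: dict[str, float] | None = None
    sd_ddG: float | None = None
    replicates_ddG: np.ndarray | None = None
    n_boot: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "eeff_point": self.eeff_point,
            "dG1_kcal_mol": self.dG1,
            "dG2_kcal_mol": self.dG2,
            "dG1p_kcal_mol": self.dG1p,
            "dG2p_kcal_mol": self.dG2p,
            "ddG_int_kcal_mol": self.ddG_int,
            "abs_ddG_int_kcal_mol": abs(self.ddG_int),
            "closure_residual_kcal_mol": self.closure_residual,
            "estimator": self.estimator,
            "n_excluded": self.n_excluded,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        if self.sd_dG is not None:
            out["sd_dG_kcal_mol"] = self.sd_dG
        if self.sd_ddG is not None:
            out["sd_ddG_kcal_mol"] = self.sd_ddG
        return out


def popen_to_eeff(p: float) -> float:
    """Invert maxPopen = E/(E+1): returns p/(1-p), strictly increasing."""
    if not 0.0 <= p <= 1.0:
        raise DataError(f"popen must lie in [0, 1], got {p!r}")
    if p == 1.0:
        raise DataError("popen = 1 gives an infinite gating constant; apply an exclusion or continuity-correction policy first")
    return p / (1.0 - p)


def eeff_to_popen(e: float) -> float:
    """Forward relation: maxPopen = E/(E+1)."""
    if e < 0:
        raise DataError(f"gating constant must be >= 0, got {e!r}")
    return e / (e + 1.0)


def free_energy_change(
    e_ref: float, e_mod: float, constants: EfficacyConstants = EfficacyConstants()
) -> float:
    """ΔG = -RT ln(e_mod / e_ref), in kcal/mol."""
    if e_ref <= 0 or e_mod <= 0:
        raise DataError(
            f"gating constants must be strictly positive, got ({e_ref!r}, {e_mod!r})"
        )
    return -constants.RT_kcal * math.log(e_mod / e_ref)


def _corner_eeffs(
    cs: AgonistClusterSet, policy: str, epsilon_ms: float
) -> tuple[np.ndarray, int]:
    """Per-cluster E_eff values after applying the popen∈{0,1} policy."""
    p = np.asarray(cs.popens, dtype=float)
    if policy == "exclude":
        keep = (p > 0.0) & (p < 1.0)
        n_excluded = int((~keep).sum())
        p = p[keep]
    elif policy == "continuity":
        # (t_open + eps)/(t + 2 eps) applied on the probability scale with a
        # nominal unit duration; keeps every cluster at the cost of a small
        # shrinkage toward 1/2.
        eps = epsilon_ms
        p = (p + eps) / (1.0 + 2.0 * eps)
        n_excluded = 0
    else:
        raise DataError(f"unknown popen boundary policy {policy!r}")
    if p.size == 0:
        raise DataError(f"corner {cs.agonist!r} has no usable clusters after the boundary policy")
    return p / (1.0 - p), n_excluded


def _estimate(values: np.ndarray, estimator: str) -> float:
    if estimator == "mean":
        return float(np.mean(values))
    if estimator == "median":
        return float(np.median(values))
    raise DataError(f"estimator must be 'mean' or 'median', got {estimator!r}")


def cycle_from_eeffs(
    e_ref: float,
    e_len: float,
    e_swap: float,
    e_both: float,
    constants: EfficacyConstants = EfficacyConstants(),
) -> tuple[float, float, float, float, float, float]:
    """Edge ΔGs, coupling energy and closure residual from four corner E_eff."""
    dG1 = free_energy_change(e_ref, e_len, constants)
    dG1p = free_energy_change(e_swap, e_both, constants)
    dG2 = free_energy_change(e_ref, e_swap, constants)
    dG2p = free_energy_change(e_len, e_both, constants)
    ddG = dG1 - dG1p
    closure = (dG1 + dG2p) - (dG2 + dG1p)
    return dG1, dG2, dG1p, dG2p, ddG, closure


def coupling_energy(
    spec: CycleSpec,
    estimator: str = "mean",
    constants: EfficacyConstants = EfficacyConstants(),
    boundary_policy: str = "exclude",
    continuity_epsilon: float = 1e-3,
) -> ThermoCycleResult:
    """Point-estimate thermodynamic cycle from per-cluster E_eff values."""
    eeffs: dict[str, float] = {}
    n_excluded: dict[str, int] = {}
    for role, cs in spec.corners().items():
        vals, nex = _corner_eeffs(cs, boundary_policy, continuity_epsilon)
        eeffs[role] = _estimate(vals, estimator)
        n_excluded[role] = nex
    dG1, dG2, dG1p, dG2p, ddG, closure = cycle_from_eeffs(
        eeffs["reference"], eeffs["lengthened"], eeffs["swapped"], eeffs["both"], constants
    )
    assert abs(closure) < 1e-9, "cycle closure is an algebraic identity"
    return ThermoCycleResult(
        eeff_point=eeffs,
        dG1=dG1,
        dG2=dG2,
        dG1p=dG1p,
        dG2p=dG2p,
        ddG_int=ddG,
        closure_residual=closure,
        estimator=estimator,
        n_excluded=n_excluded,
    )


def bootstrap_cycle(
    spec: CycleSpec,
    n_boot: int = 10_000,
    seed: int = 0,
    estimator: str = "mean",
    constants: EfficacyConstants = EfficacyConstants(),
    boundary_policy: str = "exclude",
    continuity_epsilon: float = 1e-3,
) -> ThermoCycleResult:
    """Bootstrap the per-cluster E_eff values of each corner independently.

    Each of the ``n_boot`` replicates resamples every corner's E_eff list
    with replacement, recomputes the four edge free energies and the
    coupling energy, and the standard deviations of those replicate
    distributions are reported as the uncertainties.
    """
    if n_boot < 1:
        raise DataError(f"n_boot must be >= 1, got {n_boot!r}")
    point = coupling_energy(spec, estimator, constants, boundary_policy, continuity_epsilon)

    rng = np.random.default_rng(seed)
    rep_eeff: dict[str, np.ndarray] = {}
    for role, cs in spec.corners().items():
        vals, _ = _corner_eeffs(cs, boundary_policy, continuity_epsilon)
        if vals.size < 2:
            warnings.warn(
                f"corner {role!r} has fewer than 2 clusters; bootstrap SD is degenerate",
                stacklevel=2,
            )
        idx = _resample_indices(rng, vals.size, n_boot)
        draws = vals[idx]  # (n_boot, n)
        if estimator == "mean":
            rep_eeff[role] = draws.mean(axis=1)
        else:
            rep_eeff[role] = np.median(draws, axis=1)

    RT = constants.RT_kcal
    logs = {role: np.log(v) for role, v in rep_eeff.items()}
    dG1 = -RT * (logs["lengthened"] - logs["reference"])
    dG1p = -RT * (logs["both"] - logs["swapped"])
    dG2 = -RT * (logs["swapped"] - logs["reference"])
    dG2p = -RT * (logs["both"] - logs["lengthened"])
    ddG = dG1 - dG1p

    point.sd_dG = {
        "dG1": float(np.std(dG1, ddof=1)) if n_boot > 1 else 0.0,
        "dG2": float(np.std(dG2, ddof=1)) if n_boot > 1 else 0.0,
        "dG1p": float(np.std(dG1p, ddof=1)) if n_boot > 1 else 0.0,
        "dG2p": float(np.std(dG2p, ddof=1)) if n_boot > 1 else 0.0,
    }
    point.sd_ddG = float(np.std(ddG, ddof=1)) if n_boot > 1 else 0.0
    point.replicates_ddG = ddG
    point.n_boot = n_boot
    point.seed = seed
    return point
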