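"""Whole-cell dose-response analysis: Hill fits, rundown exclusion,
normalization/pooling, and the zwitterion-fraction helper.

Peak currents above baseline are fitted with the three-parameter Hill
equation

    I(c) = Imax * c^nH / (c^nH + EC50^nH)

by unweighted least squares.  Cells whose response to the interleaved
saturating reference agonist (100 mM glycine) runs down by more than 30%
are discarded.  For relative-efficacy curves a partial agonist's maximum is
expressed as a fraction of the same cell's glycine maximum.

The zwitterion helper is Henderson-Hasselbalch arithmetic for the amino
group: at pH around the pKa of 5.75 the fraction of aminomethanesulfonate
in its stable zwitterionic form changes steeply, which is why recordings
with this agonist are made at pH 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError


@dataclass
class CellDoseResponse:
    """One cell's peak currents (nA) at each agonist concentration (mM)."""

    cell_id: str
    points: list[tuple[float, float]]
    reference_responses: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(c <= 0 for c, _ in self.points):
            raise DataError(f"cell {self.cell_id}: concentrations must be positive")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=float)

    @property
    def currents(self) -> np.ndarray:
        return np.array([i for _, i in self.points], dtype=float)


@dataclass
class HillFit:
    Imax: float
    EC50: float
    nH: float
    converged: bool = True
    cov: np.ndarray | None = None
    residual_ss: float | None = None

    def to_dict(self) -> dict:
        return {
            "Imax": self.Imax,
            "EC50": self.EC50,
            "nH": self.nH,
            "converged": self.converged,
            "residual_ss": self.residual_ss,
        }


@dataclass(frozen=True)
class ProtonationSpec:
    pKa: float = 5.75
    pH: float = 7.4

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pKa) and np.isfinite(self.pH)):
            raise DataError("pH and pKa must be finite")


def hill_response(c, fit: HillFit):
    """Hill equation with bottom fixed at zero; vectorized over ``c``."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        out = fit.Imax * c**fit.nH / (c**fit.nH + fit.EC50**fit.nH)
    return out if out.shape else float(out)


def _hill(c, imax, ec50, nh):
    return imax * c**nh / (c**nh + ec50**nh)


def fit_hill(cell: CellDoseResponse, init: HillFit | None = None) -> HillFit:
    """Unweighted least-squares Hill fit of one cell's dose-response points.

    Initialization policy (fixed for determinism): Imax = max response,
    EC50 = concentration of the point nearest half-max, nH = 1.
    Non-convergence is reported as a flagged fit, not an exception.
    """
    c = cell.concentrations
    i = cell.currents
    if np.unique(c).size < 3:
        raise DataError(
            f"cell {cell.cell_id}: need >= 3 distinct concentrations, got {np.unique(c).size}"
        )
    if init is not None:
        p0 = [init.Imax, init.EC50, init.nH]
    else:
        imax0 = float(i.max())
        if imax0 <= 0:
            return HillFit(Imax=np.nan, EC50=np.nan, nH=np.nan, converged=False)
        ec50_0 = float(c[np.argmin(np.abs(i - imax0 / 2.0))])
        p0 = [imax0, ec50_0, 1.0]
    try:
        popt, pcov = curve_fit(
            _hill,
            c,
            i,
            p0=p0,
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, 10.0]),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError):
        return HillFit(Imax=np.nan, EC50=np.nan, nH=np.nan, converged=False)
    resid = i - _hill(c, *popt)
    return HillFit(
        Imax=float(popt[0]),
        EC50=float(popt[1]),
        nH=float(popt[2]),
        converged=True,
        cov=pcov,
        residual_ss=float(np.sum(resid**2)),
    )


def check_rundown(reference_responses, threshold: float = 0.30) -> dict:
    """Rundown rule: discard the cell if the reference response fell > 30%.

    ``max_decline = 1 - min(later responses)/first response`` (clipped at 0
    when responses grow); ``keep`` when the decline does not exceed the
    threshold.
    """
    r = np.asarray(reference_responses, dtype=float)
    if r.size < 2:
        raise DataError("need at least 2 reference responses to assess rundown")
    max_decline = max(0.0, 1.0 - float(r[1:].min()) / float(r[0]))
    return {"keep": max_decline <= threshold, "max_decline": max_decline}


def normalize_and_pool(
    cells: list[CellDoseResponse],
    mode: str = "own_max",
    rundown_threshold: float = 0.30,
    references: dict[str, float] | None = None,
) -> dict:
    """Normalize each cell, pool the points, and refit the Hill equation.

    ``mode="own_max"`` divides each cell's responses by its own maximum (the
    same-agonist dose-response convention); ``mode="reference"`` divides by
    the cell's saturating glycine response supplied in ``references``, so the
    pooled maximum of a partial agonist comes out as a fraction of the
    glycine maximum.  Cells failing the rundown check are rejected and
    recorded in the audit list.
    """
    if mode not in ("own_max", "reference"):
        raise DataError(f"mode must be 'own_max' or 'reference', got {mode!r}")
    kept: list[CellDoseResponse] = []
    audit: list[dict] = []
    points: list[tuple[float, float]] = []
    for cell in cells:
        if len(cell.reference_responses) >= 2:
            rd = check_rundown(cell.reference_responses, rundown_threshold)
            if not rd["keep"]:
                audit.append(
                    {"cell_id": cell.cell_id, "reason": "rundown", **rd}
                )
                continue
        if mode == "reference":
            if references is None or cell.cell_id not in references:
                raise DataError(f"missing reference response for cell {cell.cell_id!r}")
            denom = references[cell.cell_id]
        else:
            denom = float(cell.currents.max())
        if denom <= 0:
            raise DataError(f"cell {cell.cell_id}: non-positive normalization reference")
        kept.append(cell)
        points.extend((c, i / denom) for c, i in cell.points)

    if not kept:
        raise DataError("no cells passed the rundown criterion")
    pooled = CellDoseResponse(cell_id="pooled", points=points)
    return {"fit": fit_hill(pooled), "pooled": pooled, "cells_kept": kept, "audit": audit}


def zwitterion_fraction(spec: ProtonationSpec) -> float:
    """Protonated (zwitterionic) fraction of the amino group.

    Henderson-Hasselbalch: f = 1 / (1 + 10^(pH - pKa)).  With pKa 5.75 this
    gives ~2% at physiological pH 7.4 and ~85% at pH 5.
    """
    return 1.0 / (1.0 + 10.0 ** (spec.pH - spec.pKa))
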