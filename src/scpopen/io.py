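"""Readers and writers for the package's plain-text formats.

Dwell tables are CSV with columns ``record_id, cluster_id, state,
duration_ms, amplitude_pA`` and an optional ``truth_state``.  Per-cluster
open probabilities travel as CSV with columns ``agonist, patch_id, popen``
(layout compatible with spreadsheet-exported source data).  Sampled traces
are single-column CSV plus a JSON sidecar with ``fs, fc, baseline, amp``.
All readers validate and reject malformed rows rather than coercing them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clusters import AgonistClusterSet
from .errors import DataError, SchemaError
from .simulate import DESENSITIZED, Dwell, IdealizedRecord, SampledTrace

DWELL_COLUMNS = ["record_id", "cluster_id", "state", "duration_ms", "amplitude_pA"]
_STATES = {"open", "shut", "desensitized"}


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def write_dwell_table(records: list[IdealizedRecord] | IdealizedRecord, path) -> None:
    if isinstance(records, IdealizedRecord):
        records = [records]
    rows = []
    for rec in records:
        cluster_id = 0
        for i, d in enumerate(rec.dwells):
            row = {
                "record_id": rec.record_id,
                "cluster_id": cluster_id,
                "state": d.state,
                "duration_ms": d.duration_ms,
                "amplitude_pA": d.amplitude_pA,
            }
            if rec.truth is not None:
                row["truth_state"] = rec.truth[i]
            rows.append(row)
            if d.state == DESENSITIZED:
                cluster_id += 1
    # %.17g guarantees exact float round-trips through the CSV
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_dwell_table(path) -> dict[str, IdealizedRecord]:
    """Parse a dwell-table CSV into records keyed by ``record_id``."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DWELL_COLUMNS, path)
    if df.empty:
        import warnings

        warnings.warn(f"{path}: dwell table has a valid header but no rows", stacklevel=2)
        return {}
    bad_dur = df.index[~(df["duration_ms"] > 0)]
    if len(bad_dur):
        raise DataError(
            f"{path}: non-positive duration_ms at row {int(bad_dur[0]) + 2} "
            "(1-based, counting the header)"
        )
    bad_state = df.index[~df["state"].isin(_STATES)]
    if len(bad_state):
        raise DataError(
            f"{path}: unknown state {df.loc[bad_state[0], 'state']!r} at row "
            f"{int(bad_state[0]) + 2}"
        )
    records: dict[str, IdealizedRecord] = {}
    has_truth = "truth_state" in df.columns
    for rid, grp in df.groupby("record_id", sort=False):
        dwells = [
            Dwell(r.state, float(r.duration_ms), float(r.amplitude_pA))
            for r in grp.itertuples()
        ]
        truth = list(grp["truth_state"]) if has_truth else None
        records[str(rid)] = IdealizedRecord(
            dwells=dwells, sample_interval_ms=None, truth=truth, record_id=str(rid)
        )
    return records


def read_popen_table(path) -> dict[str, AgonistClusterSet]:
    """Read per-cluster Popen rows grouped into per-agonist sets.

    Required columns: ``agonist, patch_id, popen``; optional
    ``concentration_mM`` and ``pH``.  Duplicate rows are preserved — each
    row is one cluster observation.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["agonist", "patch_id", "popen"], path)
    bad = df.index[~df["popen"].astype(float).between(0.0, 1.0)]
    if len(bad):
        raise DataError(
            f"{path}: popen outside [0, 1] at row {int(bad[0]) + 2} "
            f"(value {df.loc[bad[0], 'popen']!r})"
        )
    sets: dict[str, AgonistClusterSet] = {}
    for agonist, grp in df.groupby("agonist", sort=False):
        sets[str(agonist)] = AgonistClusterSet(
            agonist=str(agonist),
            popens=[float(p) for p in grp["popen"]],
            n_patches=int(grp["patch_id"].nunique()),
            concentration_mM=(
                float(grp["concentration_mM"].iloc[0])
                if "concentration_mM" in grp.columns
                else None
            ),
            pH=float(grp["pH"].iloc[0]) if "pH" in grp.columns else None,
        )
    return sets


def write_popen_table(sets: dict[str, AgonistClusterSet], path) -> None:
    rows = []
    for agonist, cs in sets.items():
        for j, p in enumerate(cs.popens):
            rows.append({"agonist": agonist, "patch_id": 1, "cluster_id": j, "popen": p})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_trace(trace: SampledTrace, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    np.savetxt(csv_path, trace.samples, fmt="%.8g", header="current_pA", comments="")
    meta = {"fs": trace.fs, "fc": trace.fc, "baseline": trace.baseline, "amp": trace.amp}
    Path(sidecar_path).write_text(json.dumps(meta, sort_keys=True, indent=1))


def read_trace(csv_path, sidecar_path=None) -> SampledTrace:
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    try:
        meta = json.loads(Path(sidecar_path).read_text())
    except FileNotFoundError as exc:
        raise DataError(f"trace sidecar {sidecar_path} not found") from exc
    samples = np.loadtxt(csv_path, skiprows=1)
    return SampledTrace(
        samples=np.atleast_1d(samples),
        fs=float(meta["fs"]),
        fc=float(meta["fc"]),
        baseline=float(meta.get("baseline", 0.0)),
        amp=float(meta.get("amp", 5.0)),
    )


def write_json(obj, path) -> None:
    """Deterministic JSON writer (sorted keys, fixed float repr)."""
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1, default=_jsonify))


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"cannot serialize {type(x)!r}")
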