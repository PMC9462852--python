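"""Top-level pipeline: simulate -> (render/idealize) -> clusters -> cycle.

A :class:`PipelineConfig` carries every stage parameter and a single global
seed from which per-stage seeds are derived by fixed offsets, so a rerun
with the same config produces byte-identical outputs.  Each run writes the
per-agonist cluster tables, summary statistics, the thermodynamic-cycle
result, and a manifest recording the configuration, the seeds and the
SHA-256 of every output file.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import __version__
from .clusters import cluster_popen, filter_clusters, segment_clusters, summarize
from .cycle import CycleSpec, bootstrap_cycle
from .errors import ConfigurationError
from .idealize import IdealizationSettings, gaussian_filter, resample, threshold_idealize
from .io import write_dwell_table, write_json, write_popen_table
from .simulate import GatingParams, alpha_for_popen, render_trace, simulate_dwells
from .clusters import AgonistClusterSet

log = logging.getLogger("scpopen")

#: fixed per-stage seed offsets derived from the global seed
SEED_OFFSETS = {"simulate": 1, "render": 101, "bootstrap": 901}

#: corner roles of the agonist thermodynamic cycle
DEFAULT_ROLES = {
    "glycine": "reference",
    "beta-alanine": "lengthened",
    "AMS": "swapped",
    "taurine": "both",
}

DEFAULT_TARGETS = {"glycine": 0.96, "beta-alanine": 0.54, "AMS": 0.85, "taurine": 0.12}


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "scpopen_out"
    targets: dict = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    roles: dict = field(default_factory=lambda: dict(DEFAULT_ROLES))
    # opening rate is fixed (mean shut 4 ms << tcrit) and the closing rate
    # is derived per agonist from its target Popen
    beta: float = 250.0
    desens_prob: float = 0.01
    mean_desens: float = 2.0
    n_clusters: int = 100
    render: bool = False
    fs: float = 100_000.0
    fc: float = 10_000.0
    amp: float = 5.0
    noise_sd: float = 0.5
    fc_post: float = 3000.0
    fs_out: float = 33_333.0
    threshold_frac: float = 0.5
    tcrit_ms: float = 100.0
    min_duration_ms: float = 100.0
    exclude_double: bool = True
    n_boot: int = 10_000
    estimator: str = "mean"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a global seed is required")
        missing = set(self.roles) - set(self.targets)
        if missing:
            raise ConfigurationError(f"roles reference unknown agonists: {sorted(missing)}")
        roles = set(self.roles.values())
        if roles != {"reference", "lengthened", "swapped", "both"}:
            raise ConfigurationError(f"roles must cover the four cycle corners, got {sorted(roles)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write all stage outputs plus a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    sets: dict[str, AgonistClusterSet] = {}
    summaries = {}
    for i, (agonist, target) in enumerate(sorted(config.targets.items())):
        params = GatingParams(
            alpha=alpha_for_popen(config.beta, target),
            beta=config.beta,
            desens_prob=config.desens_prob,
            mean_desens=config.mean_desens,
            n_clusters=config.n_clusters,
            seed=(config.seed + SEED_OFFSETS["simulate"] + i) % 2**31,
        )
        record = simulate_dwells(params, amp=config.amp)
        record.record_id = agonist
        if config.render:
            trace = render_trace(
                record,
                fs=config.fs,
                amp=config.amp,
                noise_sd=config.noise_sd,
                fc=config.fc,
                seed=(config.seed + SEED_OFFSETS["render"] + i) % 2**31,
            )
            settings = IdealizationSettings(
                fc_post=config.fc_post,
                fs_out=config.fs_out,
                threshold_frac=config.threshold_frac,
            )
            idealized = threshold_idealize(
                resample(gaussian_filter(trace, config.fc_post), config.fs_out), settings
            )
        else:
            idealized = record
        clusters = segment_clusters(idealized, tcrit_ms=config.tcrit_ms)
        kept, audit = filter_clusters(
            clusters,
            min_duration_ms=config.min_duration_ms,
            exclude_double=config.exclude_double,
        )
        log.info(
            "%s: %d clusters segmented, %d accepted, %d rejected",
            agonist,
            len(clusters),
            len(kept),
            len(audit),
        )
        cs = AgonistClusterSet(agonist=agonist, popens=[cluster_popen(c) for c in kept])
        sets[agonist] = cs
        summaries[agonist] = summarize(cs)

        dwell_path = outdir / f"dwells_{agonist}.csv"
        write_dwell_table(record, dwell_path)
        written.append(dwell_path)

    popen_path = outdir / "cluster_popen.csv"
    write_popen_table(sets, popen_path)
    written.append(popen_path)

    summary_path = outdir / "summary.json"
    write_json(summaries, summary_path)
    written.append(summary_path)

    by_role = {config.roles[a]: sets[a] for a in config.roles}
    result = bootstrap_cycle(
        CycleSpec(
            reference=by_role["reference"],
            lengthened=by_role["lengthened"],
            swapped=by_role["swapped"],
            both=by_role["both"],
        ),
        n_boot=config.n_boot,
        seed=(config.seed + SEED_OFFSETS["bootstrap"]) % 2**31,
        estimator=config.estimator,
    )
    cycle_path = outdir / "cycle.json"
    write_json(result.to_dict(), cycle_path)
    written.append(cycle_path)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "outputs": {p.name: _sha256(p) for p in written},
    }
    manifest_path = outdir / "manifest.json"
    write_json(manifest, manifest_path)

    return {"sets": sets, "summaries": summaries, "cycle": result, "manifest": manifest}
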