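"""End-to-end orchestration from a declarative YAML run configuration.

A run configuration names the inputs for any subset of the analysis
stages -- batch-assay rate estimation (with optional pathway
partitioning of anammox-type assays), reactor-cycle guard checks,
clone-library diversity, and tree building -- and :func:`run` executes
the configured stages in dependency order, recording per-stage failures
without aborting independent stages.  The report is a JSON-serializable
dict with stable key ordering; trees are written as sibling Newick
files referenced by path.

Configuration schema (all sections optional)::

    seed: 1                     # global seed, recorded in the report
    output_dir: out             # where report.json and trees are written
    assays:
      - path: bottle1.csv       # time_min,TAN_mgN_L,TNN_mgN_L,NO3_mgN_L
        label: aob_pH8
        assay_type: AOB_aerobic # or anammox_anoxic, denitrification_*
        condition: {pH: 8.0, temperature_C: 23.0, protein_conc: 2.85, tss: 10.0}
        partition: false        # partition nitrite sinks from the ratio
    clone_libraries:
      - {path: amoa_counts.csv, marker: amoA}
    alignments:
      - {path: clones.fasta, model: jc, bootstrap: 100}
    envelope:
      path: cycle.csv           # phase,tan_mgN_L,tnn_mgN_L,ph,temp_C
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assay import BatchAssayModel, read_assay_csv
from .diversity import read_clone_counts
from .envelope import OperatingPoint, check_sbr_guards
from .errors import ConfigError, SnadError
from .partition import partition_nitrite
from .phylo import bootstrap_support, distance_matrix, nj_tree, read_fasta
from .speciation import AssayCondition

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with paths resolved against its base dir."""

    assays: tuple[dict, ...] = ()
    clone_libraries: tuple[dict, ...] = ()
    alignments: tuple[dict, ...] = ()
    envelope: dict | None = None
    seed: int = 0
    output_dir: Path = Path("snadlab_out")
    base_dir: Path = Path(".")

    def resolve(self, p) -> Path:
        path = Path(p)
        return path if path.is_absolute() else self.base_dir / path


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run configuration must be a mapping")
    cfg = RunConfig(
        assays=tuple(raw.get("assays", ()) or ()),
        clone_libraries=tuple(raw.get("clone_libraries", ()) or ()),
        alignments=tuple(raw.get("alignments", ()) or ()),
        envelope=raw.get("envelope"),
        seed=int(raw.get("seed", 0)),
        output_dir=Path(raw.get("output_dir", "snadlab_out")),
        base_dir=path.parent,
    )
    for section, entries in (
        ("assays", cfg.assays),
        ("clone_libraries", cfg.clone_libraries),
        ("alignments", cfg.alignments),
    ):
        for entry in entries:
            if "path" not in entry:
                raise ConfigError(f"every {section} entry needs a 'path'")
            if not cfg.resolve(entry["path"]).exists():
                raise ConfigError(f"{section}: file not found: {entry['path']}")
    if cfg.envelope is not None and not cfg.resolve(cfg.envelope["path"]).exists():
        raise ConfigError(f"envelope: file not found: {cfg.envelope['path']}")
    return cfg


def _condition_from(entry: dict) -> AssayCondition:
    return AssayCondition(**(entry.get("condition") or {}))


def _run_assays(cfg: RunConfig) -> dict:
    out = {}
    for entry in cfg.assays:
        label = entry.get("label") or Path(entry["path"]).stem
        series = read_assay_csv(
            cfg.resolve(entry["path"]),
            condition=_condition_from(entry),
            assay_type=entry.get("assay_type", "AOB_aerobic"),
            label=label,
        )
        res = BatchAssayModel(series).fit(
            window=tuple(entry["window"]) if "window" in entry else None,
            trim_lag=bool(entry.get("trim_lag", False)),
        )
        report = res.to_dict()
        if entry.get("partition") and res.headline_ratio is not None:
            report["partition"] = partition_nitrite(res.headline_ratio.ratio).to_dict()
        out[label] = report
    return out


def _run_envelope(cfg: RunConfig) -> dict:
    df = pd.read_csv(cfg.resolve(cfg.envelope["path"]))
    points = [
        OperatingPoint(
            tan=float(r["tan_mgN_L"]),
            tnn=float(r.get("tnn_mgN_L", 0.0)),
            pH=float(r["ph"]),
            temperature_C=float(r["temp_C"]),
            phase_label=str(r["phase"]),
        )
        for _, r in df.iterrows()
    ]
    return check_sbr_guards(points)


def _run_diversity(cfg: RunConfig) -> dict:
    out = {}
    for entry in cfg.clone_libraries:
        marker = entry.get("marker") or Path(entry["path"]).stem
        out[marker] = read_clone_counts(cfg.resolve(entry["path"]), marker=marker).summary()
    return out


def _run_trees(cfg: RunConfig, outdir: Path) -> dict:
    out = {}
    for entry in cfg.alignments:
        name = entry.get("label") or Path(entry["path"]).stem
        aln = read_fasta(cfg.resolve(entry["path"]), kind=entry.get("kind"))
        model = entry.get("model", "jc" if aln.kind == "nt" else "poisson")
        n_boot = int(entry.get("bootstrap", 0))
        if n_boot > 0:
            tree = bootstrap_support(aln, model=model, n_reps=n_boot, seed=cfg.seed)
        else:
            tree = nj_tree(distance_matrix(aln, model))
        tree_path = outdir / f"{name}.nwk"
        tree.write(tree_path)
        out[name] = {
            "model": model,
            "n_sequences": len(aln),
            "n_sites": aln.n_sites,
            "bootstrap_replicates": tree.bootstrap_replicates,
            "bootstrap_dropped": tree.bootstrap_dropped,
            "newick_file": tree_path.name,
            "newick": tree.to_newick(),
        }
    return out


def run(config: RunConfig | str | Path, write: bool = True) -> dict:
    """Execute all configured stages; return the machine-readable report.

    Stages are independent: a failure in one is recorded under
    ``errors`` and the remaining stages still run.  Deterministic for a
    fixed seed.  When ``write`` is true the report is saved as
    ``report.json`` in the configured output directory (trees are
    always written there).
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    outdir = cfg.output_dir if cfg.output_dir.is_absolute() else cfg.base_dir / cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "software": {"name": "snadlab", "version": __version__},
        "seed": cfg.seed,
        "config": {
            "assays": [dict(e) for e in cfg.assays],
            "clone_libraries": [dict(e) for e in cfg.clone_libraries],
            "alignments": [dict(e) for e in cfg.alignments],
            "envelope": cfg.envelope,
        },
        "errors": {},
    }
    stages = []
    if cfg.assays:
        stages.append(("assays", lambda: _run_assays(cfg)))
    if cfg.envelope:
        stages.append(("envelope", lambda: _run_envelope(cfg)))
    if cfg.clone_libraries:
        stages.append(("diversity", lambda: _run_diversity(cfg)))
    if cfg.alignments:
        stages.append(("trees", lambda: _run_trees(cfg, outdir)))

    for name, fn in stages:
        logger.info("[%s] running", name)
        try:
            report[name] = fn()
        except SnadError as exc:
            logger.error("[%s] failed: %s", name, exc)
            report["errors"][name] = f"{type(exc).__name__}: {exc}"

    if write:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
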