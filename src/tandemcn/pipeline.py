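"""Stage orchestration: simulate -> summarize -> select -> quantify -> stats.

Each stage reads the previous stage's on-disk outputs, writes its own
atomically (tmp file + rename), and records itself in a JSON run manifest
with a config hash and output checksums, so a re-run with the same seed is
verifiably identical.  Stages can be run individually or via ``run_all``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import architecture, copynumber, coverage, gee, selection, simulate, stats

log = logging.getLogger("tandemcn")

STAGES = ("simulate", "summarize", "select-exons", "copynumber", "architecture", "stats")


@dataclass
class RunConfig:
    """One config object for the whole pipeline (YAML-loadable)."""

    outdir: str = "results"
    seed: int = 0
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    min_exon_length: int = 300
    tolerance: float = 0.10
    min_lineages: int | None = None
    outlier_factor: float = 2.0
    evalue_cutoff: float = architecture.DEFAULT_EVALUE_CUTOFF
    gee_gene: str = "5.8S"
    skip_architecture: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.tolerance < 1:
            raise ValueError("tolerance must lie in (0, 1)")
        if self.outlier_factor <= 1:
            raise ValueError("outlier factor must exceed 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("e-value cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        if "seed" in raw and "seed" not in sim_raw:
            sim_raw["seed"] = raw["seed"]
        for key in ("cn_range_sexual", "cn_range_asexual", "five_s_dropout_range",
                    "outlier_factors"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(sim_raw[key])
        cfg = cls(**raw, simulation=simulate.SimulationConfig(**sim_raw))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    tmp = Path(tempfile.mkstemp(dir=path.parent, suffix=".tmp")[1])
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {
                "tool": "tandemcn",
                "version": __version__,
                "config_hash": config.config_hash(),
                "stages": {},
            }

    def record(self, stage: str, outputs: list[Path], skipped: bool = False) -> None:
        self.data["stages"][stage] = {
            "skipped": skipped,
            "outputs": {
                str(p.name): _checksum(p) for p in outputs if p.is_file()
            },
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    _atomic_write(
        path, lambda tmp: df.to_csv(tmp, sep="\t", index=False, float_format="%.6g")
    )


def _stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    sim = simulate.simulate_all(sim_cfg)
    paths = simulate.write_cohort(sim, outdir)
    return [p for p in paths.values() if isinstance(p, Path) and p.is_file()]


def _load_depth_tracks(outdir: Path) -> dict[str, list[coverage.DepthTrack]]:
    depth_dir = outdir / "depth"
    if not depth_dir.is_dir():
        raise FileNotFoundError(f"missing upstream depth tables in {depth_dir}")
    tracks = {}
    for path in sorted(depth_dir.glob("*.depth.tsv")):
        lineage = path.name.removesuffix(".depth.tsv")
        tracks[lineage] = coverage.read_depth_table(path, lineage=lineage)
    if not tracks:
        raise FileNotFoundError(f"no depth tables found in {depth_dir}")
    return tracks


def _stage_summarize(config: RunConfig, outdir: Path) -> list[Path]:
    tracks = _load_depth_tracks(outdir)
    all_tracks = [t for ts in tracks.values() for t in ts]
    summaries = coverage.summarize_all(all_tracks)
    out = outdir / "summaries.tsv"
    _write_tsv(summaries, out)
    return [out]


def _stage_select(config: RunConfig, outdir: Path) -> list[Path]:
    models_path = outdir / "gene_models.tsv"
    summaries_path = outdir / "summaries.tsv"
    for p in (models_path, summaries_path):
        if not p.is_file():
            raise FileNotFoundError(f"missing upstream file: {p}")
    gene_models = pd.read_csv(models_path, sep="\t")
    summaries = pd.read_csv(summaries_path, sep="\t")
    candidates = selection.pick_candidates(gene_models, config.min_exon_length)
    result = selection.select_single_copy(
        summaries,
        candidates,
        tolerance=config.tolerance,
        min_lineages=config.min_lineages,
        outlier_factor=config.outlier_factor,
    )
    retained_path = outdir / "retained_exons.tsv"
    _write_tsv(
        pd.DataFrame(
            {
                "exon_id": result.retained,
            }
        ),
        retained_path,
    )
    matrix_path = outdir / "pass_matrix.tsv"
    _atomic_write(
        matrix_path,
        lambda tmp: result.pass_matrix.rename_axis("exon_id").to_csv(tmp, sep="\t"),
    )
    report_path = outdir / "selection_report.txt"
    _atomic_write(
        report_path, lambda tmp: tmp.write_text(selection.selection_report(result))
    )
    return [retained_path, matrix_path, report_path]


def _stage_copynumber(config: RunConfig, outdir: Path) -> list[Path]:
    retained_path = outdir / "retained_exons.tsv"
    if not retained_path.is_file():
        raise FileNotFoundError(f"missing upstream file: {retained_path}")
    retained = pd.read_csv(retained_path, sep="\t")["exon_id"].tolist()
    tracks = _load_depth_tracks(outdir)
    counts_path = outdir / "read_counts.tsv"
    read_counts = (
        pd.read_csv(counts_path, sep="\t") if counts_path.is_file() else None
    )
    table, proportions = copynumber.build_table(
        tracks, retained, simulate.UNIT_GENES, read_counts
    )
    cn_path = outdir / "copy_number.tsv"
    _atomic_write(cn_path, lambda tmp: copynumber.write_table(table, tmp))
    outputs = [cn_path]
    if proportions is not None:
        prop_path = outdir / "proportions.tsv"
        _write_tsv(proportions, prop_path)
        outputs.append(prop_path)
    return outputs


def _stage_architecture(config: RunConfig, outdir: Path) -> list[Path]:
    hits_path = outdir / "blast_hits.tsv"
    if not hits_path.is_file():
        raise FileNotFoundError(f"missing upstream file: {hits_path}")
    hits = architecture.read_blast_tab(hits_path)
    filtered = architecture.filter_hits(hits, config.evalue_cutoff)
    model = architecture.infer_unit_model(filtered)
    model_path = outdir / "unit_model.tsv"
    _write_tsv(model.consensus, model_path)
    schematic_path = outdir / "unit_schematic.txt"
    _atomic_write(
        schematic_path, lambda tmp: tmp.write_text(architecture.report(model))
    )
    return [model_path, schematic_path]


def _stage_stats(config: RunConfig, outdir: Path) -> list[Path]:
    cn_path = outdir / "copy_number.tsv"
    meta_path = outdir / "lineages.tsv"
    tree_path = outdir / "tree.nwk"
    for p in (cn_path, meta_path):
        if not p.is_file():
            raise FileNotFoundError(f"missing upstream file: {p}")
    if not tree_path.is_file():
        raise FileNotFoundError(
            f"missing tree file {tree_path}; the phylogenetic GEE requires one"
        )
    table = copynumber.read_table(cn_path)
    metadata = pd.read_csv(meta_path, sep="\t")
    outputs = []

    modes = set(metadata["mode"])
    if {"sexual", "asexual"} <= modes:
        tests = stats.compare_modes(table.values, metadata)
        corr, _ = stats.pearson_matrix(
            table.values[list(simulate.SHARED_UNIT_GENES)]
        )
        corr_path = outdir / "pearson_matrix.tsv"
        _atomic_write(
            corr_path, lambda tmp: corr.rename_axis("gene").to_csv(
                tmp, sep="\t", float_format="%.6g"
            )
        )
        outputs.append(corr_path)
        tree = gee.load_tree(tree_path)
        fit = gee.fit_mode_gee(table.values, metadata, tree, gene=config.gee_gene)
        gee_path = outdir / "gee_fit.tsv"
        _atomic_write(
            gee_path,
            lambda tmp: fit.summary()
            .rename_axis("coefficient")
            .to_csv(tmp, sep="\t", float_format="%.6g"),
        )
        outputs.append(gee_path)
    else:
        log.warning("only one reproductive mode present; skipping two-group tests")
        tests = pd.DataFrame(
            columns=["test", "statistic", "pvalue", "exact", "family", "pvalue_adj"]
        )
    tests_path = outdir / "stats_tests.tsv"
    _write_tsv(tests, tests_path)
    outputs.append(tests_path)
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "summarize": _stage_summarize,
    "select-exons": _stage_select,
    "copynumber": _stage_copynumber,
    "architecture": _stage_architecture,
    "stats": _stage_stats,
}


def quantify(
    sim: simulate.SimulatedCohort,
    tolerance: float = 0.10,
    min_lineages: int | None = None,
    outlier_factor: float = 2.0,
) -> tuple[
    copynumber.CopyNumberTable, pd.DataFrame | None, selection.SelectionResult
]:
    """In-memory pipeline: summaries -> exon selection -> copy-number table.

    Convenience wrapper over the same operations the disk stages run, for
    interactive use on a :class:`~tandemcn.simulate.SimulatedCohort`.
    """
    tracks = {
        lid: coverage.tracks_from_frame(table, lid)
        for lid, table in sim.depth_tables.items()
    }
    summaries = coverage.summarize_all([t for ts in tracks.values() for t in ts])
    candidates = selection.pick_candidates(sim.reference.gene_models)
    result = selection.select_single_copy(
        summaries,
        candidates,
        tolerance=tolerance,
        min_lineages=min_lineages,
        outlier_factor=outlier_factor,
    )
    table, proportions = copynumber.build_table(
        tracks, result.retained, simulate.UNIT_GENES, sim.read_counts
    )
    return table, proportions, result


def run_stage(stage: str, config: RunConfig) -> list[Path]:
    """Run one named stage, record it in the manifest, return its outputs."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config)
    if stage == "architecture" and config.skip_architecture:
        log.info("stage %s skipped by config", stage)
        manifest.record(stage, [], skipped=True)
        return []
    log.info("running stage %s -> %s", stage, outdir)
    outputs = _STAGE_FUNCS[stage](config, outdir)
    manifest.record(stage, outputs)
    return outputs


def run_all(config: RunConfig) -> dict[str, list[Path]]:
    """Run every stage in order; returns outputs per stage."""
    results = {}
    for stage in STAGES:
        results[stage] = run_stage(stage, config)
    return results
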