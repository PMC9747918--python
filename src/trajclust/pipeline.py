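"""End-to-end orchestration: simulate/read → screen → trajectories →
two-step clustering → enrichment, with a manifest and deterministic seeding.

A single master seed deterministically derives per-stage seeds, so one
number reproduces a whole run bit-identically. Every intermediate table is
written as TSV under the output directory; the manifest (YAML) echoes the
configuration and records per-stage counts, the chosen cluster number, the
agreement statistics and any significant enrichments. A failing stage
aborts the run, leaving partial outputs plus a FAILED marker in the
manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import TwoStepResult, two_step_cluster
from .enrichment import EnrichmentTable, enrich_clusters
from .io import (CountMatrix, GeneSetCollection, log2_cpm, read_counts,
                 read_gmt, write_table)
from .screen import ScreenResult, screen_genes
from .simulate import SimConfig, simulate_timecourse, write_fixture
from .trajectories import build_trajectories, write_trajectories


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one data source must be set."""

    # data source: either explicit paths ...
    counts_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    # ... or a simulation block
    simulate: SimConfig | None = None

    # screen
    screen_alpha: float = 0.1
    screen_expr_min: float = 1.0
    # trajectories
    trajectory_mode: str = "logfc"
    time_scale: float = 1.0
    # clustering
    n_train: int = 500
    k_min: int = 2
    k_max: int = 10
    n_components: int = 3
    restarts: int = 50
    # enrichment
    enrich_alpha: float = 0.05
    universe_mode: str = "annotated"
    # master seed
    seed: int = 0

    def validate(self) -> None:
        has_paths = self.counts_path is not None or self.design_path is not None
        has_sim = self.simulate is not None
        if has_paths and has_sim:
            raise ValueError("config must set either input paths or a "
                             "simulate block, not both")
        if not has_paths and not has_sim:
            raise ValueError("config needs input paths or a simulate block")
        if has_paths and (self.counts_path is None or self.design_path is None):
            raise ValueError("both counts_path and design_path are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            if "time_grid_h" in sim:
                sim["time_grid_h"] = tuple(sim["time_grid_h"])
            for key in ("baseline_log2cpm_range", "library_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulate = SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulate is not None:
            out["simulate"] = dataclasses.asdict(self.simulate)
        return out


@dataclass
class RunManifest:
    """Summary of one pipeline run, written as manifest.yaml."""

    config: dict
    seed: int
    version: str
    status: str = "OK"
    failed_stage: str | None = None
    counts: dict = field(default_factory=dict)
    chosen_k: int | None = None
    agreement_percent: float | None = None
    agreement_kappa: float | None = None
    significant_enrichments: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    manifest: RunManifest
    matrix: CountMatrix
    screen: ScreenResult | None
    two_step: TwoStepResult | None
    enrichment: EnrichmentTable | None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute every stage in order, writing tables and a manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.to_dict(), config.seed, __version__)
    sim_seed, cluster_seed = _derive_seeds(config.seed, 2)

    screen = two_step = enrich = None
    matrix = None
    stage = "input"
    try:
        gene_sets: GeneSetCollection | None = None
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=sim_seed)
            matrix, truth = simulate_timecourse(sim_cfg)
            write_fixture(matrix, truth, outdir / "input")
            gene_sets = truth.gene_sets if len(truth.gene_sets) else None
        else:
            matrix = read_counts(config.counts_path, config.design_path)
            if config.gmt_path:
                gene_sets = read_gmt(config.gmt_path)
        manifest.counts["genes_input"] = matrix.n_genes
        manifest.counts["samples"] = matrix.n_samples

        stage = "screen"
        screen = screen_genes(matrix, alpha=config.screen_alpha,
                              expr_min=config.screen_expr_min)
        write_table(screen.table, outdir / "screen.tsv", index_label="gene")
        selected = screen.passing_genes
        manifest.counts["genes_screened"] = screen.n_tested
        manifest.counts["genes_passed"] = len(selected)

        stage = "trajectories"
        expr = log2_cpm(matrix)
        ts = build_trajectories(expr, selected, mode=config.trajectory_mode)
        write_trajectories(ts, outdir / "trajectories.tsv")

        stage = "cluster"
        two_step = two_step_cluster(
            ts, n_train=config.n_train, k_min=config.k_min,
            k_max=config.k_max, n_components=config.n_components,
            restarts=config.restarts, seed=cluster_seed,
            time_scale=config.time_scale)
        write_table(two_step.cascade.summary(), outdir / "cascade.tsv")
        write_table(two_step.embedding.to_frame(), outdir / "embedding.tsv",
                    index_label="gene")
        write_table(two_step.references.profiles, outdir / "references.tsv",
                    index_label="cluster")
        write_table(two_step.assignment.table, outdir / "assignments.tsv",
                    index_label="gene")
        write_table(two_step.agreement.confusion, outdir / "agreement.tsv",
                    index_label="step1")
        manifest.counts["genes_trained"] = len(two_step.training_labels)
        manifest.counts["genes_clustered"] = len(two_step.assignment.table)
        manifest.chosen_k = int(two_step.cascade.chosen_k)
        manifest.agreement_percent = round(float(two_step.agreement.percent), 4)
        manifest.agreement_kappa = round(float(two_step.agreement.kappa), 6)

        if gene_sets is not None and len(gene_sets):
            stage = "enrichment"
            enrich = enrich_clusters(two_step.assignment, gene_sets,
                                     universe_mode=config.universe_mode,
                                     alpha=config.enrich_alpha)
            write_table(enrich.table, outdir / "enrichment.tsv")
            manifest.significant_enrichments = [
                {"cluster": str(r["cluster"]), "set": str(r["set"]),
                 "bonferroni": float(r["bonferroni"])}
                for _, r in enrich.significant.iterrows()
            ]
    except Exception as exc:
        manifest.status = "FAILED"
        manifest.failed_stage = stage
        manifest.write(outdir / "manifest.yaml")
        raise StageError(stage, exc) from exc

    manifest.write(outdir / "manifest.yaml")
    return PipelineResult(manifest, matrix, screen, two_step, enrich)
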