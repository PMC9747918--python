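"""Synthetic two-arm time-course RNA-seq counts with planted response patterns.

The generator emulates a treated-vs-vehicle experiment read out at a handful
of time points with a few biological replicates per arm and time point
(default: 2 arms × {4, 12, 24, 48} h × 3 replicates). Each gene is either a
non-responder (flat in both arms) or follows one of six response archetypes
in the treated arm:

1. gradual sustained up-regulation,
2. rapid sustained up-regulation,
3. transient down-regulation, recovered by mid-course,
4. rapid sustained down-regulation,
5. gradual sustained down-regulation,
6. transient up-regulation.

Templates are piecewise-linear, unit-amplitude curves over min-max-normalized
time; the treated-arm expected expression is
``log2(CPM + 1) = baseline + amplitude * template(pattern, t)`` while the
control arm stays at the flat baseline. Noise enters twice: gene-wise
Gaussian jitter on the log2 mean (biological replicate scatter) and
negative-binomial sampling at the count level (variance = mu + phi * mu^2).

A pathway annotation is planted alongside: one gene set draws most of its
members from a single response pattern, so that downstream over-representation
tests have a known positive, while the remaining sets are uniform draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSetCollection, write_counts, write_gmt

# Anchor points (normalized time u in [0,1], value) for the six archetypes.
# Piecewise-linear interpolation between anchors yields the template.
_PATTERN_ANCHORS: dict[int, tuple[tuple[float, float], ...]] = {
    1: ((0.0, 0.0), (1.0, 1.0)),                    # gradual sustained up
    2: ((0.0, 0.8), (0.25, 1.0), (1.0, 1.0)),       # rapid sustained up
    3: ((0.0, -1.0), (0.45, 0.0), (1.0, 0.0)),      # transient down, recovers
    4: ((0.0, -0.8), (0.25, -1.0), (1.0, -1.0)),    # rapid sustained down
    5: ((0.0, 0.0), (1.0, -1.0)),                   # gradual sustained down
    6: ((0.0, 1.0), (0.45, 0.0), (1.0, 0.0)),       # transient up
}

PATTERN_IDS: tuple[int, ...] = tuple(sorted(_PATTERN_ANCHORS))
NULL_PATTERN = "null"


def pattern_template(pattern_id: int, time_grid_h) -> np.ndarray:
    """Unit-amplitude response curve for one archetype on a time grid.

    Time is min-max scaled to [0, 1] before evaluating the piecewise-linear
    template, so the shapes are invariant to the absolute hours used. A
    single-point grid evaluates the template at u = 0.
    """
    if pattern_id not in _PATTERN_ANCHORS:
        raise ValueError(
            f"unknown pattern id {pattern_id!r}; valid ids are {list(PATTERN_IDS)}"
        )
    t = np.asarray(time_grid_h, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time grid must be a nonempty 1-D sequence of hours")
    span = t.max() - t.min()
    u = np.zeros_like(t) if span == 0 else (t - t.min()) / span
    xs, ys = zip(*_PATTERN_ANCHORS[pattern_id])
    return np.interp(u, xs, ys)


@dataclass
class SimConfig:
    """Configuration of the synthetic study design.

    Defaults mirror the emulated experiment: four time points, two arms,
    three replicates, six planted archetypes plus a fraction of null genes,
    a 2.0 log2-unit response amplitude and replicate noise of 0.3 log2
    units. Biological replicate scatter is carried by the log-scale jitter;
    ``nb_dispersion`` covers only the residual count-level overdispersion
    beyond shot noise, hence its small default.
    """

    n_genes: int = 2000
    null_frac: float = 0.25
    time_grid_h: tuple[float, ...] = (4.0, 12.0, 24.0, 48.0)
    n_replicates: int = 3
    baseline_log2cpm_range: tuple[float, float] = (3.0, 9.0)
    pattern_amplitude_log2: float = 2.0
    noise_sd_log2: float = 0.3
    nb_dispersion: float = 0.01
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    n_pathways: int = 8
    genes_per_pathway: int = 40
    planted_pathway_cluster: int | None = 3
    planted_pathway_purity: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.time_grid_h, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing and nonempty")
        if not (0.0 <= self.null_frac <= 1.0):
            raise ValueError("null_frac must lie in [0, 1]")
        if not (0.0 <= self.planted_pathway_purity <= 1.0):
            raise ValueError("planted_pathway_purity must lie in [0, 1]")
        if self.pattern_amplitude_log2 < 0 or self.noise_sd_log2 < 0:
            raise ValueError("amplitude and noise SD must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not isinstance(self.n_replicates, (int, np.integer)):
            raise ValueError("n_replicates must be an integer")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_genes < len(PATTERN_IDS):
            raise ValueError(
                f"n_genes must be >= {len(PATTERN_IDS)} (one per planted pattern)"
            )
        lo, hi = self.baseline_log2cpm_range
        if hi < lo:
            raise ValueError("baseline_log2cpm_range must be (low, high)")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")
        if (self.planted_pathway_cluster is not None
                and self.planted_pathway_cluster not in PATTERN_IDS):
            raise ValueError(
                f"planted_pathway_cluster must be one of {list(PATTERN_IDS)} or None"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation run.

    ``table`` has one row per gene with the planted pattern id ("null" for
    non-responders), the baseline log2(CPM+1) actually used after library
    rescaling, and the planted amplitude. ``gene_sets`` is the planted
    pathway annotation and ``planted_set`` names the set concentrated in one
    pattern (None if no set was planted).
    """

    table: pd.DataFrame
    gene_sets: GeneSetCollection
    planted_set: str | None

    def pattern_of(self, gene: str) -> str:
        return str(self.table.loc[gene, "pattern"])

    def genes_with_pattern(self, pattern_id: int) -> list[str]:
        return list(self.table.index[self.table["pattern"] == str(pattern_id)])


def _plant_gene_sets(rng: np.random.Generator, genes: pd.Index,
                     patterns: np.ndarray, config: SimConfig
                     ) -> tuple[GeneSetCollection, str | None]:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    planted_name: str | None = None
    size = min(config.genes_per_pathway, len(genes))
    for i in range(config.n_pathways):
        name = f"pathway_{i + 1:02d}"
        if i == 0 and config.planted_pathway_cluster is not None:
            target = str(config.planted_pathway_cluster)
            pool_in = genes[patterns == target]
            pool_out = genes[patterns != target]
            n_in = min(int(round(config.planted_pathway_purity * size)),
                       len(pool_in))
            n_out = min(size - n_in, len(pool_out))
            members = list(rng.choice(pool_in, size=n_in, replace=False))
            members += list(rng.choice(pool_out, size=n_out, replace=False))
            descriptions[name] = f"planted: concentrated in pattern {target}"
            planted_name = name
        else:
            members = list(rng.choice(genes, size=size, replace=False))
            descriptions[name] = "random background set"
        sets[name] = sorted(members)
    if not sets:
        return GeneSetCollection({}, {}), None
    return GeneSetCollection(sets, descriptions), planted_name


def simulate_timecourse(config: SimConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one synthetic count matrix plus its ground truth.

    The same seed yields bit-identical output. Baselines are rescaled by a
    single common factor so the control-arm expected CPMs sum to 1e6; the
    truth table records the rescaled baseline, which makes the generative
    formula exact: expected log2(CPM+1) of a treated sample at time t is
    ``baseline + amplitude * template(pattern, t)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    times = np.asarray(config.time_grid_h, dtype=float)
    T = times.size
    R = config.n_replicates

    genes = pd.Index([f"g{i + 1:05d}" for i in range(G)], name="gene")

    # pattern assignment: nulls first, responders split evenly over archetypes
    n_null = int(round(config.null_frac * G))
    n_resp = G - n_null
    resp_patterns = np.array(
        [PATTERN_IDS[i % len(PATTERN_IDS)] for i in range(n_resp)]
    )
    patterns = np.array([NULL_PATTERN] * n_null + [str(p) for p in resp_patterns],
                        dtype=object)
    rng.shuffle(patterns)

    lo, hi = config.baseline_log2cpm_range
    base_raw = rng.uniform(lo, hi, size=G)
    mu0 = 2.0 ** base_raw - 1.0
    scale = 1e6 / mu0.sum()
    baseline = np.log2(scale * mu0 + 1.0)

    amplitude = np.where(patterns == NULL_PATTERN, 0.0,
                         config.pattern_amplitude_log2)

    templates = {str(p): pattern_template(p, times) for p in PATTERN_IDS}
    shape_mat = np.zeros((G, T))
    for p, tmpl in templates.items():
        shape_mat[patterns == p] = tmpl

    sample_ids, arms, s_time, s_rep = [], [], [], []
    for arm in ("treated", "control"):
        for t in times:
            for r in range(1, R + 1):
                sample_ids.append(f"{arm}_t{t:g}h_r{r}")
                arms.append(arm)
                s_time.append(t)
                s_rep.append(r)
    design = pd.DataFrame(
        {"treatment": arms, "time_h": s_time, "replicate": s_rep},
        index=pd.Index(sample_ids, name="sample"),
    )
    n_samples = len(sample_ids)

    lib = rng.uniform(*config.library_size_range, size=n_samples)

    t_index = {t: i for i, t in enumerate(times)}
    mean_log2 = np.empty((G, n_samples))
    for j, sid in enumerate(sample_ids):
        effect = 0.0
        if arms[j] == "treated":
            effect = amplitude * shape_mat[:, t_index[s_time[j]]]
        mean_log2[:, j] = baseline + effect
    mean_log2 += rng.normal(0.0, config.noise_sd_log2, size=(G, n_samples))

    mu_cpm = 2.0 ** mean_log2 - 1.0
    mu_count = np.clip(mu_cpm * lib[None, :] / 1e6, 1e-8, None)
    phi = config.nb_dispersion
    if phi > 0:
        r_nb = 1.0 / phi
        counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu_count))
    else:
        counts = rng.poisson(mu_count)

    matrix = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=genes, columns=sample_ids),
        design,
    )

    gene_sets, planted = _plant_gene_sets(rng, genes, patterns, config)
    truth_table = pd.DataFrame(
        {"pattern": patterns, "baseline": baseline, "amplitude": amplitude},
        index=genes,
    )
    return matrix, SyntheticTruth(truth_table, gene_sets, planted)


def write_fixture(matrix: CountMatrix, truth: SyntheticTruth,
                  directory: str | Path) -> dict[str, Path]:
    """Write counts, sample sheet, GMT and truth table to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "design": directory / "samples.csv",
        "gmt": directory / "gene_sets.gmt",
        "truth": directory / "truth.tsv",
    }
    write_counts(matrix, paths["counts"], paths["design"])
    write_gmt(truth.gene_sets, paths["gmt"])
    truth.table.to_csv(paths["truth"], sep="\t", index_label="gene")
    return paths
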