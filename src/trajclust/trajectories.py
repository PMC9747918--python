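"""Per-gene response trajectories on a shared time grid.

A trajectory summarizes one gene's treatment response over the measured time
points. Three summaries are supported:

- ``logfc`` (default): mean treated log2(CPM+1) minus mean control
  log2(CPM+1) at each time point — the treatment-vs-control contrast;
- ``treated_only``: the treated-arm mean curve;
- ``zscore_logfc``: the logfc curve standardized per gene to mean 0, SD 1
  (an all-zero curve when the SD is 0).

No 0 h point is imputed; curves start at the first measured time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONTROL, TREATED, ExpressionMatrix

logger = logging.getLogger(__name__)

MODES = ("logfc", "treated_only", "zscore_logfc")


@dataclass
class Trajectory:
    """One gene's ordered (time, value) response curve."""

    gene: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size == 0:
            raise ValueError("trajectory must be nonempty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("trajectory values must be finite")


@dataclass
class TrajectorySet:
    """Trajectories of many genes on one shared time grid."""

    times: np.ndarray
    values: pd.DataFrame  # genes × time points
    mode: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[1] != self.times.size:
            raise ValueError("value columns must match the time grid")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in trajectory set")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def trajectory(self, gene: str) -> Trajectory:
        return Trajectory(gene, self.times, self.values.loc[gene].to_numpy())

    def subset(self, genes) -> "TrajectorySet":
        return TrajectorySet(self.times, self.values.loc[list(genes)], self.mode)


def build_trajectories(expr: ExpressionMatrix, genes=None,
                       mode: str = "logfc") -> TrajectorySet:
    """Collapse replicate expression into one response curve per gene."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    if genes is None:
        genes = list(expr.values.index)
    else:
        genes = list(genes)
        unknown = [g for g in genes if g not in expr.values.index]
        if unknown:
            raise ValueError(f"unknown genes: {unknown[:5]}")

    design = expr.design
    times = np.sort(design["time_h"].unique())
    vals = expr.values.loc[genes]

    arm_means = {}
    for arm in (TREATED, CONTROL):
        cols = []
        for t in times:
            sel = design.index[(design["treatment"] == arm)
                               & (design["time_h"] == t)]
            if len(sel) == 0:
                raise ValueError(f"no samples in cell (arm={arm}, time={t:g}h)")
            cols.append(vals[sel].mean(axis=1))
        arm_means[arm] = np.column_stack(cols)

    if mode == "treated_only":
        curve = arm_means[TREATED]
    else:
        curve = arm_means[TREATED] - arm_means[CONTROL]
        if mode == "zscore_logfc":
            mu = curve.mean(axis=1, keepdims=True)
            sd = curve.std(axis=1, keepdims=True)
            curve = np.where(sd > 0, (curve - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    frame = pd.DataFrame(curve, index=pd.Index(genes, name="gene"),
                         columns=[f"t{t:g}" for t in times])
    return TrajectorySet(times, frame, mode)


def subsample_training(ts: TrajectorySet, n: int = 500,
                       seed: int | None = 0) -> TrajectorySet:
    """Uniformly sample ``n`` genes without replacement (all if fewer)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if len(ts) <= n:
        logger.info("trajectory set has %d <= %d genes; using all", len(ts), n)
        return ts
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ts), size=n, replace=False)
    pick.sort()
    return TrajectorySet(ts.times, ts.values.iloc[pick], ts.mode)


def write_trajectories(ts: TrajectorySet, path) -> None:
    out = ts.values.copy()
    out["mode"] = ts.mode
    out.to_csv(path, sep="\t", index_label="gene")
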