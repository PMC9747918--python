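import numpy as np
import pandas as pd
import pytest

from trajclust import (CountMatrix, SimConfig, TrajectorySet,
                       pattern_template, simulate_timecourse, PATTERN_IDS)

TIME_GRID = (4.0, 12.0, 24.0, 48.0)


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulation shared by read-only tests."""
    cfg = SimConfig(n_genes=120, null_frac=0.25, seed=11)
    return simulate_timecourse(cfg)


@pytest.fixture(scope="session")
def template_set():
    """Exact, noise-free template trajectories: 6 patterns x 40 copies."""
    times = np.asarray(TIME_GRID)
    rows, ids, truth = [], [], []
    for p in PATTERN_IDS:
        for r in range(40):
            ids.append(f"p{p}_{r:02d}")
            rows.append(2.0 * pattern_template(p, times))
            truth.append(p)
    values = pd.DataFrame(rows, index=pd.Index(ids, name="gene"),
                          columns=[f"t{t:g}" for t in times])
    return TrajectorySet(times, values, "logfc"), truth


def toy_count_matrix(counts: np.ndarray, times=(4.0, 12.0),
                     reps: int = 2) -> CountMatrix:
    """Wrap a raw array as a CountMatrix with a balanced two-arm design."""
    counts = np.asarray(counts)
    ids, arm, t_h, rep = [], [], [], []
    for a in ("treated", "control"):
        for t in times:
            for r in range(1, reps + 1):
                ids.append(f"{a}_t{t:g}_r{r}")
                arm.append(a)
                t_h.append(t)
                rep.append(r)
    assert counts.shape[1] == len(ids)
    design = pd.DataFrame({"treatment": arm, "time_h": t_h, "replicate": rep},
                          index=pd.Index(ids, name="sample"))
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=ids), design)
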