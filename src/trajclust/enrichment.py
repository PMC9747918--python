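"""Per-cluster gene-set over-representation by exact hypergeometric tests.

For each (cluster, gene set) pair with nonzero set presence in the universe,
the upper-tail probability P(X >= x) of drawing x annotated genes in a
cluster of size m, from a universe of N genes of which K carry the
annotation, is computed exactly. Bonferroni correction runs over all tests
actually performed. The default universe is the clustered genes that carry
any annotation; ``universe_mode="all"`` uses every clustered gene instead.
Only over-representation (one-sided) is tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .frechet import ClusterAssignment
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(x: int, m: int, K: int, N: int) -> float:
    """Exact P(X >= x) for X ~ Hypergeometric(N, K, m).

    x successes in a draw of size m from N items of which K are successes.
    Returns 1 when x == 0.
    """
    if not (0 <= K <= N and 0 <= m <= N):
        raise ValueError(f"inconsistent counts: m={m}, K={K}, N={N}")
    if not (0 <= x <= min(m, K)):
        raise ValueError(f"overlap x={x} outside [0, min(m={m}, K={K})]")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, m))


@dataclass
class EnrichmentTable:
    """Cluster × gene-set overlap tests.

    ``table`` columns: cluster, set, cluster_size, set_size, universe_size,
    overlap, pvalue, bonferroni, significant.
    """

    table: pd.DataFrame
    alpha: float
    universe_mode: str
    universe_size: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def enrich_clusters(assignment: ClusterAssignment, sets: GeneSetCollection,
                    universe_mode: str = "annotated",
                    alpha: float = 0.05) -> EnrichmentTable:
    """Test every cluster for over-representation of every gene set."""
    if universe_mode not in ("annotated", "all"):
        raise ValueError("universe_mode must be 'annotated' or 'all'")
    labels = assignment.labels
    if len(labels) == 0:
        raise ValueError("assignment is empty")
    clustered = set(labels.index)
    annotated = sets.all_genes() if len(sets) else set()
    universe = clustered & annotated if universe_mode == "annotated" else clustered
    if not universe:
        if universe_mode == "annotated" and clustered:
            logger.warning("no clustered gene carries any annotation; "
                           "empty enrichment table")
            empty = pd.DataFrame(columns=[
                "cluster", "set", "cluster_size", "set_size",
                "universe_size", "overlap", "pvalue", "bonferroni",
                "significant"])
            return EnrichmentTable(empty, alpha, universe_mode, 0)
        raise ValueError("enrichment universe is empty")
    N = len(universe)

    rows = []
    for cluster in sorted(labels.unique(), key=str):
        members = set(labels.index[labels == cluster]) & universe
        m = len(members)
        for name, genes in sets:
            in_universe = set(genes) & universe
            K = len(in_universe)
            if K == 0:
                continue
            x = len(members & in_universe)
            rows.append({
                "cluster": cluster, "set": name, "cluster_size": m,
                "set_size": K, "universe_size": N, "overlap": x,
                "pvalue": hypergeom_upper_tail(x, m, K, N),
            })
    if not rows:
        logger.warning("no (cluster, set) pair had set presence in the "
                       "universe; empty enrichment table")
        empty = pd.DataFrame(columns=[
            "cluster", "set", "cluster_size", "set_size", "universe_size",
            "overlap", "pvalue", "bonferroni", "significant"])
        return EnrichmentTable(empty, alpha, universe_mode, N)
    table = pd.DataFrame(rows)
    T = len(table)
    table["bonferroni"] = np.minimum(1.0, T * table["pvalue"])
    table["significant"] = table["bonferroni"] < alpha
    table = table.sort_values("pvalue", kind="stable").reset_index(drop=True)
    return EnrichmentTable(table, alpha, universe_mode, N)
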