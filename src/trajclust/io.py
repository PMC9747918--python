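"""Readers, writers and basic transforms for count data and gene sets.

The on-disk formats are deliberately plain: counts as a TSV with gene ids in
the first column and sample ids in the header, the sample sheet as a CSV/TSV
with columns ``sample, treatment, time_h, replicate``, and gene sets in
standard GMT (set name, description, then tab-separated gene ids).
Expression is quantified as log2(CPM + 1), with CPM computed against the raw
per-sample library size (column sum); no between-sample normalization such
as TMM is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATED = "treated"
CONTROL = "control"
_ARMS = (TREATED, CONTROL)

DESIGN_COLUMNS = ("treatment", "time_h", "replicate")


@dataclass
class CountMatrix:
    """Gene × sample integer counts together with the sample design.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integers, genes as rows, samples as columns.
    design
        DataFrame indexed by sample id with columns ``treatment`` (one of
        ``treated`` / ``control``), ``time_h`` (positive hours) and
        ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        c, d = self.counts, self.design
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        if d.index.duplicated().any():
            dup = d.index[d.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate design rows for samples: {dup[:5]}")
        missing = [s for s in c.columns if s not in d.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        extra = [s for s in d.index if s not in c.columns]
        if extra:
            raise ValueError(f"design samples missing from counts: {extra}")
        for col in DESIGN_COLUMNS:
            if col not in d.columns:
                raise ValueError(f"design lacks required column '{col}'")
        bad_arm = sorted(set(d["treatment"]) - set(_ARMS))
        if bad_arm:
            raise ValueError(f"unknown treatment labels: {bad_arm}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(vals < 0) or np.any(vals != np.floor(vals)):
            g, s = np.argwhere((vals < 0) | (vals != np.floor(vals)))[0]
            raise ValueError(
                f"counts must be nonnegative integers; offending entry at "
                f"gene '{c.index[g]}', sample '{c.columns[s]}'"
            )
        # align design to the count columns once, so downstream code can zip
        self.design = d.loc[c.columns]
        self.counts = c.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """log2(CPM + 1) values on the same gene × sample axes as the counts."""

    values: pd.DataFrame
    design: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class GeneSetCollection:
    """Named gene sets (a parsed GMT file)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set '{name}' is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out


def read_counts(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a counts TSV and its sample sheet into a validated CountMatrix."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    sep = "," if str(design_path).endswith(".csv") else "\t"
    design = pd.read_csv(design_path, sep=sep)
    if "sample" not in design.columns:
        raise ValueError("sample sheet must have a 'sample' column")
    design = design.set_index("sample")
    return CountMatrix(counts, design)


def write_counts(matrix: CountMatrix, counts_path: str | Path,
                 design_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene")
    sep = "," if str(design_path).endswith(".csv") else "\t"
    matrix.design.to_csv(design_path, sep=sep, index_label="sample")


def log2_cpm(matrix: CountMatrix) -> ExpressionMatrix:
    """Transform counts to log2(CPM + 1).

    value(g, s) = log2(1 + 1e6 * count(g, s) / total(s)), where total(s) is
    the raw library size of sample s. Samples with zero total are rejected.
    """
    totals = matrix.library_sizes()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total count: {zero}")
    cpm = matrix.counts.div(totals, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm + 1.0), matrix.design)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate gene ids within one set are dropped (order preserved) with a
    logged warning; a line with fewer than three fields is an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            seen: set[str] = set()
            unique = []
            for g in genes:
                if g in seen:
                    continue
                seen.add(g)
                unique.append(g)
            if len(unique) < len(genes):
                logger.warning(
                    "GMT set '%s': %d duplicate gene id(s) de-duplicated",
                    name, len(genes) - len(unique),
                )
            if name in sets:
                raise ValueError(f"duplicate gene set name '{name}' (line {lineno})")
            sets[name] = unique
            descriptions[name] = desc
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index_label=None) -> None:
    """Write a result table as TSV with a header row."""
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
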