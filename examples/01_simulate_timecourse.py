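"""Simulate a two-arm expression time course with planted response patterns.

Generates counts for 300 genes measured at 4, 12, 24 and 48 h in treated and
control arms (3 replicates each). 75% of genes respond to treatment
following one of six archetypes (gradual/rapid/transient, up/down); the rest
are flat. The printed table shows how many genes carry each pattern and the
first few rows of the count matrix.
"""

from trajclust import SimConfig, simulate_timecourse, write_fixture

config = SimConfig(n_genes=300, null_frac=0.25, seed=42)
matrix, truth = simulate_timecourse(config)

print(f"count matrix: {matrix.n_genes} genes x {matrix.n_samples} samples")
print("\nplanted pattern counts (1..6 = response archetypes):")
print(truth.table["pattern"].value_counts().sort_index().to_string())
print("\nfirst genes, first samples:")
print(matrix.counts.iloc[:4, :4])

paths = write_fixture(matrix, truth, "scratch/example_fixture")
print("\nwrote fixture files:")
for name, path in paths.items():
    print(f"  {name}: {path}")
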