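# trajclust

Two-step trajectory clustering of drug-response gene-expression time
courses, built for experiments of the form *treated vs. vehicle, a handful
of time points, a few biological replicates* — e.g. an epigenetic inhibitor
applied to a cancer cell line and read out by RNA-seq at 4, 12, 24 and 48 h.
The package answers two questions: **which genes respond to the treatment**,
and **what temporal shapes do the responses take** (gradual vs. rapid,
sustained vs. transient, up vs. down), with pathway over-representation per
response cluster.

It is aimed at computational biologists who want the whole procedure — or
any single stage — as tested, importable Python, plus a synthetic-data
generator that makes every stage verifiable without access to a real
(often restricted) RNA-seq dataset.

## Method

1. **Screen** — per gene, a negative-binomial GLM with log link and
   library-size offset; LRT of the full design
   `~ time + treatment + treatment:time` against the time-only null,
   χ²(*T*) p-values (*T* = number of time levels), Bonferroni FWER; a gene
   is kept when FWER < 0.1 and mean log₂(CPM+1) > 1. Dispersions are
   per-gene method-of-moments estimates shrunk 50/50 toward the median.
2. **Trajectories** — each kept gene becomes a curve
   x_g(t) = mean log₂(CPM+1) treated − control at each time point.
3. **Distances** — discrete Fréchet distance between curves: embed points
   as (scaled time, value) and take the minimum over monotone couplings of
   the maximum Euclidean gap (exact Eiter–Mannila dynamic programme).
4. **Two-step clustering** — *step 1*: on 500 randomly sampled training
   genes, pairwise Fréchet distances → principal coordinate analysis →
   K-means for k = 2..10 on the first three coordinates, the
   Calinski–Harabasz criterion (B/(k−1))/(W/(n−k)) choosing k; averaged
   member curves become per-cluster *reference profiles*. *Step 2*: every
   gene is re-assigned to the Fréchet-nearest reference profile. Agreement
   between the step-1 partition and the step-2 re-assignment of the
   training genes (percent correct, Cohen's κ) measures internal
   consistency.
5. **Enrichment** — per (cluster, gene set): exact hypergeometric
   upper-tail test P(X ≥ x), Bonferroni over all tests performed.

The synthetic generator plants six response archetypes (gradual sustained
up, rapid sustained up, transient down, rapid sustained down, gradual
sustained down, transient up) at a configurable amplitude on top of NB
count noise and per-replicate log-scale jitter, together with one pathway
concentrated in a single archetype — so recovery, error control and
enrichment specificity can all be tested against known truth.

## Worked example

```bash
python examples/04_two_step_clustering.py
```

simulates 2000 genes (six archetypes, amplitude 2.0 log₂ units, replicate
noise 0.3) and runs the two-step procedure:

```
chosen k = 6
training-set agreement: 99.4% (kappa 0.993)
adjusted Rand index vs planted patterns: 0.999
```

The cascade picked six clusters (the number of planted archetypes); 99.4%
of the 500 training genes were re-assigned by nearest-reference Fréchet
distance to the same cluster K-means gave them (κ = 0.993, i.e. far beyond
chance), and the final labels of all 2000 genes almost perfectly recover
the planted patterns. The other scripts in `examples/` walk through each
stage separately; `trajclust --help` exposes the same stages as a CLI.

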