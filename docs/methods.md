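# Methods

## Scope and model

`trajclust` classifies per-gene treatment-response curves from a two-arm
(treated / control) expression time course into temporal archetypes. The
pipeline is: NB-GLM screen → log-fold-change trajectories → discrete
Fréchet distances → principal coordinate analysis (PCO) → cascade K-means
with Calinski–Harabasz (CH) selection → reference-profile re-assignment →
hypergeometric pathway enrichment. Each stage is exposed on its own; the
pipeline only composes them.

## Differential-expression screen

Counts y_gs are modelled as NB(μ_gs, φ_g) with log link,
log μ_gs = x_sᵀβ_g + log L_s, where L_s is the raw library size (column
sum). The full design is intercept + time (factor) + treatment +
treatment:time; the null drops **all** treatment terms, so the test asks
for any association with treatment, not only interaction. With T time
levels the LRT has T degrees of freedom (1 main effect + T−1 interactions);
p-values use the χ²(T) approximation and are Bonferroni-corrected over the
genes actually tested. A gene passes at FWER < `alpha` (default 0.1) and
mean log₂(CPM+1) > `expr_min` (default 1.0).

Design choices:

- **Time as a factor.** No linearity in time is assumed; four time points
  support a saturated time effect.
- **Dispersion.** Per gene, a method-of-moments estimate pooled over
  (arm, time) groups: φ̂ = max(0, Σ(s² − m)/Σ m²) on counts rescaled to a
  common library size, then shrunk 50/50 toward the median across genes;
  degenerate genes (no finite estimate) get the median. This is the
  simplest estimator with predictable behavior; it does not attempt
  empirical-Bayes precision, and the tests characterize it only through
  coarse bands (Poisson data → median ≤ 0.05; φ = 0.4 data → median in
  [0.2, 0.6]).
- **Batched fitting.** All genes share one design matrix, so IRLS is run
  for every gene simultaneously (stacked normal equations, one batched
  solve per iteration; ridge 1e-10 for stability; log-likelihood
  convergence at relative 1e-8, 50 iterations max). Non-converged genes are
  excluded with NA statistics and counted, never silently passed.
- **Raw-library CPM and offsets.** CPM is defined against the raw column
  sum, with the +1 pseudocount inside the log; no TMM/median-ratio
  normalization anywhere. See *Limitations* for the compositional
  consequence.

## Trajectories

Default mode `logfc`: value(t) = mean treated log₂(CPM+1) − mean control
log₂(CPM+1) at t. Alternatives: `treated_only` (treated mean curve) and
`zscore_logfc` (per-gene standardization of the logfc curve; an exactly
constant curve maps to all zeros rather than NaN). No 0 h point is imputed.
Whether curves should additionally be z-scored before distance computation
is a genuinely open representation question; both behaviors are first-class
and the mode is recorded in every output.

## Discrete Fréchet distance

Point i of a curve is embedded as (`time_scale` · t̂_i, v_i), with t̂ the
curve's time grid min-max scaled to [0, 1] and Euclidean ground distance.
The classical discrete Fréchet distance (minimum over monotone couplings of
the maximum ground distance) is computed exactly by the Eiter–Mannila
dynamic programme — with ≤ ~6 samples per curve the discrete variant is the
natural representation, and the DP is exact for it. `time_scale` spans the
plausible geometries: 1.0 (default) weighs shape-in-time; 0 reduces to
value-profile comparison. A non-default `mean` variant aggregates by the
average ground distance along the optimizing coupling (minimal summed cost
divided by that path's length — the normalization is a package convention,
stated here because no standard one exists). All-pairs computation
vectorizes the DP across gene pairs in row blocks (default 256 rows) to
bound memory at a few tens of MB for 500-gene training sets.

## PCO, cascade K-means, and the two-step procedure

PCO is classical Torgerson–Gower scaling: double-center −½D², eigendecompose,
keep the top `n_components` (default 3) eigenvectors scaled by √λ.
Eigenvalues below 1e-12 of the largest count as zero; negative eigenvalues
(possible — Fréchet distances need not be Euclidean) contribute zero
coordinates, with no Cailliez/Lingoes correction. For Euclidean input the
embedding reproduces all pairwise distances to ≤1e-8.

K-means runs on those coordinates for every k in 2..10, best of 50
k-means++ restarts (scikit-learn, tolerance 1e-8), with per-k seeds derived
deterministically from the master seed. CH is evaluated **in the same
embedding space** — the criterion should score the geometry the clustering
saw. A k whose best solution has fewer than k nonempty clusters is marked
degenerate and excluded. W ≤ 1e-6·B is treated as perfect separation
(CH = +∞); ties — including ties between sentinel ks — resolve to the
smallest k. The tolerance matters: with near-duplicate points, W is
machine noise and CH would otherwise grow without bound in k.

Step 1 runs on a uniform random training sample (default 500 genes; the
whole set, with a log note, when smaller). Reference profiles are pointwise
arithmetic means of member curves. Step 2 assigns every gene to the
Fréchet-nearest reference, ties toward the lowest cluster index. Agreement
on the training genes uses the identity label matching (step-2 labels *are*
step-1 cluster ids); a greedy maximum-overlap matcher exists only for
comparing against external labelings. Percent agreement is the matched
diagonal over the total; Cohen's κ uses marginal-derived chance agreement.

## Enrichment

Exact hypergeometric upper tail P(X ≥ x) per (cluster, set) pair
(scipy's stable implementation), Bonferroni over the tests actually
performed (pairs with zero set presence in the universe are not tested).
Default universe: clustered genes carrying any annotation — testing against
unannotated genes inflates enrichment; `universe_mode="all"` is available.
One-sided over-representation only.

## Synthetic data generator

The generator emulates a two-arm inhibitor time course: 2 arms ×
{4, 12, 24, 48} h × 3 replicates, thousands of genes, six response
archetypes plus a null fraction. Templates are piecewise-linear,
unit-amplitude curves over min-max-normalized time (anchor values chosen to
express the qualitative shapes: rapid patterns are at ≥80% of amplitude by
the first time point; transient patterns return to baseline ~45% through
the course). Expected treated-arm expression is
log₂(CPM+1) = baseline + amplitude·template(pattern, t); controls stay at
baseline. Noise enters twice: per-gene-per-sample Gaussian jitter on the
log₂ mean (biological replicate scatter, default SD 0.3) and NB sampling at
the count level (variance μ + φμ²).

Parameter defaults and rationale:

- `pattern_amplitude_log2 = 2.0`, `noise_sd_log2 = 0.3`: a strong but
  realistic perturbation with clearly visible replicate scatter.
- `nb_dispersion = 0.01`: with biological scatter already modelled on the
  log scale (SD 0.3 ≈ BCV 0.21), the count-level term covers only residual
  technical overdispersion; 0.01 is typical for cell-line RNA-seq once
  biological variance is accounted for separately. Setting it higher
  double-counts biological noise.
- `null_frac = 0.25`, `n_genes = 2000`, `baseline_log2cpm_range = (3, 9)`,
  `library_size_range = (0.8e6, 1.2e6)`: a desk-scale transcriptome with a
  broad expression range.
- Baselines are rescaled by one common factor so control-arm expected CPMs
  sum to 1e6; the truth table records the rescaled baseline, making the
  generative formula exact in expectation (tests rely on this).
- Pathways: `n_pathways` sets of `genes_per_pathway` genes; the first set
  draws 80% of its members from one archetype (default pattern 3) so the
  enrichment stage has a known positive; the rest are uniform draws.
- The time grid is configurable (e.g. a {6, 12, 24, 48} variant) but
  defaults to {4, 12, 24, 48}.

What the generator does **not** emulate: batch effects, read-level
artifacts (it produces gene counts directly), gene-length bias, correlated
noise between genes, and unbalanced designs. Passing tests therefore show
correctness of the machinery and its behavior under idealized NB noise, not
robustness to those real-data features.

## Determinism and seeds

Every stochastic component takes a seed; the pipeline derives per-stage
seeds from one master seed via `numpy.random.SeedSequence`. Identical
seeds give bit-identical outputs, including all written tables.

## Problem sizes used in the test suite

The self-consistency and recovery suites run the documented study design
(2000 genes, 500 training genes) over ten seeds; error-control suites use
20 seeds × 2000 genes (screen nulls) and 10 seeds × 600 genes
(enrichment). These sizes keep a full run in tens of seconds while leaving
the statistics stable across seeds.

## Limitations

- **Compositionality.** CPM is a relative measure. When a large fraction of
  the transcriptome responds in one direction, library totals shift and
  every gene's relative expression moves; flat genes can then show genuine
  relative-expression changes, and up-regulated genes lose apparent
  amplitude. The package deliberately keeps raw-library CPM (the quantity
  its contracts define) rather than introducing TMM-style normalization;
  interpret screen hits as *relative* expression changes.
- The χ²(T) approximation to the LRT is slightly anticonservative at very
  small counts; the moment dispersion estimator is noisier than
  empirical-Bayes alternatives.
- CH selection inherits K-means' preference for spherical, comparable-size
  clusters in the PCO space.
- The hypergeometric test treats genes as exchangeable; correlated gene
  sets inflate significance as in any over-representation analysis.
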