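"""PCO embedding, cascade K-means and the two-step re-clustering procedure.

Step 1: sample a training set of genes, compute pairwise discrete Fréchet
distances, embed them by principal coordinate analysis (classical metric
scaling), and run K-means for every k in a cascade (default 2..10) on the
first three coordinates; the Calinski-Harabasz criterion, evaluated in the
same embedding space, picks the cluster number. Averaged member trajectories
("reference profiles") summarize each cluster.

Step 2: every gene — training or not — is re-assigned to the reference
profile at minimal Fréchet distance. Agreement between the step-1 partition
and the step-2 re-assignment of the training genes (percent correct and
Cohen's kappa) quantifies the internal consistency of the two steps.

Negative PCO eigenvalues (possible, since Fréchet distances need not be
Euclidean) contribute zero coordinates; no Cailliez/Lingoes correction is
applied by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .frechet import ClusterAssignment, DistanceMatrix, assign_by_reference, \
    pairwise_frechet
from .trajectories import TrajectorySet, subsample_training

logger = logging.getLogger(__name__)


@dataclass
class PCOEmbedding:
    """Classical-scaling coordinates of a distance matrix."""

    ids: list[str]
    coords: np.ndarray          # items × n_components
    eigenvalues: np.ndarray     # all eigenvalues, descending
    positive_inertia: float     # fraction of positive inertia captured

    def to_frame(self) -> pd.DataFrame:
        cols = [f"pco{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.ids, columns=cols)


def pco(dist: DistanceMatrix, n_components: int = 3) -> PCOEmbedding:
    """Principal coordinate analysis (Torgerson/Gower classical scaling).

    Double-center -0.5 * D^2, eigendecompose, and keep the top
    ``n_components`` eigenvectors scaled by sqrt(eigenvalue). Components
    with nonpositive eigenvalues yield zero coordinates. For a Euclidean
    input the embedding reproduces all pairwise distances.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n = len(dist.ids)
    if n < n_components + 1:
        raise ValueError(f"need >= {n_components + 1} items for "
                         f"{n_components} components")
    D2 = dist.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = 0.5 * (B + B.T)
    lam, vec = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    # eigenvalues below machine-noise scale count as zero
    tol = max(lam.max(), 0.0) * 1e-12
    coords = np.zeros((n, n_components))
    for k in range(n_components):
        if lam[k] > tol:
            coords[:, k] = vec[:, k] * np.sqrt(lam[k])
    pos = lam[lam > tol]
    captured = float(lam[:n_components][lam[:n_components] > tol].sum())
    frac = captured / pos.sum() if pos.size else 0.0
    return PCOEmbedding(list(dist.ids), coords, lam, frac)


def calinski_harabasz(points: np.ndarray, labels) -> float:
    """Calinski-Harabasz criterion (B/(k-1)) / (W/(n-k)).

    B is the size-weighted between-cluster dispersion around the grand mean
    and W the pooled within-cluster dispersion. Perfect separation — W zero,
    or numerically negligible (W <= 1e-6 * B) — returns +inf so it wins any
    selection; ties between sentinel ks resolve toward the smallest k in
    ``cascade_kmeans``.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = X.shape[0], uniq.size
    if k < 2:
        raise ValueError("need >= 2 clusters")
    if n <= k:
        raise ValueError("need more points than clusters")
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for c in uniq:
        mask = labels == c
        nc = int(mask.sum())
        if nc == 0:
            raise ValueError(f"empty cluster {c!r}")
        mu = X[mask].mean(axis=0)
        B += nc * float(((mu - grand) ** 2).sum())
        W += float(((X[mask] - mu) ** 2).sum())
    if W <= 1e-6 * B:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


@dataclass
class CascadeResult:
    """Best-of-restarts K-means over a cascade of cluster numbers."""

    ks: list[int]
    scores: dict[int, float]
    inertia: dict[int, float]
    labels: dict[int, pd.Series]
    chosen_k: int
    degenerate: list[int]
    restarts: int
    seed: int | None

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in self.ks:
            rows.append({
                "k": k,
                "calinski_harabasz": self.scores.get(k, np.nan),
                "inertia": self.inertia.get(k, np.nan),
                "degenerate": k in self.degenerate,
                "chosen": k == self.chosen_k,
            })
        return pd.DataFrame(rows)


def cascade_kmeans(embedding: PCOEmbedding, k_min: int = 2, k_max: int = 10,
                   restarts: int = 50, seed: int | None = 0) -> CascadeResult:
    """K-means for each k in [k_min, k_max]; Calinski-Harabasz picks k.

    Each k runs best-of-``restarts`` k-means++ initializations to a tight
    tolerance. A k whose best solution uses fewer than k nonempty clusters
    is marked degenerate and excluded from selection. Ties favor smaller k.
    """
    X = embedding.coords
    n = X.shape[0]
    if n < k_max + 1:
        raise ValueError(f"need >= {k_max + 1} items for k_max={k_max}")
    ks = list(range(k_min, k_max + 1))
    child = np.random.SeedSequence(seed).spawn(len(ks))
    scores: dict[int, float] = {}
    inertia: dict[int, float] = {}
    labels: dict[int, pd.Series] = {}
    degenerate: list[int] = []
    import warnings
    for k, ss in zip(ks, child):
        rs = int(ss.generate_state(1)[0] % (2 ** 31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=k, n_init=restarts, tol=1e-8,
                        random_state=rs).fit(X)
        lab = km.labels_
        labels[k] = pd.Series(lab, index=embedding.ids, name="cluster")
        inertia[k] = float(km.inertia_)
        if np.unique(lab).size < k:
            degenerate.append(k)
            logger.info("k=%d degenerate (%d nonempty clusters); excluded",
                        k, np.unique(lab).size)
            continue
        scores[k] = calinski_harabasz(X, lab)
    if not scores:
        raise ValueError("every k in the cascade was degenerate")
    best = max(scores, key=lambda k: (scores[k], -k))
    return CascadeResult(ks, scores, inertia, labels, best, degenerate,
                         restarts, seed)


@dataclass
class ReferenceProfiles:
    """Per-cluster averaged trajectories on the shared time grid."""

    times: np.ndarray
    profiles: pd.DataFrame      # cluster id × time points
    member_counts: pd.Series

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.profiles.shape[1] != self.times.size:
            raise ValueError("profile columns must match the time grid")


def reference_profiles(training: TrajectorySet, labels: pd.Series
                       ) -> ReferenceProfiles:
    """Pointwise mean trajectory of each cluster's members."""
    labels = pd.Series(labels)
    missing = [g for g in training.gene_ids if g not in labels.index]
    if missing:
        raise ValueError(f"labels missing for genes: {missing[:5]}")
    lab = labels.loc[training.gene_ids]
    means = training.values.groupby(lab.to_numpy()).mean()
    counts = lab.value_counts().sort_index()
    if (counts == 0).any():
        raise ValueError("cannot average an empty cluster")
    means.index.name = "cluster"
    return ReferenceProfiles(training.times, means.sort_index(), counts)


@dataclass
class AgreementStats:
    """Confusion matrix, percent good classification and Cohen's kappa."""

    confusion: pd.DataFrame     # rows: labels_a, cols: matched labels_b
    percent: float
    kappa: float
    mapping: dict = field(default_factory=dict)


def _greedy_match(conf: pd.DataFrame) -> dict:
    """Map column labels onto row labels by maximum overlap, greedily."""
    mapping: dict = {}
    work = conf.copy().astype(float)
    while work.shape[0] and work.shape[1]:
        r, c = np.unravel_index(np.argmax(work.to_numpy()), work.shape)
        mapping[work.columns[c]] = work.index[r]
        work = work.drop(index=work.index[r], columns=work.columns[c])
    return mapping


def agreement(labels_a: pd.Series, labels_b: pd.Series) -> AgreementStats:
    """Chance-corrected agreement between two labelings of the same items.

    When ``labels_b`` uses labels outside ``labels_a``'s alphabet, a greedy
    maximum-overlap matching renames them first; the default two-step path
    (step-2 labels are step-1 cluster ids) needs no matching.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if set(a.index) != set(b.index):
        raise ValueError("labelings cover different items")
    b = b.loc[a.index]
    set_a, set_b = set(a.unique()), set(b.unique())
    mapping: dict = {}
    if not set_b <= set_a:
        conf0 = pd.crosstab(a, b)
        mapping = _greedy_match(conf0)
        b = b.map(lambda x: mapping.get(x, x))
    all_labels = sorted(set(a.unique()) | set(b.unique()), key=str)
    conf = pd.crosstab(a, b).reindex(index=all_labels, columns=all_labels,
                                     fill_value=0)
    n = conf.to_numpy().sum()
    diag = np.trace(conf.to_numpy())
    po = diag / n
    row = conf.sum(axis=1).to_numpy() / n
    col = conf.sum(axis=0).to_numpy() / n
    pe = float((row * col).sum())
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return AgreementStats(conf, 100.0 * po, float(kappa), mapping)


@dataclass
class TwoStepResult:
    """Everything the two-step procedure produces."""

    cascade: CascadeResult
    references: ReferenceProfiles
    assignment: ClusterAssignment
    agreement: AgreementStats
    training_labels: pd.Series
    embedding: PCOEmbedding
    distances: DistanceMatrix


def two_step_cluster(all_ts: TrajectorySet, n_train: int = 500,
                     k_min: int = 2, k_max: int = 10, n_components: int = 3,
                     restarts: int = 50, seed: int | None = 0,
                     time_scale: float = 1.0,
                     variant: str = "max") -> TwoStepResult:
    """Run the full two-step trajectory-clustering procedure.

    Step 1 on a random training subset: pairwise Fréchet → PCO →
    cascade K-means → reference profiles. Step 2 re-assigns every gene to
    the nearest reference; agreement is computed on the training genes.
    """
    if len(all_ts) < k_max + 1:
        raise ValueError(f"need >= {k_max + 1} trajectories")
    ss = np.random.SeedSequence(seed).spawn(2)
    sub_seed = int(ss[0].generate_state(1)[0] % (2 ** 31))
    km_seed = int(ss[1].generate_state(1)[0] % (2 ** 31))

    train = subsample_training(all_ts, n_train, sub_seed)
    dist = pairwise_frechet(train, time_scale=time_scale, variant=variant)
    emb = pco(dist, n_components)
    cascade = cascade_kmeans(emb, k_min, k_max, restarts, km_seed)
    step1 = cascade.labels[cascade.chosen_k]
    refs = reference_profiles(train, step1)
    assignment = assign_by_reference(all_ts, refs, time_scale=time_scale,
                                     variant=variant,
                                     provenance="step2_full_set")
    step2 = assignment.labels.loc[train.gene_ids]
    stats = agreement(step1, step2)
    return TwoStepResult(cascade, refs, assignment, stats, step1, emb, dist)
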