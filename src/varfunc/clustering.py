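"""Subfamily detection on the alignment window.

Two partitioners are provided.  The primary one minimises a combinatorial
entropy criterion with two terms.  The fit term sums, for every cluster and
every column, the log multinomial coefficient of the observed residue counts
(the number of distinguishable arrangements of the column within the
cluster) minus the expectation of that quantity for a random same-sized
subset of the column; columns conserved inside a cluster contribute strongly
negative terms.  The second term, ln(n! / prod_c s_c!) over the cluster
sizes, is the combinatorial entropy of the partition itself — the cost of
encoding which row belongs to which cluster.  Without it the fit term alone
is minimised by shaving off small groups of rows that merely share noise
residues (every polymorphic column pays the full log-binomial for such a
split); the encoding term charges exactly that currency for the split, so
only splits supported by consistent column-wise structure survive.  The
number of clusters is an output of the optimisation, not an input.  A
K-means baseline on one-hot encoded rows, and the Dunn and Davies-Bouldin
cluster-validity indices, support comparison of partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln
from sklearn.cluster import KMeans

from .msa import GAP, AlignmentWindow

SYMBOLS = "ACDEFGHIKLMNPQRSTVWY" + GAP   # gap counted as a 21st symbol


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterPartition:
    """Disjoint clusters of window rows; the cluster holding the query is
    always relabeled 0 and labels are contiguous."""

    labels: list[int]      # per kept row of the window
    k: int

    target_label: int = 0

    def __post_init__(self) -> None:
        seen = sorted(set(self.labels))
        if seen != list(range(self.k)):
            raise ClusteringError("cluster labels must be contiguous 0..k-1")

    def members(self, label: int) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == label]

    def sizes(self) -> list[int]:
        return [self.labels.count(l) for l in range(self.k)]

    def eligible_labels(self) -> list[int]:
        """Clusters usable for prediction: size > 1."""
        return [l for l in range(self.k) if self.labels.count(l) > 1]


@dataclass(frozen=True)
class ClusterQuality:
    dunn: float
    davies_bouldin: float
    degenerate: bool = False


def _relabel(labels: list[int], query_row: int) -> ClusterPartition:
    """Relabel so the query's cluster is 0 and labels are contiguous,
    remaining clusters ordered by first appearance."""
    order: list[int] = [labels[query_row]]
    for l in labels:
        if l not in order:
            order.append(l)
    mapping = {old: new for new, old in enumerate(order)}
    new_labels = [mapping[l] for l in labels]
    return ClusterPartition(labels=new_labels, k=len(order))


# ---------------------------------------------------------------------------
# combinatorial entropy
# ---------------------------------------------------------------------------

def column_combinatorial_entropy(residue_counts: dict[str, int]) -> float:
    """ln of the multinomial coefficient n! / prod_a n_a! for one column's
    residue counts within a cluster (gaps count as a 21st symbol).

    Zero iff the column is monomorphic within the cluster.
    """
    if not residue_counts:
        raise ClusteringError("empty residue count map")
    counts = np.array([c for c in residue_counts.values() if c > 0], dtype=float)
    if counts.size == 0 or np.any(counts < 0):
        raise ClusteringError("counts must be nonnegative with total >= 1")
    n = counts.sum()
    return float(gammaln(n + 1) - gammaln(counts + 1).sum())


def _entropy_from_array(symbols: np.ndarray) -> float:
    _, counts = np.unique(symbols, return_counts=True)
    n = counts.sum()
    return float(gammaln(n + 1) - gammaln(counts + 1).sum())


class _CeoScorer:
    """Caches the per-column observed/expected entropy machinery.

    Expected entropy for a cluster of size s at a column is the Monte-Carlo
    mean of the entropy of the first s entries of seeded random permutations
    of that column's residues across all window rows; it therefore depends on
    cluster *size* only, so merge comparisons are consistent."""

    def __init__(self, window: AlignmentWindow, shuffles: int, seed: int):
        rows = window.rows
        self.n = len(rows)
        self.cols = np.array([[ord(r[c]) for r in rows]
                              for c in range(window.width)], dtype=np.int16)
        rng = np.random.default_rng(seed)
        self.perms = [
            np.array([rng.permutation(col) for _ in range(shuffles)])
            for col in self.cols
        ]
        self._expected: dict[tuple[int, int], float] = {}
        self._contrib: dict[frozenset, float] = {}

    def expected(self, col: int, size: int) -> float:
        key = (col, size)
        if key not in self._expected:
            samples = self.perms[col][:, :size]
            self._expected[key] = float(
                np.mean([_entropy_from_array(s) for s in samples])
            )
        return self._expected[key]

    def cluster_contribution(self, members: frozenset) -> float:
        """sum over columns of (observed - expected) entropy for one cluster."""
        if members not in self._contrib:
            idx = sorted(members)
            size = len(idx)
            total = 0.0
            for c in range(len(self.cols)):
                total += _entropy_from_array(self.cols[c][idx]) - self.expected(c, size)
            self._contrib[members] = total
        return self._contrib[members]

    def objective(self, clusters: list[frozenset]) -> float:
        fit = sum(self.cluster_contribution(c) for c in clusters)
        return fit + partition_entropy([len(c) for c in clusters])


def partition_entropy(sizes: list[int]) -> float:
    """ln( n! / prod_c s_c! ): the combinatorial entropy of the partition
    itself, charged as the cost of encoding the row-to-cluster assignment."""
    n = sum(sizes)
    return float(gammaln(n + 1) - sum(gammaln(s + 1) for s in sizes))


def ceo_objective(
    window: AlignmentWindow,
    partition: ClusterPartition,
    expected_entropy_shuffles: int = 20,
    seed: int = 0,
) -> float:
    """The combinatorial-entropy objective of a partition: the lower, the
    better the partition separates column-wise conserved groups.

    Sum over clusters and columns of (observed - expected) entropy, plus the
    partition-encoding entropy ln(n!/prod s_c!).  Both terms vanish for the
    trivial single-cluster partition, so the objective of any proposed
    partition is directly its improvement over not clustering at all.
    """
    if expected_entropy_shuffles < 1:
        raise ClusteringError("need at least one shuffle")
    if len(partition.labels) != window.n_rows:
        raise ClusteringError("partition inconsistent with window rows")
    scorer = _CeoScorer(window, expected_entropy_shuffles, seed)
    clusters = [frozenset(partition.members(l)) for l in range(partition.k)]
    return scorer.objective(clusters)


def _p_distance_matrix(window: AlignmentWindow) -> np.ndarray:
    """Per-column mismatch fraction over columns where both rows are non-gap."""
    rows = window.rows
    n = len(rows)
    arr = np.array([[ord(c) for c in r] for r in rows], dtype=np.int16)
    gap = ord(GAP)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != gap) & (arr[j] != gap)
            m = both.sum()
            d[i, j] = d[j, i] = (
                float(np.mean(arr[i][both] != arr[j][both])) if m else 1.0
            )
    return d


def _fine_partition(window: AlignmentWindow) -> list[int]:
    """Initial fine partition: average-linkage tree on p-distance cut at
    height zero, so identical rows start together and everything else is a
    singleton."""
    n = window.n_rows
    if n == 2:
        d = _p_distance_matrix(window)
        return [0, 0] if d[0, 1] == 0 else [0, 1]
    d = _p_distance_matrix(window)
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=0.0, criterion="distance")
    return [int(l) - 1 for l in labels]


def ceo_cluster(
    window: AlignmentWindow,
    restarts: int = 3,
    shuffles: int = 20,
    seed: int = 0,
) -> ClusterPartition:
    """Greedy agglomerative minimisation of the combinatorial-entropy
    objective; the number of clusters falls out of where merging stops.

    Best of ``restarts`` runs (restarts differ in the permutation stream used
    for the expected-entropy estimate); deterministic given the seed.  The
    cluster containing the query is relabeled 0.
    """
    if window.n_rows < 2:
        raise ClusteringError("need at least 2 rows to cluster")
    seeds = np.random.SeedSequence(seed).generate_state(restarts) % (2**31)
    best: tuple[float, list[int]] | None = None
    init = _fine_partition(window)
    for run_seed in seeds:
        scorer = _CeoScorer(window, shuffles, int(run_seed))
        clusters = [frozenset(np.flatnonzero(np.array(init) == l))
                    for l in sorted(set(init))]
        while len(clusters) > 1:
            best_delta, best_pair = 0.0, None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    na, nb = len(clusters[a]), len(clusters[b])
                    merged = clusters[a] | clusters[b]
                    # merging drops ln C(na+nb, na) from the encoding term
                    delta = (
                        scorer.cluster_contribution(merged)
                        - scorer.cluster_contribution(clusters[a])
                        - scorer.cluster_contribution(clusters[b])
                        - float(gammaln(na + nb + 1) - gammaln(na + 1) - gammaln(nb + 1))
                    )
                    if delta < best_delta - 1e-12:
                        best_delta, best_pair = delta, (a, b)
            if best_pair is None:
                break
            a, b = best_pair
            clusters = (
                [clusters[i] for i in range(len(clusters)) if i not in (a, b)]
                + [clusters[a] | clusters[b]]
            )
        obj = scorer.objective(clusters)
        labels = [0] * window.n_rows
        for l, members in enumerate(clusters):
            for i in members:
                labels[i] = l
        if best is None or obj < best[0]:
            best = (obj, labels)
    return _relabel(best[1], window.query_index)


# ---------------------------------------------------------------------------
# K-means baseline
# ---------------------------------------------------------------------------

def _one_hot(window: AlignmentWindow) -> np.ndarray:
    rows = window.rows
    sym_index = {s: i for i, s in enumerate(SYMBOLS)}
    x = np.zeros((len(rows), window.width * len(SYMBOLS)))
    for i, r in enumerate(rows):
        for c, ch in enumerate(r):
            x[i, c * len(SYMBOLS) + sym_index[ch]] = 1.0
    return x


def kmeans_cluster(
    window: AlignmentWindow, k: int, restarts: int = 100, seed: int = 0
) -> ClusterPartition:
    """K-means on one-hot row encodings; best of ``restarts`` random
    initialisations by within-cluster sum of squares."""
    n = window.n_rows
    if not 2 <= k <= n:
        raise ClusteringError(f"k={k} must be in [2, {n}]")
    if k == n:
        return _relabel(list(range(n)), window.query_index)
    x = _one_hot(window)
    km = KMeans(
        n_clusters=k, n_init=restarts, init="random",
        random_state=int(seed) % (2**31),
    ).fit(x)
    return _relabel([int(l) for l in km.labels_], window.query_index)


# ---------------------------------------------------------------------------
# cluster-validity indices
# ---------------------------------------------------------------------------

def dunn_davies_bouldin(dist: np.ndarray, labels: list[int]) -> ClusterQuality:
    """Dunn and Davies-Bouldin indices from a distance matrix.

    Dunn: minimum between-cluster point distance over maximum within-cluster
    diameter (higher is better).  Davies-Bouldin: mean over clusters of the
    worst (scatter_i + scatter_j) / medoid-distance ratio, with scatter the
    mean distance to the cluster medoid (lower is better).  All-singleton
    diameters make Dunn infinite; that case is flagged degenerate.
    """
    labels = list(labels)
    ks = sorted(set(labels))
    if len(ks) < 2:
        return ClusterQuality(float("inf"), 0.0, degenerate=True)
    members = {l: [i for i, x in enumerate(labels) if x == l] for l in ks}

    max_diam = 0.0
    for idx in members.values():
        if len(idx) > 1:
            sub = dist[np.ix_(idx, idx)]
            max_diam = max(max_diam, float(sub.max()))
    min_inter = min(
        float(dist[np.ix_(members[a], members[b])].min())
        for ai, a in enumerate(ks) for b in ks[ai + 1:]
    )
    if max_diam == 0.0:
        return ClusterQuality(float("inf"), 0.0, degenerate=True)
    dunn = min_inter / max_diam

    medoid, scatter = {}, {}
    for l, idx in members.items():
        sub = dist[np.ix_(idx, idx)]
        m = int(np.argmin(sub.sum(axis=1)))
        medoid[l] = idx[m]
        scatter[l] = float(sub[m].mean())
    db_terms = []
    for a in ks:
        worst = 0.0
        for b in ks:
            if a == b:
                continue
            sep = float(dist[medoid[a], medoid[b]])
            if sep == 0:
                return ClusterQuality(dunn, float("inf"), degenerate=True)
            worst = max(worst, (scatter[a] + scatter[b]) / sep)
        db_terms.append(worst)
    return ClusterQuality(dunn, float(np.mean(db_terms)))


def cluster_quality(window: AlignmentWindow, partition: ClusterPartition) -> ClusterQuality:
    """Dunn / Davies-Bouldin of a partition of the window, under p-distance."""
    if partition.k < 2:
        return ClusterQuality(float("inf"), 0.0, degenerate=True)
    if len(partition.labels) != window.n_rows:
        raise ClusteringError("partition inconsistent with window rows")
    return dunn_davies_bouldin(_p_distance_matrix(window), partition.labels)


# ---------------------------------------------------------------------------
# partition IO
# ---------------------------------------------------------------------------

def write_partition(window: AlignmentWindow, partition: ClusterPartition, path) -> None:
    with open(path, "w") as fh:
        for sid, label in zip(window.ids, partition.labels):
            fh.write(f"{sid}\t{label}\n")


def read_partition(window: AlignmentWindow, path) -> ClusterPartition:
    by_id: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                sid, label = line.rstrip("\n").split("\t")
                by_id[sid] = int(label)
    labels = [by_id[sid] for sid in window.ids]
    return _relabel(labels, window.query_index)
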