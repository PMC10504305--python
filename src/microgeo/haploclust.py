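"""Hierarchical clustering of samples by binary marker-gene SNPs.

The route is: binary Jaccard dissimilarity between samples' variant-allele
profiles -> WPGMA (McQuitty) agglomeration -> cluster count chosen by the
elbow of the within-cluster sum-of-squares curve -> character (column)
bootstrap to score each cluster's stability, with clusters below a support
threshold flagged and excluded downstream. A separate complete-linkage tree
on Euclidean distances serves genome presence/absence comparisons.

Agglomeration is authored here rather than delegated so tie-breaking is
explicit (ties in the minimum dissimilarity are broken by the smallest
(i, j) slot pair, where a cluster occupies the slot of its earliest member);
scipy's implementations are used as independent oracles in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .consensus import SNPMatrix
from .formats import DistanceMatrix, ValidationError

logger = logging.getLogger(__name__)

LINKAGE_METHODS = ("wpgma", "complete")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def jaccard_binary(m: SNPMatrix) -> DistanceMatrix:
    """Binary Jaccard dissimilarity: d = (b + c) / (a + b + c).

    a = columns scored 1 in both samples, b/c = columns scored 1 in exactly
    one. A pair of all-zero rows (a = b = c = 0) gets d = 0 by convention.
    """
    if m.n_samples < 2 or m.n_columns < 1:
        raise ValidationError("jaccard_binary needs >=2 samples and >=1 column")
    x = m.values.astype(np.float64)
    a = x @ x.T
    r = x.sum(axis=1)
    union = r[:, None] + r[None, :] - a
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, (union - a) / union, 0.0)
    if np.any((union == 0) & ~np.eye(len(d), dtype=bool)):
        logger.warning("all-zero sample pair(s): Jaccard distance set to 0")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([str(i) for i in m.ids], d, metric_name="binary_jaccard")


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Merge list in scipy linkage layout plus leaf labels.

    ``merges`` row i = (id_a, id_b, height, size) where leaf ids are 0..n-1
    and the cluster formed at row i has id n+i. Rows follow agglomeration
    order; WPGMA heights may invert (decrease), which is logged, not an error.
    """

    merges: np.ndarray
    ids: list[str]
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def cut(self, k: int) -> pd.Series:
        """Partition into k groups by undoing the last k-1 merges.

        Cluster labels are 1..k, numbered by order of first appearance in
        the leaf ordering (deterministic).
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValidationError(f"cannot cut {n}-leaf tree into {k} groups")
        parent = np.arange(n + len(self.merges))
        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i
        for row in range(n - k):
            a, b, _, _ = self.merges[row]
            new = n + row
            parent[find(int(a))] = new
            parent[find(int(b))] = new
        roots = [find(i) for i in range(n)]
        label_of: dict[int, int] = {}
        labels = []
        for r in roots:
            if r not in label_of:
                label_of[r] = len(label_of) + 1
            labels.append(label_of[r])
        return pd.Series(labels, index=self.ids, name="cluster")

    def to_newick(self) -> str:
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.ids[i] for i in range(n)}
        for row in range(len(self.merges)):
            a, b, h, _ = self.merges[row]
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + row] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + row] = h
        return node[n + len(self.merges) - 1] + ";"


def _agglomerate(dm: DistanceMatrix, method: str) -> Dendrogram:
    if method not in LINKAGE_METHODS:
        raise ValidationError(f"unknown linkage method {method!r}")
    n = len(dm)
    if n < 2:
        raise ValidationError("agglomeration needs >=2 items")
    D = dm.d.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    link_id = np.arange(n)          # current linkage id held in each slot
    size = np.ones(n, dtype=int)
    merges = np.zeros((n - 1, 4))
    last_h = -np.inf
    for step in range(n - 1):
        W = np.where(active[:, None] & active[None, :], D, np.inf)
        W[np.tril_indices(n)] = np.inf
        flat = int(np.argmin(W))            # row-major: smallest (i, j) on ties
        i, j = divmod(flat, n)
        h = float(W[i, j])
        if h < last_h - 1e-12:
            logger.debug("%s linkage inversion at step %d (%.4g < %.4g)",
                         method, step, h, last_h)
        last_h = max(last_h, h)
        merges[step] = (link_id[i], link_id[j], h, size[i] + size[j])
        if method == "wpgma":
            new_row = 0.5 * (D[i, :] + D[j, :])
        else:
            new_row = np.maximum(D[i, :], D[j, :])
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        active[j] = False
        link_id[i] = n + step
        size[i] += size[j]
    return Dendrogram(merges=merges, ids=list(dm.ids), method=method)


def wpgma(dm: DistanceMatrix) -> Dendrogram:
    """WPGMA / McQuitty agglomeration: d(k, i∪j) = (d(k,i) + d(k,j)) / 2."""
    return _agglomerate(dm, "wpgma")


def presence_absence_tree(gene_matrix: pd.DataFrame) -> Dendrogram:
    """Complete-linkage tree on Euclidean distances between 0/1 gene rows."""
    x = gene_matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("presence_absence_tree needs >=2 genomes")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValidationError("gene matrix must be binary")
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    dm = DistanceMatrix([str(i) for i in gene_matrix.index], np.sqrt(sq),
                        metric_name="euclidean")
    return _agglomerate(dm, "complete")


# ---------------------------------------------------------------------------
# cluster-count selection
# ---------------------------------------------------------------------------

def _wss(x: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        rows = x[labels == lab]
        total += float(((rows - rows.mean(axis=0)) ** 2).sum())
    return total


def select_k(dend: Dendrogram, m: SNPMatrix, k_max: int = 10) -> int:
    """Pick the cluster count at the elbow of the within-cluster SS curve.

    WSS(k) of the binary rows about their cluster means is non-increasing in
    k, so the curve's elbow — the k maximising the second difference
    WSS(k-1) - 2 WSS(k) + WSS(k+1) — operationalizes "minimize within-cluster
    sum of squares". Returns 1 when no positive curvature exists.
    """
    n = m.n_samples
    if n < 3:
        raise ValidationError("select_k needs >=3 samples")
    if k_max >= n:
        logger.warning("k_max=%d >= n=%d; clamping to %d", k_max, n, n - 1)
        k_max = n - 1
    x = m.values.astype(float)
    wss = {}
    for k in range(1, k_max + 2):
        if k > n:
            break
        labels = dend.cut(k).to_numpy()
        wss[k] = _wss(x, labels)
    best_k, best_curv = 1, 0.0
    for k in range(2, k_max + 1):
        if k + 1 not in wss:
            break
        curv = wss[k - 1] - 2 * wss[k] + wss[k + 1]
        if curv > best_curv + 1e-12:
            best_k, best_curv = k, curv
    return best_k


# ---------------------------------------------------------------------------
# bootstrap stability
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: pd.Series                 # sample -> cluster id (1..k)
    k: int
    dendrogram: Dendrogram
    support: dict[int, float] | None = None
    stable: dict[int, bool] | None = None
    n_boot: int = 0
    seed: int | None = None
    stability_threshold: float | None = None

    def __post_init__(self):
        counts = self.labels.value_counts()
        if len(counts) != self.k or (counts == 0).any():
            raise ValidationError(
                f"labels form {len(counts)} non-empty groups, expected k={self.k}"
            )

    def stable_sample_ids(self) -> list[str]:
        if self.stable is None:
            raise ValidationError("stability flags not computed")
        return [s for s, lab in self.labels.items() if self.stable[lab]]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for lab in sorted(self.labels.unique()):
            rows.append({
                "cluster": lab,
                "n_samples": int((self.labels == lab).sum()),
                "support": None if self.support is None else self.support[lab],
                "stable": None if self.stable is None else self.stable[lab],
            })
        return pd.DataFrame(rows)


def cluster_snps(m: SNPMatrix, k: int | None = None, k_max: int = 10) -> ClusterResult:
    """Convenience route: Jaccard -> WPGMA -> (select k) -> cut."""
    dm = jaccard_binary(m)
    dend = wpgma(dm)
    if k is None:
        k = select_k(dend, m, k_max=k_max)
    labels = dend.cut(k)
    return ClusterResult(labels=labels, k=k, dendrogram=dend)


def _membership_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.sum(a & b)
    union = np.sum(a | b)
    return inter / union if union else 0.0


def bootstrap_support(m: SNPMatrix, base: ClusterResult, n_boot: int = 1000,
                      match_threshold: float = 0.9,
                      seed: int | None = None) -> dict[int, float]:
    """Column-bootstrap support for each base cluster.

    Each replicate resamples SNP columns with replacement, recomputes
    Jaccard -> WPGMA -> cut at the base k, and counts a base cluster as
    recovered when some replicate cluster matches it with membership Jaccard
    similarity >= match_threshold. A replicate whose resampled rows are all
    identical cannot support multi-cluster structure and recovers nothing
    (unless k = 1).
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(m.ids)
    base_labels = base.labels.loc[ids].to_numpy()
    clusters = sorted(set(base_labels))
    base_masks = {lab: base_labels == lab for lab in clusters}
    hits = {lab: 0 for lab in clusters}
    p = m.n_columns
    for _ in range(n_boot):
        cols = rng.integers(0, p, size=p)
        rep = SNPMatrix(ids=ids, columns=[m.columns[c] for c in cols],
                        values=m.values[:, cols])
        if base.k > 1 and (rep.values == rep.values[0]).all():
            continue
        rep_labels = cluster_snps(rep, k=base.k).labels.to_numpy()
        rep_masks = [rep_labels == lab for lab in np.unique(rep_labels)]
        for lab in clusters:
            best = max(_membership_jaccard(base_masks[lab], rm)
                       for rm in rep_masks)
            if best >= match_threshold:
                hits[lab] += 1
    return {lab: hits[lab] / n_boot for lab in clusters}


def stable_clusters(result: ClusterResult, threshold: float = 0.60) -> ClusterResult:
    """Flag clusters with bootstrap support >= threshold (inclusive) as stable."""
    if result.support is None:
        raise ValidationError("bootstrap support not computed")
    stable = {lab: s >= threshold for lab, s in result.support.items()}
    return replace(result, stable=stable, stability_threshold=threshold)
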