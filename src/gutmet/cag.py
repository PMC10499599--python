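"""Two-stage co-abundance group (CAG) construction for metabolites.

Stage one follows the weighted co-abundance network recipe: biweight
midcorrelation between features, soft-threshold adjacency ``|bicor|^beta``,
topological overlap similarity, and an adaptive cut of the average-linkage
dendrogram of ``1 - TOM``.  Features left unassigned are re-clustered in a
second stage directly on ``1 - bicor``.  Each cluster is summarised by its
first principal component (the eigen-metabolite), and clusters whose
eigen-metabolites correlate above ``merge_threshold`` are merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .tables import FeatureTable

__all__ = [
    "CAGParams",
    "CAGResult",
    "bicor",
    "bicor_matrix",
    "soft_adjacency",
    "tom_similarity",
    "dynamic_tree_cut",
    "primary_cag",
    "secondary_cag",
    "eigen_metabolite",
    "merge_cags",
    "run_cag_pipeline",
]


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (constant vector under the Pearson fallback)."""


@dataclass(frozen=True)
class CAGParams:
    """Clustering parameters.

    Defaults are the hydrophilic-metabolite settings: soft threshold
    ``beta = 12``, minimum cluster size 3, deep split 4, cut height 0.9999,
    PAM assignment stage off, merge threshold 0.8.  The lipid settings
    (beta 14, min size 20, cut height 0.999, secondary min size 6) are the
    same machinery with different numbers.
    """

    beta: float = 12.0
    min_cluster_size: int = 3
    deep_split: int = 4
    cut_height: float = 0.9999
    pam_stage: bool = False
    merge_threshold: float = 0.8
    secondary_min_cluster_size: int | None = None

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ValueError("deep_split must be an integer 0..4")
        if self.pam_stage:
            raise NotImplementedError("the PAM assignment stage is disabled by design")


@dataclass
class CAGResult:
    labels: pd.Series  # feature -> cluster id, 0 = unassigned
    eigen: pd.DataFrame  # samples x clusters
    stage: pd.Series  # feature -> {primary, secondary, unassigned}
    merge_log: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# biweight midcorrelation


def _bicor_weights(x: np.ndarray) -> np.ndarray | None:
    """Median/MAD-based deviations ``(x - med) * w`` or None if MAD = 0."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def _pearson_terms(x: np.ndarray) -> np.ndarray:
    d = x - x.mean()
    if np.all(d == 0):
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    return d


def bicor(x, y) -> float:
    """Biweight midcorrelation with 9-MAD outlier down-weighting.

    A vector whose MAD is zero falls back to Pearson terms for that vector
    (the robust weights are undefined); two constant vectors raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("bicor needs two equal-length 1-d vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("bicor inputs must be finite")
    ax = _bicor_weights(x)
    ay = _bicor_weights(y)
    if ax is None:
        ax = _pearson_terms(x)
    if ay is None:
        ay = _pearson_terms(y)
    denom = np.sqrt(np.sum(ax**2) * np.sum(ay**2))
    if denom == 0:
        raise UndefinedCorrelationError("zero denominator in bicor")
    return float(np.clip(np.sum(ax * ay) / denom, -1.0, 1.0))


def bicor_matrix(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """All-pairs bicor of the columns of a samples-by-features matrix."""
    A = np.asarray(X, dtype=float)
    n, p = A.shape
    terms = np.empty((n, p))
    for j in range(p):
        t = _bicor_weights(A[:, j])
        if t is None:
            t = _pearson_terms(A[:, j])
        norm = np.sqrt(np.sum(t**2))
        if norm == 0:
            raise UndefinedCorrelationError(f"column {j} has zero dispersion")
        terms[:, j] = t / norm
    C = terms.T @ terms
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


# ---------------------------------------------------------------------------
# adjacency and topological overlap


def soft_adjacency(C: np.ndarray, beta: float) -> np.ndarray:
    """Unsigned soft-threshold adjacency ``a_ij = |c_ij|^beta`` (diagonal 1)."""
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if np.max(np.abs(C)) > 1 + 1e-12:
        raise ValueError("correlation entries must lie in [-1, 1]")
    A = np.abs(C) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    ``l_ij`` sums shared-neighbour adjacency excluding i and j themselves;
    ``k_i`` is the connectivity of node i (off-diagonal row sum).
    """
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12 or not np.allclose(np.diag(A), 1.0):
        raise ValueError("adjacency entries must be in [0, 1] with unit diagonal")
    Aoff = A.copy()
    np.fill_diagonal(Aoff, 0.0)
    k = Aoff.sum(axis=1)
    L = Aoff @ Aoff  # L_ij = sum_u a_iu a_uj over u != i, j plus a_ii terms removed
    kmin = np.minimum.outer(k, k)
    T = (L + Aoff) / (kmin + 1.0 - Aoff)
    np.fill_diagonal(T, 1.0)
    return np.clip(T, 0.0, 1.0)


# ---------------------------------------------------------------------------
# adaptive tree cut


#: minimum relative height gap required to split a branch, by deep-split level
#: (higher deep split = more sensitive splitting)
_GAP_BY_DEEP_SPLIT = {0: 0.15, 1: 0.12, 2: 0.09, 3: 0.06, 4: 0.03}


def dynamic_tree_cut(D: np.ndarray, params: CAGParams, *, min_cluster_size: int | None = None) -> np.ndarray:
    """Adaptive cut of the average-linkage dendrogram of a dissimilarity matrix.

    The dendrogram is first cut statically at ``cut_height``; each resulting
    branch is then split recursively wherever both children reach
    ``min_cluster_size`` and the merge sits above the children by a relative
    height gap scaled by ``deep_split`` (4 = most sensitive).  Branches below
    ``min_cluster_size`` are left unassigned (label 0).  Labels are renumbered
    by decreasing cluster size.
    """
    D = np.asarray(D, dtype=float)
    p = D.shape[0]
    msize = params.min_cluster_size if min_cluster_size is None else min_cluster_size
    if p < msize:
        warnings.warn("fewer features than min_cluster_size; all unassigned", stacklevel=2)
        return np.zeros(p, dtype=int)
    if not np.allclose(D, D.T, atol=1e-10) or not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")

    Z = linkage(squareform(D, checks=False), method="average")
    n = p
    # children and merge heights per internal node (node ids n..2n-2)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for i, (a, b, h, _) in enumerate(Z):
        node = n + i
        a, b = int(a), int(b)
        members[node] = members[a] + members[b]
        height[node] = float(h)
        children[node] = (a, b)

    # static cut: maximal nodes whose merge height <= cut_height
    roots: list[int] = []

    def collect(node: int) -> None:
        if node < n or height[node] <= params.cut_height:
            roots.append(node)
        else:
            a, b = children[node]
            collect(a)
            collect(b)

    if len(Z) == 0:
        return np.zeros(p, dtype=int)
    collect(n + len(Z) - 1)

    gap_min = _GAP_BY_DEEP_SPLIT[params.deep_split]

    def split(node: int) -> list[int]:
        """Return the list of cluster-root nodes under ``node``."""
        if node < n or len(members[node]) < 2 * msize:
            return [node]
        a, b = children[node]
        if len(members[a]) < msize or len(members[b]) < msize:
            return [node]
        h_children = max(height[a], height[b])
        gap = (height[node] - h_children) / height[node] if height[node] > 0 else 0.0
        if gap < gap_min:
            return [node]
        return split(a) + split(b)

    clusters: list[list[int]] = []
    for r in roots:
        for sub in split(r):
            mem = members[sub]
            if len(mem) >= msize:
                clusters.append(mem)

    labels = np.zeros(p, dtype=int)
    clusters.sort(key=lambda mem: (-len(mem), min(mem)))
    for lab, mem in enumerate(clusters, start=1):
        labels[mem] = lab
    return labels


# ---------------------------------------------------------------------------
# two-stage pipeline


def primary_cag(X: FeatureTable | pd.DataFrame, params: CAGParams) -> pd.Series:
    """Stage-one labels: bicor -> |.|^beta -> TOM -> cut of 1 - TOM."""
    df = X.values if isinstance(X, FeatureTable) else X
    C = bicor_matrix(df)
    A = soft_adjacency(C, params.beta)
    T = tom_similarity(A)
    labels = dynamic_tree_cut(1.0 - T, params)
    return pd.Series(labels, index=df.columns, name="cag")


def secondary_cag(X_unassigned: FeatureTable | pd.DataFrame, params: CAGParams,
                  label_offset: int = 0) -> pd.Series:
    """Stage-two labels on 1 - bicor for features the first stage left out."""
    df = X_unassigned.values if isinstance(X_unassigned, FeatureTable) else X_unassigned
    if df.shape[1] == 0:
        return pd.Series(dtype=int, name="cag")
    msize = params.secondary_min_cluster_size or params.min_cluster_size
    if df.shape[1] < msize:
        return pd.Series(np.zeros(df.shape[1], dtype=int), index=df.columns, name="cag")
    C = bicor_matrix(df)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    labels = dynamic_tree_cut(D, params, min_cluster_size=msize)
    labels = np.where(labels > 0, labels + label_offset, 0)
    return pd.Series(labels, index=df.columns, name="cag")


def eigen_metabolite(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """PC1 of each cluster's column-standardised member submatrix.

    The sign is flipped so the eigen-metabolite correlates non-negatively
    with the mean standardised member profile; columns have unit variance.
    Zero-variance members are dropped from the PCA with a warning.
    """
    cols = {}
    for lab in sorted(set(labels) - {0}):
        mem = labels.index[labels == lab]
        sub = X.loc[:, mem]
        sd = sub.std(axis=0, ddof=1)
        if (sd == 0).any():
            warnings.warn(f"cluster {lab}: dropping zero-variance members", stacklevel=2)
            sub = sub.loc[:, sd[sd > 0].index]
        if sub.shape[1] < 2:
            raise ValueError(f"cluster {lab} has fewer than 2 usable members")
        Zm = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
        U, S, Vt = np.linalg.svd(Zm.to_numpy(), full_matrices=False)
        pc1 = U[:, 0] * S[0]
        mean_profile = Zm.mean(axis=1).to_numpy()
        if np.dot(pc1, mean_profile) < 0:
            pc1 = -pc1
        pc1 = pc1 / np.std(pc1, ddof=1)
        cols[lab] = pc1
    return pd.DataFrame(cols, index=X.index)


def merge_cags(X: pd.DataFrame, labels: pd.Series, merge_threshold: float = 0.8,
               stage: pd.Series | None = None) -> CAGResult:
    """Iteratively merge the cluster pair with the highest eigen bicor above threshold.

    After each merge the combined eigen-metabolite is recomputed.  Ties are
    broken by larger correlation then smaller label id.  Final labels are
    renumbered by decreasing cluster size; the merge log records each step.
    """
    labels = labels.copy()
    merge_log: list[dict] = []
    while True:
        active = sorted(set(labels) - {0})
        if len(active) < 2:
            break
        eig = eigen_metabolite(X, labels)
        best = None
        for i, li in enumerate(active):
            for lj in active[i + 1:]:
                r = bicor(eig[li].to_numpy(), eig[lj].to_numpy())
                if r > merge_threshold and (best is None or r > best[0] + 1e-15):
                    best = (r, li, lj)
        if best is None:
            break
        r, li, lj = best
        labels[labels == lj] = li
        merge_log.append({"kept": int(li), "merged": int(lj), "bicor": float(r)})
    # renumber by decreasing size, ties by smaller old label
    sizes = labels[labels > 0].value_counts()
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = labels.map(lambda v: remap.get(v, 0))
    eigen = eigen_metabolite(X, labels)
    if stage is None:
        stage = pd.Series(np.where(labels > 0, "primary", "unassigned"), index=labels.index)
    else:
        stage = stage.where(labels > 0, "unassigned")
    return CAGResult(labels=labels, eigen=eigen, stage=stage, merge_log=merge_log)


def run_cag_pipeline(X: FeatureTable | pd.DataFrame, params: CAGParams) -> CAGResult:
    """Full two-stage clustering with eigen-metabolites and cluster merging."""
    df = X.values if isinstance(X, FeatureTable) else X
    lab1 = primary_cag(df, params)
    leftover = lab1.index[lab1 == 0]
    lab2 = secondary_cag(df.loc[:, leftover], params, label_offset=int(lab1.max()))
    labels = lab1.copy()
    labels.loc[lab2.index] = lab2
    stage = pd.Series("unassigned", index=labels.index)
    stage[lab1 > 0] = "primary"
    stage[(labels > 0) & (lab1 == 0)] = "secondary"
    return merge_cags(df, labels, params.merge_threshold, stage=stage)
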