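"""Correlation networks across omics layers.

* ``reboot_correlations`` builds genus co-abundance edges under a
  compositionality-aware null: each feature is permuted independently across
  samples and every sample row renormalised to sum 1, which reproduces the
  spurious negative dependence a closed composition induces; significance
  compares the Fisher-z bootstrap distribution of the observed correlation
  against that permutation null.
* ``call_microbial_groups`` reads co-abundance groups off the positive
  significant edges (connected components).
* ``cluster_participants`` is agglomerative Ward clustering of participants
  on genus abundances, clusters relabelled by ascending IR proportion.
* ``microbe_metabolite_network`` and ``cross_omics_network`` assemble signed
  edge lists at an adjusted-p cutoff, the latter with partial Spearman
  correlations adjusted for age, sex, BMI and fasting glucose.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .stats import bh_adjust, partial_spearman
from .tables import FeatureTable

log = logging.getLogger(__name__)

__all__ = [
    "NetworkParams",
    "OmicsNetwork",
    "reboot_correlations",
    "call_microbial_groups",
    "cluster_participants",
    "microbe_metabolite_network",
    "cross_omics_network",
    "write_network",
    "read_network",
]


@dataclass(frozen=True)
class NetworkParams:
    n_perm: int = 1000
    n_boot: int = 1000
    alpha_adj: float = 0.05
    prevalence_min: float = 0.40
    n_participant_clusters: int = 4
    xnet_covariates: tuple = ("age", "sex", "bmi", "fbg_mgdl")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0 < self.alpha_adj < 1:
            raise ValueError("alpha_adj must be in (0, 1)")


@dataclass
class OmicsNetwork:
    """Typed nodes and signed weighted edges of one analysis network."""

    nodes: pd.DataFrame  # index node id; columns layer, size_ratio
    edges: pd.DataFrame  # columns source, target, sign, coefficient, p, p_adj

    def __post_init__(self) -> None:
        if len(self.edges):
            if (self.edges["source"] == self.edges["target"]).any():
                raise ValueError("self-edges are not allowed")
            seen = set()
            for u, v in zip(self.edges["source"], self.edges["target"]):
                key = frozenset((u, v))
                if key in seen:
                    raise ValueError(f"duplicate edge {u}-{v}")
                seen.add(key)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for nid, row in self.nodes.iterrows():
            g.add_node(nid, **{k: v for k, v in row.items() if pd.notna(v)})
        for _, e in self.edges.iterrows():
            g.add_edge(e["source"], e["target"], sign=int(e["sign"]),
                       coefficient=float(e["coefficient"]), p=float(e["p"]),
                       p_adj=float(e["p_adj"]), width=abs(float(e["coefficient"])))
        return g


# ---------------------------------------------------------------------------
# ReBoot-style compositionality-corrected correlations


def _renormalise(M: np.ndarray) -> np.ndarray:
    s = M.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return M / s


def _pairwise_spearman(M: np.ndarray) -> np.ndarray:
    R = np.apply_along_axis(stats.rankdata, 0, M)
    return np.corrcoef(R, rowvar=False)


def reboot_correlations(X_comp: FeatureTable | pd.DataFrame,
                        params: NetworkParams = NetworkParams()) -> pd.DataFrame:
    """Per-pair compositionality-corrected Spearman correlations.

    For each feature pair the observed Spearman correlation is referenced
    against (a) a permutation null (independently permute each feature
    column, renormalise rows to sum 1, ``n_perm`` times) and (b) a bootstrap
    distribution (``n_boot`` row resamples, renormalised).  Both are
    Fisher-z transformed and the two-sided p-value is the normal tail of
    ``(mean_boot - mean_perm) / sd_perm``.  BH adjustment runs over all
    retained pairs.  Zero-variance features are excluded with a warning.
    """
    df = X_comp.values if isinstance(X_comp, FeatureTable) else X_comp
    keep = df.columns[df.std(axis=0, ddof=1) > 0]
    if len(keep) < len(df.columns):
        warnings.warn(
            f"excluding {len(df.columns) - len(keep)} zero-variance features", stacklevel=2
        )
    df = df.loc[:, keep]
    M = _renormalise(df.to_numpy(dtype=float))
    n, p = M.shape
    rng = np.random.default_rng(params.seed)

    obs = _pairwise_spearman(M)

    def fisher_z(r):
        return np.arctanh(np.clip(r, -0.999999, 0.999999))

    perm_sum = np.zeros((p, p))
    perm_sq = np.zeros((p, p))
    for _ in range(params.n_perm):
        P = np.empty_like(M)
        for j in range(p):
            P[:, j] = M[rng.permutation(n), j]
        z = fisher_z(_pairwise_spearman(_renormalise(P)))
        perm_sum += z
        perm_sq += z**2
    perm_mean = perm_sum / params.n_perm
    perm_sd = np.sqrt(np.maximum(perm_sq / params.n_perm - perm_mean**2, 1e-300))

    boot_sum = np.zeros((p, p))
    for _ in range(params.n_boot):
        idx = rng.integers(0, n, n)
        z = fisher_z(_pairwise_spearman(_renormalise(M[idx])))
        boot_sum += z
    boot_mean = boot_sum / params.n_boot

    zstat = (boot_mean - perm_mean) / perm_sd
    pmat = 2.0 * stats.norm.sf(np.abs(zstat))

    iu = np.triu_indices(p, k=1)
    out = pd.DataFrame(
        {
            "source": np.asarray(keep)[iu[0]],
            "target": np.asarray(keep)[iu[1]],
            "rho": obs[iu],
            "z": zstat[iu],
            "p": pmat[iu],
        }
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["sign"] = np.sign(out["rho"]).astype(int)
    return out


def call_microbial_groups(edges: pd.DataFrame, alpha_adj: float = 0.05,
                          overrides: dict | None = None) -> pd.Series:
    """Co-abundance microbial groups = connected components of the positive
    significant edge subgraph; everything else is ``miscellaneous`` (group 0).

    ``overrides`` maps a feature id to the group id of another named feature
    (e.g. ``{"Robinsoniella": "Blautia"}`` moves the former into the latter's
    group), mirroring a curated reassignment; applications are logged.
    """
    sig = edges[(edges["p_adj"] < alpha_adj) & (edges["sign"] > 0)]
    g = nx.Graph()
    g.add_edges_from(zip(sig["source"], sig["target"]))
    nodes = sorted(set(edges["source"]) | set(edges["target"]))
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: c[0])  # deterministic: lexicographic smallest member
    labels = {}
    for i, comp in enumerate(comps, start=1):
        for node in comp:
            labels[node] = i
    out = pd.Series({node: labels.get(node, 0) for node in nodes}, name="group")
    if overrides:
        for feature, anchor in overrides.items():
            if feature in out.index and anchor in out.index:
                log.info("group override: %s -> group of %s (%d)", feature, anchor, out[anchor])
                out[feature] = out[anchor]
    return out


def cluster_participants(genus_table: FeatureTable | pd.DataFrame, k: int,
                         ir_labels=None) -> pd.Series:
    """Ward clustering of participants on genus abundances, cut at k clusters.

    Uses the classic Ward update on squared Euclidean distances.  When
    ``ir_labels`` is given, clusters are renumbered by ascending proportion
    of IR participants so the lowest-IR cluster is cluster 1 (the reference).
    The partition is invariant to sample order.
    """
    df = genus_table.values if isinstance(genus_table, FeatureTable) else genus_table
    n = df.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of samples")
    order = np.argsort(df.index.to_numpy())  # canonical order for invariance
    X = df.to_numpy(dtype=float)[order]
    D2 = pdist(X, metric="sqeuclidean")
    Z = linkage(D2, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(index=df.index[order], data=raw).reindex(df.index)

    if ir_labels is not None:
        ir = pd.Series(np.asarray(ir_labels) == "IR", index=df.index)
        props = {c: ir[labels == c].mean() for c in sorted(labels.unique())}
        new_order = sorted(props, key=lambda c: (props[c], c))
        remap = {old: i + 1 for i, old in enumerate(new_order)}
        labels = labels.map(remap)
    return labels.rename("participant_cluster")


# ---------------------------------------------------------------------------
# cross-layer networks


def _size_ratios(values: pd.DataFrame, ir_mask: np.ndarray, is_mask: np.ndarray) -> pd.Series:
    med_ir = values.loc[ir_mask].median(axis=0)
    med_is = values.loc[is_mask].median(axis=0)
    ratio = med_ir / med_is
    ratio[med_is == 0] = np.nan  # dropped from sizing, kept in topology
    return ratio


def microbe_metabolite_network(genus_table: FeatureTable, metabolite_table: FeatureTable,
                               alpha_adj: float = 0.05) -> tuple[OmicsNetwork, OmicsNetwork]:
    """Genus-by-metabolite Spearman networks, split by sign.

    All pairs are tested, BH-adjusted jointly, and edges with p_adj below
    the cutoff are split into a positive and a negative network.
    """
    G, Mx = genus_table.values, metabolite_table.values
    if not G.index.equals(Mx.index):
        raise ValueError("tables must be sample-aligned")
    rows = []
    for g in G.columns:
        for m in Mx.columns:
            rho, p = stats.spearmanr(G[g], Mx[m])
            rows.append((g, m, rho, p))
    edges = pd.DataFrame(rows, columns=["source", "target", "coefficient", "p"])
    edges["p_adj"] = bh_adjust(edges["p"].to_numpy())
    edges["sign"] = np.sign(edges["coefficient"]).astype(int)
    sig = edges[edges["p_adj"] < alpha_adj]

    nodes = pd.DataFrame(
        {"layer": ["genus"] * len(G.columns) + ["metabolite"] * len(Mx.columns)},
        index=list(G.columns) + list(Mx.columns),
    )
    nodes["size_ratio"] = np.nan
    pos = OmicsNetwork(nodes, sig[sig["sign"] > 0].reset_index(drop=True))
    neg = OmicsNetwork(nodes, sig[sig["sign"] < 0].reset_index(drop=True))
    return pos, neg


def cross_omics_network(feature_sets: dict, phenotypes: pd.DataFrame,
                        params: NetworkParams = NetworkParams()) -> OmicsNetwork:
    """Partial-Spearman network across layers, adjusted for the configured
    covariates, with IR/IS median-ratio node sizes.

    ``feature_sets`` maps a layer name to a sample-aligned DataFrame of the
    selected features for that layer.  Samples missing any covariate are
    dropped (logged).  Edges keep p_adj < alpha; node ``size_ratio`` is
    median(IR)/median(IS), undefined (NaN) when the IS median is zero.
    """
    frames = []
    for layer, df in feature_sets.items():
        d = df.values if isinstance(df, FeatureTable) else df
        frames.append(d.add_prefix(""))
    combined = pd.concat(frames, axis=1)
    layer_of = {}
    for layer, df in feature_sets.items():
        d = df.values if isinstance(df, FeatureTable) else df
        for c in d.columns:
            layer_of[c] = layer
    if combined.columns.duplicated().any():
        raise ValueError("feature ids must be unique across layers")

    cov = phenotypes.loc[combined.index, list(params.xnet_covariates)]
    ok = cov.notna().all(axis=1)
    if (~ok).any():
        log.info("cross_omics_network: dropping %d samples with missing covariates", (~ok).sum())
    combined, cov = combined.loc[ok], cov.loc[ok]

    feats = list(combined.columns)
    Zc = cov.to_numpy(dtype=float)
    rows = []
    for i, fi in enumerate(feats):
        for fj in feats[i + 1:]:
            rho, p = partial_spearman(combined[fi].to_numpy(), combined[fj].to_numpy(), Zc)
            rows.append((fi, fj, rho, p))
    edges = pd.DataFrame(rows, columns=["source", "target", "coefficient", "p"])
    edges["p_adj"] = bh_adjust(edges["p"].to_numpy()) if len(edges) else []
    edges["sign"] = np.sign(edges["coefficient"]).astype(int)
    sig = edges[edges["p_adj"] < params.alpha_adj].reset_index(drop=True)

    nodes = pd.DataFrame({"layer": [layer_of[f] for f in feats]}, index=feats)
    ir_class = phenotypes.loc[combined.index, "ir_class"]
    ir_mask = (ir_class == "IR").to_numpy()
    is_mask = (ir_class == "IS").to_numpy()
    nodes["size_ratio"] = _size_ratios(combined, ir_mask, is_mask)
    return OmicsNetwork(nodes, sig)


# ---------------------------------------------------------------------------
# I/O


def write_network(net: OmicsNetwork, path_prefix) -> None:
    """Write an edge-list TSV and a GraphML file (Cytoscape-compatible)."""
    edges = net.edges.loc[:, ["source", "target", "sign", "coefficient", "p", "p_adj"]]
    edges.to_csv(f"{path_prefix}.edges.tsv", sep="\t", index=False)
    g = net.to_graph()
    nx.write_graphml(g, f"{path_prefix}.graphml")


def read_network(path_prefix) -> OmicsNetwork:
    g = nx.read_graphml(f"{path_prefix}.graphml")
    nodes = pd.DataFrame.from_dict(dict(g.nodes(data=True)), orient="index")
    if "size_ratio" not in nodes.columns:
        nodes["size_ratio"] = np.nan
    rows = [
        (u, v, d.get("sign"), d.get("coefficient"), d.get("p"), d.get("p_adj"))
        for u, v, d in g.edges(data=True)
    ]
    edges = pd.DataFrame(rows, columns=["source", "target", "sign", "coefficient", "p", "p_adj"])
    return OmicsNetwork(nodes, edges)
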