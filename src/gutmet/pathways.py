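"""KO-level association tests and pathway propagation scoring.

Each KEGG orthologue (KO) that is significantly positively (negatively)
associated with a target contributes +1 (-1) to every pathway it belongs to;
a pathway's score is that signed sum divided by its number of member KOs, so
scores live in [-1, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_adjust, wilcoxon_rank_sum
from .tables import FeatureTable, TransformSpec, apply_transform

log = logging.getLogger(__name__)

__all__ = [
    "KOPathwayMap",
    "PathwayScore",
    "ko_association",
    "propagate_pathway_score",
    "summarize_categories",
    "DEFAULT_CATEGORIES",
]

#: KEGG BRITE category ids of the four summarised super-categories
DEFAULT_CATEGORIES = {
    "09101": "carbohydrate metabolism",
    "09105": "amino acid metabolism",
    "09103": "lipid metabolism",
    "09131": "membrane transport",
}


@dataclass
class KOPathwayMap:
    """Many-to-many KO -> pathway membership."""

    ko_to_pathways: dict  # ko_id -> frozenset of pathway ids
    pathway_sizes: dict  # pathway_id -> member KO count (full map)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KOPathwayMap":
        if not {"ko_id", "pathway_id"}.issubset(df.columns):
            raise ValueError("map needs ko_id and pathway_id columns")
        k2p: dict[str, set] = {}
        sizes: dict[str, set] = {}
        for ko, pw in zip(df["ko_id"], df["pathway_id"]):
            k2p.setdefault(ko, set()).add(pw)
            sizes.setdefault(pw, set()).add(ko)
        if any(len(v) == 0 for v in sizes.values()):
            raise ValueError("every pathway must have at least one KO")
        return cls(
            ko_to_pathways={k: frozenset(v) for k, v in k2p.items()},
            pathway_sizes={p: len(v) for p, v in sizes.items()},
        )

    @classmethod
    def read_tsv(cls, path) -> "KOPathwayMap":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class PathwayScore:
    pathway_id: str
    n_ko: int
    signed_sum: int
    score: float


def ko_association(ko_table: FeatureTable | pd.DataFrame, target,
                   mode: str = "spearman_metabolite", alpha_adj: float = 0.05,
                   arcsine: bool = True) -> pd.DataFrame:
    """Per-KO association sign (+1/-1, 0 when non-significant) and adjusted p.

    ``spearman_metabolite``: Spearman correlation of each KO with a numeric
    target.  ``cluster_vs_rest``: two-sided rank-sum test of each KO between
    one participant cluster and the rest, with ``target`` the boolean (or
    0/1) membership vector; the sign is the sign of the median difference.
    KO relative abundances are arcsine-square-root transformed first.
    """
    table = ko_table if isinstance(ko_table, FeatureTable) else FeatureTable(
        ko_table, "ko", compositional=False)
    if arcsine:
        table = apply_transform(table, TransformSpec("arcsine_sqrt"))
    df = table.values
    rows = []
    target = np.asarray(target, dtype=float)
    for ko in df.columns:
        x = df[ko].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"constant KO column {ko!r}: sign 0", stacklevel=2)
            rows.append((ko, 0.0, 1.0))
            continue
        if mode == "spearman_metabolite":
            rho, p = stats.spearmanr(x, target)
            rows.append((ko, rho, p))
        elif mode == "cluster_vs_rest":
            in_c = target > 0.5
            if in_c.sum() < 2 or (~in_c).sum() < 2:
                warnings.warn("cluster with < 2 members: comparison skipped", stacklevel=2)
                rows.append((ko, 0.0, 1.0))
                continue
            p = wilcoxon_rank_sum(x[in_c], x[~in_c])
            effect = np.median(x[in_c]) - np.median(x[~in_c])
            if effect == 0:
                effect = x[in_c].mean() - x[~in_c].mean()
            rows.append((ko, effect, p))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame(rows, columns=["ko_id", "effect", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["sign"] = np.where(out["p_adj"] < alpha_adj, np.sign(out["effect"]), 0).astype(int)
    return out


def propagate_pathway_score(ko_signs: pd.Series | dict, pmap: KOPathwayMap,
                            denominator: str = "detected") -> pd.DataFrame:
    """Propagate per-KO signs (+1/0/-1) to pathway scores.

    Each signed KO contributes its sign to every pathway it maps to; a
    pathway's score is signed_sum / n_ko.  With ``denominator='detected'``
    n_ko counts the pathway's KOs present in ``ko_signs``; with
    ``'database'`` it is the full map size.  Unmapped KOs are logged and
    skipped; pathways with no detected KOs are omitted with a warning.
    """
    signs = dict(ko_signs)
    bad = {k: s for k, s in signs.items() if s not in (-1, 0, 1)}
    if bad:
        raise ValueError(f"signs must be in {{-1, 0, 1}}: {bad}")
    if denominator not in ("detected", "database"):
        raise ValueError("denominator must be 'detected' or 'database'")

    signed_sum: dict[str, int] = {p: 0 for p in pmap.pathway_sizes}
    detected: dict[str, int] = {p: 0 for p in pmap.pathway_sizes}
    for ko, s in signs.items():
        pws = pmap.ko_to_pathways.get(ko)
        if pws is None:
            log.info("KO %s absent from the pathway map; skipped", ko)
            continue
        for p in pws:
            detected[p] += 1
            signed_sum[p] += int(s)

    rows = []
    for p in sorted(pmap.pathway_sizes):
        n_ko = detected[p] if denominator == "detected" else pmap.pathway_sizes[p]
        if n_ko == 0:
            warnings.warn(f"pathway {p!r} has no detected KOs; omitted", stacklevel=2)
            continue
        rows.append(PathwayScore(p, n_ko, signed_sum[p], signed_sum[p] / n_ko))
    return pd.DataFrame(
        [(s.pathway_id, s.n_ko, s.signed_sum, s.score) for s in rows],
        columns=["pathway_id", "n_ko", "signed_sum", "score"],
    )


def summarize_categories(scores: pd.DataFrame, category_map: pd.DataFrame,
                         categories: dict = DEFAULT_CATEGORIES) -> pd.DataFrame:
    """Group pathway scores under the named super-categories.

    ``category_map`` has columns pathway_id, category_id.  Pathways without
    a category land in the ``other`` bucket; categories with no pathways
    still appear as empty rows.
    """
    cat_of = dict(zip(category_map["pathway_id"], category_map["category_id"]))
    rows = []
    for cat_id, cat_name in categories.items():
        members = scores[scores["pathway_id"].map(lambda p: cat_of.get(p) == cat_id)]
        rows.append((cat_id, cat_name, len(members),
                     float(members["score"].mean()) if len(members) else np.nan))
    other = scores[scores["pathway_id"].map(lambda p: cat_of.get(p) not in categories)]
    rows.append(("other", "other", len(other),
                 float(other["score"].mean()) if len(other) else np.nan))
    return pd.DataFrame(rows, columns=["category_id", "category", "n_pathways", "mean_score"])
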