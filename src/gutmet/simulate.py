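"""Synthetic multi-omics cohort generator with planted structure.

The generator emulates the statistical shapes the downstream analyses assume:

* a faecal metabolome on a lognormal scale with correlated co-abundance
  blocks tied to a latent insulin-resistance (IR) factor and censored to
  zero below a per-feature detection limit;
* genus-level relative abundances from a logistic-normal draw with planted
  positively-correlated co-abundance groups (rows sum to 1);
* KO (gene-family) relative abundances driven by the genus table through a
  fixed genus-to-KO incidence matrix plus noise, renormalised per sample;
* plasma cytokines generated as linear mediators between planted metabolites
  and IR markers (cytokine = a*met + covariates + noise;
  marker = c'*met + b*cytokine + covariates + noise);
* insulin and glucose derived by monotone maps so that recomputed HOMA-IR
  tracks the structural IR score.

Everything is driven by one seeded generator, so a fixed config is bitwise
reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotypes import derive_phenotypes
from .tables import FeatureTable, write_feature_table

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "Cohort",
    "generate_cohort",
    "generate_mediation_data",
    "prevalence_filter",
]


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class MediationTriplet:
    metabolite_idx: int
    cytokine_idx: int
    marker: str  # one of homa_ir, bmi, tg_mgdl, hdl_mgdl
    a: float
    b: float
    c_prime: float


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults give a desk-scale analogue of the cohort: 300 participants,
    120 faecal metabolites organised in 4 co-abundance blocks of 30 with
    within-block correlation 0.7 on the log scale, 60 genera with 4 planted
    positively-correlated groups of 8, 150 KOs driven by the genera, and
    10 plasma cytokines of which a few are planted mediators.
    """

    n_samples: int = 300
    n_metabolites: int = 120
    n_genera: int = 60
    n_kos: int = 150
    n_cytokines: int = 10
    n_cag_blocks: int = 4
    block_corr: float = 0.7
    n_genus_groups: int = 4
    genus_group_size: int = 8
    genus_group_corr: float = 0.7
    #: loading of each metabolite block's factor on the latent IR factor
    ir_effect_sizes: tuple = (0.5, -0.4, 0.3, 0.0)
    #: loading of each genus group's log-scale factor on latent IR
    genus_ir_effects: tuple = (0.6, -0.6, 0.3, 0.0)
    mediation_triplets: tuple = (
        MediationTriplet(0, 0, "homa_ir", 0.5, 0.4, 0.2),
        MediationTriplet(1, 1, "homa_ir", 0.4, 0.5, 0.1),
        MediationTriplet(30, 2, "bmi", 0.5, 0.3, 0.2),
        MediationTriplet(31, 3, "tg_mgdl", 0.4, 0.4, 0.1),
    )
    detection_limit_quantile: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cag_blocks < 1 or self.n_metabolites // self.n_cag_blocks < 3:
            raise ConfigError("metabolite blocks must have at least 3 members")
        if not 0 < self.block_corr < 1:
            raise ConfigError("block_corr must be in (0, 1)")
        if not 0 <= self.detection_limit_quantile < 1:
            raise ConfigError("detection_limit_quantile must be in [0, 1)")
        if len(self.ir_effect_sizes) != self.n_cag_blocks:
            raise ConfigError("need one IR effect size per metabolite block")
        if self.n_genus_groups * self.genus_group_size > self.n_genera:
            raise ConfigError("genus groups exceed n_genera")
        for t in self.mediation_triplets:
            if not (0 <= t.metabolite_idx < self.n_metabolites):
                raise ConfigError(f"triplet metabolite index {t.metabolite_idx} out of range")
            if not (0 <= t.cytokine_idx < self.n_cytokines):
                raise ConfigError(f"triplet cytokine index {t.cytokine_idx} out of range")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    metabolite_block_of: dict
    genus_group_of: dict
    mediation_effects: list  # (metabolite_id, cytokine_id, marker, a, b, c_prime)
    latent_ir: pd.Series

    def to_json(self, path) -> None:
        obj = {
            "metabolite_block_of": self.metabolite_block_of,
            "genus_group_of": self.genus_group_of,
            "mediation_effects": self.mediation_effects,
            "latent_ir": {k: float(v) for k, v in self.latent_ir.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=1))


@dataclass
class Cohort:
    tables: dict  # layer -> FeatureTable
    phenotypes: pd.DataFrame
    truth: SyntheticTruth
    ko_pathway_map: pd.DataFrame  # columns ko_id, pathway_id

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for layer, table in self.tables.items():
            write_feature_table(table, out / f"{layer}.tsv")
        ph = self.phenotypes.copy()
        ph.index.name = "sample_id"
        ph.to_csv(out / "phenotypes.tsv", sep="\t", na_rep="NA")
        self.ko_pathway_map.to_csv(out / "ko_pathway_map.tsv", sep="\t", index=False)
        self.truth.to_json(out / "truth.json")


#: multiplier applied to the structural (score-scale) mediation signal when a
#: marker lives on a wider measurement scale
_MARKER_SCALE = {"homa_ir": 1.0, "bmi": 1.0, "tg_mgdl": 25.0, "hdl_mgdl": 10.0}


def _block_sizes(total: int, k: int) -> list[int]:
    base = total // k
    sizes = [base] * k
    for i in range(total - base * k):
        sizes[i] += 1
    return sizes


def generate_cohort(config: SimConfig) -> Cohort:
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    latent_ir = rng.standard_normal(n)
    age = np.clip(rng.normal(50, 10, n), 20, 80)
    sex = rng.integers(0, 2, n).astype(float)  # 0 = male, 1 = female
    age_z = (age - age.mean()) / age.std()

    # ---- genus layer: logistic-normal with planted positive groups --------
    g_names = [f"g{j:03d}" for j in range(config.n_genera)]
    group_of = {}
    group_factors = rng.standard_normal((config.n_genus_groups, n))
    for g, eff in zip(range(config.n_genus_groups), config.genus_ir_effects):
        group_factors[g] = eff * latent_ir + np.sqrt(max(0.0, 1 - eff**2)) * group_factors[g]
    log_g = np.empty((n, config.n_genera))
    rho_g = config.genus_group_corr
    base_logmean = rng.normal(0.0, 1.0, config.n_genera)
    for j in range(config.n_genera):
        grp = j // config.genus_group_size if j < config.n_genus_groups * config.genus_group_size else 0
        in_group = j < config.n_genus_groups * config.genus_group_size
        group_of[g_names[j]] = (grp + 1) if in_group else 0
        eps = rng.standard_normal(n)
        if in_group:
            z = np.sqrt(rho_g) * group_factors[grp] + np.sqrt(1 - rho_g) * eps
        else:
            z = eps
        log_g[:, j] = base_logmean[j] + 1.0 * z
    G = np.exp(log_g)
    G /= G.sum(axis=1, keepdims=True)
    genus = FeatureTable(pd.DataFrame(G, index=samples, columns=g_names), "genus")

    # ---- metabolite layer: lognormal blocks + detection-limit censoring ---
    m_names = [f"m{j:03d}" for j in range(config.n_metabolites)]
    sizes = _block_sizes(config.n_metabolites, config.n_cag_blocks)
    block_of = {}
    rho = config.block_corr
    M_log = np.empty((n, config.n_metabolites))
    j = 0
    for b in range(config.n_cag_blocks):
        eff = config.ir_effect_sizes[b]
        # couple the first two blocks to the matching genus groups so that a
        # genuine microbe-metabolite signal exists in the cohort
        micro = 0.3 if b < 2 and b < config.n_genus_groups else 0.0
        resid = max(0.0, 1 - eff**2 - micro**2)
        f = eff * latent_ir + micro * group_factors[min(b, config.n_genus_groups - 1)] \
            + np.sqrt(resid) * rng.standard_normal(n)
        for _ in range(sizes[b]):
            block_of[m_names[j]] = b + 1
            z = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n)
            mu = rng.normal(1.0, 0.8)
            M_log[:, j] = mu + 0.6 * z
            j += 1
    M = np.exp(M_log)
    if config.detection_limit_quantile > 0:
        lod = np.quantile(M, config.detection_limit_quantile, axis=0)
        M = np.where(M < lod, 0.0, M)
    met_df = pd.DataFrame(M, index=samples, columns=m_names)
    metab = FeatureTable(met_df, "metabolite")

    # ---- cytokines: linear mediators of planted metabolites ---------------
    c_names = [f"c{j:02d}" for j in range(config.n_cytokines)]
    met_z = (met_df - met_df.mean()) / met_df.std(ddof=1)
    C = np.empty((n, config.n_cytokines))
    trip_by_cyt = {}
    for t in config.mediation_triplets:
        trip_by_cyt.setdefault(t.cytokine_idx, []).append(t)
    for c in range(config.n_cytokines):
        signal = np.zeros(n)
        var_used = 0.0
        for t in trip_by_cyt.get(c, []):
            signal = signal + t.a * met_z.iloc[:, t.metabolite_idx].to_numpy()
            var_used += t.a**2
        # non-mediator cytokines still load weakly on latent IR, as real
        # inflammatory analytes do
        if c not in trip_by_cyt:
            signal = 0.3 * latent_ir
            var_used = 0.09
        noise_sd = np.sqrt(max(0.1, 1 - var_used))
        C[:, c] = signal + 0.1 * age_z + 0.1 * sex + noise_sd * rng.standard_normal(n)
    # mimic assay range handling: below detection -> 0, above -> analyte max
    C = np.exp(0.5 * C)  # positive concentration scale
    lo = np.quantile(C, 0.005, axis=0)
    hi = np.quantile(C, 0.995, axis=0)
    C = np.where(C < lo, 0.0, np.minimum(C, hi))
    cyto = FeatureTable(pd.DataFrame(C, index=samples, columns=c_names), "cytokine")

    # ---- IR markers from the structural equations -------------------------
    cyt_df = cyto.values
    cyt_z = (cyt_df - cyt_df.mean()) / cyt_df.std(ddof=1)

    def marker_signal(name: str) -> np.ndarray:
        s = np.zeros(n)
        for t in config.mediation_triplets:
            if t.marker == name:
                s = s + t.c_prime * met_z.iloc[:, t.metabolite_idx].to_numpy() \
                    + t.b * cyt_z.iloc[:, t.cytokine_idx].to_numpy()
        return s

    homa_score = 0.8 * latent_ir + marker_signal("homa_ir") + 0.05 * age_z + 0.3 * rng.standard_normal(n)
    homa = np.maximum(0.2, 2.0 + 1.0 * homa_score)
    # monotone map latent -> glucose; insulin recovered so HOMA-IR is exact
    glucose = 85.0 + 20.0 * (1.0 / (1.0 + np.exp(-homa_score)))
    insulin = 405.0 * homa / glucose

    bmi = 23.0 + 1.5 * latent_ir + marker_signal("bmi") + 0.2 * age_z + 1.5 * rng.standard_normal(n)
    tg = np.maximum(30.0, 120.0 + 30.0 * latent_ir + 25.0 * marker_signal("tg_mgdl")
                    + 25.0 * rng.standard_normal(n))
    hdl = np.maximum(20.0, 55.0 - 8.0 * latent_ir + 10.0 * marker_signal("hdl_mgdl")
                     + 4.0 * sex + 8.0 * rng.standard_normal(n))
    waist = 82.0 + 2.0 * (bmi - 23.0) + 5.0 * (1 - sex) + 4.0 * rng.standard_normal(n)
    sbp = 120.0 + 6.0 * latent_ir + 0.25 * (age - 50.0) + 10.0 * rng.standard_normal(n)
    dbp = 75.0 + 4.0 * latent_ir + 7.0 * rng.standard_normal(n)
    fbg = np.maximum(60.0, glucose + 5.0 * rng.standard_normal(n))

    pheno = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "waist_cm": waist,
            "bmi": bmi,
            "tg_mgdl": tg,
            "hdl_mgdl": hdl,
            "sbp_mmhg": sbp,
            "dbp_mmhg": dbp,
            "fbg_mgdl": fbg,
            "insulin_uU_ml": insulin,
            "glucose_mg_dl": glucose,
        },
        index=samples,
    )
    pheno = derive_phenotypes(pheno)

    # ---- KO layer driven by genera ----------------------------------------
    k_names = [f"K{j:05d}" for j in range(config.n_kos)]
    incidence = (rng.random((config.n_genera, config.n_kos)) < 0.15).astype(float)
    incidence *= rng.lognormal(0.0, 0.5, size=incidence.shape)
    K = G @ incidence
    K *= rng.lognormal(0.0, 0.3, size=K.shape)  # multiplicative measurement noise
    K = np.maximum(K, 1e-12)
    K /= K.sum(axis=1, keepdims=True)
    ko = FeatureTable(pd.DataFrame(K, index=samples, columns=k_names), "ko")

    # toy KO -> pathway map (many-to-many)
    n_pathways = 20
    rows = []
    for kn in k_names:
        for p in rng.choice(n_pathways, size=rng.integers(1, 4), replace=False):
            rows.append((kn, f"map{p:05d}"))
    ko_map = pd.DataFrame(rows, columns=["ko_id", "pathway_id"])

    truth = SyntheticTruth(
        metabolite_block_of=block_of,
        genus_group_of=group_of,
        mediation_effects=[
            # b and c' recorded on the marker's own measurement scale
            (
                m_names[t.metabolite_idx],
                c_names[t.cytokine_idx],
                t.marker,
                t.a,
                _MARKER_SCALE[t.marker] * t.b,
                _MARKER_SCALE[t.marker] * t.c_prime,
            )
            for t in config.mediation_triplets
        ],
        latent_ir=pd.Series(latent_ir, index=samples),
    )
    tables = {"metabolite": metab, "genus": genus, "ko": ko, "cytokine": cyto}
    return Cohort(tables=tables, phenotypes=pheno, truth=truth, ko_pathway_map=ko_map)


def generate_mediation_data(
    n: int, a: float, b: float, c_prime: float, seed: int = 0
) -> pd.DataFrame:
    """Draw one exactly-linear mediation triplet (used for coverage checks).

    metabolite ~ N(0,1); cytokine = a*met + 0.1*age_z + 0.1*sex + e;
    marker = c'*met + b*cytokine + 0.1*age_z + 0.1*sex + e.
    """
    rng = np.random.default_rng(seed)
    met = rng.standard_normal(n)
    age = rng.normal(50, 10, n)
    sex = rng.integers(0, 2, n).astype(float)
    age_z = (age - age.mean()) / age.std()
    cyt = a * met + 0.1 * age_z + 0.1 * sex + rng.standard_normal(n)
    marker = c_prime * met + b * cyt + 0.1 * age_z + 0.1 * sex + rng.standard_normal(n)
    return pd.DataFrame(
        {"metabolite": met, "cytokine": cyt, "marker": marker, "age": age, "sex": sex}
    )


def prevalence_filter(table: FeatureTable, min_fraction: float):
    """Keep features detected (> 0) in strictly more than ``min_fraction`` of samples."""
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    frac = (table.values > 0).mean(axis=0)
    keep = [f for f in table.feature_ids if frac[f] > min_fraction]
    if not keep:
        warnings.warn("prevalence filter removed every feature", stacklevel=2)
        return FeatureTable(table.values.iloc[:, :0], table.layer, None, compositional=False)
    return table.subset_features(keep)
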