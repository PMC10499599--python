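"""End-to-end driver: simulate -> filter -> cag -> assoc -> micronet ->
enrich -> predict -> mediate -> report.

Every stage writes its tables under an output directory and returns its
in-memory result; ``run_pipeline`` chains them on one synthetic cohort and
is bitwise-reproducible under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cag import CAGParams, run_cag_pipeline
from .mediation import MediationParams, mediation_table, screen_triplets
from .networks import (
    NetworkParams,
    call_microbial_groups,
    cluster_participants,
    cross_omics_network,
    microbe_metabolite_network,
    reboot_correlations,
    write_network,
)
from .pathways import KOPathwayMap, ko_association, propagate_pathway_score
from .predict import PredictionParams, auc_over_k
from .simulate import Cohort, SimConfig, generate_cohort, prevalence_filter
from .stats import bh_adjust, rank_regression
from .tables import TransformSpec, apply_transform

log = logging.getLogger(__name__)


def run_pipeline(config: SimConfig | None = None, out_dir=None,
                 cag_params: CAGParams | None = None,
                 net_params: NetworkParams | None = None,
                 pred_params: PredictionParams | None = None,
                 med_params: MediationParams | None = None) -> dict:
    """Run every analysis stage on one synthetic cohort; return the results.

    When ``out_dir`` is given, per-stage tables are written beneath it
    together with a ``run.json`` recording the seed and a config hash.
    """
    config = config or SimConfig()
    seed = config.seed
    cag_params = cag_params or CAGParams()
    net_params = net_params or NetworkParams(seed=seed, n_perm=200, n_boot=200)
    pred_params = pred_params or PredictionParams(
        seed=seed, n_repeats=5, n_trees=100, tune_mtry=False, k_grid=(5, 10, 20))
    med_params = med_params or MediationParams(seed=seed, n_boot=300)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    results: dict = {}

    # 1. simulate
    cohort: Cohort = generate_cohort(config)
    results["cohort"] = cohort
    if out is not None:
        cohort.write(out / "cohort")

    # 2. prevalence filter (metabolites 75%, genera 40%)
    met = prevalence_filter(cohort.tables["metabolite"], 0.75)
    gen = prevalence_filter(cohort.tables["genus"], net_params.prevalence_min)
    results["filtered"] = {"metabolite": met, "genus": gen}

    # 3. co-abundance groups on log-scaled metabolite abundances
    met_log = apply_transform(met, TransformSpec("log10_scale"))
    cag_res = run_cag_pipeline(met_log, cag_params)
    results["cag"] = cag_res
    if out is not None:
        lab = pd.DataFrame({"cag_id": cag_res.labels, "stage": cag_res.stage})
        lab.index.name = "feature_id"
        lab.to_csv(out / "cag_labels.tsv", sep="\t")
        eig = cag_res.eigen.copy()
        eig.index.name = "sample_id"
        eig.to_csv(out / "cag_eigen.tsv", sep="\t")
        (out / "cag_merge_log.json").write_text(json.dumps(cag_res.merge_log, indent=1))

    # 4. rank-based association of each eigen-metabolite with HOMA-IR
    pheno = cohort.phenotypes
    assoc_rows = []
    for cag_id in cag_res.eigen.columns:
        X = np.column_stack([
            cag_res.eigen[cag_id].to_numpy(),
            pheno["age"].to_numpy(),
            pheno["sex"].to_numpy(),
        ])
        fit = rank_regression(pheno["homa_ir"].to_numpy(), X,
                              feature_names=["eigen", "age", "sex"])
        assoc_rows.append((cag_id, fit.loc["eigen", "coef"], fit.loc["eigen", "p"]))
    assoc = pd.DataFrame(assoc_rows, columns=["cag_id", "coef", "p"])
    assoc["p_adj"] = bh_adjust(assoc["p"].to_numpy())
    results["assoc"] = assoc
    if out is not None:
        assoc.to_csv(out / "cag_assoc.tsv", sep="\t", index=False)

    # 5. genus network with compositionality-corrected null; groups; clusters
    edges = reboot_correlations(gen, net_params)
    groups = call_microbial_groups(edges, net_params.alpha_adj)
    clusters = cluster_participants(gen, net_params.n_participant_clusters,
                                    ir_labels=pheno["ir_class"])
    pos_net, neg_net = microbe_metabolite_network(gen, met, net_params.alpha_adj)
    results["micronet"] = {"edges": edges, "groups": groups, "participant_clusters": clusters,
                           "mm_positive": pos_net, "mm_negative": neg_net}
    if out is not None:
        edges.to_csv(out / "genus_edges.tsv", sep="\t", index=False)
        groups.rename("group").to_frame().to_csv(out / "genus_groups.tsv", sep="\t")
        clusters.to_frame().to_csv(out / "participant_clusters.tsv", sep="\t")
        write_network(pos_net, out / "mm_positive")
        write_network(neg_net, out / "mm_negative")

    # 6. KO associations per participant cluster -> pathway scores
    pmap = KOPathwayMap.from_frame(cohort.ko_pathway_map)
    scores = {}
    for c in sorted(clusters.unique()):
        ko_res = ko_association(cohort.tables["ko"], (clusters == c).to_numpy(),
                                mode="cluster_vs_rest")
        sc = propagate_pathway_score(
            pd.Series(ko_res["sign"].to_numpy(), index=ko_res["ko_id"]), pmap)
        scores[int(c)] = sc
    results["pathway_scores"] = scores
    if out is not None:
        allsc = pd.concat({c: s.set_index("pathway_id") for c, s in scores.items()},
                          names=["cluster", "pathway_id"]).reset_index()
        allsc.to_csv(out / "pathway_scores.tsv", sep="\t", index=False)

    # 7. cross-omics network on IR/IS samples
    keep = pheno["ir_class"].isin(["IR", "IS", "intermediate"])
    sig_mets = assoc.loc[assoc["p_adj"] < 0.05, "cag_id"]
    member_mets = [f for f in cag_res.labels.index
                   if cag_res.labels[f] in set(sig_mets)] or list(met.feature_ids[:10])
    xnet = cross_omics_network(
        {
            "metabolite": met.values.loc[keep, member_mets[:15]],
            "genus": gen.values.loc[keep, groups.index[groups > 0][:15]],
            "cytokine": cohort.tables["cytokine"].values.loc[keep],
        },
        pheno.loc[keep],
        net_params,
    )
    results["xnet"] = xnet
    if out is not None:
        write_network(xnet, out / "cross_omics")

    # 8. prediction benchmark (IR vs rest)
    y = (pheno["ir_class"] == "IR").astype(int).to_numpy()
    auc_tab = auc_over_k(
        {"metabolite": met.values, "genus": gen.values}, y, pred_params)
    results["auc"] = auc_tab
    if out is not None:
        auc_tab.to_csv(out / "auc_over_k.tsv", sep="\t", index=False)

    # 9. mediation cascade
    cyt = cohort.tables["cytokine"].values
    cyt_log = apply_transform(cohort.tables["cytokine"], TransformSpec("log10_scale")).values
    carbs = met.values.iloc[:, :15]
    markers = pheno.loc[:, list(med_params.markers)]
    cov = pheno.loc[:, list(med_params.covariates)]
    triplets = screen_triplets(carbs, cyt_log, markers, cov, med_params.alpha_adj)
    data = pd.concat([carbs, cyt_log, markers, cov], axis=1)
    med_tab = mediation_table(data, triplets, med_params)
    results["mediation"] = med_tab
    if out is not None:
        med_tab.to_csv(out / "mediation.tsv", sep="\t", index=False)

    # 10. report
    if out is not None:
        cfg_repr = repr(config).encode()
        meta = {
            "seed": seed,
            "config_sha256": hashlib.sha256(cfg_repr).hexdigest(),
            "n_samples": config.n_samples,
            "n_cags": int(cag_res.labels.max()),
            "n_genus_groups": int(groups.max()),
            "n_significant_mediations": int(med_tab["significant"].sum()) if len(med_tab) else 0,
        }
        (out / "run.json").write_text(json.dumps(meta, indent=1))
    return results
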