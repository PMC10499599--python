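"""Screened causal mediation: which cytokines carry the in silico effects of
faecal carbohydrate metabolites on IR markers (HOMA-IR, BMI, TG, HDL-C)?

Writes mediation.tsv and the explained-variance table under results/analysis/.
"""

import importlib.util
from pathlib import Path

import pandas as pd

from gutmet.mediation import MediationParams, mediation_table, screen_triplets
from gutmet.predict import PredictionParams, explained_variance
from gutmet.simulate import prevalence_filter
from gutmet.tables import TransformSpec, apply_transform

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    cohort = common.load_cohort()
    ph = cohort.phenotypes
    params = MediationParams(seed=common.COHORT_SEED, n_boot=1000)

    met = prevalence_filter(cohort.tables["metabolite"], 0.75)
    carbs = met.values.iloc[:, :15]  # the IR-associated carbohydrate panel
    cyt_log = apply_transform(cohort.tables["cytokine"],
                              TransformSpec("log10_scale")).values
    markers = ph.loc[:, list(params.markers)]
    cov = ph.loc[:, list(params.covariates)]

    # explained variance of each cytokine from the carbohydrate panel
    ev = {c: explained_variance(carbs, cyt_log[c],
                                PredictionParams(seed=common.COHORT_SEED, n_trees=200,
                                                 tune_mtry=False))
          for c in cyt_log.columns}
    ev_tab = pd.Series(ev, name="r2").rename_axis("cytokine").reset_index()
    ev_tab.to_csv(common.RESULTS / "cytokine_explained_variance.tsv", sep="\t",
                  index=False)
    print("explained variance (R^2) of cytokines from faecal carbohydrates:")
    print(ev_tab.round(3).to_string(index=False))

    triplets = screen_triplets(carbs, cyt_log, markers, cov, params.alpha_adj)
    print(f"{len(triplets)} eligible (metabolite, cytokine, marker) triplets")
    data = pd.concat([carbs, cyt_log, markers, cov], axis=1)
    out = mediation_table(data, triplets, params)
    out.to_csv(common.RESULTS / "mediation.tsv", sep="\t", index=False)
    sig = out[out["significant"]]
    print(f"{len(sig)} significant mediations (p_adj < {params.alpha_adj})")
    if len(sig):
        top = sig.reindex(sig["acme"].abs().sort_values(ascending=False).index).head(5)
        print(top[["metabolite", "cytokine", "marker", "acme", "ade",
                   "prop_mediated", "p_adj"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
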