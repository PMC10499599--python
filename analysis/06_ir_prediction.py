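"""Benchmark how well each omics layer classifies insulin resistance:
mRMR-selected features, random forests over a grid of feature counts,
held-out AUC distributions.

Writes auc_over_k.tsv under results/analysis/.
"""

import importlib.util
from pathlib import Path

from gutmet.predict import PredictionParams, auc_over_k
from gutmet.simulate import prevalence_filter

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    cohort = common.load_cohort()
    met = prevalence_filter(cohort.tables["metabolite"], 0.75)
    gen = prevalence_filter(cohort.tables["genus"], 0.40)
    y = (cohort.phenotypes["ir_class"] == "IR").astype(int).to_numpy()
    params = PredictionParams(seed=common.COHORT_SEED, n_repeats=10, n_trees=200,
                              tune_mtry=False, k_grid=(5, 10, 20, 40))
    tab = auc_over_k({"metabolite": met.values, "genus": gen.values,
                      "merged": met.values.join(gen.values)}, y, params)
    tab.to_csv(common.RESULTS / "auc_over_k.tsv", sep="\t", index=False)
    med = tab.groupby(["layer", "k"])["auc"].median().unstack()
    print("median held-out AUC by layer and feature count:")
    print(med.round(3).to_string())


if __name__ == "__main__":
    main()
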