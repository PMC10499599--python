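"""Associate each eigen-metabolite with HOMA-IR by rank-based regression
(adjusted for age and sex), BH-corrected within the table.

Writes cag_assoc.tsv under results/analysis/.
"""

import importlib.util
from pathlib import Path

import numpy as np
import pandas as pd

from gutmet.cag import CAGParams, run_cag_pipeline
from gutmet.simulate import prevalence_filter
from gutmet.stats import bh_adjust, rank_regression
from gutmet.tables import TransformSpec, apply_transform

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    cohort = common.load_cohort()
    met = prevalence_filter(cohort.tables["metabolite"], 0.75)
    met_log = apply_transform(met, TransformSpec("log10_scale"))
    res = run_cag_pipeline(met_log, CAGParams())
    ph = cohort.phenotypes

    rows = []
    for cag_id in res.eigen.columns:
        X = np.column_stack([res.eigen[cag_id], ph["age"], ph["sex"]])
        fit = rank_regression(ph["homa_ir"].to_numpy(), X,
                              feature_names=["eigen", "age", "sex"])
        rows.append((cag_id, fit.loc["eigen", "coef"], fit.loc["eigen", "p"]))
    out = pd.DataFrame(rows, columns=["cag_id", "coef", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out.to_csv(common.RESULTS / "cag_assoc.tsv", sep="\t", index=False)

    sig = out[out["p_adj"] < 0.05]
    print(out.to_string(index=False))
    print(f"{len(sig)} of {len(out)} CAGs associated with HOMA-IR at p_adj < 0.05")


if __name__ == "__main__":
    main()
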