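"""Generate the synthetic multi-omics cohort and summarise its phenotypes.

Writes the cohort TSV tables (metabolite, genus, KO, cytokine layers plus
phenotypes and the planted truth) under results/analysis/cohort/.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    cohort = common.load_cohort()
    out = common.RESULTS / "cohort"
    cohort.write(out)
    ph = cohort.phenotypes
    print(f"cohort: {len(ph)} participants, layers "
          f"{ {k: v.shape[1] for k, v in cohort.tables.items()} }")
    print("IR classes:", ph["ir_class"].value_counts().to_dict())
    print("MetS classes:", ph["mets_class"].value_counts().to_dict())
    print(f"median HOMA-IR: {ph['homa_ir'].median():.2f}")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
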