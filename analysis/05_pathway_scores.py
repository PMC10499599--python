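"""Compare KO abundances between each participant cluster and the rest, then
propagate the significant signs to pathway scores.

Writes pathway_scores.tsv under results/analysis/.
"""

import importlib.util
from pathlib import Path

import pandas as pd

from gutmet.networks import NetworkParams, cluster_participants
from gutmet.pathways import KOPathwayMap, ko_association, propagate_pathway_score
from gutmet.simulate import prevalence_filter

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    cohort = common.load_cohort()
    params = NetworkParams(seed=common.COHORT_SEED)
    gen = prevalence_filter(cohort.tables["genus"], params.prevalence_min)
    clusters = cluster_participants(gen, params.n_participant_clusters,
                                    ir_labels=cohort.phenotypes["ir_class"])
    pmap = KOPathwayMap.from_frame(cohort.ko_pathway_map)

    frames = []
    for c in sorted(clusters.unique()):
        ko_res = ko_association(cohort.tables["ko"], (clusters == c).to_numpy(),
                                mode="cluster_vs_rest")
        n_sig = int((ko_res["sign"] != 0).sum())
        scores = propagate_pathway_score(
            pd.Series(ko_res["sign"].to_numpy(), index=ko_res["ko_id"]), pmap)
        scores.insert(0, "cluster", c)
        frames.append(scores)
        top = scores.reindex(scores["score"].abs().sort_values(ascending=False).index)
        print(f"cluster {c}: {n_sig} differential KOs; strongest pathway "
              f"{top.iloc[0]['pathway_id']} (score {top.iloc[0]['score']:+.2f})")

    out = pd.concat(frames, ignore_index=True)
    out.to_csv(common.RESULTS / "pathway_scores.tsv", sep="\t", index=False)
    print(f"wrote {common.RESULTS / 'pathway_scores.tsv'} ({len(out)} rows)")


if __name__ == "__main__":
    main()
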