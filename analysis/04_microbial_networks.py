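"""Genus co-abundance network with the permutation-renormalisation null,
co-abundance microbial groups, participant clustering, and the sign-split
microbe-metabolite networks.

Writes genus_edges.tsv, genus_groups.tsv, participant_clusters.tsv and the
mm_{positive,negative} networks under results/analysis/.
"""

import importlib.util
from pathlib import Path

from gutmet.networks import (
    NetworkParams,
    call_microbial_groups,
    cluster_participants,
    microbe_metabolite_network,
    reboot_correlations,
    write_network,
)
from gutmet.simulate import prevalence_filter

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).with_name("00_common.py"))
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)


def main():
    cohort = common.load_cohort()
    params = NetworkParams(seed=common.COHORT_SEED, n_perm=1000, n_boot=1000)
    gen = prevalence_filter(cohort.tables["genus"], params.prevalence_min)
    print(f"prevalence filter (>40%): kept {gen.shape[1]} of "
          f"{cohort.tables['genus'].shape[1]} genera")

    edges = reboot_correlations(gen, params)
    sig = edges[edges["p_adj"] < params.alpha_adj]
    print(f"{len(sig)} significant genus-genus edges "
          f"({(sig['sign'] > 0).sum()} positive, {(sig['sign'] < 0).sum()} negative)")
    groups = call_microbial_groups(edges, params.alpha_adj)
    print(f"{int(groups.max())} co-abundance microbial groups; "
          f"{(groups == 0).sum()} genera miscellaneous")

    clusters = cluster_participants(gen, params.n_participant_clusters,
                                    ir_labels=cohort.phenotypes["ir_class"])
    ir = cohort.phenotypes["ir_class"] == "IR"
    for c in sorted(clusters.unique()):
        frac = ir[clusters == c].mean()
        print(f"participant cluster {c}: n={int((clusters == c).sum())}, "
              f"IR fraction {frac:.2f}")

    met = prevalence_filter(cohort.tables["metabolite"], 0.75)
    pos, neg = microbe_metabolite_network(gen, met, params.alpha_adj)
    print(f"microbe-metabolite edges: {len(pos.edges)} positive, {len(neg.edges)} negative")

    edges.to_csv(common.RESULTS / "genus_edges.tsv", sep="\t", index=False)
    groups.rename("group").to_frame().rename_axis("feature_id").to_csv(
        common.RESULTS / "genus_groups.tsv", sep="\t")
    clusters.to_frame().rename_axis("sample_id").to_csv(
        common.RESULTS / "participant_clusters.tsv", sep="\t")
    write_network(pos, common.RESULTS / "mm_positive")
    write_network(neg, common.RESULTS / "mm_negative")


if __name__ == "__main__":
    main()
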