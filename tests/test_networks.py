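"""Compositionality-corrected genus networks, group calling, participant
clustering, microbe-metabolite and cross-omics networks, network I/O."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gutmet.networks import (
    NetworkParams,
    OmicsNetwork,
    call_microbial_groups,
    cluster_participants,
    cross_omics_network,
    microbe_metabolite_network,
    read_network,
    reboot_correlations,
    write_network,
)
from gutmet.tables import FeatureTable


def _composition(rng, n=120, p=20, copies=None):
    X = np.exp(rng.normal(0, 1, (n, p)))
    if copies:
        for a, b in copies:
            X[:, b] = X[:, a]
    X /= X.sum(axis=1, keepdims=True)
    return pd.DataFrame(X, columns=[f"g{i:02d}" for i in range(p)],
                        index=[f"s{i}" for i in range(n)])


class TestReboot:
    def test_planted_copy_pair_detected(self, rng):
        df = _composition(rng, copies=[(0, 1)])
        edges = reboot_correlations(df, NetworkParams(seed=1, n_perm=200, n_boot=200))
        row = edges[(edges.source == "g00") & (edges.target == "g01")].iloc[0]
        assert row["rho"] > 0.9
        assert row["p_adj"] < 0.05
        assert row["sign"] == 1

    def test_independent_features_few_significant(self, rng):
        df = _composition(rng)
        edges = reboot_correlations(df, NetworkParams(seed=2, n_perm=200, n_boot=200))
        assert (edges["p_adj"] < 0.05).sum() <= 1

    def test_n_perm_floor_config_error(self):
        with pytest.raises(ValueError):
            NetworkParams(n_perm=50)

    def test_zero_variance_feature_excluded(self, rng):
        df = _composition(rng, p=6)
        df["flat"] = 0.0
        with pytest.warns(UserWarning):
            edges = reboot_correlations(df, NetworkParams(seed=0, n_perm=100, n_boot=100))
        assert "flat" not in set(edges.source) | set(edges.target)


class TestGroups:
    def _edges(self, rows):
        df = pd.DataFrame(rows, columns=["source", "target", "rho"])
        df["p_adj"] = 0.001
        df["sign"] = np.sign(df["rho"]).astype(int)
        return df

    def test_components_of_positive_edges(self):
        edges = self._edges([("a", "b", 0.5), ("b", "c", 0.6), ("d", "e", 0.7)])
        groups = call_microbial_groups(edges)
        assert groups["a"] == groups["b"] == groups["c"]
        assert groups["d"] == groups["e"] != groups["a"]

    def test_only_negative_edges_all_miscellaneous(self):
        edges = self._edges([("a", "b", -0.5), ("b", "c", -0.6)])
        groups = call_microbial_groups(edges)
        assert (groups == 0).all()

    def test_override_honoured(self):
        edges = self._edges([("a", "b", 0.5), ("c", "d", 0.7), ("b", "x", 0.4)])
        g0 = call_microbial_groups(edges)
        assert g0["x"] == g0["a"]
        g1 = call_microbial_groups(edges, overrides={"x": "c"})
        assert g1["x"] == g1["c"]


class TestParticipants:
    def test_two_blobs_perfect(self, rng):
        A = rng.normal(0, 0.05, (30, 5)) + np.array([1, 0, 0, 0, 0.0])
        B = rng.normal(0, 0.05, (30, 5)) + np.array([0, 1, 0, 0, 0.0])
        X = pd.DataFrame(np.vstack([A, B]), index=[f"s{i}" for i in range(60)])
        labels = cluster_participants(X, 2)
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_singletons(self, rng):
        X = pd.DataFrame(rng.random((8, 3)), index=list("abcdefgh"))
        labels = cluster_participants(X, 8)
        assert labels.nunique() == 8

    def test_k_above_n_raises(self, rng):
        X = pd.DataFrame(rng.random((4, 3)))
        with pytest.raises(ValueError):
            cluster_participants(X, 5)

    def test_lowest_ir_cluster_is_reference(self, rng):
        A = rng.normal(0, 0.05, (20, 4)) + np.array([1, 0, 0, 0.0])
        B = rng.normal(0, 0.05, (20, 4)) + np.array([0, 1, 0, 0.0])
        X = pd.DataFrame(np.vstack([A, B]), index=[f"s{i}" for i in range(40)])
        ir = ["IR"] * 20 + ["IS"] * 20  # second blob has no IR
        labels = cluster_participants(X, 2, ir_labels=ir)
        assert (labels.iloc[20:] == 1).all()
        assert (labels.iloc[:20] == 2).all()

    def test_sample_order_invariance(self, rng):
        X = pd.DataFrame(rng.random((25, 6)), index=[f"s{i:02d}" for i in range(25)])
        l1 = cluster_participants(X, 3)
        shuffled = X.sample(frac=1.0, random_state=1)
        l2 = cluster_participants(shuffled, 3).reindex(l1.index)
        assert adjusted_rand_score(l1, l2) == 1.0


class TestMicrobeMetabolite:
    def test_planted_dependence_recovered_and_sign_split(self, rng):
        n = 150
        G = np.exp(rng.normal(0, 1, (n, 6)))
        G /= G.sum(axis=1, keepdims=True)
        gt = FeatureTable(pd.DataFrame(G, columns=[f"g{i}" for i in range(6)],
                                       index=[f"s{i}" for i in range(n)]), "genus")
        M = pd.DataFrame(
            {"mpos": G[:, 0] + 0.01 * rng.standard_normal(n),
             "mneg": -G[:, 0] + 0.01 * rng.standard_normal(n),
             "mnull": rng.standard_normal(n)},
            index=gt.sample_ids)
        mt = FeatureTable(M, "metabolite")
        pos, neg = microbe_metabolite_network(gt, mt)
        pos_pairs = set(zip(pos.edges.source, pos.edges.target))
        neg_pairs = set(zip(neg.edges.source, neg.edges.target))
        assert ("g0", "mpos") in pos_pairs
        assert ("g0", "mneg") in neg_pairs
        assert not pos_pairs & neg_pairs

    def test_independent_tables_no_edges(self, rng):
        n = 100
        G = np.exp(rng.normal(0, 1, (n, 10)))
        G /= G.sum(axis=1, keepdims=True)
        gt = FeatureTable(pd.DataFrame(G, columns=[f"g{i}" for i in range(10)],
                                       index=[f"s{i}" for i in range(n)]), "genus")
        mt = FeatureTable(pd.DataFrame(rng.standard_normal((n, 10)),
                                       columns=[f"m{i}" for i in range(10)],
                                       index=gt.sample_ids), "metabolite")
        pos, neg = microbe_metabolite_network(gt, mt)
        assert len(pos.edges) + len(neg.edges) <= 2


class TestCrossOmics:
    def _inputs(self, rng, n=120):
        idx = [f"s{i}" for i in range(n)]
        f = rng.standard_normal(n)
        met = pd.DataFrame({"mA": f + 0.1 * rng.standard_normal(n),
                            "mB": rng.standard_normal(n)}, index=idx)
        cyt = pd.DataFrame({"cA": f + 0.1 * rng.standard_normal(n),
                            "cB": rng.standard_normal(n)}, index=idx)
        homa = np.exp(0.4 * f + 0.3 * rng.standard_normal(n)) + 0.8
        pheno = pd.DataFrame(
            {"age": rng.normal(50, 8, n), "sex": rng.integers(0, 2, n).astype(float),
             "bmi": rng.normal(24, 3, n), "fbg_mgdl": rng.normal(95, 8, n),
             "homa_ir": homa,
             "ir_class": np.where(homa >= 2.5, "IR", np.where(homa <= 1.6, "IS",
                                                              "intermediate"))},
            index=idx)
        return met, cyt, pheno

    def test_correlated_pair_found_with_size_ratios(self, rng):
        met, cyt, pheno = self._inputs(rng)
        net = cross_omics_network({"metabolite": met, "cytokine": cyt}, pheno,
                                  NetworkParams(seed=0))
        pairs = {frozenset((u, v)) for u, v in zip(net.edges.source, net.edges.target)}
        assert frozenset(("mA", "cA")) in pairs
        assert set(net.nodes["layer"]) == {"metabolite", "cytokine"}

    def test_size_ratio_median_rule(self, rng):
        met, cyt, pheno = self._inputs(rng)
        vals = pd.DataFrame(index=pheno.index)
        ir = pheno["ir_class"] == "IR"
        is_ = pheno["ir_class"] == "IS"
        vals["v"] = 0.0
        vals.loc[ir, "v"] = [2, 4, 6] * (ir.sum() // 3) + [4] * (ir.sum() % 3)
        vals.loc[is_, "v"] = [1, 2, 3] * (is_.sum() // 3) + [2] * (is_.sum() % 3)
        net = cross_omics_network({"metabolite": pd.concat([met, vals], axis=1)},
                                  pheno, NetworkParams(seed=0))
        assert net.nodes.loc["v", "size_ratio"] == pytest.approx(2.0)

    def test_zero_is_median_excluded_from_sizing(self, rng):
        met, cyt, pheno = self._inputs(rng)
        z = pd.DataFrame({"zed": np.zeros(len(pheno))}, index=pheno.index)
        z.loc[pheno["ir_class"] == "IR", "zed"] = 1.0
        net = cross_omics_network({"metabolite": pd.concat([met, z], axis=1)},
                                  pheno, NetworkParams(seed=0))
        assert "zed" in net.nodes.index  # retained in topology
        assert np.isnan(net.nodes.loc["zed", "size_ratio"])

    def test_duplicate_feature_across_layers_rejected(self, rng):
        met, cyt, pheno = self._inputs(rng)
        with pytest.raises(ValueError):
            cross_omics_network({"metabolite": met, "cytokine": met}, pheno,
                                NetworkParams(seed=0))


class TestNetworkIO:
    def _net(self):
        nodes = pd.DataFrame({"layer": ["genus", "metabolite"], "size_ratio": [1.5, 0.5]},
                             index=["g1", "m1"])
        edges = pd.DataFrame([{"source": "g1", "target": "m1", "sign": 1,
                               "coefficient": 0.42, "p": 0.001, "p_adj": 0.01}])
        return OmicsNetwork(nodes, edges)

    def test_roundtrip_edge_attributes(self, tmp_path):
        net = self._net()
        write_network(net, tmp_path / "net")
        back = read_network(tmp_path / "net")
        assert len(back.edges) == 1
        e = back.edges.iloc[0]
        assert e["coefficient"] == pytest.approx(0.42)
        assert e["p_adj"] == pytest.approx(0.01)
        assert int(e["sign"]) == 1

    def test_empty_network_valid_file(self, tmp_path):
        nodes = pd.DataFrame({"layer": ["genus"], "size_ratio": [1.0]}, index=["g1"])
        net = OmicsNetwork(nodes, pd.DataFrame(
            columns=["source", "target", "sign", "coefficient", "p", "p_adj"]))
        write_network(net, tmp_path / "empty")
        back = read_network(tmp_path / "empty")
        assert len(back.edges) == 0

    def test_self_edge_rejected(self):
        nodes = pd.DataFrame({"layer": ["genus"]}, index=["g1"])
        edges = pd.DataFrame([{"source": "g1", "target": "g1", "sign": 1,
                               "coefficient": 1.0, "p": 0.0, "p_adj": 0.0}])
        with pytest.raises(ValueError):
            OmicsNetwork(nodes, edges)
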