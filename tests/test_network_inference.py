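import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from milknet import (
    FeatureTable,
    SignedCorrelationNetwork,
    build_dmn,
    build_network,
    build_sin,
    filter_low_total,
    generate_metabolite_table,
    generate_otu_table,
    pearson_with_p,
)
from milknet.network import UndefinedCorrelation, _corr_matrix


def table_from(rows: dict, samples=None, kind="otu") -> FeatureTable:
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    if samples:
        df.columns = samples
    else:
        df.columns = [f"S{i+1}" for i in range(df.shape[1])]
    return FeatureTable(df, feature_kind=kind)


class TestFilterLowTotal:
    def test_boundary_total_equal_threshold_kept(self):
        t = table_from({"A": [2, 3], "B": [2, 2], "C": [50, 50]})
        kept = filter_low_total(t, min_total=5)
        assert kept.feature_ids == ["A", "C"]

    def test_all_below_threshold_warns_and_empties(self):
        t = table_from({"A": [1, 0], "B": [0, 1]})
        with pytest.warns(UserWarning, match="below min_total"):
            out = filter_low_total(t, min_total=5)
        assert out.shape[0] == 0

    def test_zero_threshold_is_identity(self):
        t = table_from({"A": [1, 0], "B": [0, 1]})
        assert filter_low_total(t, min_total=0).feature_ids == ["A", "B"]

    def test_non_integer_otu_counts_warn(self):
        t = table_from({"A": [1.5, 2.5], "B": [9, 9]})
        with pytest.warns(UserWarning, match="non-integer"):
            filter_low_total(t, min_total=1)


class TestPearsonWithP:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_closed_form_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        # independent high-precision evaluation of the closed forms
        xd, yd = x - x.mean(), y - y.mean()
        r_expected = float(np.sum(xd * yd) / math.sqrt(np.sum(xd**2) * np.sum(yd**2)))
        t_stat = r_expected * math.sqrt((len(x) - 2) / (1 - r_expected**2))
        # survival function of Student's t with 2 df has the closed form
        # P(T > t) = (1 - t / sqrt(2 + t^2)) / 2
        p_expected = 1.0 - t_stat / math.sqrt(2 + t_stat**2)
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(r_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-10)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedCorrelation):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_with_p([1.0, 2.0], [2.0, 1.0])

    def test_vectorized_path_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        A = rng.gamma(2.0, size=(6, 12))
        r_mat, p_mat = _corr_matrix(A, A)
        for i in range(6):
            for j in range(i + 1, 6):
                r, p = pearson_with_p(A[i], A[j])
                assert r_mat[i, j] == pytest.approx(r, rel=1e-9)
                assert p_mat[i, j] == pytest.approx(p, rel=1e-6)


class TestBuildNetwork:
    def test_planted_shared_factor_recovered_positive(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal(100)
        t = table_from(
            {"A": 10 + f, "B": 5 + f + 0.1 * rng.standard_normal(100),
             "C": rng.gamma(2.0, size=100) + 5}
        )
        net = build_network(t)
        assert net.has_edge("A", "B")
        assert net.edges["A", "B"]["sign"] == "pos"

    def test_constant_feature_has_no_edges_but_stays_a_node(self):
        t = table_from({"A": [1, 2, 3, 4], "B": [2, 4, 6, 8], "K": [7, 7, 7, 7]})
        net = build_network(t)
        assert "K" in net and net.degree("K") == 0

    def test_alpha_one_gives_all_pairs(self):
        rng = np.random.default_rng(1)
        t = table_from({f"F{i}": rng.gamma(2.0, size=8) for i in range(5)})
        net = build_network(t, alpha=1.0)
        assert net.number_of_edges() == 5 * 4 // 2

    def test_edge_set_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        t = table_from({f"F{i}": rng.gamma(2.0, size=10) for i in range(12)})
        tight = set(build_network(t, alpha=0.01).edges)
        loose = set(build_network(t, alpha=0.05).edges)
        assert tight <= loose

    def test_cross_mode_symmetric_in_input_order(self):
        rng = np.random.default_rng(4)
        ta = table_from({f"A{i}": rng.gamma(2.0, size=15) for i in range(4)})
        tb = table_from({f"B{i}": rng.gamma(2.0, size=15) for i in range(3)}, kind="metabolite")
        n1 = build_network(ta, tb, alpha=0.3)
        n2 = build_network(tb, ta, alpha=0.3)
        assert {frozenset(e) for e in n1.edges} == {frozenset(e) for e in n2.edges}
        for a, b in n1.edges:
            assert n1.edges[a, b]["r"] == pytest.approx(n2.edges[a, b]["r"])

    def test_cross_mode_drops_isolated_nodes(self):
        ta = table_from({"A": [1.0, 2.0, 3.0, 4.0, 5.0]})
        tb = table_from(
            {"hit": [2.0, 4.0, 6.0, 8.0, 10.0],
             "noise": [5.0, 1.0, 4.0, 2.0, 4.5]},
            kind="metabolite",
        )
        net = build_network(ta, tb, alpha=0.01)
        assert set(net.nodes) == {"A", "hit"}

    def test_too_few_shared_samples(self):
        ta = table_from({"A": [1, 2, 3]}, samples=["x", "y", "z"])
        tb = table_from({"B": [1, 2, 3]}, samples=["x", "y", "w"])
        with pytest.raises(ValueError, match="shared samples"):
            build_network(ta, tb)

    def test_retained_edges_satisfy_invariants(self):
        rng = np.random.default_rng(5)
        t = table_from({f"F{i}": rng.gamma(2.0, size=9) for i in range(15)})
        net = build_network(t, alpha=0.05)
        for a, b, attrs in net.edges(data=True):
            assert a != b
            assert attrs["p"] <= 0.05
            assert attrs["r"] != 0
            assert attrs["sign"] == ("pos" if attrs["r"] > 0 else "neg")

    def test_fdr_flag_never_adds_edges(self):
        rng = np.random.default_rng(6)
        t = table_from({f"F{i}": rng.gamma(2.0, size=10) for i in range(10)})
        raw = set(build_network(t, alpha=0.05).edges)
        corrected = set(build_network(t, alpha=0.05, fdr=True).edges)
        assert corrected <= raw


class TestBuildDMN:
    def _otu_table(self, n=30, seed=0):
        table, _ = generate_otu_table(n, 25, seed=seed)
        return table

    def test_noiseless_positive_metabolite_links_to_q1(self):
        from milknet.network import diversity_feature_table

        otu = self._otu_table()
        div = diversity_feature_table(otu)
        q1 = div.data.loc["q1"].to_numpy()
        met = table_from({"M": 2 * q1}, samples=otu.sample_ids, kind="metabolite")
        net = build_dmn(otu, met)
        assert net.has_edge("q1", "M") and net.edges["q1", "M"]["sign"] == "pos"

    def test_noiseless_negative_metabolite_links_to_q2(self):
        from milknet.network import diversity_feature_table

        otu = self._otu_table(seed=1)
        div = diversity_feature_table(otu)
        q2 = div.data.loc["q2"].to_numpy()
        met = table_from({"M": q2.max() + 1 - q2}, samples=otu.sample_ids, kind="metabolite")
        net = build_dmn(otu, met)
        assert net.has_edge("q2", "M") and net.edges["q2", "M"]["sign"] == "neg"

    def test_diversity_nodes_labeled_by_order(self):
        rng = np.random.default_rng(2)
        otu, _ = generate_otu_table(30, 25, seed=rng)
        met = generate_metabolite_table(otu, seed=rng)
        net = build_dmn(otu, met)
        div_nodes = {n for n, d in net.nodes(data=True) if d["kind"] == "diversity_order"}
        assert div_nodes <= {"q0", "q1", "q2", "q3", "q4"}
        assert len(div_nodes) > 0

    def test_generator_partition_recovered(self):
        rng = np.random.default_rng(11)
        otu, _ = generate_otu_table(100, 60, seed=rng)
        met = generate_metabolite_table(otu, seed=rng)
        net = build_dmn(otu, met)
        pos_only = {
            n for n, d in net.nodes(data=True)
            if d["kind"] == "metabolite"
            and {net.edges[n, v]["sign"] for v in net.neighbors(n)} == {"pos"}
        }
        neg_only = {
            n for n, d in net.nodes(data=True)
            if d["kind"] == "metabolite"
            and {net.edges[n, v]["sign"] for v in net.neighbors(n)} == {"neg"}
        }
        assert {"DHA", "Inositol", "Threitol", "PUFA"} <= pos_only
        assert {"Butanal", "Xlmonopalmitin", "Decanoic_acid", "Arabinose",
                "Myristic_acid"} <= neg_only


class TestSignedCorrelationNetworkEstimator:
    def test_fit_array_matches_functional_build(self):
        rng = np.random.default_rng(9)
        X = rng.gamma(2.0, size=(12, 6))  # samples x features
        est = SignedCorrelationNetwork(alpha=0.2).fit(X)
        df = pd.DataFrame(
            X.T, index=[f"f{i}" for i in range(6)], columns=[f"s{j}" for j in range(12)]
        )
        direct = build_network(FeatureTable(df), alpha=0.2)
        assert set(est.network_.edges) == set(direct.edges)

    def test_dataframe_feature_names_used(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.gamma(2.0, size=(10, 3)), columns=["a", "b", "c"])
        net = SignedCorrelationNetwork(alpha=1.0).fit_network(X)
        assert set(net.nodes) == {"a", "b", "c"}

    def test_min_total_filter_applies(self):
        X = np.array([[1, 100], [0, 120], [1, 90], [0, 110]], dtype=float)
        est = SignedCorrelationNetwork(alpha=1.0, min_total=5).fit(X)
        assert est.n_features_in_ == 1

    def test_get_set_params_round_trip(self):
        est = SignedCorrelationNetwork(alpha=0.01, fdr=True, min_total=5)
        assert est.get_params() == {"alpha": 0.01, "fdr": True, "min_total": 5}


def test_sin_pipeline_on_group_subsets(milk_scenario):
    otu = milk_scenario["otu_table"]
    groups = milk_scenario["groups"]
    for label, members in groups.groups().items():
        net = build_sin(otu.subset_samples(members))
        assert net.number_of_nodes() > 0
        kinds = {d["kind"] for _, d in net.nodes(data=True)}
        assert kinds == {"otu"}
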