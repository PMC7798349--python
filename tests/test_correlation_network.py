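import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bbrnet.core_tables import FeatureAnnotation, FeatureTable, SampleMetadata
from bbrnet.correlation_network import (
    all_pairs,
    build_network,
    spearman_pvalue,
    spearman_rho,
    subnetwork,
    topology_metrics,
    write_edge_list,
    write_graphml,
    write_sif,
)


class TestSpearmanRho:
    def test_monotone_increasing_is_one(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 25, 100]) == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_value_closed_form(self):
        # d = (1,-1,1,-1,1,-1), sum d^2 = 6 -> 1 - 36/210
        assert spearman_rho(
            [1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5]
        ) == pytest.approx(1 - 36 / 210)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(25):
            x = rng.integers(0, 4, size=8).astype(float)
            y = rng.integers(0, 4, size=8).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman_rho(x, y) == pytest.approx(
                sps.spearmanr(x, y).statistic
            )

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])


def _oracle_exact_p(x, y):
    """Brute force over all n! permutations with scipy-ranked rho."""

    def rho(a, bb):
        return np.corrcoef(sps.rankdata(a), sps.rankdata(bb))[0, 1]

    obs = abs(rho(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        if abs(rho(x, perm)) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestSpearmanPvalue:
    def test_perfect_monotone_n6(self):
        p = spearman_pvalue(np.arange(6), np.arange(6) * 2.0, method="exact")
        assert p == pytest.approx(2 / 720)  # identity and reversal only

    @pytest.mark.parametrize("trial", range(10))
    def test_exact_equals_enumeration_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 8))
        if trial % 2:
            x = rng.integers(0, n - 1, size=n).astype(float)
            y = rng.integers(0, n - 1, size=n).astype(float)
        else:
            x = rng.normal(size=n)
            y = rng.normal(size=n)
        if np.all(x == x[0]) or np.all(y == y[0]):
            pytest.skip("degenerate draw")
        assert spearman_pvalue(x, y, "exact") == pytest.approx(_oracle_exact_p(x, y))

    def test_p_bounded(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=6)
        p = spearman_pvalue(x, y, "exact")
        assert 1 / 720 <= p <= 1.0

    def test_exact_refuses_large_n(self, rng):
        with pytest.raises(ValueError, match="t_approx"):
            spearman_pvalue(rng.normal(size=10), rng.normal(size=10), "exact")

    def test_t_approx_matches_scipy(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        p = spearman_pvalue(x, y, "t_approx")
        assert p == pytest.approx(sps.spearmanr(x, y).pvalue, rel=1e-6)


def _feature_table(rng, n_features=10, n_samples=12):
    ids = [f"f{i:02d}" for i in range(n_features)]
    values = pd.DataFrame(
        rng.uniform(0, 5, size=(n_samples, n_features)),
        index=[f"C{i}" for i in range(6)] + [f"B{i}" for i in range(6)],
        columns=ids,
    )
    feats = [FeatureAnnotation(i, "bile_acid", "cecum") for i in ids]
    meta = [SampleMetadata(f"C{i}", "control", "M") for i in range(6)] + [
        SampleMetadata(f"B{i}", "berberine", "F") for i in range(6)
    ]
    return FeatureTable(values, feats, meta)


class TestAllPairs:
    def test_pair_count_is_binomial_coefficient(self, rng):
        rec = all_pairs(_feature_table(rng, 10), "control")
        assert len(rec) == 45
        rec21 = all_pairs(_feature_table(rng, 21), "berberine")
        assert len(rec21) == 210

    def test_results_independent_of_feature_order(self, rng):
        t = _feature_table(rng, 8)
        shuffled = FeatureTable(
            t.values[t.feature_ids[::-1]],
            list(reversed(t.features)),
            t.samples,
        )
        a = all_pairs(t, "control")
        bb = all_pairs(shuffled, "control")
        pd.testing.assert_frame_equal(a, bb)

    def test_canonical_ordering_and_symmetry(self, rng):
        rec = all_pairs(_feature_table(rng, 6), "control")
        assert (rec["feature_i"] < rec["feature_j"]).all()
        # each unordered pair appears exactly once
        assert not rec.duplicated(["feature_i", "feature_j"]).any()

    def test_constant_feature_skipped_with_warning(self, rng):
        t = _feature_table(rng, 5)
        t.values["f00"] = 1.0
        with pytest.warns(UserWarning, match="f00"):
            rec = all_pairs(t, "control")
        assert len(rec) == 6  # C(4,2)
        assert "f00" not in set(rec["feature_i"]) | set(rec["feature_j"])

    def test_exact_p_agrees_with_scalar_path(self, rng):
        t = _feature_table(rng, 6)
        # inject ties so both fast and fallback paths are exercised
        t.values.iloc[:4, 0] = 2.0
        with np.errstate(all="ignore"):
            rec = all_pairs(t, "berberine")
        sub = t.group_values("berberine")
        for row in rec.itertuples(index=False):
            expected = spearman_pvalue(
                sub[row.feature_i].to_numpy(), sub[row.feature_j].to_numpy(), "exact"
            )
            assert row.p == pytest.approx(expected), (row.feature_i, row.feature_j)


def _records(rows):
    return pd.DataFrame(
        rows, columns=["feature_i", "feature_j", "rho", "n", "p", "group"]
    )


class TestBuildNetwork:
    def test_threshold_semantics(self):
        rec = _records(
            [
                ("a", "b", 0.65, 6, 0.001, "control"),  # fails rho gate
                ("a", "c", 0.95, 6, 0.04, "control"),  # passes
                ("b", "c", -0.9, 6, 0.01, "control"),  # negative edge kept
                ("c", "d", 0.9, 6, 0.06, "control"),  # fails p gate
            ]
        )
        g = build_network(rec, 0.7, 0.05)
        assert set(map(frozenset, g.edges())) == {
            frozenset({"a", "c"}),
            frozenset({"b", "c"}),
        }
        assert g.edges["b", "c"]["sign"] == -1

    def test_empty_records_empty_graph(self):
        g = build_network(_records([]), 0.7, 0.05)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_filtering_is_monotone(self, rng):
        rows = [
            (f"x{i}", f"y{i}", rng.uniform(-1, 1), 6, rng.uniform(0, 1), "control")
            for i in range(200)
        ]
        rec = _records(rows)
        base = set(build_network(rec, 0.5, 0.2).edges())
        tighter_rho = set(build_network(rec, 0.8, 0.2).edges())
        tighter_p = set(build_network(rec, 0.5, 0.05).edges())
        assert tighter_rho <= base
        assert tighter_p <= base


class TestTopologyAndSubnetwork:
    def test_empty_graph_all_zero(self):
        m = topology_metrics(nx.Graph())
        assert m["n_nodes"] == m["n_edges"] == m["n_components"] == 0
        assert m["cross_type_edges"] == 0

    def test_complete_graph_density_one(self):
        m = topology_metrics(nx.complete_graph(4))
        assert m["density"] == pytest.approx(1.0)
        assert m["n_components"] == 1

    def test_handshake_lemma(self, rng):
        g = nx.gnp_random_graph(15, 0.3, seed=1)
        m = topology_metrics(g)
        assert sum(m["degree"].values()) == 2 * m["n_edges"]

    def test_cross_type_edges_counted(self):
        g = nx.Graph()
        g.add_node("gene", feature_type="transcript")
        g.add_node("DCA", feature_type="bile_acid")
        g.add_node("gene2", feature_type="transcript")
        g.add_edge("gene", "DCA")
        g.add_edge("gene", "gene2")
        assert topology_metrics(g)["cross_type_edges"] == 1

    def test_subnetwork_radius_zero_single_node(self):
        g = nx.path_graph(5)
        sub = subnetwork(g, 2, radius=0)
        assert set(sub.nodes()) == {2} and sub.number_of_edges() == 0

    def test_star_radius_one_is_full_star(self):
        g = nx.star_graph(6)
        sub = subnetwork(g, 0, radius=1)
        assert sub.number_of_nodes() == 7 and sub.number_of_edges() == 6

    def test_radius_at_least_diameter_recovers_component(self):
        g = nx.path_graph(5)
        g.add_edge("iso1", "iso2")
        sub = subnetwork(g, 0, radius=10)
        assert set(sub.nodes()) == {0, 1, 2, 3, 4}

    def test_missing_focal_raises(self):
        with pytest.raises(KeyError, match="missing"):
            subnetwork(nx.path_graph(3), "missing")


class TestExports:
    def test_graphml_round_trip_attributes(self, tmp_path, rng):
        rec = _records([("a", "b", 0.9, 6, 0.01, "control")])
        ann = [
            FeatureAnnotation("a", "bile_acid", "cecum"),
            FeatureAnnotation("b", "transcript", "cecum", "Blautia producta"),
        ]
        g = build_network(rec, 0.7, 0.05, annotations=ann)
        write_graphml(g, tmp_path / "g.graphml")
        g2 = nx.read_graphml(tmp_path / "g.graphml")
        assert g2.nodes["b"]["species"] == "Blautia producta"
        assert g2.edges["a", "b"]["rho"] == pytest.approx(0.9)

    def test_sif_contains_signed_interactions(self, tmp_path):
        rec = _records(
            [("a", "b", 0.9, 6, 0.01, "control"),
             ("a", "c", -0.8, 6, 0.02, "control")]
        )
        g = build_network(rec, 0.7, 0.05)
        write_sif(g, tmp_path / "g.sif")
        lines = (tmp_path / "g.sif").read_text().strip().splitlines()
        assert sorted(line.split("\t")[1] for line in lines) == ["neg", "pos"]

    def test_edge_list_round_trip(self, tmp_path):
        rec = _records([("a", "b", 0.9, 6, 0.01, "control")])
        write_edge_list(rec, tmp_path / "e.tsv")
        back = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert back.loc[0, "rho"] == pytest.approx(0.9)
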