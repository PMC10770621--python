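"""Reliability-weighted shortest paths, prioritization and comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from heartomics import phenotype as phen
from heartomics.io import CausalEdges

from conftest import min_dpath_by_enumeration


def causal_net(rows, phenotypes=("P",)):
    """rows: (source, target, effect_sign, reliability)."""
    df = pd.DataFrame(
        [
            (s, t, "up-regulates" if sign > 0 else "down-regulates", r)
            for s, t, sign, r in rows
        ],
        columns=["source", "target", "effect", "reliability"],
    )
    return phen.CausalNetwork.from_edges(
        CausalEdges(data=df, phenotype_nodes=list(phenotypes))
    )


class TestStepDistance:
    @pytest.mark.parametrize("r,d", [(1.0, 0.0), (0.7, 0.3), (0.25, 0.75)])
    def test_printed_formula(self, r, d):
        assert phen.step_distance(r) == pytest.approx(d)

    @pytest.mark.parametrize("r", [0.0, -0.2, 1.2])
    def test_domain(self, r):
        with pytest.raises(ValueError):
            phen.step_distance(r)


class TestShortestPath:
    def test_chain_sums_step_distances(self):
        net = causal_net([("A", "B", 1, 0.7), ("B", "P", 1, 0.8)])
        res = phen.shortest_path(net, "A", "P")
        assert res.dpath == pytest.approx(0.5)
        assert res.n_steps == 2
        assert res.path == ("A", "B", "P")

    def test_two_step_route_beats_direct_edge(self):
        net = causal_net(
            [("A", "P", 1, 0.5), ("A", "B", 1, 0.9), ("B", "P", 1, 0.9)]
        )
        res = phen.shortest_path(net, "A", "P")
        assert res.dpath == pytest.approx(0.2)
        assert res.path == ("A", "B", "P")

    def test_net_sign_is_product_of_step_signs(self):
        net = causal_net([("A", "B", 1, 0.9), ("B", "P", -1, 0.9)])
        assert phen.shortest_path(net, "A", "P").net_sign == -1
        net2 = causal_net([("A", "B", -1, 0.9), ("B", "P", -1, 0.9)])
        assert phen.shortest_path(net2, "A", "P").net_sign == 1

    def test_direction_respected(self):
        net = causal_net([("P", "A", 1, 0.9)])
        assert not phen.shortest_path(net, "A", "P").reachable

    def test_source_equals_phenotype(self):
        net = causal_net([("A", "P", 1, 0.9)])
        res = phen.shortest_path(net, "P", "P")
        assert res.dpath == 0.0 and res.path == ()

    def test_dpath_zero_iff_all_perfect_reliability(self):
        net = causal_net([("A", "B", 1, 1.0), ("B", "P", 1, 1.0)])
        assert phen.shortest_path(net, "A", "P").dpath == 0.0
        net2 = causal_net([("A", "B", 1, 1.0), ("B", "P", 1, 0.999)])
        assert phen.shortest_path(net2, "A", "P").dpath > 0.0

    def test_tie_breaks_fewer_steps_then_lexicographic(self):
        # two routes with equal Dpath 0.2: direct (1 step) wins
        net = causal_net([("A", "P", 1, 0.8), ("A", "B", 1, 0.9), ("B", "P", 1, 0.9)])
        assert phen.shortest_path(net, "A", "P").path == ("A", "P")
        # equal Dpath and equal steps: lexicographically smaller intermediate
        net2 = causal_net(
            [("A", "B", 1, 0.9), ("B", "P", 1, 0.9), ("A", "C", 1, 0.9), ("C", "P", 1, 0.9)]
        )
        assert phen.shortest_path(net2, "A", "P").path == ("A", "B", "P")

    def test_missing_node_rejected(self):
        net = causal_net([("A", "P", 1, 0.9)])
        with pytest.raises(KeyError):
            phen.shortest_path(net, "Z", "P")

    def test_matches_exhaustive_enumeration_on_random_digraphs(self):
        """Dijkstra with tie-breaks equals brute-force simple-path search."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(3, 9))
            nodes = [f"v{i}" for i in range(n)]
            rows, adj = [], {}
            for a, b in itertools.permutations(nodes, 2):
                if rng.random() < 0.25:
                    r = float(rng.uniform(0.5, 1.0))
                    rows.append((a, b, 1, r))
                    adj.setdefault(a, {})[b] = 1.0 - r
            if not rows:
                continue
            net = causal_net(rows, phenotypes=(nodes[-1],))
            present = [v for v in nodes[:-1] if v in net.nodes and nodes[-1] in net.nodes]
            for src in present:
                got = phen.shortest_path(net, src, nodes[-1])
                want = min_dpath_by_enumeration(adj, src, nodes[-1])
                if want is None:
                    assert not got.reachable
                else:
                    assert got.dpath == pytest.approx(want[0], abs=1e-9)
                    assert got.n_steps == want[1]

    def test_edge_addition_monotonicity(self):
        rows = [("A", "B", 1, 0.8), ("B", "P", 1, 0.8)]
        base = phen.shortest_path(causal_net(rows), "A", "P").dpath
        more = phen.shortest_path(
            causal_net(rows + [("A", "P", 1, 0.95)]), "A", "P"
        ).dpath
        assert more <= base

    def test_triangle_inequality(self):
        rng = np.random.default_rng(11)
        nodes = [f"v{i}" for i in range(7)]
        rows = [
            (a, b, 1, float(rng.uniform(0.5, 1.0)))
            for a, b in itertools.permutations(nodes, 2)
            if rng.random() < 0.4
        ]
        net = causal_net(rows, phenotypes=())
        for a, b, c in itertools.permutations(nodes, 3):
            d_ab = phen.shortest_path(net, a, b).dpath
            d_bc = phen.shortest_path(net, b, c).dpath
            d_ac = phen.shortest_path(net, a, c).dpath
            if math.isfinite(d_ab) and math.isfinite(d_bc):
                assert d_ac <= d_ab + d_bc + 1e-9


class TestDistanceMatrix:
    def test_single_edge(self):
        net = causal_net([("A", "P", 1, 0.9)])
        mat = phen.distance_matrix(net, ["A"], ["P"])
        assert mat.loc["A", "P"] == pytest.approx(0.1)

    def test_closer_phenotype_has_smaller_mean(self):
        rows = []
        for i in range(5):
            rows += [(f"x{i}", "P1", 1, 0.95), (f"x{i}", "M", 1, 0.9), ("M", "P2", 1, 0.7)]
        net = causal_net(rows, phenotypes=("P1", "P2"))
        mat = phen.distance_matrix(net, [f"x{i}" for i in range(5)])
        means = phen.phenotype_means(mat)
        assert means["P1"] < means["P2"]
        assert list(means.index) == ["P1", "P2"]

    def test_absent_protein_gets_unreachable_row(self):
        net = causal_net([("A", "P", 1, 0.9)])
        mat = phen.distance_matrix(net, ["A", "ghost"], ["P"])
        assert math.isinf(mat.loc["ghost", "P"])
        assert phen.phenotype_means(mat)["P"] == pytest.approx(0.1)  # reachable only


class TestPrioritizeTargets:
    def _matrix(self):
        cols = [f"P{i}" for i in range(7)]
        inf = math.inf
        data = {
            "all7": [0.8] * 7,
            "all7slow": [1.2] * 7,
            "five": [0.5] * 5 + [inf, inf],
            "four": [0.5] * 4 + [inf, inf, inf],
        }
        m = pd.DataFrame.from_dict(data, orient="index", columns=cols)
        m.index.name = "protein"
        return m

    def test_threshold_rule(self):
        out = phen.prioritize_targets(self._matrix(), min_phenotypes=5)
        assert set(out["protein"]) == {"all7", "all7slow", "five"}

    def test_ordering_by_count_then_mean(self):
        out = phen.prioritize_targets(self._matrix(), min_phenotypes=5)
        assert out["protein"].tolist() == ["all7", "all7slow", "five"]

    def test_dmax_cap(self):
        out = phen.prioritize_targets(self._matrix(), min_phenotypes=5, dmax=0.6)
        assert set(out["protein"]) == {"five"}

    def test_row_order_invariance(self):
        m = self._matrix()
        shuffled = m.sample(frac=1.0, random_state=1)
        a = phen.prioritize_targets(m, min_phenotypes=4)
        b = phen.prioritize_targets(shuffled, min_phenotypes=4)
        pd.testing.assert_frame_equal(a, b)


class TestComparePhenotypes:
    def test_identical_distributions_not_significant(self):
        vals = np.linspace(0.5, 2.0, 20)
        m = pd.DataFrame({"A": vals, "B": vals})
        out = phen.compare_phenotypes(m)
        assert len(out) == 1
        assert out["mean_difference"].iloc[0] == pytest.approx(0.0)
        assert not out["significant"].iloc[0]

    def test_bonferroni_arithmetic_for_seven_phenotypes(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(1, 2, (10, 7)), columns=[f"P{i}" for i in range(7)])
        out = phen.compare_phenotypes(m)
        assert len(out) == 21
        assert (out["m"] == 21).all()
        assert (out["p_bonferroni"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_planted_shift_is_flagged(self):
        rng = np.random.default_rng(123)
        m = pd.DataFrame(
            {"A": 1.0 + rng.normal(0, 0.1, 30), "B": 2.0 + rng.normal(0, 0.1, 30)}
        )
        out = phen.compare_phenotypes(m)
        assert bool(out["significant"].iloc[0])
        lo, hi = out["ci95_low"].iloc[0], out["ci95_high"].iloc[0]
        assert lo < -0.9 and hi > -1.1  # CI brackets the true -1 shift

    def test_sparse_phenotype_pairs_skipped(self):
        inf = math.inf
        m = pd.DataFrame({"A": [0.5, 0.6, 0.7], "B": [0.4, inf, inf], "C": [0.5, 0.6, 0.9]})
        out = phen.compare_phenotypes(m)
        assert set(zip(out["phenotype_a"], out["phenotype_b"])) == {("A", "C")}

    def test_mannwhitney_option(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame({"A": rng.uniform(0, 1, 15), "B": rng.uniform(2, 3, 15)})
        out = phen.compare_phenotypes(m, method="mannwhitney")
        assert bool(out["significant"].iloc[0])


class TestCellTypeDistance:
    def test_single_protein_cell_type(self):
        m = pd.DataFrame({"P1": [0.4], "P2": [0.8]}, index=["prot"])
        out = phen.cell_type_distance(m, {"prot": "mast cells"})
        assert out.iloc[0]["mean_dpath"] == pytest.approx(0.6)

    def test_ranking_ascending(self):
        m = pd.DataFrame({"P": [1.0, 2.0, 2.0]}, index=["a", "b", "c"])
        out = phen.cell_type_distance(m, {"a": "fast", "b": "slow", "c": "slow"})
        assert out["cell_type"].tolist() == ["fast", "slow"]
        assert out["rank"].tolist() == [1, 2]

    def test_unassigned_protein_excluded(self):
        m = pd.DataFrame({"P": [1.0, 2.0]}, index=["a", "b"])
        out = phen.cell_type_distance(m, {"a": "ct"})
        assert out["n_proteins"].sum() == 1
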