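import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from togcn.core import (
    PCCMatrix,
    TOGCN,
    CoexpressionNetwork,
    assign_level_gene_sets,
    assign_levels_bfs,
    build_gcn,
    compute_pcc_matrix,
    determine_cutoff,
    mean_zscore_profile,
)
from togcn.expr_io import ExpressionMatrix


def _matrix(rows: dict[str, list[float]]) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    )


class TestComputePCC:
    def test_worked_example(self):
        # direct formula oracle: r = 10 / sqrt(148)
        m = _matrix({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 6]})
        p = compute_pcc_matrix(m)
        assert p.get("x", "y") == pytest.approx(10 / math.sqrt(148), abs=1e-12)

    def test_self_correlation_is_one(self, rng):
        m = _matrix({"x": list(rng.uniform(size=5))})
        p = compute_pcc_matrix(m)
        assert p.get("x", "x") == 1.0

    def test_antisymmetry(self):
        m = _matrix({"x": [1, 2, 5, 3, 4], "y": [9, 8, 5, 7, 6]})
        assert compute_pcc_matrix(m).get("x", "y") == pytest.approx(-1.0)

    def test_too_few_columns(self):
        m = _matrix({"x": [1, 2], "y": [2, 1]})
        with pytest.raises(ValueError, match=">= 3 samples"):
            compute_pcc_matrix(m)

    def test_unknown_gene(self):
        m = _matrix({"x": [1, 2, 3]})
        with pytest.raises(KeyError, match="zz"):
            compute_pcc_matrix(m, ["x", "zz"])

    def test_constant_gene_excluded(self):
        m = _matrix({"x": [1, 2, 3], "flat": [5, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            p = compute_pcc_matrix(m)
        assert p.gene_ids == ("x",)
        assert p.constant_genes == ("flat",)




class _PairMultiset:
    """Minimal stand-in exposing the interface determine_cutoff needs."""

    def __init__(self, values):
        self._values = np.asarray(values, dtype=float)
        self.gene_ids = ("a", "b", "c")

    def pairwise_values(self):
        return self._values


def _pcc_from_pairs(values: np.ndarray) -> PCCMatrix:
    """Build a PCCMatrix whose strict upper triangle holds `values`."""
    n_pairs = len(values)
    n = int((1 + math.isqrt(1 + 8 * n_pairs)) // 2)
    assert n * (n - 1) // 2 == n_pairs
    mat = np.eye(n)
    iu = np.triu_indices(n, 1)
    mat[iu] = values
    mat[(iu[1], iu[0])] = values
    return PCCMatrix(tuple(f"g{i}" for i in range(n)), mat)


class TestDetermineCutoff:
    def test_worked_example_hundred_values(self):
        # 100 pair values 0.00..0.99; rank ceil(0.95*100)=95 -> 0.94 by sort
        vals = np.round(np.arange(100) / 100.0, 2)
        p = _PairMultiset(np.random.default_rng(0).permutation(vals))
        assert determine_cutoff(p, alpha=0.05) == pytest.approx(0.94)

    def test_degenerate_all_equal(self):
        p = _pcc_from_pairs(np.full(6, 0.37))
        assert determine_cutoff(p) == pytest.approx(0.37)

    def test_single_pair(self):
        p = _pcc_from_pairs(np.array([0.5]))
        assert determine_cutoff(p, alpha=0.05) == pytest.approx(0.5)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 2.0])
    def test_alpha_domain(self, alpha):
        p = _pcc_from_pairs(np.array([0.5]))
        with pytest.raises(ValueError):
            determine_cutoff(p, alpha=alpha)

    def test_member_and_exceedance_properties(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 20))
            vals = rng.uniform(-1, 1, size=n * (n - 1) // 2)
            p = _pcc_from_pairs(vals)
            cut = determine_cutoff(p, alpha=0.05)
            assert cut in vals
            assert (vals > cut).mean() <= 0.05


class TestBuildGCN:
    def test_threshold_by_hand(self):
        mat = np.array([[1.0, 0.95, 0.5], [0.95, 1.0, 0.91], [0.5, 0.91, 1.0]])
        p = PCCMatrix(("A", "B", "C"), mat)
        g = build_gcn(p, 0.9)
        assert sorted(tuple(sorted(e)) for e in g.edges) == [("A", "B"), ("B", "C")]

    def test_cutoff_above_max_gives_empty_graph(self):
        p = _pcc_from_pairs(np.array([0.1, 0.2, 0.3]))
        g = build_gcn(p, 0.99)
        assert len(g.edges) == 0
        assert len(g.isolated_nodes()) == 3

    def test_cutoff_below_min_gives_complete_graph(self):
        p = _pcc_from_pairs(np.array([0.5, 0.6, 0.7]))
        g = build_gcn(p, 0.1)
        assert len(g.edges) == 3

    def test_monotone_in_cutoff(self, rng):
        vals = rng.uniform(-1, 1, size=45)
        p = _pcc_from_pairs(vals)
        e_low = set(map(frozenset, build_gcn(p, 0.3).edges))
        e_high = set(map(frozenset, build_gcn(p, 0.6).edges))
        assert e_high <= e_low


def _net(edges, nodes=()) -> CoexpressionNetwork:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_weighted_edges_from((a, b, 1.0) for a, b in edges)
    return CoexpressionNetwork(g, 0.9)


class TestAssignLevelsBFS:
    def test_path_graph(self):
        t = assign_levels_bfs(_net([("A", "B"), ("B", "C"), ("C", "D")]), "A")
        assert t.levels == {"A": 1, "B": 1, "C": 2, "D": 3}
        assert t.n_levels == 3

    def test_star_all_level_one(self):
        t = assign_levels_bfs(_net([("hub", x) for x in "abcd"]), "hub")
        assert set(t.levels.values()) == {1}

    def test_isolated_seed(self):
        with pytest.warns(UserWarning, match="isolated"):
            t = assign_levels_bfs(_net([("A", "B")], nodes=["S"]), "S")
        assert t.levels == {"S": 1}
        assert t.unreached == {"A", "B"}

    def test_missing_seed(self):
        with pytest.raises(KeyError):
            assign_levels_bfs(_net([("A", "B")]), "Z")

    def test_agrees_with_shortest_path_oracle(self, rng):
        import warnings

        for _ in range(40):
            n = int(rng.integers(2, 40))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1 << 30)))
            net = CoexpressionNetwork(g, 0.5)
            seed = 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # isolated seeds are fine here
                t = assign_levels_bfs(net, seed)
            oracle = nx.single_source_shortest_path_length(g, seed)
            assert t.levels == {v: max(1, d) for v, d in oracle.items()}
            assert t.unreached == set(g.nodes) - set(oracle)

    def test_invariant_to_input_order(self, rng):
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("B", "D"), ("D", "E")]
        t1 = assign_levels_bfs(_net(edges), "A")
        t2 = assign_levels_bfs(_net(list(reversed(edges))), "A")
        assert t1.levels == t2.levels


class TestLevelGeneSets:
    def _togcn(self, levels: dict[str, int]) -> TOGCN:
        g = nx.Graph()
        g.add_nodes_from(levels)
        return TOGCN(CoexpressionNetwork(g, 0.9), next(iter(levels)), levels, frozenset())

    def test_identical_profile_joins_level(self):
        m = _matrix({"tf3": [1, 2, 9, 2, 1], "gene": [2, 4, 18, 4, 2]})
        sets = assign_level_gene_sets(m, self._togcn({"tf3": 3}), 0.9, ["gene"])
        assert sets[3] == {"gene"}

    def test_multi_level_membership(self):
        m = _matrix(
            {
                "tf2": [1, 5, 9, 5, 1],
                "tf3": [1, 4, 9, 6, 1],
                "gene": [1, 4.5, 9, 5.5, 1],
            }
        )
        togcn = self._togcn({"tf2": 2, "tf3": 3})
        sets = assign_level_gene_sets(m, togcn, 0.95, ["gene"])
        assert sets[2] == {"gene"} and sets[3] == {"gene"}

    def test_below_cutoff_member_of_no_set(self):
        m = _matrix({"tf1": [1, 2, 3, 4, 5], "gene": [5, 1, 4, 2, 3]})
        sets = assign_level_gene_sets(m, self._togcn({"tf1": 1}), 0.9, ["gene"])
        assert all(not s for s in sets.values())

    def test_empty_candidates_warn(self):
        m = _matrix({"tf1": [1, 2, 3]})
        with pytest.warns(UserWarning, match="empty candidate"):
            sets = assign_level_gene_sets(m, self._togcn({"tf1": 1}), 0.9, [])
        assert sets == {1: set()}

    def test_members_pass_cutoff_with_some_level_tf(self, rng):
        genes = {f"tf{i}": list(rng.uniform(size=5)) for i in range(4)}
        genes |= {f"c{i}": list(rng.uniform(size=5)) for i in range(10)}
        m = _matrix(genes)
        togcn = self._togcn({f"tf{i}": 1 + i % 2 for i in range(4)})
        cutoff = 0.5
        sets = assign_level_gene_sets(m, togcn, cutoff, [f"c{i}" for i in range(10)])
        p = compute_pcc_matrix(m)
        for lv, members in sets.items():
            tfs = [g for g, l in togcn.levels.items() if l == lv]
            for g in members:
                assert max(p.get(g, tf) for tf in tfs) >= cutoff


class TestMeanZscoreProfile:
    def _togcn(self, levels):
        g = nx.Graph()
        g.add_nodes_from(levels)
        return TOGCN(CoexpressionNetwork(g, 0.9), next(iter(levels)), levels, frozenset())

    def test_opposed_pair_cancels(self):
        m = _matrix({"up": [0, 2], "down": [2, 0]})
        prof = mean_zscore_profile(m, self._togcn({"up": 1, "down": 1}))
        assert np.allclose(prof.loc[1], [0.0, 0.0])

    def test_single_tf_level_is_own_zscore(self):
        m = _matrix({"tf": [1.0, 2.0, 6.0]})
        prof = mean_zscore_profile(m, self._togcn({"tf": 1}))
        x = np.array([1.0, 2.0, 6.0])
        z = (x - x.mean()) / x.std()
        assert np.allclose(prof.loc[1], z)
        assert prof.loc[1].mean() == pytest.approx(0, abs=1e-9)
        assert np.std(prof.loc[1]) == pytest.approx(1, abs=1e-9)

    def test_constant_tf_excluded(self):
        m = _matrix({"flat": [10, 10, 10, 10, 10], "tf": [1, 2, 3, 4, 9]})
        with pytest.warns(UserWarning, match="flat"):
            prof = mean_zscore_profile(m, self._togcn({"flat": 1, "tf": 1}))
        z = mean_zscore_profile(m, self._togcn({"tf": 1}))
        assert np.allclose(prof.loc[1], z.loc[1])
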