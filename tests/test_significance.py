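"""Null models, randomizations and p-value rules."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from pathmotifs import (
    CauseEffectNetwork,
    IntegratedNetwork,
    PathType,
    PhysicalLayer,
    build_projection,
    degree_preserving_randomize,
    hypergeometric_reach_test,
    network_enrichment,
    per_cause_specificity,
    perturbation_enrichment,
    randomize_cause_effect,
)
from pathmotifs.significance import _result_from_null

from conftest import oracle_instances, random_cause_effect, random_small_network


class TestRandomizeCauseEffect:
    def test_forced_sample_is_identity(self):
        ce = CauseEffectNetwork({"TF1": {"a", "b", "c"}})
        out = randomize_cause_effect(ce, {"TF1", "a", "b", "c"}, seed=0)
        assert out.pairs["TF1"] == {"a", "b", "c"}

    def test_sizes_preserved(self):
        ce = CauseEffectNetwork({"TF1": {"a", "b"}, "TF2": {"c"}})
        universe = {f"u{i}" for i in range(20)} | {"TF1", "TF2", "a", "b", "c"}
        for seed in range(100):
            out = randomize_cause_effect(ce, universe, seed=seed)
            assert out.causes == ce.causes
            assert {c: len(s) for c, s in out.pairs.items()} == {"TF1": 2, "TF2": 1}
            assert all(c not in out.pairs[c] for c in out.causes)

    def test_uniform_selection_frequency(self):
        """Universe of 10, one target: each eligible gene drawn with
        frequency 1/9 within 3 standard errors over 10,000 draws."""
        ce = CauseEffectNetwork({"TF1": {"u1"}})
        universe = {"TF1"} | {f"u{i}" for i in range(1, 10)}
        rng = np.random.default_rng(123)
        freq: dict[str, int] = {}
        n = 10_000
        for _ in range(n):
            out = randomize_cause_effect(ce, universe, seed=rng)
            (g,) = out.pairs["TF1"]
            freq[g] = freq.get(g, 0) + 1
        p = 1 / 9
        se = math.sqrt(p * (1 - p) / n)
        for g in universe - {"TF1"}:
            assert abs(freq.get(g, 0) / n - p) < 3 * se

    def test_universe_too_small_names_cause(self):
        ce = CauseEffectNetwork({"TF1": {"a", "b"}})
        with pytest.raises(ValueError, match="TF1"):
            randomize_cause_effect(ce, {"TF1", "a"}, seed=0)


class TestPValueRules:
    def test_observed_four_uses_empirical_rule(self):
        null = np.array([0, 1, 2, 3, 4, 5, 0, 1, 2, 3])
        r = _result_from_null(PathType(("TRI",)), 4, null, "perturbation_randomization")
        assert r.rule == "empirical" and r.z is None
        assert r.p_value == pytest.approx(2 / 10)

    def test_observed_five_uses_z_rule(self):
        null = np.array([0, 1, 2, 3, 4, 5, 0, 1, 2, 3])
        r = _result_from_null(PathType(("TRI",)), 5, null, "perturbation_randomization")
        assert r.rule == "z" and r.z is not None

    def test_observed_at_null_mean_gives_half(self):
        null = np.array([4.0, 6.0] * 50)  # mean 5, sd > 0
        r = _result_from_null(PathType(("TRI",)), 5, null, "perturbation_randomization")
        assert r.p_value == pytest.approx(0.5)

    def test_degenerate_sd_falls_back_to_empirical(self):
        null = np.full(100, 7.0)
        r = _result_from_null(PathType(("TRI",)), 7, null, "perturbation_randomization")
        assert r.rule == "empirical"
        assert r.p_value == 1.0

    def test_empirical_zero_reported_at_resolution(self):
        null = np.zeros(100)
        r = _result_from_null(PathType(("TRI",)), 3, null, "perturbation_randomization")
        assert r.n_null_ge_observed == 0
        assert r.p_value == pytest.approx(1 / 100)


class TestPerturbationEnrichment:
    def test_seed_determinism(self, tiny_net):
        ce = CauseEffectNetwork({"TF1": {"g1", "g2"}})
        a = perturbation_enrichment(tiny_net, ce, PathType(("PPI", "TRI")),
                                    n_random=200, seed=5)
        b = perturbation_enrichment(tiny_net, ce, PathType(("PPI", "TRI")),
                                    n_random=200, seed=5)
        assert a == b

    def test_matches_explicit_randomization_distribution(self, tiny_net):
        """The vectorized null agrees with naive per-replicate
        randomize_cause_effect + count in distribution (same mean within
        Monte Carlo error)."""
        from pathmotifs import count_instances
        from pathmotifs.significance import resolve_universe

        ce = CauseEffectNetwork({"TF1": {"g1", "g2"}})
        pt = PathType(("PPI", "TRI"))
        universe = resolve_universe(tiny_net, ce, "union")
        rng = np.random.default_rng(0)
        naive = [
            count_instances(tiny_net, randomize_cause_effect(ce, universe, seed=rng), pt)
            for _ in range(400)
        ]
        r = perturbation_enrichment(tiny_net, ce, pt, n_random=400, seed=1)
        assert r.null_mean == pytest.approx(np.mean(naive), abs=0.25)

    def test_n_random_one_runs(self, tiny_net):
        ce = CauseEffectNetwork({"TF1": {"g1"}})
        r = perturbation_enrichment(tiny_net, ce, PathType(("TRI",)), n_random=1, seed=0)
        assert r.p_value == 1.0


class TestProjection:
    def test_multiplicity_collapses(self):
        ppi = PhysicalLayer("PPI", False, [("TF1", "a"), ("TF1", "b")])
        tri = PhysicalLayer("TRI", True, [("a", "g1"), ("b", "g1")])
        net = IntegratedNetwork([ppi, tri])
        proj = build_projection(net, ["TF1"], PathType(("PPI", "TRI")))
        assert set(proj.edges()) == {("TF1", "g1")}

    def test_no_instances_empty(self, tiny_net):
        proj = build_projection(tiny_net, ["g3"], PathType(("PPI", "TRI")))
        assert proj.number_of_edges() == 0

    def test_edges_equal_oracle_positive_pairs(self):
        rng = np.random.default_rng(21)
        net = random_small_network(rng, 8)
        genes = sorted(net.node_universe)
        causes = genes[:3]
        for pt in [PathType(("TRI",)), PathType(("PPI", "TRI")), PathType(("PhI", "PPI"))]:
            proj = build_projection(net, causes, pt)
            exp = {
                (c, g)
                for c in causes
                for g in genes
                if g != c and oracle_instances(net, (c, g), pt)
            }
            assert set(proj.edges()) == exp


class TestDegreePreservingRandomize:
    def test_single_edge_unchanged(self):
        g = nx.DiGraph([("a", "b")])
        out = degree_preserving_randomize(g, seed=0)
        assert set(out.edges()) == {("a", "b")}

    def test_degree_sequences_preserved(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            g = nx.gnp_random_graph(12, 0.25, directed=True,
                                    seed=int(rng.integers(2**31)))
            if g.number_of_edges() < 2:
                continue
            out = degree_preserving_randomize(g, seed=int(rng.integers(2**31)))
            assert sorted(d for _, d in out.in_degree()) == \
                sorted(d for _, d in g.in_degree())
            assert sorted(d for _, d in out.out_degree()) == \
                sorted(d for _, d in g.out_degree())
            assert out.number_of_edges() == g.number_of_edges()

    def test_complete_bipartite_is_frozen_but_terminates(self):
        g = nx.DiGraph([("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")])
        out = degree_preserving_randomize(g, seed=3)
        assert set(out.edges()) == set(g.edges())  # every swap is rejected
        assert dict(out.out_degree()) == dict(g.out_degree())

    def test_actually_randomizes(self):
        g = nx.DiGraph([(f"c{i}", f"t{j}") for i in range(4) for j in range(8)
                        if (i + j) % 2 == 0])
        outs = {tuple(sorted(degree_preserving_randomize(g, seed=s).edges()))
                for s in range(5)}
        assert len(outs) > 1


def test_swap_kernel_fallback_matches_compiled():
    """The pure-python swap kernel and the (optionally) compiled one
    are the same algorithm: identical output on identical proposals."""
    from pathmotifs.significance import _swap_chunk, _swap_chunk_python

    rng = np.random.default_rng(0)
    for _ in range(10):
        n_nodes, n_edges = 8, 12
        # distinct cause->target edges drawn from the 4x4 bipartite grid
        slots = rng.choice(16, size=n_edges, replace=False)
        src = (slots // 4).astype(np.int64)
        dst = (slots % 4 + 4).astype(np.int64)
        adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
        adj[src, dst] = True
        proposals = rng.integers(0, n_edges, size=(50, 2))
        s1, d1, a1 = src.copy(), dst.copy(), adj.copy()
        s2, d2, a2 = src.copy(), dst.copy(), adj.copy()
        r1 = _swap_chunk(s1, d1, a1, proposals, 20)
        r2 = _swap_chunk_python(s2, d2, a2, proposals, 20)
        assert r1 == r2
        assert (d1 == d2).all() and (a1 == a2).all()


class TestNetworkEnrichment:
    def _planted(self):
        ppi = PhysicalLayer("PPI", False, [(f"TF{i}", f"m{i}") for i in range(4)])
        tri = PhysicalLayer(
            "TRI", True,
            [(f"m{i}", f"t{i}{j}") for i in range(4) for j in range(4)],
        )
        return IntegratedNetwork([ppi, tri])

    def test_disjoint_pairs_not_significant(self):
        net = self._planted()
        ce = CauseEffectNetwork({f"TF{i}": {"zzz1", "zzz2"} for i in range(4)})
        r = network_enrichment(net, ce, PathType(("PPI", "TRI")), n_random=99, seed=0)
        assert r.observed == 0
        assert r.p_value >= 0.5

    def test_perfect_overlap_is_extreme(self):
        net = self._planted()
        ce = CauseEffectNetwork(
            {f"TF{i}": {f"t{i}{j}" for j in range(4)} for i in range(4)}
        )
        r = network_enrichment(net, ce, PathType(("PPI", "TRI")), n_random=99, seed=0)
        assert r.observed == 16
        assert r.n_null_ge_observed <= 1  # observed is (near) maximal
        assert r.p_value < 0.05

    def test_seed_determinism(self):
        net = self._planted()
        ce = CauseEffectNetwork({f"TF{i}": {f"t{i}0", "t11"} for i in range(4)})
        pt = PathType(("PPI", "TRI"))
        a = network_enrichment(net, ce, pt, n_random=50, seed=4)
        b = network_enrichment(net, ce, pt, n_random=50, seed=4)
        assert a == b


class TestHypergeometricReach:
    def test_closed_form_full_overlap(self):
        """|U|=10, |reach|=5, |effects|=5, overlap 5: p = 1/C(10,5)."""
        tri = PhysicalLayer("TRI", True, [("TF", f"r{i}") for i in range(5)])
        net = IntegratedNetwork([tri])
        universe = {f"r{i}" for i in range(5)} | {f"o{i}" for i in range(5)}
        p = hypergeometric_reach_test(net, "TF", {f"r{i}" for i in range(5)},
                                      PathType(("TRI",)), universe)
        assert p == pytest.approx(1 / math.comb(10, 5))

    def test_empty_reach_gives_one(self):
        tri = PhysicalLayer("TRI", True, [("a", "b")])
        net = IntegratedNetwork([tri])
        p = hypergeometric_reach_test(net, "zz", {"b"}, PathType(("TRI",)),
                                      {"a", "b", "c"})
        assert p == 1.0

    def test_effects_equal_universe_gives_one(self):
        tri = PhysicalLayer("TRI", True, [("TF", "a"), ("TF", "b")])
        net = IntegratedNetwork([tri])
        universe = {"a", "b", "c"}
        assert hypergeometric_reach_test(net, "TF", universe, PathType(("TRI",)),
                                         universe) == pytest.approx(1.0)

    def test_empty_universe_errors(self, tiny_net):
        with pytest.raises(ValueError):
            hypergeometric_reach_test(tiny_net, "TF1", set(), PathType(("TRI",)), set())


class TestPerCauseSpecificity:
    def test_direct_regulator_prefers_tri(self):
        tri = PhysicalLayer("TRI", True, [("TF", f"g{i}") for i in range(5)])
        ppi = PhysicalLayer("PPI", False, [("TF", "p"), ("p", "q")])
        net = IntegratedNetwork([tri, ppi])
        ce = CauseEffectNetwork({"TF": {f"g{i}" for i in range(5)}})
        types = [PathType(("TRI",)), PathType(("PPI",)), PathType(("PPI", "PPI"))]
        df = per_cause_specificity(net, ce, types)
        assert df.iloc[0]["path_type"] == "TRI"
        assert df.iloc[0]["n_explained"] == 5

    def test_absent_cause_all_ones(self, tiny_net):
        ce = CauseEffectNetwork({"ghost": {"g1"}})
        df = per_cause_specificity(tiny_net, ce, [PathType(("TRI",)),
                                                  PathType(("PPI", "TRI"))])
        assert (df["p_value"] == 1.0).all()
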