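"""Diversity-graph construction, compression, and graph statistics."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crossfeed.diversity_graph import (
    ByproductProfile,
    attribute_assortativity,
    binarize,
    build_graph,
    byproduct_profile,
    clustering_coefficient,
    compress,
    conservation_density,
    edge_weight,
    fast_graph_from_fba,
    network_centralization,
    strength_centrality,
)
from crossfeed.errors import DomainError, UndefinedStatisticError
from crossfeed.fixtures import make_random_graph


def profile(strain_id, **cmax):
    return ByproductProfile(strain_id, dict(cmax))


# --------------------------------------------------------------------------- #
# profiles and edge weights
# --------------------------------------------------------------------------- #

class TestByproductProfile:
    def test_coculture_trajectory_rejected(
        self, crossfeed_specs, crossfeed_mutants, crossfeed_cond
    ):
        from crossfeed.batch_dynamics import simulate_coculture

        traj = simulate_coculture(
            [
                (crossfeed_specs["provider"], crossfeed_mutants["provider"]),
                (crossfeed_specs["consumer"], crossfeed_mutants["consumer"]),
            ],
            [0.0015, 0.0015],
            crossfeed_cond,
        )
        with pytest.raises(DomainError):
            byproduct_profile(traj)

    def test_nonsecreting_strain_has_empty_map(self, crossfeed_sweep):
        _, profiles, _ = crossfeed_sweep
        assert profiles["consumer"].cmax == {}

    def test_provider_cmax_matches_stoichiometry(self, provider_trajectory):
        """All consumed source leaves as by-product: Cmax ~ f * C0."""
        prof = byproduct_profile(provider_trajectory)
        assert prof.cmax["byp_e"] == pytest.approx(10.0, rel=0.01)

    def test_primal_source_never_in_profile(self, wildtype_trajectory):
        assert "glc_e" not in byproduct_profile(wildtype_trajectory).cmax


class TestEdgeWeight:
    def test_identical_profiles_weight_zero(self):
        p = profile("a", ac=3.0, form=1.0)
        q = profile("b", ac=3.0, form=1.0)
        assert edge_weight(p, q) == 0.0

    def test_novel_byproduct_weight_one(self):
        assert edge_weight(profile("a", ac=2.0, gly=1.0), profile("b", ac=2.0)) == 1.0

    def test_half_ratio(self):
        assert edge_weight(profile("a", A=2.0), profile("b", A=1.0)) == 0.5

    def test_empty_union_weight_zero(self):
        assert edge_weight(profile("a"), profile("b")) == 0.0

    # concentrations are either absent or non-negligible: the simulation
    # filters sub-1e-9 fluxes before they ever reach a profile
    conc = st.one_of(st.just(0.0), st.floats(1e-3, 1e3, allow_nan=False))

    @given(
        st.dictionaries(st.sampled_from(["m1", "m2", "m3"]), conc, max_size=3),
        st.dictionaries(st.sampled_from(["m1", "m2", "m3"]), conc, max_size=3),
    )
    def test_symmetry_and_range(self, cmax_p, cmax_q):
        p, q = ByproductProfile("p", cmax_p), ByproductProfile("q", cmax_q)
        w = edge_weight(p, q)
        assert w == edge_weight(q, p)
        assert 0.0 <= w <= 1.0
        # weight hits 1 exactly when some metabolite is secreted by one only
        exclusive = any(
            (cmax_p.get(m, 0) > 0) != (cmax_q.get(m, 0) > 0)
            for m in set(cmax_p) | set(cmax_q)
        )
        assert (w == 1.0) == exclusive


class TestBuildGraph:
    def test_two_identical_plus_novel_producer(self):
        graph = build_graph(
            [profile("a", ac=2.0), profile("b", ac=2.0), profile("c", ac=2.0, gly=1.0)]
        )
        weights = sorted(d["weight"] for _, _, d in graph.edges(data=True))
        assert weights == [0.0, 1.0, 1.0]

    def test_fewer_than_two_viable_strains_rejected(self):
        with pytest.raises(DomainError):
            build_graph(
                [profile("a", ac=1.0), profile("b", ac=1.0)],
                viability={"a": True, "b": False},
            )

    def test_concentration_invariance_bitwise(self, crossfeed_model, crossfeed_specs):
        """Doubling the initial source leaves the graph bit-identical."""
        from crossfeed.fixtures import crossfeed_condition
        from crossfeed.workflows import sweep_knockouts

        subset = [
            crossfeed_specs[k] for k in ("provider", "provider_dup", "consumer")
        ]
        weights = {}
        for c0 in (10.0, 20.0):
            _, profiles, _ = sweep_knockouts(
                crossfeed_model, subset, crossfeed_condition(c0)
            )
            g = build_graph(list(profiles.values()))
            weights[c0] = {
                frozenset((u, v)): d["weight"] for u, v, d in g.edges(data=True)
            }
        assert weights[10.0] == weights[20.0]

    def test_intermediate_weights_nearly_invariant(
        self, crossfeed_model, crossfeed_specs
    ):
        """Strains with different secretion stoichiometries give the exact
        flux ratio up to the final-step discretization (~1e-3)."""
        from crossfeed.fixtures import crossfeed_condition
        from crossfeed.workflows import sweep_knockouts

        subset = [crossfeed_specs[k] for k in ("provider", "half_provider")]
        for c0 in (10.0, 20.0):
            _, profiles, _ = sweep_knockouts(
                crossfeed_model, subset, crossfeed_condition(c0)
            )
            w = edge_weight(profiles["provider"], profiles["half_provider"])
            assert w == pytest.approx(0.5, abs=1e-3)


class TestFastGraph:
    def test_binary_agreement_with_dynamic_construction(
        self, crossfeed_model, crossfeed_specs, crossfeed_mutants,
        crossfeed_cond, crossfeed_sweep,
    ):
        table, profiles, _ = crossfeed_sweep
        viability = dict(zip(table["strain"], table["viable"]))
        dynamic = binarize(build_graph(list(profiles.values()), viability), 0.6)
        fast = binarize(
            fast_graph_from_fba(
                [(s, crossfeed_mutants[k]) for k, s in crossfeed_specs.items()],
                crossfeed_cond,
            ),
            0.6,
        )
        assert set(dynamic.nodes) == set(fast.nodes)
        assert {frozenset(e) for e in dynamic.edges} == {
            frozenset(e) for e in fast.edges
        }

    def test_inviable_strain_excluded(
        self, crossfeed_specs, crossfeed_mutants, crossfeed_cond
    ):
        graph = fast_graph_from_fba(
            [(s, crossfeed_mutants[k]) for k, s in crossfeed_specs.items()],
            crossfeed_cond,
        )
        assert "no_uptake" not in graph.nodes

    def test_efficiency_scale_invariant_to_cap(
        self, crossfeed_specs, crossfeed_mutants
    ):
        """LP homogeneity: halving the uptake cap leaves flux ratios, hence
        weights, unchanged."""
        from crossfeed.fixtures import CrossfeedSpec, crossfeed_condition

        pairs = [
            (s, crossfeed_mutants[k]) for k, s in crossfeed_specs.items()
            if k in ("provider", "half_provider", "consumer")
        ]
        weights = {}
        for cap in (5.0, 10.0):
            spec = CrossfeedSpec(source_cap=cap, reuse_cap=cap / 5)
            g = fast_graph_from_fba(pairs, crossfeed_condition(spec=spec))
            weights[cap] = {
                frozenset((u, v)): round(d["weight"], 12)
                for u, v, d in g.edges(data=True)
            }
        assert weights[5.0] == weights[10.0]


# --------------------------------------------------------------------------- #
# binarization and compression
# --------------------------------------------------------------------------- #

class TestBinarize:
    def test_boundary_weight_kept(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.6)
        assert binarize(g, 0.6).has_edge("a", "b")

    def test_all_zero_graph_is_edgeless(self):
        g = build_graph([profile("a", x=1.0), profile("b", x=1.0)])
        assert binarize(g, 0.6).number_of_edges() == 0

    def test_threshold_robustness_on_coarse_weights(self):
        """With weights in {0, 0.5, 1} every threshold in (0.5, 1] selects
        the same edges."""
        g = build_graph(
            [profile("a", x=1.0), profile("b", x=0.5), profile("c")]
        )
        e55 = {frozenset(e) for e in binarize(g, 0.55).edges}
        e65 = {frozenset(e) for e in binarize(g, 0.65).edges}
        assert e55 == e65

    def test_invalid_threshold(self):
        with pytest.raises(DomainError):
            binarize(nx.Graph(), 0.0)


class TestCompression:
    def test_star_graph_two_supernodes(self):
        star = nx.star_graph(6)
        compressed = compress(star)
        assert sorted(compressed.sizes()) == [1, 6]
        compressed.verify(star)

    def test_edgeless_graph_one_supernode(self):
        g = nx.empty_graph(5)
        assert len(compress(g).supernodes) == 1

    def test_quotient_expansion_reproduces_edges(self):
        for seed in range(5):
            g = make_random_graph(12, 0.4, seed=seed)
            compress(g).verify(g)

    def test_quotient_max_clique_matches_original(self):
        from crossfeed.communities import max_clique

        for seed in range(5):
            g = make_random_graph(12, 0.5, seed=100 + seed)
            compressed = compress(g)
            size_q, _ = max_clique(compressed.quotient)
            size_g, _ = max_clique(g)
            assert size_q == size_g


# --------------------------------------------------------------------------- #
# statistics
# --------------------------------------------------------------------------- #

class TestStrengthCentrality:
    def test_three_node_path(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_edge("b", "c", weight=0.5)
        centrality = strength_centrality(g)
        assert centrality["b"] == pytest.approx(0.5)
        assert centrality["a"] == pytest.approx(0.25)

    def test_isolated_and_saturated_nodes(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("a", "c", weight=1.0)
        centrality = strength_centrality(g)
        assert centrality["a"] == 1.0

    def test_needs_two_nodes(self):
        with pytest.raises(DomainError):
            strength_centrality(nx.empty_graph(1))


class TestNetworkCentralization:
    def test_binary_star_is_maximal(self):
        star = nx.star_graph(5)
        nx.set_edge_attributes(star, 1.0, "weight")
        assert network_centralization(star) == pytest.approx(1.0)

    def test_regular_graph_is_zero(self):
        triangle = nx.complete_graph(3)
        nx.set_edge_attributes(triangle, 0.7, "weight")
        assert network_centralization(triangle) == pytest.approx(0.0)

    def test_four_node_fixture_against_direct_formula(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("a", "c", weight=0.6)
        g.add_edge("c", "d", weight=0.3)
        strengths = {"a": 1.5 / 3, "b": 0.9 / 3, "c": 0.9 / 3, "d": 0.3 / 3}
        expected = sum(max(strengths.values()) - s for s in strengths.values()) / 2
        assert network_centralization(g) == pytest.approx(expected)

    def test_needs_three_nodes(self):
        with pytest.raises(DomainError):
            network_centralization(nx.complete_graph(2))


class TestClustering:
    def test_triangle_and_star(self):
        local, mean = clustering_coefficient(nx.complete_graph(3))
        assert all(v == 1.0 for v in local.values()) and mean == 1.0
        local, mean = clustering_coefficient(nx.star_graph(4))
        assert all(v == 0.0 for v in local.values()) and mean == 0.0

    def test_against_exhaustive_triangle_count(self):
        g = make_random_graph(5, 0.6, seed=7)
        local, _ = clustering_coefficient(g)
        for node in g.nodes:
            neigh = list(g.neighbors(node))
            k = len(neigh)
            expected = 0.0
            if k >= 2:
                links = sum(
                    1 for u, v in itertools.combinations(neigh, 2)
                    if g.has_edge(u, v)
                )
                expected = 2 * links / (k * (k - 1))
            assert local[node] == pytest.approx(expected)


class TestAssortativity:
    def test_homogeneous_cliques_are_assortative(self):
        g = nx.Graph()
        g.add_edges_from([("a1", "a2"), ("a1", "a3"), ("a2", "a3")])
        g.add_edges_from([("b1", "b2"), ("b1", "b3"), ("b2", "b3")])
        attrs = {n: (0.2 if n.startswith("a") else 0.9) for n in g.nodes}
        assert attribute_assortativity(g, attrs) == pytest.approx(1.0)

    def test_complete_bipartite_is_disassortative(self):
        g = nx.complete_bipartite_graph(3, 3)
        attrs = {n: (0.0 if n < 3 else 1.0) for n in g.nodes}
        assert attribute_assortativity(g, attrs) == pytest.approx(-1.0)

    def test_against_direct_correlation(self):
        g = make_random_graph(6, 0.6, seed=3)
        attrs = {n: float(n % 3) for n in g.nodes}
        xs, ys = [], []
        for u, v in g.edges:
            xs.extend((attrs[u], attrs[v]))
            ys.extend((attrs[v], attrs[u]))
        expected = np.corrcoef(xs, ys)[0, 1]
        assert attribute_assortativity(g, attrs) == pytest.approx(expected)

    def test_zero_variance_is_undefined(self):
        g = nx.complete_graph(3)
        with pytest.raises(UndefinedStatisticError):
            attribute_assortativity(g, {n: 1.0 for n in g.nodes})

    def test_missing_attribute_reported(self):
        g = nx.complete_graph(3)
        with pytest.raises(DomainError, match="2"):
            attribute_assortativity(g, {0: 1.0, 1: 0.5})


class TestConservationDensity:
    def test_all_conserved(self):
        strains = [f"s{i}" for i in range(20)]
        frame = conservation_density(strains, {s: 1.0 for s in strains})
        assert (frame["density_percent"] == 100.0).all()

    def test_alternating_attributes(self):
        strains = [f"s{i}" for i in range(20)]
        attrs = {s: float(i % 2) for i, s in enumerate(strains)}
        frame = conservation_density(strains, attrs)
        assert (frame["density_percent"] == 50.0).all()

    def test_trailing_partial_window(self):
        strains = [f"s{i}" for i in range(25)]
        frame = conservation_density(strains, {s: 0.0 for s in strains})
        assert list(frame["size"]) == [10, 10, 5]
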