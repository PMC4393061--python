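"""Topological indices and exact invariants against closed forms and oracles."""

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from conftest import random_multigraph
from rnadual.descriptors import (
    auxiliary_network_measures,
    balaban_index,
    chromatic_index,
    chromatic_number,
    circular_chromatic_number,
    clique_number,
    combinatorial_invariants,
    compute_feature_table,
    default_registry,
    domination_number,
    independence_number,
    laplacian_spectrum,
    platt_index,
    randic_index,
    simple_distance_matrix,
    wiener_index,
)
from rnadual.distances import Convention, distance_matrix
from rnadual.linegraph import line_graph_of_multigraph
from rnadual.multigraph import Multigraph


class TestChemicalIndices:
    def test_balaban_single_edge(self):
        g = Multigraph([0, 1], [(0, 1)])
        assert balaban_index(g, distance_matrix(g)) == pytest.approx(1.0)

    def test_balaban_triangle(self, triangle):
        assert balaban_index(triangle, distance_matrix(triangle)) == pytest.approx(2.25)

    def test_balaban_loop_free_conventions_agree(self, triangle):
        j_std = balaban_index(triangle, distance_matrix(triangle, Convention.STANDARD))
        j_ld = balaban_index(triangle, distance_matrix(triangle, Convention.LOOP_DIAGONAL))
        assert j_std == pytest.approx(j_ld)

    @pytest.mark.parametrize(
        "conv", [Convention.STANDARD, Convention.LOOP_DIAGONAL, Convention.LOOP_TRAVERSAL]
    )
    def test_balaban_loop_variants_finite(self, loop_double, conv):
        j = balaban_index(loop_double, distance_matrix(loop_double, conv))
        assert math.isfinite(j) and j > 0

    def test_wiener_path3(self, path3):
        assert wiener_index(distance_matrix(path3)) == 4

    def test_wiener_single_edge(self):
        g = Multigraph([0, 1], [(0, 1)])
        assert wiener_index(distance_matrix(g)) == 1

    def test_randic(self, path3, triangle):
        assert randic_index(path3) == pytest.approx(2 / math.sqrt(2))
        assert randic_index(triangle) == pytest.approx(1.5)
        assert randic_index(Multigraph([0, 1], [(0, 1)])) == pytest.approx(1.0)

    def test_platt(self, path3, triangle):
        assert platt_index(path3) == 2
        assert platt_index(triangle) == 6
        assert platt_index(Multigraph([0, 1], [(0, 1)])) == 0

    def test_laplacian_single_edge_and_triangle(self, triangle):
        g = Multigraph([0, 1], [(0, 1)])
        assert np.allclose(laplacian_spectrum(g), [0, 2])
        assert np.allclose(laplacian_spectrum(triangle), [0, 3, 3])

    def test_laplacian_connected_single_zero(self, catalog3):
        # the classic (loops-ignored) Laplacian of a connected graph has
        # exactly one zero eigenvalue; the loop-weighted variant adds 2
        # per loop to the diagonal and shifts the spectrum strictly up
        for g in catalog3.graphs:
            spec = laplacian_spectrum(g, include_loops=False)
            assert np.sum(np.abs(spec) < 1e-9) == 1
            weighted = laplacian_spectrum(g)
            assert weighted[0] >= -1e-9
            if any(g.loops_at(v) for v in g.vertices):
                assert weighted.sum() > spec.sum()

    def test_laplacian_loops_add_two_on_diagonal(self):
        g = Multigraph([0, 1], [(0, 0), (0, 1)])
        with_loops = laplacian_spectrum(g)
        without = laplacian_spectrum(g, include_loops=False)
        assert with_loops.sum() == pytest.approx(without.sum() + 2)


class TestExactInvariants:
    def test_complete_graph_facts(self):
        k3 = nx.complete_graph(3)
        inv = combinatorial_invariants(k3)
        assert inv["clique_number"] == 3
        assert inv["independence_number"] == 1
        assert inv["domination_number"] == 1
        assert inv["chromatic_number"] == 3
        assert inv["chromatic_index"] == 3

    def test_single_vertex(self):
        g = nx.Graph()
        g.add_node(0)
        inv = combinatorial_invariants(g)
        assert inv["diameter"] == 0
        assert inv["domination_number"] == 1

    def test_circular_chromatic_c5(self):
        assert circular_chromatic_number(nx.cycle_graph(5)) == Fraction(5, 2)

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_circular_chromatic_odd_cycles_closed_form(self, n):
        assert circular_chromatic_number(nx.cycle_graph(n)) == Fraction(n, (n - 1) // 2)

    def test_circular_chromatic_bounds(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            h = nx.gnp_random_graph(6, 0.5, seed=int(rng.integers(1 << 30)))
            chi = chromatic_number(h)
            chi_c = circular_chromatic_number(h)
            assert chi - 1 < chi_c <= chi

    def test_size_above_bound_rejected(self):
        with pytest.raises(ValueError, match="12"):
            combinatorial_invariants(nx.path_graph(13))

    def test_subset_oracles_on_random_graphs(self):
        """Clique/independence/domination vs exhaustive subset search."""
        rng = np.random.default_rng(43)
        for trial in range(200):
            n = int(rng.integers(3, 9))
            h = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)),
                                    seed=int(rng.integers(1 << 30)))
            nodes = list(h.nodes())
            best_clique = best_indep = 0
            best_dom = n
            for r in range(1, n + 1):
                for sub in itertools.combinations(nodes, r):
                    pairs = list(itertools.combinations(sub, 2))
                    if all(h.has_edge(a, b) for a, b in pairs):
                        best_clique = max(best_clique, r)
                    if not any(h.has_edge(a, b) for a, b in pairs):
                        best_indep = max(best_indep, r)
                    covered = set(sub)
                    for v in sub:
                        covered |= set(h.neighbors(v))
                    if len(covered) == n:
                        best_dom = min(best_dom, r)
            assert clique_number(h) == best_clique
            assert independence_number(h) == best_indep
            assert domination_number(h) == best_dom

    def test_chromatic_index_equals_line_graph_chromatic_number(self):
        for h in (nx.path_graph(4), nx.cycle_graph(5), nx.complete_graph(4),
                  nx.star_graph(3)):
            assert chromatic_index(h) == chromatic_number(nx.line_graph(h))


class TestAuxiliaryMeasures:
    def test_clustering_extremes(self):
        assert auxiliary_network_measures(nx.cycle_graph(4))["clustering_coefficient"] == 0
        assert auxiliary_network_measures(nx.complete_graph(3))["clustering_coefficient"] == 1

    def test_star_center_betweenness_and_stress(self):
        star = nx.star_graph(3)  # center 0, three leaves
        aux = auxiliary_network_measures(star)
        assert aux["max_betweenness"] == 3  # all three leaf pairs route via center
        assert aux["max_stress"] == 3

    def test_disconnected_rejected(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="connected"):
            auxiliary_network_measures(g)


class TestIsomorphismInvariance:
    def _relabeled(self, g, rng):
        perm = list(rng.permutation(g.order))
        return g.relabel({v: perm[i] for i, v in enumerate(g.vertices)})

    def test_descriptors_invariant_under_relabeling(self):
        registry = default_registry()
        rng = np.random.default_rng(47)
        checked = 0
        while checked < 8:
            g = random_multigraph(rng, n_max=4, m_max=7)
            if g.order < 2 or not g.is_connected() or g.size == 0:
                continue
            h = self._relabeled(g, rng)
            lg_g = line_graph_of_multigraph(g)
            lg_h = line_graph_of_multigraph(h)
            for spec in registry:
                try:
                    a = spec.evaluate(g, lg_g)
                except ValueError:
                    with pytest.raises(ValueError):
                        spec.evaluate(h, lg_h)
                    continue
                b = spec.evaluate(h, lg_h)
                if math.isnan(a):
                    assert math.isnan(b), spec.name
                else:
                    assert a == pytest.approx(b), spec.name
            checked += 1


class TestFeatureTable:
    def test_order2_wiener_table(self, catalog2):
        from rnadual.descriptors import DescriptorSpec

        spec = DescriptorSpec(
            "wiener_standard", "multigraph",
            lambda g: wiener_index(distance_matrix(g)),
        )
        fm = compute_feature_table(catalog2, [spec])
        assert fm.values.shape == (3, 1)
        # all order-2 dual graphs have a single vertex pair at distance 1
        assert set(fm.values["wiener_standard"]) == {1.0}

    def test_empty_registry_rejected(self, catalog2):
        with pytest.raises(ValueError, match="empty"):
            compute_feature_table(catalog2, [])

    def test_duplicate_names_rejected(self, catalog2):
        from rnadual.descriptors import DescriptorSpec

        s = DescriptorSpec("x", "multigraph", lambda g: 0.0)
        with pytest.raises(ValueError, match="duplicate"):
            compute_feature_table(catalog2, [s, s])

    def test_order4_row_count_and_missing_flags(self, catalog4):
        fm = compute_feature_table(catalog4)
        assert fm.values.shape[0] == 30
        # every NaN cell is flagged missing, never a silent hole
        assert (fm.values.isna() == fm.missing).all().all()

    def test_balaban_line_graph_distance_matrix_consistency(self, catalog2):
        for g in catalog2.graphs:
            lg = line_graph_of_multigraph(g)
            j = balaban_index(lg, simple_distance_matrix(lg))
            assert math.isfinite(j)
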