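"""LP/ILP extraction methods against the brute-force oracle."""

from fractions import Fraction

import pytest

from densehot.fixtures import random_graph
from densehot.graph import (
    GraphInputError,
    UndirectedGraph,
    brute_force_densest,
    minimal_densest_sets,
)
from densehot.solvers import (
    extract_densest,
    find_all_minimal_densest,
    find_densest,
    find_maximal_densest_ilp,
    find_maximal_densest_iterative,
    find_one_minimal_densest,
    maximum_density,
    min_sds,
    solve_basic_lp,
    solve_max_lp,
)
from conftest import k_complete

# A deterministic battery of small random graphs shared by the property tests.
RANDOM_CASES = [
    (6 + seed % 6, p, seed * 13 + int(10 * p))
    for seed in range(12)
    for p in (0.2, 0.5, 0.8)
]


def _random_with_edges(n, p, seed):
    G = random_graph(n, p, seed)
    return G if G.m else None


class TestBasicLP:
    def test_k4_objective(self, k4):
        assert solve_basic_lp(k4).objective == pytest.approx(1.5, abs=1e-7)

    def test_single_edge_symmetric_optimum(self):
        sol = solve_basic_lp(UndirectedGraph.from_edges([(1, 2)]))
        assert sol.objective == pytest.approx(0.5, abs=1e-7)
        assert sol.vertex_values[1] == pytest.approx(0.5, abs=1e-6)
        assert sol.vertex_values[2] == pytest.approx(0.5, abs=1e-6)

    def test_two_triangles_objective(self, two_triangles):
        assert solve_basic_lp(two_triangles).objective == pytest.approx(1.0, abs=1e-7)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(GraphInputError):
            solve_basic_lp(UndirectedGraph.from_edges([], vertices=[1, 2]))

    def test_solution_satisfies_lp_invariants(self, triangle_pendant):
        sol = solve_basic_lp(triangle_pendant)
        tol = 1e-7
        for (i, j), x in sol.edge_values.items():
            assert x <= min(sol.vertex_values[i], sol.vertex_values[j]) + tol
            assert x >= -tol
        assert sum(sol.vertex_values.values()) <= 1 + tol


class TestDensestExtraction:
    def test_k4(self, k4):
        r = find_densest(k4)
        assert r.vertices == (1, 2, 3, 4) and r.density == Fraction(3, 2)
        assert r.method == "ds"

    def test_triangle_pendant_hits_an_oracle_optimum(self, triangle_pendant):
        best, sets = brute_force_densest(triangle_pendant)
        r = find_densest(triangle_pendant)
        assert r.density == best and r.vertex_set in set(sets)

    def test_two_triangles_hits_an_oracle_optimum(self, two_triangles):
        best, sets = brute_force_densest(two_triangles)
        r = extract_densest(solve_basic_lp(two_triangles), two_triangles)
        assert r.density == best and r.vertex_set in set(sets)

    def test_isolated_vertices_never_selected(self):
        G = UndirectedGraph.from_edges([(1, 2), (1, 3), (2, 3)], vertices=[9, 10])
        assert 9 not in find_densest(G).vertices


class TestMinimalDensest:
    def test_triangle_pendant_picks_triangle_only(self, triangle_pendant):
        assert find_one_minimal_densest(triangle_pendant).vertices == (1, 2, 3)

    def test_k4_has_no_proper_densest_subset(self, k4):
        assert find_one_minimal_densest(k4).vertices == (1, 2, 3, 4)

    def test_two_triangles_lexicographic_tie_break(self, two_triangles):
        assert find_one_minimal_densest(two_triangles).vertices == (1, 2, 3)

    def test_all_minimal_two_triangles(self, two_triangles):
        res = find_all_minimal_densest(two_triangles)
        assert [r.vertices for r in res] == [(1, 2, 3), (4, 5, 6)]
        assert all(r.method == "min-ds" for r in res)

    def test_all_minimal_triangle_pendant(self, triangle_pendant):
        assert [r.vertices for r in find_all_minimal_densest(triangle_pendant)] == [(1, 2, 3)]

    def test_sparser_component_not_peeled(self):
        G = UndirectedGraph.from_edges(
            list(k_complete([1, 2, 3, 4]).edges) + [(5, 6), (5, 7), (6, 7)]
        )
        assert [r.vertices for r in find_all_minimal_densest(G)] == [(1, 2, 3, 4)]

    def test_different_sized_minimal_sets_both_found(self):
        # triangle and 4-cycle both have density 1 and are inclusion-minimal
        G = UndirectedGraph.from_edges(
            [(1, 2), (1, 3), (2, 3), (4, 5), (5, 6), (6, 7), (4, 7)]
        )
        res = find_all_minimal_densest(G)
        assert {r.vertex_set for r in res} == {
            frozenset({1, 2, 3}),
            frozenset({4, 5, 6, 7}),
        }


class TestMaximalDensest:
    def test_triangle_pendant_union(self, triangle_pendant):
        assert find_maximal_densest_ilp(triangle_pendant).vertices == (1, 2, 3, 4)

    def test_two_triangles_union(self, two_triangles):
        assert find_maximal_densest_ilp(two_triangles).vertices == (1, 2, 3, 4, 5, 6)

    def test_k4_whole_graph(self, k4):
        r = find_maximal_densest_ilp(k4)
        assert r.vertices == (1, 2, 3, 4) and r.method == "max-ds"

    def test_grow_step_extends_triangle(self, triangle_pendant):
        D = maximum_density(triangle_pendant)
        S = solve_max_lp(triangle_pendant, D, {1, 2, 3})
        assert S is not None and {1, 2, 3} < set(S)

    def test_grow_step_recovers_k4(self, k4):
        S = solve_max_lp(k4, Fraction(3, 2), {1, 2, 3})
        assert S == frozenset({1, 2, 3, 4})

    def test_grow_step_joins_second_triangle(self, two_triangles):
        S = solve_max_lp(two_triangles, Fraction(1), {1, 2, 3})
        assert S is not None and set(S) - {1, 2, 3}

    def test_grow_step_requires_proper_subset(self, k4):
        with pytest.raises(GraphInputError):
            solve_max_lp(k4, Fraction(3, 2), {1, 2, 3, 4})

    def test_iterative_equals_ilp_on_fixtures(
        self, k4, triangle_pendant, two_triangles, k4_k3_k2
    ):
        for G in (k4, triangle_pendant, two_triangles, k4_k3_k2):
            assert (
                find_maximal_densest_iterative(G).vertices
                == find_maximal_densest_ilp(G).vertices
            )

    def test_growth_does_not_stall_on_split_outside_mass(self):
        """The whole graph is densest (rho = 2) but the LP start extracts a
        6-vertex densest core; the grow LP admits alternative optima whose
        outside y-mass is spread below the 1/|V| selection threshold, which
        stalled a re-thresholding growth loop.  Anchored growth must still
        reach all 11 vertices."""
        G = UndirectedGraph.from_edges(
            [(0, 1), (0, 4), (0, 6), (0, 7), (0, 8), (0, 9), (1, 6), (1, 7),
             (1, 8), (2, 3), (2, 4), (3, 4), (3, 6), (4, 6), (5, 6), (5, 7),
             (5, 8), (5, 9), (6, 7), (6, 8), (8, 10), (9, 10)]
        )
        assert maximum_density(G) == Fraction(2)
        result = find_maximal_densest_iterative(G)
        assert result.vertices == tuple(range(11))
        assert result.vertices == find_maximal_densest_ilp(G).vertices

    def test_unique_densest_is_a_fixed_point(self, k4):
        assert find_maximal_densest_iterative(k4).vertices == find_densest(k4).vertices


class TestMinSDS:
    @pytest.mark.parametrize(
        "theta,expected_blocks",
        [
            (0.3, [(1, 2, 3, 4), (5, 6, 7), (8, 9)]),
            (0.6, [(1, 2, 3, 4), (5, 6, 7)]),
            (0.9, [(1, 2, 3, 4)]),
        ],
    )
    def test_hand_peeled_example(self, k4_k3_k2, theta, expected_blocks):
        res = min_sds(k4_k3_k2, theta)
        assert [r.vertices for r in res] == expected_blocks
        assert all(r.method == "min-sds" for r in res)

    def test_peel_densities(self, k4_k3_k2):
        res = min_sds(k4_k3_k2, 0.3)
        assert [r.density for r in res] == [Fraction(3, 2), Fraction(1), Fraction(1, 2)]

    @pytest.mark.parametrize("theta", [0, 1, 1.5, -0.2])
    def test_theta_bounds_enforced(self, k4, theta):
        with pytest.raises(GraphInputError):
            min_sds(k4, theta)

    def test_exact_threshold_is_selected(self, k4_k3_k2):
        # theta*D = (2/3)*(3/2) = 1 equals the triangle density: kept, not dropped
        res = min_sds(k4_k3_k2, Fraction(2, 3))
        assert [r.vertices for r in res] == [(1, 2, 3, 4), (5, 6, 7)]

    def test_prefix_monotonicity_on_theta_grid(self, k4_k3_k2):
        grid = [Fraction(k, 20) for k in range(1, 20)]
        sequences = {th: [r.vertices for r in min_sds(k4_k3_k2, th)] for th in grid}
        for lo, hi in zip(grid, grid[1:]):
            longer, shorter = sequences[lo], sequences[hi]
            assert longer[: len(shorter)] == shorter

    def test_limit_theta_to_one_matches_min_ds(self, triangle_pendant, two_triangles):
        theta = Fraction(10**9 - 1, 10**9)
        for G in (triangle_pendant, two_triangles):
            assert [r.vertices for r in min_sds(G, theta)] == [
                r.vertices for r in find_all_minimal_densest(G)
            ]


class TestOracleEquivalenceProperties:
    """Solver results must match exhaustive enumeration on random graphs."""

    @pytest.mark.parametrize("n,p,seed", RANDOM_CASES)
    def test_random_graphs_agree_with_oracle(self, n, p, seed):
        G = _random_with_edges(n, p, seed)
        if G is None:
            return
        best, all_dense = brute_force_densest(G)

        sol = solve_basic_lp(G)
        assert sol.objective == pytest.approx(float(best), abs=1e-6)
        ds = extract_densest(sol, G)
        assert ds.density == best and ds.vertex_set in set(all_dense)

        mins = find_all_minimal_densest(G)
        assert {r.vertex_set for r in mins} == set(minimal_densest_sets(all_dense))
        seen = set()
        for r in mins:
            assert not (r.vertex_set & seen)  # pairwise disjoint
            seen |= r.vertex_set

        mx = find_maximal_densest_ilp(G)
        assert mx.vertex_set == frozenset().union(*all_dense)
        assert all(r.vertex_set <= mx.vertex_set for r in mins)
        assert find_maximal_densest_iterative(G).vertices == mx.vertices

    @pytest.mark.parametrize("n,p,seed", RANDOM_CASES[::3])
    def test_min_sds_results_disjoint_and_above_threshold(self, n, p, seed):
        G = _random_with_edges(n, p, seed)
        if G is None:
            return
        D = maximum_density(G)
        theta = Fraction(7, 10)
        res = min_sds(G, theta)
        seen = set()
        for r in res:
            assert r.density >= theta * D
            assert not (r.vertex_set & seen)
            seen |= r.vertex_set
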