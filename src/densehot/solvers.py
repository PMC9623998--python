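"""LP/ILP densest-subgraph extraction: DS, Min-DS, Max-DS and Min-SDS.

Four related extraction methods over an :class:`~densehot.graph.UndirectedGraph`:

``find_densest`` (DS)
    One densest subgraph, from the classic LP relaxation (maximise the total
    edge mass ``sum x_ij`` subject to ``x_ij <= y_i``, ``x_ij <= y_j`` and
    ``sum y_i <= 1``).  At the optimum the objective equals the maximum
    density ``D`` and the vertices with ``y_i >= 1/|V|`` induce a densest
    subgraph, so no rounding search is needed.

``find_all_minimal_densest`` (Min-DS)
    All inclusion-minimal densest subgraphs.  Distinct minimal densest
    subgraphs are vertex-disjoint (the intersection of two intersecting
    densest subgraphs is itself densest), so they can be peeled off one at a
    time: find one minimal densest subgraph, delete its vertices, repeat while
    the remaining graph still attains the original maximum density.

``find_maximal_densest_ilp`` / ``find_maximal_densest_iterative`` (Max-DS)
    The unique maximal densest subgraph — the union of all densest subgraphs.
    The ILP route adds binary selection variables ``z_i`` with
    ``y_i >= z_i/|V|`` and maximises ``sum z_i`` subject to the LP constraints
    plus ``sum x_ij >= D``.  The iterative route repeatedly grows a known
    densest subgraph ``R`` by solving an LP that forces all of ``R`` plus at
    least one outside vertex into the solution; both routes must agree.

``min_sds`` (Min-SDS)
    Peeling with a relaxed stopping rule: keep extracting minimal densest
    subgraphs of the remaining graph while their density is at least
    ``theta * D`` for a tolerance ``0 < theta < 1``.  This surfaces secondary
    dense regions (e.g. additional binding interfaces) that the strict
    methods ignore.

All solver output is cross-checked by recounting each extracted subgraph's
density in exact rational arithmetic before it is returned; floating-point
LP objectives never decide a comparison between candidate subgraphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .graph import GraphInputError, SubgraphResult, UndirectedGraph

__all__ = [
    "SolverError",
    "ExtractionError",
    "LPSolution",
    "solve_basic_lp",
    "extract_densest",
    "find_densest",
    "maximum_density",
    "find_one_minimal_densest",
    "find_all_minimal_densest",
    "find_maximal_densest_ilp",
    "solve_max_lp",
    "find_maximal_densest_iterative",
    "min_sds",
]

#: Membership tolerance for the y_i >= 1/|V| vertex-selection rule.
MEMBERSHIP_EPS = 1e-6
#: Slack subtracted from the (exact) maximum density D when it appears as an
#: LP/ILP constraint bound, to absorb solver round-off.  Densities of distinct
#: subgraphs of an n-vertex graph differ by at least 1/n^2, far above this.
DENSITY_EPS = 1e-9


class SolverError(RuntimeError):
    """LP/ILP backend failed on input that should be feasible."""


class ExtractionError(RuntimeError):
    """Vertex selection from a solver solution failed its exact recount."""


@dataclass(frozen=True)
class LPSolution:
    """Optimal solution of the densest-subgraph LP relaxation."""

    edge_values: dict
    vertex_values: dict
    objective: float


def _theta_fraction(theta) -> Fraction:
    """Tolerance as an exact fraction; decimals pass through str() losslessly."""
    if isinstance(theta, Fraction):
        frac = theta
    else:
        frac = Fraction(str(theta))
    if not (0 < frac < 1):
        raise GraphInputError(f"theta must satisfy 0 < theta < 1, got {theta!r}")
    return frac


def _require_edges(G: UndirectedGraph) -> None:
    if G.n == 0:
        raise GraphInputError("empty graph")
    if G.m == 0:
        raise GraphInputError(
            "graph has no edges: maximum density is trivially 0 and no densest "
            "subgraph extraction is defined"
        )


def _edge_rows(edges: Sequence, vindex: dict, n_vars: int):
    """Sparse rows x_e - y_i <= 0 and x_e - y_j <= 0 (edge vars first)."""
    m = len(edges)
    rows, cols, vals = [], [], []
    r = 0
    for e_idx, (u, v) in enumerate(edges):
        for w in (u, v):
            rows += [r, r]
            cols += [e_idx, m + vindex[w]]
            vals += [1.0, -1.0]
            r += 1
    return sparse.csr_matrix((vals, (rows, cols)), shape=(r, n_vars))


# ---------------------------------------------------------------------------
# BasicLP and Proposition-1 extraction (DS)
# ---------------------------------------------------------------------------

def solve_basic_lp(G: UndirectedGraph) -> LPSolution:
    """Solve the densest-subgraph LP relaxation to optimality.

    Maximise ``sum_{(i,j) in E} x_ij`` subject to ``x_ij <= y_i``,
    ``x_ij <= y_j``, ``sum_i y_i <= 1`` and nonnegativity.  The optimal
    objective equals the maximum subgraph density of ``G``.
    """
    _require_edges(G)
    edges = sorted(G.edges)
    verts = list(G.vertices)
    m, n = len(edges), len(verts)
    vindex = {v: i for i, v in enumerate(verts)}
    nv = m + n

    A_edge = _edge_rows(edges, vindex, nv)
    budget = sparse.csr_matrix(
        (np.ones(n), (np.zeros(n, dtype=int), np.arange(m, m + n))), shape=(1, nv)
    )
    A_ub = sparse.vstack([A_edge, budget], format="csr")
    b_ub = np.concatenate([np.zeros(2 * m), [1.0]])
    c = np.concatenate([-np.ones(m), np.zeros(n)])

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, 1), method="highs")
    if not res.success:
        raise SolverError(f"BasicLP failed: {res.message}")
    x = res.x
    return LPSolution(
        edge_values={e: float(x[i]) for i, e in enumerate(edges)},
        vertex_values={v: float(x[m + i]) for i, v in enumerate(verts)},
        objective=float(-res.fun),
    )


def extract_densest(sol: LPSolution, G: UndirectedGraph) -> SubgraphResult:
    """Select ``{i : y_i >= 1/|V| - eps}`` from an optimal LP solution.

    The selected set provably induces a densest subgraph for *any* optimal
    solution; its density is recounted exactly and compared against the LP
    objective as a guard against solver misbehaviour.
    """
    thr = 1.0 / G.n - MEMBERSHIP_EPS
    subset = [v for v in G.vertices if sol.vertex_values[v] >= thr]
    if not subset:
        raise ExtractionError("no vertex reached the 1/|V| selection threshold")
    result = SubgraphResult.from_subset(G, subset, method="ds")
    if abs(float(result.density) - sol.objective) > 1e-5:
        raise ExtractionError(
            f"recounted density {result.density} != LP objective {sol.objective:.9f}"
        )
    return result


def find_densest(G: UndirectedGraph) -> SubgraphResult:
    """One densest subgraph of ``G`` (the DS method)."""
    return extract_densest(solve_basic_lp(G), G)


def maximum_density(G: UndirectedGraph) -> Fraction:
    """Exact maximum subgraph density ``D`` of ``G`` (via LP + recount)."""
    return find_densest(G).density


# ---------------------------------------------------------------------------
# Shared MILP scaffolding
# ---------------------------------------------------------------------------

def _milp_select(
    G: UndirectedGraph,
    D: Fraction,
    *,
    link: str,
    objective: str,
    forced_in: Iterable = (),
    forced_out: Iterable = (),
    cardinality: Optional[int] = None,
):
    """Solve a selection MILP over (x, y, z) and return the z=1 vertex set.

    ``link='upper'`` adds ``y_i <= z_i`` (selection covers the y-support;
    used when minimising), ``link='lower'`` adds ``y_i >= z_i/|V|`` (selection
    is contained in the Proposition-1 set; used when maximising).
    ``objective`` is ``'min_card'``, ``'max_card'`` or ``'feasible'``.
    Returns ``None`` when infeasible.
    """
    edges = sorted(G.edges)
    verts = list(G.vertices)
    m, n = len(edges), len(verts)
    vindex = {v: i for i, v in enumerate(verts)}
    nv = m + 2 * n  # x | y | z

    cons = []
    A_edge = _edge_rows(edges, vindex, nv)
    cons.append(LinearConstraint(A_edge, -np.inf, 0.0))

    row_budget = np.zeros(nv)
    row_budget[m : m + n] = 1.0
    cons.append(LinearConstraint(row_budget[None, :], -np.inf, 1.0))

    row_mass = np.zeros(nv)
    row_mass[:m] = 1.0
    cons.append(LinearConstraint(row_mass[None, :], float(D) - DENSITY_EPS, np.inf))

    link_rows, link_cols, link_vals = [], [], []
    for i in range(n):
        link_rows += [i, i]
        link_cols += [m + i, m + n + i]
        if link == "upper":  # y_i - z_i <= 0
            link_vals += [1.0, -1.0]
        elif link == "lower":  # y_i - z_i/n >= 0
            link_vals += [1.0, -1.0 / n]
        else:  # pragma: no cover - internal misuse
            raise ValueError(link)
    A_link = sparse.csr_matrix((link_vals, (link_rows, link_cols)), shape=(n, nv))
    if link == "upper":
        cons.append(LinearConstraint(A_link, -np.inf, 0.0))
    else:
        cons.append(LinearConstraint(A_link, 0.0, np.inf))

    if cardinality is not None:
        row_card = np.zeros(nv)
        row_card[m + n :] = 1.0
        cons.append(LinearConstraint(row_card[None, :], cardinality, cardinality))

    lb = np.zeros(nv)
    ub = np.ones(nv)
    for v in forced_in:
        lb[m + n + vindex[v]] = 1.0
    for v in forced_out:
        ub[m + n + vindex[v]] = 0.0

    c = np.zeros(nv)
    if objective == "min_card":
        c[m + n :] = 1.0
    elif objective == "max_card":
        c[m + n :] = -1.0
    elif objective != "feasible":  # pragma: no cover - internal misuse
        raise ValueError(objective)

    integrality = np.concatenate([np.zeros(m + n), np.ones(n)])
    res = milp(
        c,
        constraints=cons,
        integrality=integrality,
        bounds=Bounds(lb, ub),
    )
    if res.status == 2:  # infeasible
        return None
    if not res.success:
        raise SolverError(f"MILP failed (status {res.status}): {res.message}")
    z = res.x[m + n :]
    return frozenset(verts[i] for i in range(n) if z[i] > 0.5)


# ---------------------------------------------------------------------------
# Min-DS
# ---------------------------------------------------------------------------

def find_one_minimal_densest(G: UndirectedGraph) -> SubgraphResult:
    """One minimal densest subgraph: the minimum-cardinality densest subgraph,
    lexicographically least among ties.

    A densest subgraph of minimum vertex count cannot properly contain another
    densest subgraph, so minimum cardinality implies inclusion-minimality.
    The cardinality ``k`` is found by an ILP minimising ``sum z_i`` with
    ``y_i <= z_i``; the lexicographic tie-break then fixes vertices one by one
    in sorted order, testing feasibility of a size-``k`` densest subgraph that
    contains the fixed prefix, reusing the last witness solution to skip
    solves whenever it already certifies feasibility.
    """
    _require_edges(G)
    D = maximum_density(G)

    witness = _milp_select(G, D, link="upper", objective="min_card")
    if witness is None:
        raise SolverError("minimum-cardinality densest ILP infeasible")
    k = len(witness)

    chosen: list = []
    excluded: list = []
    for v in sorted(G.vertices):
        if len(chosen) == k:
            break
        if v in witness and set(chosen) | {v} <= witness:
            chosen.append(v)
            continue
        cand = _milp_select(
            G,
            D,
            link="upper",
            objective="feasible",
            forced_in=[*chosen, v],
            forced_out=excluded,
            cardinality=k,
        )
        if cand is None:
            excluded.append(v)
        else:
            chosen.append(v)
            witness = cand

    result = SubgraphResult.from_subset(G, chosen, method="min-ds")
    if len(result.vertices) != k or result.density != D:
        raise ExtractionError(
            f"minimal densest recount failed: |S|={len(result.vertices)} (want {k}), "
            f"rho={result.density} (want {D})"
        )
    return result


def find_all_minimal_densest(G: UndirectedGraph) -> list[SubgraphResult]:
    """All minimal densest subgraphs of ``G`` by iterative peeling (Min-DS).

    Peeling is exhaustive because distinct minimal densest subgraphs are
    vertex-disjoint, and removing one neither creates new densest subgraphs
    nor destroys the remaining minimal ones.
    """
    _require_edges(G)
    D = maximum_density(G)
    results: list[SubgraphResult] = []
    H = G
    while H.m > 0:
        R = find_one_minimal_densest(H)
        if R.density < D:
            break
        results.append(SubgraphResult.from_subset(G, R.vertices, method="min-ds"))
        H = H.remove(R.vertices)
    return results


# ---------------------------------------------------------------------------
# Max-DS
# ---------------------------------------------------------------------------

def find_maximal_densest_ilp(G: UndirectedGraph, D: Optional[Fraction] = None) -> SubgraphResult:
    """The unique maximal densest subgraph of ``G``, by ILP (Max-DS).

    Maximises ``sum z_i`` subject to the LP-relaxation constraints,
    ``sum x_ij >= D`` and ``y_i >= z_i/|V|``; the ``z_i = 1`` vertices induce
    the union of all densest subgraphs.
    """
    _require_edges(G)
    if D is None:
        D = maximum_density(G)
    selected = _milp_select(G, D, link="lower", objective="max_card")
    if selected is None:
        raise SolverError("maximal densest ILP infeasible; supplied D exceeds the maximum density?")
    result = SubgraphResult.from_subset(G, selected, method="max-ds")
    if result.density != D:
        raise ExtractionError(
            f"maximal densest recount failed: rho={result.density} != D={D}"
        )
    return result


def solve_max_lp(
    G: UndirectedGraph, D: Fraction, R: Iterable, require_outside: bool = True
) -> Optional[frozenset]:
    """Grow step of the iterative Max-DS: a densest superset of ``R``.

    Solves the LP relaxation with the extra constraints ``sum x_ij >= D`` and
    ``y_i >= 1/|V|`` for every ``i`` in ``R`` (all of ``R`` selected); with
    ``require_outside`` also ``sum_{i not in R} y_i >= 1/|V|`` (some outside
    vertex carries weight).  Returns the selected vertex set, or ``None``
    when no densest subgraph accommodating ``R`` (plus outside mass) exists.
    """
    Rset = set(R)
    if not Rset <= set(G.vertices):
        raise GraphInputError("R must be a subset of the vertex set")
    if require_outside and Rset == set(G.vertices):
        raise GraphInputError("R must be a proper subset of the vertex set")
    edges = sorted(G.edges)
    verts = list(G.vertices)
    m, n = len(edges), len(verts)
    vindex = {v: i for i, v in enumerate(verts)}
    nv = m + n

    A_edge = _edge_rows(edges, vindex, nv)

    row_budget = np.zeros(nv)
    row_budget[m:] = 1.0
    row_mass = np.zeros(nv)
    row_mass[:m] = 1.0
    # budget <= 1; sum x >= D and (optionally) outside y-mass >= 1/n, negated
    extra_rows = [row_budget, -row_mass]
    extra_b = [1.0, -(float(D) - DENSITY_EPS)]
    if require_outside:
        row_outside = np.zeros(nv)
        for i, v in enumerate(verts):
            if v not in Rset:
                row_outside[m + i] = 1.0
        extra_rows.append(-row_outside)
        extra_b.append(-(1.0 / n - DENSITY_EPS))
    A_ub = sparse.vstack(
        [A_edge, sparse.csr_matrix(np.vstack(extra_rows))], format="csr"
    )
    b_ub = np.concatenate([np.zeros(A_edge.shape[0]), extra_b])

    lb = np.zeros(nv)
    ub = np.ones(nv)
    for v in Rset:
        lb[m + vindex[v]] = 1.0 / n - DENSITY_EPS

    c = np.concatenate([-np.ones(m), np.zeros(n)])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if not res.success:
        return None
    if -res.fun < float(D) - 1e-6:
        return None
    thr = 1.0 / n - MEMBERSHIP_EPS
    return frozenset(v for i, v in enumerate(verts) if res.x[m + i] >= thr)


def find_maximal_densest_iterative(G: UndirectedGraph) -> SubgraphResult:
    """The maximal densest subgraph by repeated LP growth (FindMaximal).

    Starts from one densest subgraph ``R`` and tests each remaining vertex
    ``v`` once: the grow LP asks for a densest subgraph containing
    ``R | {v}``, which is feasible exactly when ``v`` lies in some densest
    subgraph (the union of two densest subgraphs is densest, so ``R`` stays
    densest as it grows).  At most |V| grow-LP calls.  A naive variant —
    demand *any* extra outside y-mass and re-threshold — can stall on
    alternative LP optima that spread the outside mass below the 1/|V|
    selection threshold, so growth is anchored to a named vertex instead.
    Must agree with the ILP route on every input (the maximal densest
    subgraph is unique).
    """
    _require_edges(G)
    base = find_densest(G)
    D = base.density
    R = set(base.vertices)
    for v in sorted(G.vertices):
        if v in R:
            continue
        S = solve_max_lp(G, D, R | {v}, require_outside=False)
        if S is None:
            continue
        grown = SubgraphResult.from_subset(G, S, method="max-ds")
        if grown.density != D:
            raise ExtractionError(
                f"grow step selected a non-densest set: rho={grown.density} != D={D}"
            )
        R |= S
    result = SubgraphResult.from_subset(G, R, method="max-ds")
    if result.density != D:
        raise ExtractionError(
            f"iterative maximal densest recount failed: rho={result.density} != D={D}"
        )
    return result


# ---------------------------------------------------------------------------
# Min-SDS
# ---------------------------------------------------------------------------

def min_sds(G: UndirectedGraph, theta) -> list[SubgraphResult]:
    """Minimal sub-densest subgraphs: tolerance-relaxed peeling (Min-SDS).

    With ``D`` the maximum density of the *original* graph, repeatedly peel
    the minimal densest subgraph ``R`` of the remaining graph while
    ``rho(R) >= theta * D`` (the comparison is exact: rational density against
    rational ``theta * D``; a peel hitting the threshold exactly is kept).
    Results are pairwise vertex-disjoint.
    """
    _require_edges(G)
    frac = _theta_fraction(theta)
    D = maximum_density(G)
    threshold = frac * D
    results: list[SubgraphResult] = []
    H = G
    while H.m > 0:
        R = find_one_minimal_densest(H)
        if R.density < threshold:
            break
        results.append(SubgraphResult.from_subset(G, R.vertices, method="min-sds"))
        H = H.remove(R.vertices)
    return results
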