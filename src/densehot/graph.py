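"""Simple undirected graphs with exact rational density.

The density of a graph ``G = (V, E)`` is ``rho(G) = |E| / |V|``, i.e. half the
average degree.  A *densest subgraph* is a vertex-induced subgraph maximising
this ratio.  All density values in this package are :class:`fractions.Fraction`
instances, so comparisons between candidate subgraphs are exact integer
cross-multiplications and never subject to floating-point round-off.  LP/ILP
objective values, which *are* floats, are only ever compared against a rational
recount with an explicit tolerance — see :mod:`densehot.solvers`.

Vertex identifiers are opaque but must be mutually orderable; the sorted order
defines every deterministic tie-break in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "GraphInputError",
    "UndirectedGraph",
    "SubgraphResult",
    "density",
    "brute_force_densest",
    "minimal_densest_sets",
    "parse_edge_list",
    "format_edge_list",
]

#: Exhaustive enumeration bound for the brute-force oracle (2^n subsets).
BRUTE_FORCE_CAP = 15


class GraphInputError(ValueError):
    """Invalid graph input (empty vertex set, unknown vertices, bad file...)."""


def _norm_edge(u, v):
    if u == v:
        raise GraphInputError(f"self-loop on vertex {u!r} is not allowed")
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class UndirectedGraph:
    """Immutable simple undirected graph.

    Parameters
    ----------
    vertices : tuple
        Sorted, duplicate-free vertex identifiers.
    edges : frozenset of 2-tuples
        Each edge stored once as ``(u, v)`` with ``u < v``.

    Use :meth:`from_edges` instead of the raw constructor; it normalises and
    validates.
    """

    vertices: tuple
    edges: frozenset

    @classmethod
    def from_edges(cls, edges: Iterable, vertices: Iterable = ()) -> "UndirectedGraph":
        """Build a graph from an edge iterable plus optional extra vertices.

        Extra vertices allow isolated vertices, which are legal graph members
        but can never belong to a densest subgraph (they strictly lower the
        edge/vertex ratio).
        """
        edge_set = {_norm_edge(u, v) for (u, v) in edges}
        vset = set(vertices)
        for u, v in edge_set:
            vset.add(u)
            vset.add(v)
        return cls(vertices=tuple(sorted(vset)), edges=frozenset(edge_set))

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def m(self) -> int:
        return len(self.edges)

    def __contains__(self, v) -> bool:
        return v in set(self.vertices)

    def degree(self, v) -> int:
        return sum(1 for e in self.edges if v in e)

    def neighbors(self, v) -> set:
        return {u if w == v else w for (u, w) in self.edges if v in (u, w)}

    # -- subgraph operations ----------------------------------------------

    def induced(self, subset: Iterable) -> "UndirectedGraph":
        """Vertex-induced subgraph on ``subset`` (must be a subset of V)."""
        s = set(subset)
        missing = s - set(self.vertices)
        if missing:
            raise GraphInputError(f"vertices not in graph: {sorted(missing)!r}")
        edges = {e for e in self.edges if e[0] in s and e[1] in s}
        return UndirectedGraph(vertices=tuple(sorted(s)), edges=frozenset(edges))

    def remove(self, subset: Iterable) -> "UndirectedGraph":
        """Graph with ``subset`` and all incident edges deleted."""
        s = set(subset)
        keep = [v for v in self.vertices if v not in s]
        edges = {e for e in self.edges if e[0] not in s and e[1] not in s}
        return UndirectedGraph(vertices=tuple(keep), edges=frozenset(edges))

    def induced_edge_count(self, subset: Iterable) -> int:
        s = set(subset)
        return sum(1 for e in self.edges if e[0] in s and e[1] in s)


def density(G: UndirectedGraph) -> Fraction:
    """Exact density |E|/|V| of ``G``.

    Raises :class:`GraphInputError` on an empty vertex set.
    """
    if G.n == 0:
        raise GraphInputError("density of the empty graph is undefined")
    return Fraction(G.m, G.n)


@dataclass(frozen=True)
class SubgraphResult:
    """A vertex-induced subgraph reported by one of the extraction methods.

    ``density`` is always the exact rational recount ``edge_count / |vertices|``
    on the *original* graph, never an LP objective value.
    """

    vertices: tuple
    edge_count: int
    density: Fraction
    method: str

    @classmethod
    def from_subset(cls, G: UndirectedGraph, subset: Iterable, method: str) -> "SubgraphResult":
        s = tuple(sorted(set(subset)))
        if not s:
            raise GraphInputError("empty vertex subset")
        missing = set(s) - set(G.vertices)
        if missing:
            raise GraphInputError(f"vertices not in graph: {sorted(missing)!r}")
        m = G.induced_edge_count(s)
        return cls(vertices=s, edge_count=m, density=Fraction(m, len(s)), method=method)

    @property
    def vertex_set(self) -> frozenset:
        return frozenset(self.vertices)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_densest(G: UndirectedGraph, cap: int = BRUTE_FORCE_CAP):
    """Exhaustive densest-subgraph oracle for tiny graphs.

    Enumerates all ``2^|V| - 1`` non-empty vertex subsets with a bitmask
    dynamic program and returns ``(max_density, all_densest)`` where
    ``all_densest`` is the sorted list of *every* vertex subset (as frozensets)
    attaining the maximum induced density.

    This is the independent ground truth that the LP/ILP solvers are tested
    against; it shares no code with them.
    """
    n = G.n
    if n == 0:
        raise GraphInputError("empty graph")
    if n > cap:
        raise GraphInputError(f"brute force limited to {cap} vertices, got {n}")
    verts = list(G.vertices)
    index = {v: i for i, v in enumerate(verts)}
    adj = [0] * n
    for u, v in G.edges:
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]

    size = 1 << n
    edge_count = [0] * size
    best = Fraction(0)
    best_masks: list[int] = []
    for mask in range(1, size):
        low = mask & -mask
        i = low.bit_length() - 1
        rest = mask ^ low
        edge_count[mask] = edge_count[rest] + (adj[i] & rest).bit_count()
        d = Fraction(edge_count[mask], mask.bit_count())
        if d > best:
            best = d
            best_masks = [mask]
        elif d == best:
            best_masks.append(mask)
    all_densest = sorted(
        (frozenset(verts[i] for i in range(n) if mask >> i & 1) for mask in best_masks),
        key=lambda s: (len(s), sorted(s)),
    )
    return best, all_densest


def minimal_densest_sets(all_densest: Sequence[frozenset]) -> list[frozenset]:
    """Inclusion-minimal members of an oracle ``all_densest`` list."""
    return [
        s
        for s in all_densest
        if not any(t < s for t in all_densest)
    ]


# ---------------------------------------------------------------------------
# Edge-list text format
# ---------------------------------------------------------------------------
# One edge per line: two whitespace-separated vertex identifiers.  Lines
# beginning with '#' are comments, except '#vertex <id>' which declares a
# (possibly isolated) vertex.

def parse_edge_list(text: str) -> UndirectedGraph:
    edges = []
    vertices = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "vertex":
                if len(parts) != 2:
                    raise GraphInputError(f"line {lineno}: malformed '#vertex' header")
                vertices.append(parts[1])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphInputError(
                f"line {lineno}: expected two vertex identifiers, got {len(parts)}"
            )
        edges.append((parts[0], parts[1]))
    return UndirectedGraph.from_edges(edges, vertices)


def format_edge_list(G: UndirectedGraph, header: str = "") -> str:
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    endpoint = set()
    for u, v in G.edges:
        endpoint.add(u)
        endpoint.add(v)
    for v in G.vertices:
        if v not in endpoint:
            lines.append(f"#vertex {v}")
    for u, v in sorted(G.edges):
        lines.append(f"{u} {v}")
    return "\n".join(lines) + "\n"
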