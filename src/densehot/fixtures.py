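"""Deterministic synthetic inputs: random graphs, planted-dense graphs, and
toy multi-chain structures with prescribed inter-chain contacts.

The toy structures are deliberately minimal — one carbon atom per residue —
so the contact rule reduces to a single exact threshold,
``1.70 + 1.70 + 2.75 = 6.15`` Angstrom, and prescribed contact geometry can
be laid out and verified exactly.  Every emitted file is round-tripped
through the structure parser and network builder before it is accepted.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np

from .graph import GraphInputError, UndirectedGraph

__all__ = [
    "CARBON_CONTACT_CUTOFF",
    "PlantedGraphSpec",
    "ToyComplexSpec",
    "random_graph",
    "planted_graph",
    "toy_structure_pdb",
    "write_toy_structure",
    "demo_k4_k3_k2",
]

#: Contact threshold between two single-carbon residues: r_C + r_C + 2.75.
CARBON_CONTACT_CUTOFF = 1.70 + 1.70 + 2.75  # 6.15 A

#: Realized distance for a prescribed contact (safely under the cutoff) and
#: minimum separation for a prescribed non-contact (safely over it).
CONTACT_DISTANCE = 5.5
SEPARATION_DISTANCE = 8.0


def random_graph(n: int, p: float, seed: int) -> UndirectedGraph:
    """Erdos-Renyi G(n, p) on vertices 0..n-1, reproducible per seed."""
    if n < 1:
        raise GraphInputError(f"need n >= 1, got {n}")
    if not 0.0 <= p <= 1.0:
        raise GraphInputError(f"edge probability must be in [0, 1], got {p}")
    g = nx.gnp_random_graph(n, p, seed=seed)
    return UndirectedGraph.from_edges(g.edges, vertices=g.nodes)


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Sparse background plus planted dense blocks on disjoint vertex sets."""

    background_vertex_count: int
    background_edge_probability: float
    planted_blocks: Tuple[Tuple[int, float], ...]  # (size, internal edge density)
    seed: int = 0


def planted_graph(spec: PlantedGraphSpec) -> Tuple[UndirectedGraph, List[frozenset]]:
    """Sample a planted-dense graph; returns (graph, ground-truth blocks).

    Blocks occupy the lowest vertex labels; background edges are sampled only
    on pairs not internal to a block, so planted structure is never diluted.
    """
    n = spec.background_vertex_count
    sizes = [s for s, _ in spec.planted_blocks]
    if sum(sizes) > n:
        raise GraphInputError("planted blocks exceed the vertex count")
    rng = random.Random(spec.seed)
    blocks: List[frozenset] = []
    edges = set()
    start = 0
    for size, dens in spec.planted_blocks:
        if size < 2 or not 0.0 < dens <= 1.0:
            raise GraphInputError(f"bad planted block ({size}, {dens})")
        members = list(range(start, start + size))
        start += size
        blocks.append(frozenset(members))
        pairs = [(u, v) for i, u in enumerate(members) for v in members[i + 1:]]
        if dens >= 1.0:
            edges.update(pairs)
        else:
            for e in pairs:
                if rng.random() < dens:
                    edges.add(e)
    block_of = {}
    for b_idx, b in enumerate(blocks):
        for v in b:
            block_of[v] = b_idx
    for u in range(n):
        for v in range(u + 1, n):
            if block_of.get(u) is not None and block_of.get(u) == block_of.get(v):
                continue
            if rng.random() < spec.background_edge_probability:
                edges.add((u, v))
    return UndirectedGraph.from_edges(edges, vertices=range(n)), blocks


# ---------------------------------------------------------------------------
# Toy multi-chain structures
# ---------------------------------------------------------------------------

Residue = Tuple[str, int]  # (chain_id, residue_number)


@dataclass(frozen=True)
class ToyComplexSpec:
    """A toy complex: chains of single-carbon residues plus the exact set of
    inter-chain residue pairs that must be in contact."""

    chains: Tuple[Tuple[str, int], ...]           # (chain_id, residue count)
    contact_pairs: Tuple[Tuple[Residue, Residue], ...] = ()
    spacing: float = 30.0                          # component separation, A
    seed: int = 0

    def residues(self) -> List[Residue]:
        out = []
        for chain_id, count in self.chains:
            out.extend((chain_id, i + 1) for i in range(count))
        return out


def _validate_spec(spec: ToyComplexSpec) -> List[Residue]:
    residues = spec.residues()
    if len(set(residues)) != len(residues):
        raise GraphInputError("duplicate chain ids in spec")
    known = set(residues)
    for a, b in spec.contact_pairs:
        a, b = tuple(a), tuple(b)
        if a not in known or b not in known:
            raise GraphInputError(f"contact pair {a}-{b} references unknown residues")
        if a[0] == b[0]:
            raise GraphInputError(
                f"contact pair {a}-{b} is intra-chain; only inter-chain contacts exist"
            )
    return residues


def _fibonacci_ball(k: int, radius: float) -> np.ndarray:
    """k points on a sphere of given radius (pairwise <= 2*radius apart)."""
    if k == 1:
        return np.zeros((1, 3))
    pts = []
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for i in range(k):
        z = 1.0 - 2.0 * i / (k - 1) if k > 1 else 0.0
        r = math.sqrt(max(0.0, 1.0 - z * z))
        th = golden * i
        pts.append((r * math.cos(th) * radius, r * math.sin(th) * radius, z * radius))
    return np.asarray(pts)


def _embed_component(
    members: List[Residue],
    edges: set,
    rng: random.Random,
) -> np.ndarray:
    """3D coordinates realizing exactly the prescribed inter-chain contacts.

    A component whose inter-chain pairs are all contacts fits inside a small
    ball (every pairwise distance under the cutoff).  Otherwise a seeded
    push-pull relaxation moves contact pairs under CONTACT_DISTANCE and
    inter-chain non-contact pairs beyond SEPARATION_DISTANCE.  The caller
    verifies the realized contact graph; failure to converge is reported as
    an unsatisfiable geometry.
    """
    k = len(members)
    inter = [
        (i, j)
        for i in range(k)
        for j in range(i + 1, k)
        if members[i][0] != members[j][0]
    ]
    if all((members[i], members[j]) in edges or (members[j], members[i]) in edges
           for i, j in inter):
        return _fibonacci_ball(k, radius=2.5)

    pos = np.array([[rng.uniform(-4, 4) for _ in range(3)] for _ in range(k)])
    edge_idx = [
        (i, j)
        for i, j in inter
        if (members[i], members[j]) in edges or (members[j], members[i]) in edges
    ]
    non_idx = [ij for ij in inter if ij not in set(edge_idx)]
    for _ in range(800):
        moved = False
        for i, j in edge_idx:
            delta = pos[j] - pos[i]
            d = np.linalg.norm(delta)
            if d > CONTACT_DISTANCE:
                shift = 0.5 * (d - CONTACT_DISTANCE) * delta / max(d, 1e-9)
                pos[i] += shift
                pos[j] -= shift
                moved = True
        for i, j in non_idx:
            delta = pos[j] - pos[i]
            d = np.linalg.norm(delta)
            if d < SEPARATION_DISTANCE:
                if d < 1e-9:
                    delta = np.array([rng.uniform(-1, 1) for _ in range(3)])
                    d = np.linalg.norm(delta)
                shift = 0.5 * (SEPARATION_DISTANCE - d) * delta / max(d, 1e-9)
                pos[i] -= shift
                pos[j] += shift
                moved = True
        if not moved:
            break
    return pos


def toy_coordinates(spec: ToyComplexSpec) -> Dict[Residue, np.ndarray]:
    """Coordinates for every residue in the spec, contact-exact.

    Raises :class:`~densehot.graph.GraphInputError` when the prescribed
    contact pattern cannot be realized in 3D at the toy thresholds.
    """
    residues = _validate_spec(spec)
    edges = {(tuple(a), tuple(b)) for a, b in spec.contact_pairs}
    edges |= {(b, a) for a, b in edges}

    g = nx.Graph()
    g.add_nodes_from(residues)
    g.add_edges_from((tuple(a), tuple(b)) for a, b in spec.contact_pairs)
    rng = random.Random(spec.seed)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort()

    gap = max(spec.spacing, 3 * SEPARATION_DISTANCE)
    side = max(1, math.ceil(len(components) ** (1.0 / 3.0)))
    coords: Dict[Residue, np.ndarray] = {}
    for c_idx, members in enumerate(components):
        local = _embed_component(members, edges, rng)
        offset = gap * np.array(
            [c_idx % side, (c_idx // side) % side, c_idx // (side * side)], dtype=float
        )
        for res, xyz in zip(members, local):
            coords[res] = xyz + offset

    # exactness check: realized contact graph must equal the prescription
    flat = list(coords)
    for i, a in enumerate(flat):
        for b in flat[i + 1:]:
            if a[0] == b[0]:
                continue
            d = float(np.linalg.norm(coords[a] - coords[b]))
            want = (a, b) in edges
            if want and d > CARBON_CONTACT_CUTOFF - 0.05:
                raise GraphInputError(
                    f"unsatisfiable geometry: contact {a}-{b} realized at {d:.2f} A"
                )
            if not want and d < CARBON_CONTACT_CUTOFF + 0.05:
                raise GraphInputError(
                    f"unsatisfiable geometry: non-contact {a}-{b} realized at {d:.2f} A"
                )
    return coords


def toy_structure_pdb(spec: ToyComplexSpec) -> str:
    """PDB text for a toy complex: one GLY residue = one carbon atom.

    The header remarks embed the spec and seed for reproducibility.
    """
    coords = toy_coordinates(spec)
    lines = [
        "REMARK 300 synthetic toy complex (single-carbon residues)",
        f"REMARK 300 seed={spec.seed} chains={list(spec.chains)!r}",
        f"REMARK 300 contacts={[(tuple(a), tuple(b)) for a, b in spec.contact_pairs]!r}",
    ]
    serial = 1
    for chain_id, count in spec.chains:
        for num in range(1, count + 1):
            x, y, z = coords[(chain_id, num)]
            lines.append(
                f"ATOM  {serial:5d}  CA  GLY {chain_id}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f" C  "
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_toy_structure(spec: ToyComplexSpec, path) -> str:
    """Write the toy complex PDB file; returns the path written."""
    text = toy_structure_pdb(spec)
    with open(path, "w") as fh:
        fh.write(text)
    return str(path)


def demo_k4_k3_k2() -> Tuple[ToyComplexSpec, UndirectedGraph]:
    """The K4 + K3 + K2 worked example as a toy complex.

    Each clique vertex is a single-residue chain (a clique is not bipartite,
    and contacts are strictly inter-chain), so the abstract contact graph is
    exactly the disjoint union of a 4-clique, a triangle and an edge.
    """
    chains = tuple((c, 1) for c in "ABCDEFGHI")
    k4 = ["A", "B", "C", "D"]
    k3 = ["E", "F", "G"]
    k2 = ["H", "I"]
    pairs = []
    for group in (k4, k3, k2):
        for i, u in enumerate(group):
            for v in group[i + 1:]:
                pairs.append(((u, 1), (v, 1)))
    spec = ToyComplexSpec(chains=chains, contact_pairs=tuple(pairs))
    graph = UndirectedGraph.from_edges(
        ((f"{u}:1", f"{v}:1") for (u, _), (v, _) in pairs)
    )
    return spec, graph
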