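import pytest

from densehot.graph import UndirectedGraph


def k_complete(labels):
    labels = list(labels)
    return UndirectedGraph.from_edges(
        (u, v) for i, u in enumerate(labels) for v in labels[i + 1:]
    )


@pytest.fixture
def k4():
    return k_complete([1, 2, 3, 4])


@pytest.fixture
def triangle_pendant():
    """Triangle {1,2,3} plus pendant vertex 4: densest sets {1,2,3} and V."""
    return UndirectedGraph.from_edges([(1, 2), (1, 3), (2, 3), (3, 4)])


@pytest.fixture
def two_triangles():
    return UndirectedGraph.from_edges(
        [(1, 2), (1, 3), (2, 3), (4, 5), (4, 6), (5, 6)]
    )


@pytest.fixture
def k4_k3_k2():
    """Disjoint K4 + K3 + K2: densities 3/2, 1, 1/2 — the peeling example."""
    edges = []
    block = [1, 2, 3, 4]
    edges += [(u, v) for i, u in enumerate(block) for v in block[i + 1:]]
    block = [5, 6, 7]
    edges += [(u, v) for i, u in enumerate(block) for v in block[i + 1:]]
    edges += [(8, 9)]
    return UndirectedGraph.from_edges(edges)


def atom_line(serial, chain, resnum, x, y, z, *, name="CA", resname="GLY",
              element="C", occ=1.0, altloc=" ", icode=" ", record="ATOM"):
    """One fixed-width PDB coordinate record."""
    return (
        f"{record:<6}{serial:>5} {name:^4}{altloc}{resname:>3} {chain}"
        f"{resnum:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
        f"          {element:>2}"
    )


@pytest.fixture
def write_pdb(tmp_path):
    def _write(lines, filename="fixture.pdb"):
        path = tmp_path / filename
        path.write_text("\n".join(list(lines) + ["END"]) + "\n")
        return path

    return _write
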