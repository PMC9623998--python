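# densehot

Densest-subgraph extraction on residue interaction networks for predicting
protein–protein interaction **hot spots** — the interface residues whose
mutation to alanine raises the binding free energy by ΔΔG ≥ 2.0 kcal/mol.

Experimental hot-spot annotation (alanine-scanning mutagenesis) is sparse and
expensive, and many true hot spots are never assayed. `densehot` takes the
opposite, data-free route: it builds a residue interaction network directly
from the 3D structure of a complex and predicts hot spots purely from network
topology, by extracting vertex-induced subgraphs of high density. High density
(high average degree) marks tightly packed inter-chain contact clusters —
exactly where binding energy concentrates.

## The methods

For an undirected graph *G = (V, E)* the density is ρ(*G*) = |*E*|/|*V*|, and
*D* denotes the maximum density over all vertex-induced subgraphs. Four exact
extraction methods are provided, all solved with LP/ILP (HiGHS via SciPy) and
all cross-checked in exact rational arithmetic:

| method | output |
|---|---|
| **DS** | one densest subgraph, from the LP relaxation: maximise Σ x\_ij s.t. x\_ij ≤ y\_i, x\_ij ≤ y\_j, Σ y\_i ≤ 1; the vertices with y\_i ≥ 1/\|V\| induce a densest subgraph |
| **Min-DS** | *all* minimal densest subgraphs (no proper subgraph is densest); they are pairwise disjoint and found by peel-and-repeat |
| **Max-DS** | the unique *maximal* densest subgraph — the union of all densest subgraphs — via an ILP with binary selection variables, or equivalently by iterative LP growth |
| **Min-SDS** | disjoint minimal dense subgraphs peeled while ρ ≥ θ·*D* for a tolerance θ ∈ (0, 1) (default 0.85); the main prediction method, built to cover secondary binding interfaces |

The residue interaction network puts an edge between residues of *different*
chains whenever some atom pair is closer than r(a) + r(b) + 2.75 Å (van der
Waals radii plus one water diameter). Predictions are scored against
alanine-scanning labels (ΔG = RT ln K\_d at 298.15 K, SKEMPI-style tables)
with precision, recall, F1 and F2.

## Worked example

The bundled fixture is a toy complex whose inter-chain contact pattern is a
disjoint K4 ⊔ K3 ⊔ K2 (densities 3/2, 1 and 1/2):

```sh
densehot make-fixtures fx
densehot predict --graph fx/k4_k3_k2.edges --method min-sds --theta 0.6
```

```json
{
  "report_version": 1,
  "method": "min-sds",
  "theta": 0.6,
  "subgraphs": [
    {"vertices": ["A:1", "B:1", "C:1", "D:1"],
     "edge_count": 6, "density_fraction": "3/2", "density": 1.5},
    {"vertices": ["E:1", "F:1", "G:1"],
     "edge_count": 3, "density_fraction": "1/1", "density": 1.0}
  ]
}
```

The maximum density is *D* = 3/2 (the K4). At θ = 0.6 the stopping threshold
is θ·*D* = 0.9, so peeling keeps the K4 (ρ = 3/2) and the triangle (ρ = 1) and
stops at the edge (ρ = 1/2 < 0.9). At θ = 0.9 only the K4 survives; at θ = 0.3
all three blocks are returned. The same pipeline runs from the structure file
(`--structure fx/k4_k3_k2.pdb`), and `densehot evaluate` / `densehot
sweep-theta` score reports against a mutation table.

Library use mirrors the CLI:

```python
from densehot import parse_edge_list, min_sds
G = parse_edge_list(open("fx/k4_k3_k2.edges").read())
for sub in min_sds(G, theta=0.6):
    print(sub.vertices, sub.density)   # exact fractions: 3/2 then 1
```

## Layout

- `src/densehot/graph.py` — graph container, exact rational density, brute-force oracle, edge-list I/O
- `src/densehot/solvers.py` — BasicLP, Min-DS, MaxILP/MaxLP, Min-SDS
- `src/densehot/rin.py` — structure parsing (gemmi) and contact networks
- `src/densehot/hotspots.py` — ΔΔG labelling, SKEMPI parsing, metrics
- `src/densehot/fixtures.py` — synthetic graphs and toy structure files
- `src/densehot/cli.py` — `densehot` command-line front end
- `docs/methods.md` — models, conventions and numerical choices
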