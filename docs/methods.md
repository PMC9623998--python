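# Methods

## Problem and model

A protein complex is reduced to an undirected *residue interaction network*:
vertices are residues, and an edge joins two residues of different chains
whenever some atom pair (a, b), one atom from each residue, satisfies

    d(a, b) ≤ r(a) + r(b) + 2.75 Å

with r the van der Waals radius and 2.75 Å the diameter of a water molecule
(the gap can accommodate at most one bridging water). Only residues with at
least one contact become vertices, so every vertex has degree ≥ 1 and no
intra-chain edge exists. Hot-spot prediction is then treated as a pure graph
problem: find the vertices of high-density subgraphs, where the density of
G = (V, E) is ρ(G) = |E|/|V|.

The biological premise is that binding free energy concentrates in tightly
packed interface clusters, which appear as locally dense regions of the
contact graph. Because experimental hot-spot annotation is sparse (a residue
never assayed is not a confirmed negative), the evaluation emphasises recall:
F2 (β = 2) is the headline score.

## Exact density arithmetic

Every density in the package is a `fractions.Fraction`. Comparisons that
drive control flow — the peeling stop rules of Min-DS and Min-SDS, the
equality checks between extracted subgraphs and the maximum density D — are
exact integer cross-multiplications. Floating-point LP/ILP objectives are
used only two ways: (i) compared against a rational recount with tolerance
1e-5 as a sanity guard, and (ii) supplied as the bound of the
`Σ x_ij ≥ D` constraint, slackened by 1e-9. Densities of distinct subgraphs
of an n-vertex graph differ by at least 1/n², so the 1e-9 slack can never
admit a strictly sparser subgraph at any realistic n, and the rational
recount would catch it if it did. The Min-SDS tolerance θ is converted to an
exact fraction through its decimal string (0.85 → 17/20), so θ·D is rational
and the stop rule ρ(R) < θ·D is exact; a peel whose density equals θ·D
exactly is *kept* (stopping only on strict inequality).

## Solvers

LP and ILP are solved with HiGHS through `scipy.optimize.linprog` /
`scipy.optimize.milp`.

**DS.** The LP relaxation (variables x_ij per edge, y_i per vertex; maximise
Σ x_ij subject to x_ij ≤ y_i, x_ij ≤ y_j, Σ y_i ≤ 1) has optimal objective D,
and for any optimal solution the set {i : y_i ≥ 1/|V|} induces a densest
subgraph; membership uses tolerance ε = 1e-6. At any optimum the whole y
budget is spent productively, so isolated vertices can never be selected.

**Min-DS.** A minimal densest subgraph is realised as the
minimum-cardinality densest subgraph: ILP with binary z_i, continuous x, y;
minimise Σ z_i under the LP constraints, Σ x_ij ≥ D and y_i ≤ z_i. Minimum
cardinality implies inclusion-minimality. Ties are broken to the
lexicographically least vertex set by greedy fixing: with the optimal
cardinality k known, vertices are scanned in sorted order and forced into the
set when a feasibility ILP (same constraints, Σ z_i = k, forced/excluded
vertices pinned via variable bounds) still admits a size-k densest subgraph;
the most recent feasible solution is kept as a witness so a solve is only
needed when the greedy choice leaves the witness. All minimal densest
subgraphs are enumerated by peeling: distinct minimal densest subgraphs are
vertex-disjoint (two intersecting densest subgraphs have a densest
intersection, by the standard supermodularity argument), removing one cannot
create a new densest subgraph (induced subgraphs of the remainder are
induced subgraphs of the original), and minimality is preserved under
removal — so repeat *find-one / delete* until the remaining graph's minimal
densest subgraph falls below D.

**Max-DS.** The maximal densest subgraph (the union of all densest
subgraphs; it is unique) is found two independent ways, which must agree:
(a) an ILP maximising Σ z_i under the LP constraints, Σ x_ij ≥ D and
y_i ≥ z_i/|V|; (b) iterative growth: start from one densest subgraph R and
test each remaining vertex v once by solving the LP with the extra
constraints Σ x_ij ≥ D and y_i ≥ 1/|V| for i ∈ R ∪ {v} — feasible exactly
when v belongs to some densest subgraph, because the union of two densest
subgraphs is densest, so R remains densest as it absorbs each feasible
selection. This costs at most |V| grow-LP calls. Growth is anchored to a
named vertex rather than merely demanding extra y-mass outside R
(Σ_{i∉R} y_i ≥ 1/|V|), because the latter admits alternative LP optima
that split the outside mass across several vertices, each below the 1/|V|
selection threshold — the re-thresholded selection then collapses back to R
and the loop stalls before reaching the maximal set.

**Min-SDS.** Identical peeling to Min-DS but with the relaxed stop rule
ρ(R) < θ·D, θ ∈ (0, 1), D fixed to the *original* graph's maximum density.
Smaller θ admits sparser secondary regions (more recall, less precision);
θ = 0.85 is the default operating point. Peeling is deterministic, so for
θ₁ < θ₂ the θ₂ result sequence is a prefix of the θ₁ sequence, and as θ → 1⁻
the output converges to the Min-DS list.

Every extracted subgraph is recounted on the original graph before being
returned; a recount that disagrees with the expected D raises an extraction
error rather than returning a silently wrong set.

## Contact-network conventions

- **Radii:** Bondi (1964) values — C 1.70, N 1.55, O 1.52, S 1.80, H 1.20,
  P 1.80 Å — with a 1.80 Å fallback for other elements (logged). The table
  lives in `RinOptions` and can be swapped.
- **Parsing:** gemmi; first model only; polymer amino acids only; waters and
  HETATM groups excluded except MSE, which is kept and renamed MET;
  hydrogens used when present (no placement); alternate locations resolved
  to the highest-occupancy conformer, ties to label 'A'.
- **Search:** a KD-tree prefilter at the maximum possible cutoff
  (2·max radius + 2.75 Å) followed by the exact per-element test; verified in
  tests to equal the all-pairs double loop.
- **Scope:** all chains of the first model. Selecting biological assemblies
  (or filtering complexes by assembly ambiguity) is dataset curation, outside
  the builder.

## Hot-spot labelling and evaluation

ΔG = RT ln K_d with RT = (8.314/4184)·(273.15 + 25.0) ≈ 0.59248 kcal/mol;
temperature is fixed at 298.15 K regardless of per-experiment conditions, for
consistency across records. ΔΔG = ΔG_mut − ΔG_wt = RT ln(K_mut/K_wt); a
residue is a hot spot when ΔΔG ≥ 2.0 kcal/mol (inclusive) in some alanine
mutation. Replicates aggregate by max ΔΔG by default (any qualifying
experiment marks the residue; 'mean' is available). Records whose wild-type
amino acid contradicts the structure are skipped with a warning. Predicted
residues without a label count as false positives; labelled hot spots absent
from the network are excluded from the false negatives by default (no graph
method can reach them) with an option to include them. Zero-denominator
conventions: empty prediction has precision 0; undefined F-scores are 0.
Per-complex metrics aggregate as unweighted means.

SKEMPI-style tables are semicolon-separated with a configurable column map;
mutation fields such as `TI38A` decompose as wild-type / chain / position
(optional lowercase insertion code) / mutant. Only single-point mutations are
used.

## Synthetic data

The generator provides three kinds of inputs:

- **Erdős–Rényi graphs** G(n, p), seeded, for the solver-vs-oracle battery.
  The battery uses n ∈ {6..12} and p ∈ {0.2, 0.5, 0.8} — small enough for
  exhaustive 2ⁿ enumeration, dense and sparse enough to produce degenerate
  ties, multiple densest subgraphs and disconnected optima.
- **Planted graphs:** disjoint near-clique blocks over a sparse background,
  with ground truth returned, for recovery tests.
- **Toy complexes:** chains of single-carbon (GLY, one CA atom) residues with
  a prescribed inter-chain contact set. With only carbon the threshold is
  exactly 1.70 + 1.70 + 2.75 = 6.15 Å. Per connected component, an
  all-contact pattern is placed inside a 2.5 Å-radius ball (every pairwise
  distance < 6.15 Å); other patterns are embedded by a seeded push–pull
  relaxation (contacts pulled under 5.5 Å, inter-chain non-contacts pushed
  past 8 Å); components sit ≥ 30 Å apart on a grid. The emitted file is
  verified by re-deriving its contact graph with a ±0.05 Å margin; an
  unrealizable prescription (e.g. a 60-leaf star) raises an input error. A
  clique contact pattern uses one single-residue chain per vertex, since
  cliques are not bipartite and contacts are strictly inter-chain.

What the toys deliberately lack: real side-chain geometry, mixed elements,
crowded intra-chain packing, crystallographic artefacts. Passing tests
demonstrate the graph machinery and the contact rule's boundary behaviour
exactly; they do not validate biological prediction quality, which requires
curated structures and affinity data.

## Determinism and limitations

All randomness is seeded; vertex order (lexicographic) fixes every
tie-break, so identical inputs give byte-identical reports. The brute-force
oracle is capped at 15 vertices (2ⁿ enumeration). The lexicographic
tie-break costs up to |V| feasibility ILPs per peel in the worst case; for
typical interaction networks (hundreds of residues) the witness-reuse
shortcut keeps the count near the number of deviations from the first
optimum. Weighted/directed density variants, flow-based exact algorithms and
peeling approximations are out of scope, as are biological-assembly
expansion and protonation.
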