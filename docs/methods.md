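# Methods

## Molecular graphs

Ligands are undirected labeled graphs: nodes carry element symbols,
edges carry one of four bond labels — `single`, `double`, `triple` and a
dedicated `aromatic` type that never matches single or double bonds.
Hydrogens are implicit; charges, isotopes and stereochemistry are
dropped, because the substructure patterns are defined purely over
element and bond labels. Multi-fragment inputs (salts) keep the largest
fragment only: the miner requires connected substructures of connected
parents. Molecular weights come from RDKit (`Descriptors.MolWt`) on the
kept fragment.

## Dataset filters

A compound is active when any record reports Ki/IC50/EC **strictly
below 10 µM**, or reports an affinity with no numeric value (the
convention of source databases that list actives without potencies).
The boundary value 10.0 µM is excluded. Molecular-weight bounds are
inclusive: 50 ≤ MW ≤ 700 Da. A molecule joins a class if *any* of its
records qualifies; duplicate (molecule, target) memberships collapse to
one. Targets need ≥ 20 surviving ligands. Filtering is idempotent and
classes are ordered lexicographically by target id, so reruns are
byte-stable.

## Frequent substructure mining

For each class the miner returns exactly the connected labeled
subgraphs contained in at least `ceil(f·n)` of the n class molecules
(default f = 0.30; containment counted once per molecule regardless of
embedding multiplicity). `ceil` is computed as `ceil(f·n − 1e−9)`
because binary floats overshoot (0.3 × 10 would otherwise round up
to 4).

The search is level-wise a-priori. Single atoms seed level 0; each
stored pattern is extended by one edge — to a new atom, or closing a
ring between mapped atoms — with candidate extensions read off the
pattern's embedding list, so only substructures that actually occur are
ever constructed, and no extension of an infrequent pattern is
generated. Embedding lists (all monomorphisms, all molecules) are grown
along with the patterns; a pattern's support is the number of distinct
molecules among its embeddings. Duplicates are removed by canonical
code. Input molecules are sorted by ascending bond count, a memory
optimisation that provably cannot change the result (and is tested not
to). Single atoms are reported by the miner — the ≥ 50 Da fragment
filter is a separate downstream stage, which keeps the exhaustive-oracle
equivalence tests clean.

**Canonical codes.** Each pattern's identifier is the lexicographically
minimal connected-construction code: vertices are emitted one at a time,
each attached to earlier vertices, and the minimal token sequence over
all valid emission orders is taken (Weisfeiler–Lehman color refinement
restricts start vertices and prunes the backtracking; branching is
bounded by graph automorphisms in practice). The code is
self-describing — `C()|C(0a)|O(1s)` decodes back into atoms and bonds —
which makes serialized results and occurrence lookups self-contained.
Only uniqueness-per-isomorphism-class is contractual; permutation
invariance is tested over thousands of random relabelings.

**Fragment masses.** Implicit hydrogens per atom = standard valence −
Σ(bond orders), with aromatic bonds counted 1.5 and fractional totals
floored, clamped at ≥ 0. A lone O therefore weighs as water (18.02 Da),
C–C as ethane (30.07 Da), the aromatic 6-ring as benzene (78.11 Da).

**Dominance cap.** A class whose pattern count exceeds 10⁶, or exceeds
1000 × the median count of the other classes, keeps only patterns that
also occur in another class's result. Both rules are checked per class
against the others' median; the capped flag is recorded. The union of
per-class frequent sets remains downward-closed under this cap (any
kept pattern lives in some uncapped result, which contains all its
sub-patterns), a property the occurrence machinery relies on.

## Profiles and ligand-space distance

The per-class frequent sets are merged, duplicates removed, fragments
under 50 Da discarded, and the relative frequency `f(s, c)` of every
merged pattern is computed for **every** class — including classes where
s was not frequent — from a persistent occurrence table (pattern →
molecule-id set). That table is built in one embedding-extension pass
over the whole molecule set, walking only the merged pattern lattice;
this is exactly equivalent to per-pair subgraph-isomorphism tests
(cross-checked in the suite) and an order of magnitude faster.

Target distance: `d_raw = 1 − r` with r the Pearson correlation of the
two profile columns over all merged patterns. Relative frequencies (not
raw counts) are used so class size does not bias similarity. The final
matrix min-max rescales the off-diagonal entries to [0, 1]; the zero
diagonal is excluded from the rescale so the closest observed pair maps
to 0. If all off-diagonal distances are equal the matrix degenerates to
zeros with a warning. A constant (zero-variance) profile column is an
error naming the offending target, since it cannot be correlated.

## Trees

Neighbor-Joining is implemented directly (Saitou–Nei with the
Studier–Keppler Q-criterion) rather than delegated to a library, because
the consensus procedure randomizes the taxon *input order* and depends
on order-sensitive tie-breaking: ties in Q resolve toward the smallest
(i, j) index pair of the current matrix, so permuting the input can
change which equally-good join is made — the behaviour the 10-fold
randomization is designed to average out. On additive matrices NJ is
exact (topology and branch lengths; tested on random additive trees to
1e−9). Negative branch lengths are clamped to zero with the deficit
logged.

The consensus is plain majority rule: exactly the bipartitions in
strictly more than half of the 10 trees, supports = bipartition
frequencies (independently recounted in tests; a PHYLIP-consense-style
"extended" mode that greedily adds compatible minority splits is behind
a flag). Consensus trees have no lengths of their own, so the first
replicate tree's lengths are mapped onto matching bipartitions (zero
where unmatched) — enough to midpoint-root; consensus topologies are
reported as topology + support, not as metric trees.

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path; ties between equally long pairs break lexicographically by the
(name, name) pair. An all-zero-length tree is rooted at an arbitrary
internal node with a warning. Trees are scikit-bio `TreeNode` objects;
Newick round-trips preserve topology, lengths and supports (supports
ride as internal labels).

## Sequence space

The MSA is an input; this package never aligns. Built-in distances are
the p-distance (mismatch fraction over pairwise-complete columns, i.e.
columns where neither sequence of the pair has a gap) and its Poisson
correction −ln(1 − p), with saturated pairs (p = 1) set to a
configurable ceiling (default 10) with a warning. Maximum-likelihood
protein distances (e.g. JTT) are deliberately not reimplemented: for an
exact reproduction of that workflow, import the precomputed PHYLIP
square matrix. Binding-site analyses (30- or 44-residue sets) enter as
1-based column lists. Sequence matrices are not min-max normalized:
de-orphanization consumes ranks only, and the delta-delta comparison
normalizes both spaces on the fly.

## Delta-delta comparison

Both matrices are restricted to the shared label set and min-max
rescaled over the off-diagonal (symmetric treatment of both axes, so
they are comparable), then each receptor's mean distance to all other
shared receptors is computed in each space; the residual is
mean_sequence − mean_substructure, positive when a receptor is
relatively more isolated in sequence space. The mean is the default
statistic; a median option exists. The TSV is the contract; the scatter
plot is decoration.

## Leave-one-out de-orphanization

For each pretended orphan: its column is removed from the frequency
matrix, and every pattern whose within-class frequency reaches the
support threshold **only** in the orphan class is dropped from the rows
(the orphan's private chemistry must not leak into the reduced space);
all other entries are untouched — pure row/column deletion from the
persistent occurrence table, no re-mining. Each orphan ligand gets a
binary presence vector over the remaining rows and is assigned to the
class minimizing the Euclidean distance to the class frequency column
(ties lexicographic, logged; a ligand containing none of the patterns
still gets a prediction and is flagged uninformative). Ligands shared
with other classes stay in those classes' profiles but are still scored
as orphan ligands.

Non-orphan receptors are ranked by ascending sequence distance to the
orphan (ties lexicographic). With y[k] the fraction of orphan ligands
whose predicted class ranks ≤ k, the relative AUC is the mean of y over
k = 1..N−1 (a trapezoid variant is behind a flag). Closed forms: 1.0
best case, 1/(N−1) worst case, expectation N/(2(N−1)) ≈ 0.5 under
uniform ranks — all verified, the last by Monte-Carlo. The summary
reports the fractions of receptors with AUC > 0.5 and > 0.7.

## Synthetic benchmark

The generator plants the one property the method needs: family-coherent
ligand chemistry co-occurring with family-coherent sequences. Each
receptor's ligands decorate a heteroaromatic family scaffold (indole,
purine, quinoline, benzofuran, …) with 1–3 small substituents at open
valence positions (chemistry kept valid by construction); the scaffold
is the receptor's own family's with weight 0.85 versus 0.15 spread over
the other families — setting the weights equal removes the signal, which
is the permutation-null control. Sequences are 300-residue gapless
alignments: one root per family at 0.4 substitutions/site from a common
ancestor, receptors at 0.05 from their root, i.i.d. over 20 amino
acids. Defaults (4 families × 4 receptors × 30 ligands, seed-driven and
byte-reproducible) are the benchmark world used by the tests and the
acceptance script.

What a green benchmark does *not* establish: real ligand sets have
shared pharmacophores without shared scaffolds, activity-type
heterogeneity, promiscuous ligands and alignment gaps; real sequence
divergence is not i.i.d. The benchmark validates the machinery and the
planted-signal recovery, not field performance on database extracts.

## Numerical and degenerate-input choices

- Support threshold `ceil(f·n − 1e−9)`; strict "< 10 µM"; inclusive MW
  bounds.
- Pearson distances symmetrized and diagonal forced to zero before
  rescaling (guards float drift from `corrcoef`).
- NJ ties → smallest index pair; consensus requires strict majority;
  midpoint ties → lexicographic leaf pair.
- PHYLIP matrices: asymmetry beyond 1e−6 is an error; below that the
  matrix is symmetrized by averaging. Labels longer than 10 characters
  are written and read in a relaxed whitespace-delimited dialect (a
  strict padded mode exists for interoperability).
- Retrieval with 2 non-orphan classes degenerates to a single step at
  k = 1; AUC bounds are attained exactly in the best/worst cases.

## Known limitations

- The miner targets molecule-sized labeled graphs; it is exponential in
  pattern count by nature, and pathological inputs (dense highly
  symmetric graphs) will be slow despite the a-priori pruning.
- Consensus branch lengths are borrowed from one replicate, not
  re-estimated; treat consensus trees as topology + support.
- No maximal/closed-pattern condensation, no embedding-count support,
  no tautomer or charge standardization, no alignment construction, no
  ML protein distances (import a matrix instead).
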