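# Methods

## Molecular graph model

A molecule is a simple undirected graph: nodes carry element, formal
charge, an optional partial charge (elementary-charge units) and
optional coordinates; edges carry a bond order (1, 2, 3, or aromatic,
stored as 1.5). Hydrogens are always explicit — matching and charge
bookkeeping are meaningless on a united-atom skeleton — and atom ids
are 0-based and stable (for SDF input, the atom-block order). Parsing
goes through RDKit; aromaticity is whatever the parser perceives, and
no further perception is attempted.

The *matching label* of an atom is the pair (element, total degree in
the full molecule). Bond orders deliberately play no role in matching:
the matching criterion is element plus connectivity, and two atoms
whose neighborhoods agree in those terms are treated as equivalent
even if drawn with different Kekulé structures. Bond orders *are* used
for valence accounting during capping.

Validation enforces: no self or duplicate bonds, per-element degree
bounds (a structural sanity table, not a valence model), and — when
all partial charges are present — agreement between their sum and the
net charge: within 0.5 e as a sanity bound on intermediate states,
within 1e-6 e on finalized (redistributed) molecules.

## k-shell compatibility

Atom `a` of one molecule is *k-compatible* with atom `b` of another
when there is a rooted isomorphism between the subgraphs induced by
their k-balls (all atoms within k bonds) sending `a` to `b` and
preserving every atom's matching label, with degrees taken in the full
molecules. This makes compatibility symmetric and monotone (agreement
out to k implies agreement out to any smaller shell), and at k = 0 it
degenerates to label equality. The shell size k is the resolution
knob: larger shells demand more context and give fewer, higher-quality
matches. The default is 3, the radius at which transferred charges
are, in practice, insensitive to what lies beyond.

## Maximal common fragments

A *common fragment* is a bijective, bond-preserving (in both
directions) mapping between a connected set of query atoms and
reference atoms, in which every mapped pair is k-compatible, and —
the *consistency rule* — the core mapping extends to a single
injective map over the union of the core atoms' k-balls that preserves
labels, adjacency and non-adjacency. The strict single-witness reading
prevents stitching together incompatible per-pair shell witnesses:
two adjacent compatible pairs may only fuse if one environment
isomorphism covers both shells. A fragment is *maximal* when no
single additional compatible adjacent pair extends it consistently.
Since the consistency rule is hereditary (any restriction of a valid
witness is a valid witness), validity-filtered search remains
complete.

### Enumeration algorithm

Enumeration runs on the product graph whose vertices are compatible
atom pairs, with *c*-edges between pairs adjacent in both molecules
and *d*-edges between pairs adjacent in neither (pairs sharing an atom
or disagreeing on adjacency are non-adjacent). Common connected
induced subgraph mappings are exactly the cliques whose c-edge
subgraph is connected. Phase 1 enumerates all maximal c-connected
cliques with a Bron–Kerbosch-style recursion over candidate sets split
into c-reachable (P/X) and d-only (D/Y) parts, using a pivot
restricted to vertices adjacent to all of D (which keeps the classic
branch-covering argument valid for c-cliques) and a domination prune
on excluded vertices. Phase 2 applies the shell-consistency filter:
cliques that fail are shrunk to their maximal valid c-connected
subsets (complete, by heredity), and shrunken candidates get a global
single-pair-extension maximality check.

Self-similar molecules expose the enumeration's inherent worst case:
a reference with many local symmetries (flip-symmetric phenyl rings,
rotatable methyls, equivalent gem-dimethyl branches) has exponentially
many maximal *mappings* that differ only by a reference automorphism
and share one query core. The collapsed mode therefore prunes
symmetry-redundant branches: a candidate pair (q, r₂) is skipped when
an ancestor of the current search node branched (q, r₁) and some
reference automorphism σ with σ(r₂) = r₁ fixes every reference atom
that was in use at that ancestor — every maximal clique through the
candidate then has a σ-image, with the same query core, inside the
already-explored subtree. The automorphisms are found lazily by an
identity-preferring seeded search, gated by Weisfeiler–Lehman colors
and step-budgeted (a budget miss only disables a prune). The raw mode
used by the oracle tests never prunes and returns every maximal
mapping.

The output collapses to one fragment per query core. The reported
mapping is re-derived as the lexicographically smallest valid mapping
of that core (ordered by query atom, then reference atom) rather than
whichever representative enumeration happened to keep; for a
self-match this canonical mapping is the identity, which is what makes
charge recovery from a molecule's own fragments exact. If the
canonical mapping is not itself maximal (possible in principle when a
core admits non-automorphic mappings), the enumerated representative
is kept instead.

An independent brute-force enumerator grows every connected,
consistent set of compatible pairs exhaustively and reports the
unextendable ones. It is exponential and refuses instances above 400
atom-pair products; the test suite asserts exact agreement with the
product-graph enumerator — both raw and collapsed — on hundreds of
seeded random molecule pairs.

## Library matching and charge assignment

`match_library` enumerates fragments against every library entry and
ranks them by size (descending), then library id, then query atom
ids; each fragment reports its total reference charge. Reference
atoms tagged as synthetic caps are excluded from matching outright,
so cap bookkeeping charges can never be transferred. The per-atom
index distinguishes matched atoms from *missing* ones (covered by no
fragment).

Charge transfer appends each mapped reference charge to the query
atom's candidate list with provenance. Equal values collapse
(re-applying a fragment is a no-op); a second distinct value marks the
atom as conflicted. Conflicts are resolved by selecting a candidate,
averaging the *distinct* values (duplicates must not weight the mean),
or entering a manual value. The *residual charge* is
sum(assigned) − target; redistribution subtracts residual/N from every
atom, after which a final fsum-based correction pins the total to the
target within 1e-6 e (in practice exactly), idempotently.

The automated (greedy) protocol replaces interactive fragment
selection: pick a seeded random unassigned atom, apply the largest
fragment covering it — preferring, among equally large candidates,
those that do not overlap atoms already assigned — and repeat until
every matchable atom is covered; then resolve conflicts
(batch default: averaging), redistribute the residual, and optionally
symmetrize. Preferring *any* non-overlapping fragment regardless of
size was rejected: in symmetric molecules it lets one-atom fragments
whose charges come from a topologically equivalent twin elsewhere in
the molecule outrank large consistent fragments, which is chemically
backwards and destroys exact self-recovery. Multi-seed runs report
per-atom mean and standard deviation across starting points; the
spread is computed exactly (identical values give exactly 0).

Symmetrization averages resolved charges within topological
equivalence classes: Weisfeiler–Lehman refinement to a fixed point,
confirmed (up to 150 atoms) by exact automorphism checks between
class members, so refinement's rare false merges are split. Class
means preserve the total charge, and the operation is idempotent.

## Missing fragments, splitting, capping

Unmatched atoms are grouped by connected component; each group's
region is the union of its atoms' k-balls, *closed* under two rules:
a severed ring bond pulls the whole ring into the region, and a
severed multiple-order bond pulls in the partner atom. Closure keeps
ring systems intact ("do not alter the nature of ring structures")
and guarantees every severed bond is an acyclic single bond, so open
valences are integers that hydrogen caps can fill and caps always sit
at least k+1 bonds from any core atom. Groups whose regions share
atoms are merged, so every unmatched atom lands in exactly one core.

Oversized regions are split recursively at bridge bonds (single
order, not on any parent ring), cutting the bridge whose two sides
are most balanced; the size measure is the *capped* atom count
(region atoms plus one hydrogen per open valence), targeting the
30–40-atom window that downstream quantum processing can handle, with
40 as the default limit. A piece with no cuttable bond — a fused ring
system — is returned whole even if oversized: ring protection beats
the size limit.

Capping completes each piece into a neutral molecule. The rule table
maps elements to applicable cap groups; the default table is
hydrogen-only (1–3 H by open valence), honoring the no-net-charge /
no-polar-groups constraint, and is a JSON config so richer caps
(e.g. methyl) can be added without code changes. Cap selection is an
integer program (scipy's HiGHS-backed MILP): counts per (atom, group)
subject to exact valence completion, minimizing added heavy atoms
first and added hydrogens second (lexicographic via weighting). With
the default table the program is trivially forced; with richer tables
the suite checks it against exhaustive search. Cap atoms carry formal
charge 0, are tagged `is_cap`, and every capped output must pass
valence validation. Hybridization at severed multiple bonds is never
an issue because closure prevents severing them.

## Synthetic data

`synthetic_charges` draws per-atom charges from a seeded
uniform(−0.6, 0.6) — ESP-like magnitudes — shifted so they sum to the
integer target exactly. `make_self_library` fragments a charged
molecule into n overlapping pieces: well-separated seed atoms
(farthest-point placement), multi-source BFS cells (connected by
construction), dilation until adjacent cores overlap by the requested
atom count, then per-piece k-shell extension, ring/multiple-bond
closure and hydrogen capping. Real atoms keep the parent's charges;
each cap hydrogen receives the aggregate charge of the neighbors it
replaces (bookkeeping only — caps are flagged and never used as
charge sources). Because the cores cover the molecule and every core
atom's k-ball survives intact inside its piece, reassembling the
molecule from its own library must reproduce every charge exactly;
this recovery property is the pipeline's end-to-end correctness probe
and the desk-scale analog of a multi-start consistency experiment on
a large natural product. `random_molecule` grows random
valence-bounded connected labeled graphs for the enumeration oracle
tests; these are deliberately not chemically sensible.

What the synthetic library does *not* emulate: real reference
databases carry charges from independent ESP fits, so matched
fragments disagree by genuine physics (conformation, long-range
effects), residuals are nonzero, and multi-start spreads are finite.
Passing the exact-recovery suite shows the machinery is
self-consistent, not that transferred charges approximate any
particular quantum chemistry.

## Numerical and design choices

- Charges are serialized at 4 decimals (SDF `PARTIAL_CHARGES` field
  and JSON outputs); internal arithmetic is full double precision
  with fsum where sums matter.
- Residual sign convention: residual = sum − target, so subtracting
  residual/N per atom lands on the target.
- Degenerate shells: k larger than a molecule's diameter demands
  whole-component isomorphism; k = 0 reduces to label equality.
- Determinism: identical inputs and seeds give byte-identical
  reports. All randomness (start atoms, library generation, test
  instances) is seeded.
- Problem sizes in the test suite: oracle equivalence uses 200 random
  pairs of ≤ 10 atoms across shell sizes 0–3; recovery runs 4 fixture
  molecules × 3 library sizes × 3 seeds. Both suites complete in well
  under a minute on one CPU.

## Known limitations

- Worst-case enumeration remains exponential; the symmetry pruning
  removes automorphism-image blowup but pathological non-molecular
  graphs can still be slow.
- The collapse to one mapping per query core discards reference-side
  multiplicity; a caller who needs every symmetric image must use raw
  mode.
- Equivalence classes above 150 atoms fall back to refinement colors
  alone, which can over-merge atoms on regular graphs (not observed
  on chemical structures).
- PDB input, 2D depiction, conformer handling and topology-file
  emission are out of scope.
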