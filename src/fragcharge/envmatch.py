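"""k-shell atom compatibility and maximal common fragment enumeration.

Two atoms in different molecules are *k-compatible* when their
neighborhoods out to ``k`` bonds (their k-balls) are isomorphic as
rooted labeled graphs, every atom matched by element and by total
degree taken in the full molecule.  A *common fragment* is a connected
set of query atoms mapped one-to-one onto reference atoms such that the
mapping preserves bonds in both directions, every mapped pair is
k-compatible, and the whole core mapping extends to a single injective,
label- and adjacency-preserving map over the union of the core atoms'
k-balls.  Enumeration returns every *maximal* such fragment: one that
no single additional compatible adjacent pair can extend.

The enumerator builds the product graph of compatible atom pairs with
*c*-edges (pairs adjacent in both molecules) and *d*-edges (pairs
adjacent in neither) and lists all maximal c-connected cliques with a
Bron-Kerbosch-style recursion, filtering by the shell-consistency rule
(which is hereditary, so filtering preserves completeness).  A naive
frontier-growth enumerator, :func:`brute_force_k_mcf`, serves as an
independent oracle on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .molgraph import FragmentLibrary, MolecularGraph

__all__ = [
    "FragmentMatch",
    "MatchResult",
    "atoms_compatible",
    "brute_force_k_mcf",
    "enumerate_k_mcf",
    "match_library",
]

BRUTE_FORCE_PAIR_LIMIT = 400


@dataclass(frozen=True)
class FragmentMatch:
    """A maximal common fragment between a query and a reference molecule.

    ``mapping`` pairs query atoms with reference atoms; ``query_atoms``
    is the sorted core; ``shell_atoms`` are the query atoms within ``k``
    bonds of the core (excluding the core itself).
    """

    mapping: tuple[tuple[int, int], ...]
    k: int
    shell_atoms: frozenset[int]
    library_id: Optional[str] = None
    fragment_charge: Optional[float] = None

    @property
    def query_atoms(self) -> tuple[int, ...]:
        return tuple(q for q, _ in self.mapping)

    @property
    def size(self) -> int:
        return len(self.mapping)

    def ref_atom(self, q: int) -> int:
        for qq, r in self.mapping:
            if qq == q:
                return r
        raise KeyError(f"query atom {q} not in fragment")

    def sort_key(self):
        return (-self.size, self.library_id or "", self.query_atoms,
                tuple(r for _, r in self.mapping))


# ---------------------------------------------------------------------------
# rooted embeddings


def _extend_embedding(
    g1: MolecularGraph,
    domain: frozenset[int],
    g2: MolecularGraph,
    seed: dict[int, int],
    allowed2: Optional[frozenset[int]] = None,
    trust_seed: bool = False,
    prefer_identity: bool = False,
    budget: Optional[int] = None,
) -> Optional[dict[int, int]]:
    """Extend ``seed`` to an injective map ``domain -> g2`` preserving
    atom labels and both adjacency and non-adjacency (induced), or
    return None if impossible.

    Candidate images may be restricted to ``allowed2``.  Backtracking
    proceeds outward from the seeded atoms so that every placement is
    constrained by at least one already-placed neighbor whenever the
    domain is connected through the seed.  ``trust_seed`` skips the
    pairwise re-validation of the seed (used when the caller has already
    established it, e.g. from product-graph clique edges).
    """
    assigned = dict(seed)
    used = set(seed.values())
    todo = set(domain) - set(seed)
    adj1 = g1.g.adj
    adj2 = g2.g.adj
    n1 = g1.g.nodes
    n2 = g2.g.nodes
    deg1 = g1.g.degree
    deg2 = g2.g.degree

    def order_next() -> tuple[Optional[int], list[int]]:
        # most-constrained-first: the atom with the most placed neighbors
        best, best_anchors = None, []
        for x in todo:
            anchors = [n for n in adj1[x] if n in assigned]
            if len(anchors) > len(best_anchors) or (
                len(anchors) == len(best_anchors) and (best is None or x < best)
            ):
                best, best_anchors = x, anchors
        return best, best_anchors

    def feasible(x: int, y: int) -> bool:
        if n1[x]["element"] != n2[y]["element"] or deg1[x] != deg2[y]:
            return False
        # induced condition: assigned neighbors of x must map onto
        # exactly the used neighbors of y
        cnt = 0
        for z in adj1[x]:
            if z in assigned:
                cnt += 1
                if assigned[z] not in adj2[y]:
                    return False
        cnt2 = 0
        for w in adj2[y]:
            if w in used:
                cnt2 += 1
        return cnt2 == cnt

    steps = [0]

    def backtrack() -> bool:
        if budget is not None:
            steps[0] += 1
            if steps[0] > budget:
                raise _BudgetExceeded
        if not todo:
            return True
        x, anchors = order_next()
        if anchors:
            cset = set(adj2[assigned[anchors[0]]])
            for z in anchors[1:]:
                cset &= set(adj2[assigned[z]])
            cands = [y for y in cset if y not in used]
        else:
            pool = allowed2 if allowed2 is not None else g2.atoms
            cands = [y for y in pool if y not in used]
        if allowed2 is not None:
            cands = [y for y in cands if y in allowed2]
        todo.discard(x)
        cands.sort()
        if prefer_identity and x in cands:
            cands.remove(x)
            cands.insert(0, x)
        for y in cands:
            if not feasible(x, y):
                continue
            assigned[x] = y
            used.add(y)
            if backtrack():
                return True
            del assigned[x]
            used.discard(y)
        todo.add(x)
        return False

    if not trust_seed:
        # seed itself must satisfy labels and induced consistency
        items = list(seed.items())
        for i, (x, y) in enumerate(items):
            if n1[x]["element"] != n2[y]["element"] or deg1[x] != deg2[y]:
                return None
            for z, w in items[:i]:
                if (z in adj1[x]) != (w in adj2[y]):
                    return None
        if len(set(seed.values())) != len(seed):
            return None
    try:
        found = backtrack()
    except _BudgetExceeded:
        return None
    return dict(assigned) if found else None


class _BudgetExceeded(Exception):
    pass


def atoms_compatible(
    g1: MolecularGraph,
    a1: int,
    g2: MolecularGraph,
    a2: int,
    k: int,
    return_witness: bool = False,
):
    """True iff the k-balls of ``a1`` and ``a2`` admit a rooted isomorphism.

    The isomorphism maps ``a1`` to ``a2``, preserves element and
    full-molecule degree of every atom, and preserves adjacency within
    the balls (induced).  Symmetric in its arguments; with
    ``return_witness=True`` returns the witness map (or None).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    ball1 = g1.k_ball(a1, k)
    ball2 = g2.k_ball(a2, k)
    witness = None
    if len(ball1) == len(ball2):
        witness = _extend_embedding(g1, ball1, g2, {a1: a2}, allowed2=ball2)
    if return_witness:
        return witness
    return witness is not None


# ---------------------------------------------------------------------------
# fragment validity (shared by both enumerators)


def _fragment_consistent(
    g1: MolecularGraph, g2: MolecularGraph, mapping: dict[int, int], k: int
) -> bool:
    """Shell-consistency: the core mapping must extend to one injective,
    label- and adjacency-preserving (induced) map over the union of the
    core atoms' k-balls."""
    if k == 0:
        return True  # clique structure already enforces the core conditions
    domain = frozenset().union(*(g1.k_ball(a, k) for a in mapping))
    return _extend_embedding(g1, domain, g2, mapping, trust_seed=True) is not None


# ---------------------------------------------------------------------------
# product graph + maximal c-connected clique enumeration


class _ProductGraph:
    """Compatible atom pairs with c-edges (adjacent in both molecules)
    and d-edges (adjacent in neither), as bitmask adjacency."""

    def __init__(self, g1, g2, k, exclude2=frozenset()):
        self.g1, self.g2, self.k = g1, g2, k
        pairs = []
        for u in g1.atoms:
            lab = g1.atom_label(u)
            for v in g2.atoms:
                if v in exclude2:
                    continue
                if g2.atom_label(v) != lab:
                    continue
                if atoms_compatible(g1, u, g2, v, k):
                    pairs.append((u, v))
        self.pairs = pairs
        self._swap_memo: dict[tuple[int, int], Optional[int]] = {}
        m = len(pairs)
        self.cN = [0] * m
        self.dN = [0] * m
        adj1, adj2 = g1.g.adj, g2.g.adj
        for i in range(m):
            u1, v1 = pairs[i]
            for j in range(i + 1, m):
                u2, v2 = pairs[j]
                if u1 == u2 or v1 == v2:
                    continue
                a1 = u2 in adj1[u1]
                a2 = v2 in adj2[v1]
                if a1 and a2:
                    self.cN[i] |= 1 << j
                    self.cN[j] |= 1 << i
                elif not a1 and not a2:
                    self.dN[i] |= 1 << j
                    self.dN[j] |= 1 << i

    def swap_moved(self, r_from: int, r_to: int) -> Optional[int]:
        """Bitmask (over reference atom ids) moved by some reference
        automorphism sending ``r_from`` to ``r_to``; None if no such
        automorphism exists.  The search prefers identity images, so the
        moved set is small for local symmetries (methyl rotations,
        ring flips, equivalent branch swaps)."""
        key = (r_from, r_to)
        if key not in self._swap_memo:
            g2 = self.g2
            wl = g2.wl_colors()
            if wl[r_from] != wl[r_to]:
                self._swap_memo[key] = None
                return None
            sigma = _extend_embedding(
                g2, frozenset(g2.atoms), g2, {r_from: r_to},
                prefer_identity=True, budget=20 * g2.n_atoms + 2000,
            )
            if sigma is None:
                self._swap_memo[key] = None
            else:
                moved = 0
                for x, y in sigma.items():
                    if x != y:
                        moved |= (1 << x) | (1 << y)
                self._swap_memo[key] = moved
        return self._swap_memo[key]

    def mapping(self, mask: int) -> dict[int, int]:
        out = {}
        while mask:
            low = mask & -mask
            u, v = self.pairs[low.bit_length() - 1]
            out[u] = v
            mask ^= low
        return out


def _bits(mask: int):
    while mask:
        low = mask & -mask
        yield low
        mask ^= low


def enumerate_k_mcf(
    g1: MolecularGraph,
    g2: MolecularGraph,
    k: int,
    exclude2: frozenset[int] = frozenset(),
    raw: bool = False,
) -> list[FragmentMatch]:
    """Enumerate all maximal common fragments between two molecules.

    Returns one :class:`FragmentMatch` per distinct query core (mappings
    related by reference-side symmetry are collapsed to the
    lexicographically smallest), ordered by size descending then by
    query atom ids.  ``exclude2`` bars reference atoms (e.g. synthetic
    caps) from being mapped.  With ``raw=True`` the uncollapsed list of
    maximal pair sets is returned instead (used by the oracle suite).
    """
    import sys

    pg = _ProductGraph(g1, g2, k, exclude2)
    m = len(pg.pairs)
    if sys.getrecursionlimit() < 3 * m + 1000:
        sys.setrecursionlimit(3 * m + 1000)
    N = [pg.cN[i] | pg.dN[i] for i in range(m)]
    cliques: list[int] = []
    prune_symmetry = not raw  # raw mode returns every mapping incl. symmetric images

    # Symmetry suppression (collapsed mode).  ``branched`` records, per
    # query atom q, every pair (q, r) already branched at an ancestor
    # node (or an earlier seed), together with the reference atoms the
    # partial mapping used at that moment.  A candidate (q, r2) is
    # redundant if some reference automorphism sigma sends r2 to such an
    # r while fixing the reference atoms used back then: every maximal
    # clique through the candidate then has a sigma-image — with the
    # same query core — through the recorded branch, which that subtree
    # has already enumerated.  Sound for per-core completeness; the
    # collapsed output is canonicalized per core afterwards anyway.
    branched: dict[int, list[tuple[int, int]]] = {}

    def redundant(i: int) -> bool:
        q, r2 = pg.pairs[i]
        for r1, refs_at in branched.get(q, ()):
            moved = pg.swap_moved(r2, r1)
            if moved is not None and moved & refs_at == 0:
                return True
        return False

    # -- phase 1: all maximal c-connected cliques of the product graph --
    def expand(R: int, P: int, D: int, X: int, Y: int, refs: int) -> None:
        if P == 0 and X == 0:
            cliques.append(R)
            return
        # domination prune: an excluded vertex compatible with everything
        # left guarantees nothing in this subtree can be maximal
        for x in _bits(X):
            if (P | D) & ~N[x.bit_length() - 1] == 0:
                return
        # pivot: skip neighbors of a vertex adjacent to all of D (the
        # restriction keeps the branch argument valid for c-cliques)
        branch = P
        best = -1
        for u in _bits(P | X):
            iu = u.bit_length() - 1
            if D & ~N[iu]:
                continue
            cand = P & ~N[iu]
            if u & P:
                cand |= u
            if best < 0 or cand.bit_count() < best:
                best = cand.bit_count()
                branch = cand
        local: list[int] = []
        for b in _bits(branch & P):
            i = b.bit_length() - 1
            if prune_symmetry and redundant(i):
                continue  # stays in P: still blocks false maximality
            P ^= b
            q, r2 = pg.pairs[i]
            expand(
                R | b,
                (P & N[i]) | (D & pg.cN[i]),
                D & pg.dN[i] & ~pg.cN[i],
                (X & N[i]) | (Y & pg.cN[i]),
                Y & pg.dN[i] & ~pg.cN[i],
                refs | (1 << r2),
            )
            X |= b
            if prune_symmetry:
                branched.setdefault(q, []).append((r2, refs))
                local.append(q)
        for q in local:
            branched[q].pop()

    T = 0
    for s in range(m):
        b = 1 << s
        if not (prune_symmetry and redundant(s)):
            expand(
                b, pg.cN[s] & ~T, pg.dN[s] & ~T, pg.cN[s] & T, pg.dN[s] & T,
                1 << pg.pairs[s][1],
            )
        if prune_symmetry:
            q, r2 = pg.pairs[s]
            branched.setdefault(q, []).append((r2, 0))
        T |= b

    # -- phase 2: shrink cliques that fail shell consistency ------------
    valid_memo: dict[int, bool] = {}

    def valid(mask: int) -> bool:
        got = valid_memo.get(mask)
        if got is None:
            got = _fragment_consistent(g1, g2, pg.mapping(mask), k)
            valid_memo[mask] = got
        return got

    def c_components(mask: int) -> list[int]:
        comps = []
        rest = mask
        while rest:
            seedbit = rest & -rest
            comp = seedbit
            frontier = seedbit
            while frontier:
                nxt = 0
                for b in _bits(frontier):
                    nxt |= pg.cN[b.bit_length() - 1] & mask & ~comp
                comp |= nxt
                frontier = nxt
            comps.append(comp)
            rest &= ~comp
        return comps

    shrink_memo: dict[int, frozenset[int]] = {}

    def max_valid_subsets(mask: int) -> frozenset[int]:
        got = shrink_memo.get(mask)
        if got is not None:
            return got
        if valid(mask):
            out = frozenset((mask,))
        else:
            acc: set[int] = set()
            for v in _bits(mask):
                for comp in c_components(mask ^ v):
                    acc.update(max_valid_subsets(comp))
            out = frozenset(
                s for s in acc if not any(s != t and s & t == s for t in acc)
            )
        shrink_memo[mask] = out
        return out

    candidates: set[int] = set()
    needs_check: set[int] = set()
    for C in set(cliques):
        if valid(C):
            candidates.add(C)  # maximal clique + valid => maximal fragment
        else:
            subs = max_valid_subsets(C)
            candidates.update(subs)
            needs_check.update(subs)

    # shrunken candidates may be extendable through a different clique
    final: list[int] = []
    for Rm in candidates:
        if Rm in needs_check:
            ext_found = False
            cadj = 0
            nall = ~0
            for b in _bits(Rm):
                i = b.bit_length() - 1
                cadj |= pg.cN[i]
                nall &= N[i]
            for v in _bits(cadj & nall & ~Rm):
                if valid(Rm | v):
                    ext_found = True
                    break
            if ext_found:
                continue
        final.append(Rm)
    # drop sub-mappings (defensive: maximality should already exclude them)
    final.sort(key=lambda r: r.bit_count(), reverse=True)
    kept: list[int] = []
    for r in final:
        if not any(r & q == r for q in kept):
            kept.append(r)
    if raw:
        return [frozenset(pg.mapping(r).items()) for r in kept]
    return _finalize(g1, g2, k, [pg.mapping(r) for r in kept], exclude2)


def _canonical_core_mapping(
    g1: MolecularGraph,
    g2: MolecularGraph,
    k: int,
    core: frozenset[int],
    exclude2: frozenset[int] = frozenset(),
    budget: int = 100000,
) -> Optional[dict[int, int]]:
    """Lexicographically smallest valid mapping of a fixed query core
    (ordered by query atom, then reference atom), or None.

    Depth-first search assigns core atoms in ascending order, trying
    reference candidates in ascending order, so the first complete
    valid mapping found is the lexicographic minimum.  For a self-match
    this is the identity whenever the identity is valid.
    """
    order = sorted(core)
    adj1, adj2 = g1.g.adj, g2.g.adj
    compat: dict[tuple[int, int], bool] = {}

    def ok(u: int, v: int) -> bool:
        if (u, v) not in compat:
            compat[(u, v)] = atoms_compatible(g1, u, g2, v, k)
        return compat[(u, v)]

    assigned: dict[int, int] = {}
    used: set[int] = set()
    steps = [0]

    def dfs(i: int) -> bool:
        steps[0] += 1
        if steps[0] > budget:
            raise _BudgetExceeded
        if i == len(order):
            return _fragment_consistent(g1, g2, assigned, k)
        u = order[i]
        for v in g2.atoms:
            if v in used or v in exclude2 or not ok(u, v):
                continue
            good = True
            for z, w in assigned.items():
                if (z in adj1[u]) != (w in adj2[v]):
                    good = False
                    break
            if not good:
                continue
            assigned[u] = v
            used.add(v)
            if dfs(i + 1):
                return True
            del assigned[u]
            used.discard(v)
        return False

    try:
        return dict(assigned) if dfs(0) else None
    except _BudgetExceeded:
        return None


def _is_maximal(
    g1: MolecularGraph,
    g2: MolecularGraph,
    k: int,
    mapping: dict[int, int],
    exclude2: frozenset[int] = frozenset(),
) -> bool:
    """No single compatible adjacent pair can extend the mapping."""
    adj1, adj2 = g1.g.adj, g2.g.adj
    used_q = set(mapping)
    used_r = set(mapping.values())
    frontier = {
        n for u in mapping for n in adj1[u] if n not in used_q
    } if mapping else set(g1.atoms)
    for u in sorted(frontier):
        for v in g2.atoms:
            if v in used_r or v in exclude2:
                continue
            if g1.atom_label(u) != g2.atom_label(v):
                continue
            good = True
            touches = False
            for z, w in mapping.items():
                a1 = z in adj1[u]
                a2 = w in adj2[v]
                if a1 != a2:
                    good = False
                    break
                if a1:
                    touches = True
            if not good or (mapping and not touches):
                continue
            if not atoms_compatible(g1, u, g2, v, k):
                continue
            if _fragment_consistent(g1, g2, dict(mapping) | {u: v}, k):
                return False
    return True


def _finalize(
    g1: MolecularGraph,
    g2: MolecularGraph,
    k: int,
    mappings: list[dict[int, int]],
    exclude2: frozenset[int] = frozenset(),
    canonicalize: bool = True,
) -> list[FragmentMatch]:
    """Collapse mappings to one per query core and canonicalize.

    Symmetric (automorphic) images share a core; the kept representative
    is the lexicographically smallest valid mapping of that core,
    re-derived independently of enumeration order (and verified still
    maximal, falling back to the enumerated mapping otherwise).
    """
    per_core: dict[frozenset[int], tuple] = {}
    for mp in mappings:
        core = frozenset(mp)
        item = tuple(sorted(mp.items()))
        if core not in per_core or item < per_core[core]:
            per_core[core] = item
    out = []
    for core, item in per_core.items():
        if canonicalize:
            canon = _canonical_core_mapping(g1, g2, k, core, exclude2)
            if canon is not None:
                citem = tuple(sorted(canon.items()))
                if citem != item and _is_maximal(g1, g2, k, canon, exclude2):
                    item = citem
                elif citem == item:
                    pass
        shell = frozenset().union(*(g1.k_ball(a, k) for a in core)) - core
        out.append(FragmentMatch(mapping=item, k=k, shell_atoms=shell))
    out.sort(key=FragmentMatch.sort_key)
    return out


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_k_mcf(
    g1: MolecularGraph,
    g2: MolecularGraph,
    k: int,
    exclude2: frozenset[int] = frozenset(),
    raw: bool = False,
) -> list[FragmentMatch]:
    """Exhaustive enumeration of maximal common fragments.

    Grows every connected, consistent set of compatible atom pairs and
    keeps those with no valid single-pair extension.  Semantically
    identical to :func:`enumerate_k_mcf`; exponential, so refused above
    ``BRUTE_FORCE_PAIR_LIMIT`` atom-pair products.
    """
    if g1.n_atoms * g2.n_atoms > BRUTE_FORCE_PAIR_LIMIT:
        raise ValueError(
            f"instance too large for brute force: {g1.n_atoms} x {g2.n_atoms} "
            f"= {g1.n_atoms * g2.n_atoms} atom pairs (limit {BRUTE_FORCE_PAIR_LIMIT})"
        )
    adj1, adj2 = g1.g.adj, g2.g.adj
    pairs = [
        (u, v)
        for u in g1.atoms
        for v in g2.atoms
        if v not in exclude2 and atoms_compatible(g1, u, g2, v, k)
    ]

    def consistent_with(cur: frozenset, p) -> bool:
        u, v = p
        touches = False
        for (x, y) in cur:
            if x == u or y == v:
                return False
            a1 = x in adj1[u]
            a2 = y in adj2[v]
            if a1 != a2:
                return False
            if a1:
                touches = True
        if cur and not touches:
            return False
        return _fragment_consistent(g1, g2, dict(cur) | {u: v}, k)

    maximal: list[frozenset] = []
    seen: set[frozenset] = set()

    def grow(cur: frozenset) -> None:
        if cur in seen:
            return
        seen.add(cur)
        ext = [p for p in pairs if p not in cur and consistent_with(cur, p)]
        if not ext:
            maximal.append(cur)
            return
        for p in ext:
            grow(cur | {p})

    for p in pairs:
        if _fragment_consistent(g1, g2, dict([p]), k):
            grow(frozenset([p]))

    if raw:
        return sorted(set(maximal), key=lambda s: (-len(s), sorted(s)))
    return _finalize(g1, g2, k, [dict(s) for s in set(maximal)], exclude2)


# ---------------------------------------------------------------------------
# library-wide search


@dataclass
class MatchResult:
    """Ranked fragments from a library search plus per-atom coverage."""

    k: int
    fragments: list[FragmentMatch]
    #: for each query atom, indices into ``fragments`` covering it
    per_atom: dict[int, list[int]] = field(default_factory=dict)

    @property
    def matched(self) -> frozenset[int]:
        return frozenset(a for a, fr in self.per_atom.items() if fr)

    @property
    def missing(self) -> frozenset[int]:
        return frozenset(a for a, fr in self.per_atom.items() if not fr)

    def to_json(self) -> dict:
        return {
            "shell_size": self.k,
            "fragments": [
                {
                    "library_id": f.library_id,
                    "size": f.size,
                    "fragment_charge": (
                        None if f.fragment_charge is None
                        else round(f.fragment_charge, 4)
                    ),
                    "mapping": [[q, r] for q, r in f.mapping],
                }
                for f in self.fragments
            ],
            "atom_status": {
                str(a): ("matched" if fr else "missing")
                for a, fr in sorted(self.per_atom.items())
            },
        }


def match_library(
    query: MolecularGraph, lib: FragmentLibrary, k: int
) -> MatchResult:
    """Enumerate maximal common fragments of the query against every
    library entry; rank by size (descending), then library id, then
    query atom ids.  Entries' cap atoms are never used as mapping
    images, so synthetic cap charges cannot be transferred."""
    if len(lib) == 0:
        raise ValueError("fragment library is empty")
    frags: list[FragmentMatch] = []
    for entry in lib.entries:
        mol = entry.molecule
        for f in enumerate_k_mcf(query, mol, k, exclude2=frozenset(entry.cap_atoms)):
            charge = sum(mol.partial_charge(r) for _, r in f.mapping)
            frags.append(
                FragmentMatch(
                    mapping=f.mapping,
                    k=k,
                    shell_atoms=f.shell_atoms,
                    library_id=entry.library_id,
                    fragment_charge=charge,
                )
            )
    frags.sort(key=FragmentMatch.sort_key)
    per_atom: dict[int, list[int]] = {a: [] for a in query.atoms}
    for i, f in enumerate(frags):
        for q in f.query_atoms:
            per_atom[q].append(i)
    return MatchResult(k=k, fragments=frags, per_atom=per_atom)
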