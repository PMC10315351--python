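"""Missing-fragment extraction, splitting and valence capping.

Query atoms that no library fragment covers must be parametrized
externally.  They are grouped into connected fragments together with
their chemical environment (the k-shell), oversized fragments are split
at acyclic single bonds (never breaking rings), and dangling valences
are completed with neutral, apolar capping groups chosen by an integer
linear program.

Fragment regions are *closed* before capping: a severed ring bond pulls
the whole ring into the region and a severed multiple-order bond pulls
in the partner atom, so every bond actually severed is an acyclic
single bond.  This keeps ring systems intact and makes every open
valence an integer that hydrogen caps can fill.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import networkx as nx
import numpy as np
from scipy.optimize import LinearConstraint, milp

from .envmatch import MatchResult
from .molgraph import (
    MolecularGraph,
    ValidationError,
    VALENCE_TARGET,
)

__all__ = [
    "CapGroup",
    "CapRuleTable",
    "MissingFragment",
    "cap_fragment",
    "close_region",
    "default_cap_rules",
    "group_missing",
    "open_valences",
    "split_fragment",
    "unmatched_atoms",
]

#: split target window from the processing size limit
DEFAULT_MAX_ATOMS = 40
MIN_MAX_ATOMS = 5


@dataclass(frozen=True)
class MissingFragment:
    """A connected region of uncovered query atoms plus its k-shell.

    ``core_atoms`` are the unmatched atoms, ``shell_atoms`` their
    surrounding environment (k-balls plus ring/multiple-bond closure).
    ``dangling`` lists (atom, open valence) for bonds severed at the
    region boundary.
    """

    core_atoms: frozenset[int]
    shell_atoms: frozenset[int]
    k: int
    dangling: tuple[tuple[int, int], ...] = ()

    @property
    def atoms(self) -> frozenset[int]:
        return self.core_atoms | self.shell_atoms

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def sort_key(self):
        return (min(self.core_atoms), sorted(self.core_atoms))


def unmatched_atoms(match_result: MatchResult) -> frozenset[int]:
    """Atoms covered by zero fragments in a library search."""
    return match_result.missing


def close_region(g: MolecularGraph, atoms: frozenset[int]) -> frozenset[int]:
    """Expand an atom set until no ring bond or multiple-order bond is
    severed at its boundary."""
    region = set(atoms)
    grew = True
    while grew:
        grew = False
        for a in list(region):
            for b in g.neighbors(a):
                if b in region:
                    continue
                if g.is_ring_bond(a, b) or g.bond_order(a, b) > 1:
                    region.add(b)
                    grew = True
    return frozenset(region)


def _dangling(g: MolecularGraph, region: frozenset[int]) -> tuple[tuple[int, int], ...]:
    out = []
    for a in sorted(region):
        severed = sum(1 for b in g.neighbors(a) if b not in region)
        if severed:
            out.append((a, severed))
    return tuple(out)


def open_valences(g: MolecularGraph, region: frozenset[int]) -> dict[int, int]:
    """Open valence per region atom, counted against the parent molecule.

    After closure every severed bond is a single bond, so the open
    valence is simply the number of severed neighbors.
    """
    return {a: v for a, v in _dangling(g, region)}


def group_missing(
    g: MolecularGraph, unmatched: frozenset[int], k: int
) -> list[MissingFragment]:
    """Group unmatched atoms into fragments with their environment.

    Cores are the connected components of the unmatched set; each
    fragment's region is the union of k-balls of its core atoms, closed
    under rings and multiple bonds.  Fragments whose regions share atoms
    are merged, so every unmatched atom ends up in exactly one core.
    Output is ordered by smallest core atom id.
    """
    unknown = unmatched - set(g.atoms)
    if unknown:
        raise KeyError(f"unmatched atoms not in molecule: {sorted(unknown)}")
    if not unmatched:
        return []
    sub = g.g.subgraph(unmatched)
    pieces = [frozenset(c) for c in nx.connected_components(sub)]
    regions = []
    for core in pieces:
        region = frozenset().union(*(g.k_ball(a, k) for a in core))
        regions.append((core, close_region(g, region)))
    # merge fragments with overlapping regions until stable
    merged = True
    while merged:
        merged = False
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                if regions[i][1] & regions[j][1]:
                    core = regions[i][0] | regions[j][0]
                    region = close_region(g, regions[i][1] | regions[j][1])
                    regions[i] = (core, region)
                    del regions[j]
                    merged = True
                    break
            if merged:
                break
    out = [
        MissingFragment(
            core_atoms=core,
            shell_atoms=region - core,
            k=k,
            dangling=_dangling(g, region),
        )
        for core, region in regions
    ]
    out.sort(key=MissingFragment.sort_key)
    return out


# ---------------------------------------------------------------------------
# splitting


def _capped_size(g: MolecularGraph, region: frozenset[int]) -> int:
    """Atom count of the region after hydrogen capping (the processing
    size that the 30-40 atom limit is measured against)."""
    return len(region) + sum(v for _, v in _dangling(g, region))


def split_fragment(
    g: MolecularGraph, frag: MissingFragment, max_atoms: int = DEFAULT_MAX_ATOMS
) -> list[MissingFragment]:
    """Recursively divide an oversized fragment at acyclic single bonds.

    The cut chosen is the bridge whose two sides are most balanced in
    capped atom count.  A piece with no cuttable bond is returned whole
    even if oversized (the ring-protection exception).  Pieces whose
    region contains no core atom are dropped; the remaining cores cover
    the input core.
    """
    if max_atoms < MIN_MAX_ATOMS:
        raise ValueError(f"max_atoms must be >= {MIN_MAX_ATOMS}")
    region = frag.atoms
    sub = g.g.subgraph(region)
    if not nx.is_connected(sub):
        raise ValidationError("cannot split a disconnected fragment")
    if _capped_size(g, region) <= max_atoms:
        return [frag]
    cuttable = [
        (a, b)
        for a, b in nx.bridges(sub)
        if g.bond_order(a, b) == 1 and not g.is_ring_bond(a, b)
    ]
    if not cuttable:
        return [frag]  # fused/ring-locked: ring protection beats the limit
    best = None
    for a, b in cuttable:
        h = sub.copy()
        h.remove_edge(a, b)
        side_a = frozenset(nx.node_connected_component(h, a))
        side_b = frozenset(nx.node_connected_component(h, b))
        bal = abs(_capped_size(g, side_a) - _capped_size(g, side_b))
        key = (bal, min(a, b), max(a, b))
        if best is None or key < best[0]:
            best = (key, side_a, side_b)
    out: list[MissingFragment] = []
    for side in best[1:]:
        core = frag.core_atoms & side
        if not core:
            continue
        piece = MissingFragment(
            core_atoms=core,
            shell_atoms=side - core,
            k=frag.k,
            dangling=_dangling(g, side),
        )
        out.extend(split_fragment(g, piece, max_atoms))
    out.sort(key=MissingFragment.sort_key)
    return out


# ---------------------------------------------------------------------------
# capping


@dataclass(frozen=True)
class CapGroup:
    """A neutral capping group bonded to one dangling atom.

    ``atoms`` are (element, bond order to the attachment point); the
    group fills ``fill`` units of open valence (one per attached atom
    here, all caps bond directly to the dangling atom).
    """

    name: str
    atoms: tuple[tuple[str, float], ...]
    fill: int

    @property
    def n_heavy(self) -> int:
        return sum(1 for el, _ in self.atoms if el != "H")

    @property
    def n_hydrogen(self) -> int:
        return sum(1 for el, _ in self.atoms if el == "H")


class CapRuleTable:
    """Element -> applicable capping groups; ``*`` is the fallback."""

    def __init__(self, rules: dict[str, list[CapGroup]]):
        self.rules = rules

    @classmethod
    def from_dict(cls, doc: dict) -> "CapRuleTable":
        rules: dict[str, list[CapGroup]] = {}
        for el, groups in doc["elements"].items():
            rules[el] = [
                CapGroup(
                    name=grp["name"],
                    atoms=tuple((a["element"], float(a.get("order", 1))) for a in grp["atoms"]),
                    fill=int(grp["fill"]),
                )
                for grp in groups
            ]
        return cls(rules)

    @classmethod
    def from_json(cls, path: str) -> "CapRuleTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def groups_for(self, element: str) -> list[CapGroup]:
        groups = self.rules.get(element, self.rules.get("*"))
        if not groups:
            raise ValidationError(f"no capping rule for element {element!r}")
        return groups


def default_cap_rules() -> CapRuleTable:
    """The built-in hydrogen-only table (1-3 H by open valence)."""
    text = resources.files("fragcharge").joinpath("data/cap_rules.json").read_text()
    return CapRuleTable.from_dict(json.loads(text))


def select_caps_ilp(
    open_vals: dict[int, int],
    groups_per_atom: dict[int, list[CapGroup]],
) -> dict[int, list[CapGroup]]:
    """Choose cap-group counts per dangling atom by integer programming.

    Minimizes added heavy atoms first, then added hydrogens
    (lexicographic via weighting), subject to exact valence completion
    at every dangling atom.  Returns the multiset of groups per atom.
    """
    atoms = sorted(open_vals)
    variables: list[tuple[int, CapGroup]] = []
    for a in atoms:
        for grp in groups_per_atom[a]:
            variables.append((a, grp))
    if not variables:
        if any(open_vals.values()):
            raise ValidationError("dangling atoms but no applicable cap groups")
        return {a: [] for a in atoms}
    nvar = len(variables)
    # lexicographic objective: heavy atoms dominate hydrogens
    weight_h = 1.0
    weight_heavy = 1.0 + weight_h * sum(open_vals.values()) * 4
    c = np.array(
        [weight_heavy * grp.n_heavy + weight_h * grp.n_hydrogen for _, grp in variables]
    )
    A = np.zeros((len(atoms), nvar))
    for j, (a, grp) in enumerate(variables):
        A[atoms.index(a), j] = grp.fill
    b = np.array([open_vals[a] for a in atoms], dtype=float)
    res = milp(
        c=c,
        constraints=LinearConstraint(A, b, b),
        integrality=np.ones(nvar),
        bounds=(0, max(open_vals.values()) if open_vals else 0),
    )
    if not res.success:
        raise ValidationError(
            f"capping integer program infeasible: {res.message}"
        )
    counts = np.round(res.x).astype(int)
    out: dict[int, list[CapGroup]] = {a: [] for a in atoms}
    for j, (a, grp) in enumerate(variables):
        out[a].extend([grp] * counts[j])
    return out


def cap_fragment(
    g: MolecularGraph,
    frag: MissingFragment,
    rules: Optional[CapRuleTable] = None,
) -> MolecularGraph:
    """Complete a fragment into a neutral, chemically whole molecule.

    The fragment's atoms keep their elements, bond orders and (renumbered)
    connectivity; every dangling atom receives the caps selected by the
    integer program.  Cap atoms carry formal charge 0 and are tagged
    (``is_cap``) so that downstream charge transfer ignores them.  The
    returned molecule records the parent atom ids in node attribute
    ``origin`` and passes valence validation.
    """
    rules = rules or default_cap_rules()
    region = frag.atoms
    mol, old2new = g.induced_subgraph(region)
    mol.name = f"{g.name}-missing-{min(frag.core_atoms)}"
    mol.net_charge = sum(g.formal_charge(a) for a in region)
    for old, new in old2new.items():
        mol.g.nodes[new]["origin"] = old
    open_vals = open_valences(g, region)
    groups_per_atom = {a: rules.groups_for(g.element(a)) for a in open_vals}
    chosen = select_caps_ilp(open_vals, groups_per_atom)
    for a in sorted(chosen):
        for grp in chosen[a]:
            for el, order in grp.atoms:
                cap = mol.add_atom(el, formal_charge=0, is_cap=True)
                mol.g.nodes[cap]["origin"] = None
                mol.add_bond(old2new[a], cap, order)
    mol.validate()
    return mol


def cap_standalone(
    g: MolecularGraph, rules: Optional[CapRuleTable] = None
) -> MolecularGraph:
    """Cap a free-standing molecule (no parent reference) by comparing
    each atom's bond-order sum against its default valence target."""
    rules = rules or default_cap_rules()
    open_vals = {}
    for a in g.atoms:
        target = VALENCE_TARGET.get(g.element(a))
        if target is None:
            raise ValidationError(f"no valence target for element {g.element(a)!r} (atom {a})")
        target += g.formal_charge(a) if g.element(a) in ("N", "P") else -g.formal_charge(a)
        gap = target - g.bond_order_sum(a)
        if gap > 0.5:
            open_vals[a] = int(round(gap))
    mol = g.copy()
    for old in mol.atoms:
        mol.g.nodes[old].setdefault("origin", old)
    groups_per_atom = {a: rules.groups_for(g.element(a)) for a in open_vals}
    chosen = select_caps_ilp(open_vals, groups_per_atom)
    for a in sorted(chosen):
        for grp in chosen[a]:
            for el, order in grp.atoms:
                cap = mol.add_atom(el, formal_charge=0, is_cap=True)
                mol.g.nodes[cap]["origin"] = None
                mol.add_bond(a, cap, order)
    mol.validate()
    return mol


def exhaustive_cap_selection(
    open_vals: dict[int, int],
    groups_per_atom: dict[int, list[CapGroup]],
) -> Optional[tuple[int, int]]:
    """Cost (heavy atoms, hydrogens) of the best capping found by
    exhaustive search over group combinations; the independent oracle
    for :func:`select_caps_ilp` on small instances."""
    best: Optional[tuple[int, int]] = None
    per_atom_options: list[list[tuple[int, int]]] = []
    for a in sorted(open_vals):
        v = open_vals[a]
        groups = groups_per_atom[a]
        opts = set()
        for combo in itertools.product(range(v + 1), repeat=len(groups)):
            if sum(n * grp.fill for n, grp in zip(combo, groups)) == v:
                heavy = sum(n * grp.n_heavy for n, grp in zip(combo, groups))
                hyd = sum(n * grp.n_hydrogen for n, grp in zip(combo, groups))
                opts.add((heavy, hyd))
        if not opts:
            return None
        per_atom_options.append(sorted(opts))
    for picks in itertools.product(*per_atom_options):
        heavy = sum(p[0] for p in picks)
        hyd = sum(p[1] for p in picks)
        if best is None or (heavy, hyd) < best:
            best = (heavy, hyd)
    return best
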