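"""Built-in test molecules and synthetic fragment-library generation.

The built-ins are the worked-example molecules (paracetamol, phenol,
N,2-diphenylacetamide, paclitaxel), encoded as SMILES and parsed at
load so the graphs are bit-stable without binary assets.

:func:`make_self_library` fragments a charged molecule into a library
of overlapping, capped pieces that carry the molecule's own charges —
a synthetic stand-in for a database of pre-parametrized reference
molecules.  Reassembling the molecule from such a library must recover
every original charge exactly, which makes it the primary end-to-end
correctness probe for the matching and assignment pipeline.
"""

from __future__ import annotations

import math
import random
from typing import Optional, Sequence

import networkx as nx

from .missing_frags import close_region, open_valences
from .molgraph import (
    FragmentLibrary,
    LibraryEntry,
    MolecularGraph,
    MAX_DEGREE,
    read_molecule,
)

__all__ = [
    "BUILTIN_SMILES",
    "builtin",
    "make_self_library",
    "random_molecule",
    "synthetic_charges",
]

BUILTIN_SMILES = {
    "phenol": "Oc1ccccc1",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "n2_diphenylacetamide": "O=C(Cc1ccccc1)Nc1ccccc1",
    "paclitaxel": (
        "CC1=C2[C@@H](C(=O)[C@@]3([C@H](C[C@@H]4[C@]([C@H]3[C@@H]([C@@](C2(C)C)"
        "(C[C@@H]1OC(=O)[C@@H]([C@H](C5=CC=CC=C5)NC(=O)C6=CC=CC=C6)O)O)OC(=O)"
        "C7=CC=CC=C7)(CO4)OC(=O)C)O)C)OC(=O)C"
    ),
}


def builtin(name: str) -> MolecularGraph:
    """One of the built-in all-atom molecules, by name."""
    if name not in BUILTIN_SMILES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(BUILTIN_SMILES)}"
        )
    return read_molecule(BUILTIN_SMILES[name], "smiles", name)


def synthetic_charges(
    g: MolecularGraph, seed: int, target: int = 0
) -> MolecularGraph:
    """Attach seeded uniform(-0.6, 0.6) charges shifted to the integer target.

    Emulates ESP-like charge magnitudes; returns a charged copy.
    """
    rng = random.Random(seed)
    out = g.copy()
    vals = [rng.uniform(-0.6, 0.6) for _ in out.atoms]
    shift = (target - math.fsum(vals)) / out.n_atoms
    for a, v in zip(out.atoms, vals):
        out.set_partial_charge(a, v + shift)
    out.net_charge = target
    return out


def random_molecule(
    n_atoms: int,
    element_palette: Sequence[str] = ("C", "N", "O", "H"),
    seed: int = 0,
) -> MolecularGraph:
    """A connected, valence-valid random labeled graph (seed-deterministic).

    Grows a random spanning tree respecting per-element degree limits,
    then sprinkles extra edges where valences allow.  Used to generate
    oracle-test instances, not chemically sensible molecules.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = random.Random(seed)
    g = MolecularGraph(f"random-{n_atoms}-{seed}")
    caps = {el: MAX_DEGREE.get(el, 4) for el in element_palette}
    if n_atoms > 1 and all(c < 1 for c in caps.values()):
        raise ValueError("palette cannot satisfy connectivity")
    for i in range(n_atoms):
        if i == 0:
            g.add_atom(rng.choice(list(element_palette)))
            continue
        # attach to an atom with spare valence; the new atom needs
        # valence >= 1 unless terminal
        open_hosts = [
            a for a in g.atoms if g.degree(a) < caps[g.element(a)]
        ]
        if not open_hosts:
            raise ValueError(
                f"palette cannot satisfy connectivity at atom {i} (seed {seed})"
            )
        host = rng.choice(open_hosts)
        el_pool = [el for el in element_palette if caps[el] >= 1]
        # keep the growth frontier open: if this is the last spare
        # valence and atoms remain, the new atom must extend the chain
        last_host = len(open_hosts) == 1 and g.degree(host) == caps[g.element(host)] - 1
        if i < n_atoms - 1 and last_host:
            branchers = [el for el in el_pool if caps[el] >= 2]
            if not branchers:
                raise ValueError("palette cannot satisfy connectivity")
            el = rng.choice(branchers)
        else:
            el = rng.choice(el_pool)
        a = g.add_atom(el)
        g.add_bond(host, a)
    extra = rng.randrange(0, n_atoms)
    for _ in range(extra):
        a, b = rng.randrange(n_atoms), rng.randrange(n_atoms)
        if a == b or g.g.has_edge(a, b):
            continue
        if g.degree(a) < caps[g.element(a)] and g.degree(b) < caps[g.element(b)]:
            g.add_bond(a, b)
    g.validate()
    return g


def _spread_seeds(g: MolecularGraph, n: int, rng: random.Random) -> list[int]:
    """n well-separated start atoms: a random start, then farthest-point."""
    atoms = sorted(g.atoms)
    first = rng.choice(atoms)
    seeds = [first]
    while len(seeds) < n:
        dist = {a: min(g.bond_distance(a, s) for s in seeds) for a in atoms}
        far = max(dist.values())
        cands = sorted(a for a, d in dist.items() if d == far)
        seeds.append(rng.choice(cands))
    return seeds


def make_self_library(
    g: MolecularGraph,
    n_fragments: int,
    min_overlap: int = 2,
    seed: int = 0,
    k: int = 3,
    name: Optional[str] = None,
) -> FragmentLibrary:
    """Fragment a fully charged molecule into a synthetic reference library.

    The molecule is partitioned into ``n_fragments`` connected cells
    grown from well-separated seed atoms, cells are dilated until
    adjacent cores overlap by at least ``min_overlap`` atoms, and each
    core is extended by its k-shell (with ring and multiple-bond
    closure) and hydrogen-capped into a standalone molecule.  Real
    atoms keep the parent's charges; each cap atom is tagged and gets
    the aggregate charge of the neighbors it replaces (caps are never
    charge sources during matching).  The union of cores covers the
    molecule, so reassignment from this library must recover the
    original charges exactly.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if n_fragments > g.n_atoms:
        raise ValueError(
            f"cannot cover {g.n_atoms} atoms with {n_fragments} fragments"
        )
    for a in g.atoms:
        if g.partial_charge(a) is None:
            raise ValueError(f"atom {a} has no partial charge")
    base = name or g.name or "mol"
    rng = random.Random(seed)
    seeds = _spread_seeds(g, n_fragments, rng)
    # multi-source BFS partition (ties to the lower seed index)
    cell = {s: i for i, s in enumerate(seeds)}
    frontier = list(seeds)
    while frontier:
        nxt = []
        for a in frontier:
            for b in g.neighbors(a):
                if b not in cell:
                    cell[b] = cell[a]
                    nxt.append(b)
        frontier = nxt
    cores = [set(a for a, c in cell.items() if c == i) for i in range(n_fragments)]
    # dilate cores until adjacent cores overlap enough
    for _ in range(g.n_atoms):
        ok = True
        for i in range(n_fragments):
            for j in range(i + 1, n_fragments):
                adjacent = any(
                    g.g.has_edge(a, b) or a == b
                    for a in cores[i] for b in cores[j]
                ) or (cores[i] & cores[j])
                if adjacent and len(cores[i] & cores[j]) < min_overlap:
                    ok = False
        if ok:
            break
        cores = [
            c | {b for a in c for b in g.neighbors(a)} for c in cores
        ]
    lib = FragmentLibrary()
    for i, core in enumerate(cores):
        region = frozenset().union(*(g.k_ball(a, k) for a in core))
        region = close_region(g, region)
        mol, old2new = g.induced_subgraph(region)
        mol.name = f"{base}-frag{i}"
        caps = []
        for a, nsev in sorted(open_valences(g, region).items()):
            severed = sorted(b for b in g.neighbors(a) if b not in region)
            share = math.fsum(g.partial_charge(b) for b in severed) / nsev
            for _ in range(nsev):
                cap = mol.add_atom("H", partial_charge=share, is_cap=True)
                mol.add_bond(old2new[a], cap)
                caps.append(cap)
        mol.net_charge = int(round(math.fsum(
            mol.partial_charge(a) for a in mol.atoms
        )))
        mol.validate()
        lib.add(LibraryEntry(f"{base}-frag{i}", mol, mol.name, frozenset(caps)))
    return lib
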