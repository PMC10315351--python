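"""Molecular graph data model and file I/O.

Molecules are simple labeled graphs: nodes are atoms (element, formal
charge, optional partial charge and coordinates), edges are covalent
bonds with an order (1, 2, 3 or aromatic, stored internally as 1.5).
Hydrogens are always explicit: every operation in this package works on
the all-atom representation.

I/O goes through RDKit for the standard formats (SMILES, SDF V2000);
partial charges travel in an SDF data field named ``PARTIAL_CHARGES``
(one value per atom line, elementary-charge units, four decimals).
Fragment libraries use a small JSON schema, see :func:`read_library`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import networkx as nx
from rdkit import Chem

__all__ = [
    "AROMATIC",
    "AtomLabel",
    "FragmentLibrary",
    "LibraryEntry",
    "MolecularGraph",
    "MoleculeParseError",
    "ValidationError",
    "read_library",
    "read_molecule",
    "load_molecule",
    "write_library",
    "write_sdf",
    "to_molblock",
]

#: Internal numeric bond order used for aromatic bonds.
AROMATIC = 1.5

SCHEMA_VERSION = "1"
CHARGE_DECIMALS = 4
#: |sum(partial charges) - net charge| allowed on a finalized molecule.
NET_CHARGE_TOL = 1e-6
#: Loose sanity bound applied before any residual-charge correction.
NET_CHARGE_SANITY = 0.5

# Maximum total connectivity (neighbor count, hydrogens included) per
# element.  Covers organic chemistry plus common heteroatoms; this is a
# structural sanity bound, not a valence model (bond orders are ignored).
MAX_DEGREE = {
    "H": 1, "He": 0, "Li": 1, "Be": 2, "B": 4, "C": 4, "N": 4, "O": 3,
    "F": 1, "Na": 1, "Mg": 2, "Al": 4, "Si": 4, "P": 6, "S": 6, "Cl": 1,
    "Br": 1, "I": 3, "K": 1, "Ca": 2, "Se": 6, "B-": 4,
}
_DEFAULT_MAX_DEGREE = 6

# Default bond-order sum (valence target) per neutral element, used when
# capping a fragment without reference to a parent molecule.
VALENCE_TARGET = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1, "Si": 4, "P": 3,
    "S": 2, "Cl": 1, "Br": 1, "I": 1,
}


class MoleculeParseError(ValueError):
    """Raised when a SMILES/SDF/JSON source cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a molecule or library violates a structural invariant."""


class AtomLabel(NamedTuple):
    """The matching label of an atom: chemical element and total degree.

    The degree counts all bonded neighbors, hydrogens included, taken in
    the full molecule.  Two atoms can only ever be considered equivalent
    if their labels agree.
    """

    element: str
    degree: int


class MolecularGraph:
    """A labeled simple graph of atoms and covalent bonds.

    Atom ids are 0-based consecutive integers; the insertion order (for
    SDF input, the atom-block order) defines the id order and is stable
    under serialization.
    """

    def __init__(self, name: str = "", net_charge: int = 0):
        self.g = nx.Graph()
        self.name = name
        self.net_charge = int(net_charge)
        self._cache: dict = {}

    # -- construction -------------------------------------------------

    def add_atom(
        self,
        element: str,
        formal_charge: int = 0,
        partial_charge: Optional[float] = None,
        coords: Optional[Sequence[float]] = None,
        is_cap: bool = False,
    ) -> int:
        a = self.g.number_of_nodes()
        self.g.add_node(
            a,
            element=element,
            formal_charge=int(formal_charge),
            partial_charge=partial_charge,
            coords=tuple(coords) if coords is not None else None,
            is_cap=is_cap,
        )
        self._cache.clear()
        return a

    def add_bond(self, a: int, b: int, order: float = 1) -> None:
        self._check_atom(a)
        self._check_atom(b)
        if a == b:
            raise ValidationError(f"self-bond on atom {a}")
        if self.g.has_edge(a, b):
            raise ValidationError(f"duplicate bond {a}-{b}")
        self.g.add_edge(a, b, order=float(order))
        self._cache.clear()

    # -- basic accessors ----------------------------------------------

    @property
    def atoms(self) -> list[int]:
        return list(self.g.nodes)

    @property
    def n_atoms(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_bonds(self) -> int:
        return self.g.number_of_edges()

    @property
    def bonds(self) -> Iterator[tuple[int, int, float]]:
        for a, b, d in self.g.edges(data="order"):
            yield a, b, d

    def element(self, a: int) -> str:
        self._check_atom(a)
        return self.g.nodes[a]["element"]

    def formal_charge(self, a: int) -> int:
        self._check_atom(a)
        return self.g.nodes[a]["formal_charge"]

    def partial_charge(self, a: int) -> Optional[float]:
        self._check_atom(a)
        return self.g.nodes[a]["partial_charge"]

    def set_partial_charge(self, a: int, q: Optional[float]) -> None:
        self._check_atom(a)
        self.g.nodes[a]["partial_charge"] = q

    def coords(self, a: int):
        self._check_atom(a)
        return self.g.nodes[a]["coords"]

    def is_cap(self, a: int) -> bool:
        self._check_atom(a)
        return bool(self.g.nodes[a].get("is_cap", False))

    @property
    def cap_atoms(self) -> list[int]:
        return [a for a in self.g.nodes if self.g.nodes[a].get("is_cap")]

    def degree(self, a: int) -> int:
        self._check_atom(a)
        return self.g.degree[a]

    def neighbors(self, a: int) -> list[int]:
        self._check_atom(a)
        return list(self.g.neighbors(a))

    def bond_order(self, a: int, b: int) -> float:
        if not self.g.has_edge(a, b):
            raise KeyError(f"no bond {a}-{b}")
        return self.g.edges[a, b]["order"]

    def bond_order_sum(self, a: int) -> float:
        self._check_atom(a)
        return sum(self.g.edges[a, n]["order"] for n in self.g.neighbors(a))

    def _check_atom(self, a: int) -> None:
        if a not in self.g:
            raise KeyError(f"unknown atom id {a!r} in molecule {self.name!r}")

    # -- distances and neighborhoods ----------------------------------

    def bond_distance(self, a: int, b: int) -> float:
        """Number of intervening bonds on a shortest path (inf if disconnected)."""
        self._check_atom(b)
        return self._dist_from(a).get(b, math.inf)

    def _dist_from(self, a: int) -> dict[int, int]:
        self._check_atom(a)
        key = ("dist", a)
        if key not in self._cache:
            self._cache[key] = nx.single_source_shortest_path_length(self.g, a)
        return self._cache[key]

    def k_ball(self, a: int, k: int) -> frozenset[int]:
        """All atoms within ``k`` bonds of ``a``, including ``a`` itself."""
        if k < 0:
            raise ValueError("k must be >= 0")
        key = ("ball", a, k)
        if key not in self._cache:
            d = self._dist_from(a)
            self._cache[key] = frozenset(x for x, dx in d.items() if dx <= k)
        return self._cache[key]

    def atom_label(self, a: int) -> AtomLabel:
        return AtomLabel(self.element(a), self.degree(a))

    def wl_colors(self) -> dict[int, int]:
        """Iterated neighborhood-label refinement (Morgan/Weisfeiler-Lehman)
        run to a fixed point.  Atoms related by a label-preserving
        automorphism always share a color (the converse can fail on rare
        regular structures)."""
        if "wl" not in self._cache:
            colors = {a: hash(self.atom_label(a)) for a in self.g.nodes}
            for _ in range(self.n_atoms):
                new = {
                    a: hash((colors[a], tuple(sorted(colors[n] for n in self.g.adj[a]))))
                    for a in self.g.nodes
                }
                if len(set(new.values())) == len(set(colors.values())):
                    colors = new
                    break
                colors = new
            index = {c: i for i, c in enumerate(sorted(set(colors.values())))}
            self._cache["wl"] = {a: index[colors[a]] for a in self.g.nodes}
        return self._cache["wl"]

    def ring_bonds(self) -> frozenset[frozenset[int]]:
        """Bonds lying on at least one cycle (i.e. non-bridges)."""
        if "ring_bonds" not in self._cache:
            bridges = {frozenset(e) for e in nx.bridges(self.g)}
            self._cache["ring_bonds"] = frozenset(
                frozenset((a, b)) for a, b in self.g.edges if frozenset((a, b)) not in bridges
            )
        return self._cache["ring_bonds"]

    def is_ring_bond(self, a: int, b: int) -> bool:
        return frozenset((a, b)) in self.ring_bonds()

    # -- validation ----------------------------------------------------

    def validate(self, finalized: bool = False) -> None:
        """Check structural invariants; raise :class:`ValidationError`.

        With ``finalized=True`` the partial charges must all be present
        and sum to the net charge within ``NET_CHARGE_TOL``; otherwise,
        if all charges happen to be present, only the loose sanity bound
        ``NET_CHARGE_SANITY`` is applied.
        """
        ids = list(self.g.nodes)
        if ids != list(range(len(ids))):
            raise ValidationError(f"atom ids not consecutive from 0 in {self.name!r}")
        for a in ids:
            el = self.element(a)
            cap = MAX_DEGREE.get(el, _DEFAULT_MAX_DEGREE)
            if self.degree(a) > cap:
                raise ValidationError(
                    f"atom {a} ({el}) in {self.name!r} has degree "
                    f"{self.degree(a)} > maximum {cap}"
                )
        charges = [self.partial_charge(a) for a in ids]
        if finalized and any(q is None for q in charges):
            missing = [a for a, q in zip(ids, charges) if q is None]
            raise ValidationError(f"atoms without partial charge: {missing}")
        if ids and all(q is not None for q in charges):
            dq = abs(sum(charges) - self.net_charge)
            tol = NET_CHARGE_TOL if finalized else NET_CHARGE_SANITY
            if dq > tol:
                raise ValidationError(
                    f"partial charges sum to {sum(charges):.6f}, net charge "
                    f"{self.net_charge} (|diff| {dq:.2e} > {tol})"
                )

    # -- derived graphs ------------------------------------------------

    def copy(self) -> "MolecularGraph":
        out = MolecularGraph(self.name, self.net_charge)
        out.g = self.g.copy()
        return out

    def induced_subgraph(self, atom_ids: Iterable[int]) -> tuple["MolecularGraph", dict[int, int]]:
        """Induced subgraph with atoms renumbered from 0.

        Returns the new molecule and the map old id -> new id.
        """
        keep = sorted(set(atom_ids))
        out = MolecularGraph(self.name, 0)
        old2new = {}
        for a in keep:
            d = self.g.nodes[a]
            old2new[a] = out.add_atom(
                d["element"], d["formal_charge"], d["partial_charge"],
                d["coords"], d.get("is_cap", False),
            )
        for a, b, order in self.bonds:
            if a in old2new and b in old2new:
                out.add_bond(old2new[a], old2new[b], order)
        return out, old2new

    # -- conversions ---------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str = "") -> "MolecularGraph":
        out = cls(name=name, net_charge=Chem.GetFormalCharge(mol))
        conf = mol.GetConformer() if mol.GetNumConformers() else None
        for at in mol.GetAtoms():
            xyz = None
            if conf is not None:
                p = conf.GetAtomPosition(at.GetIdx())
                xyz = (p.x, p.y, p.z)
            out.add_atom(at.GetSymbol(), at.GetFormalCharge(), None, xyz)
        for b in mol.GetBonds():
            order = AROMATIC if b.GetIsAromatic() else b.GetBondTypeAsDouble()
            out.add_bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order)
        return out

    def to_rdkit(self) -> Chem.Mol:
        rw = Chem.RWMol()
        for a in self.atoms:
            at = Chem.Atom(self.element(a))
            at.SetFormalCharge(self.formal_charge(a))
            at.SetNoImplicit(True)
            rw.AddAtom(at)
        for a, b, order in self.bonds:
            if order == AROMATIC:
                bt = Chem.BondType.AROMATIC
            else:
                bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                      3.0: Chem.BondType.TRIPLE}[float(order)]
            rw.AddBond(a, b, bt)
            if order == AROMATIC:
                rw.GetAtomWithIdx(a).SetIsAromatic(True)
                rw.GetAtomWithIdx(b).SetIsAromatic(True)
                rw.GetBondBetweenAtoms(a, b).SetIsAromatic(True)
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            # partial structures (uncapped fragments) may not sanitize fully
            Chem.SanitizeMol(
                mol,
                Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION,
                catchErrors=True,
            )
        if any(self.coords(a) is not None for a in self.atoms):
            conf = Chem.Conformer(self.n_atoms)
            for a in self.atoms:
                xyz = self.coords(a) or (0.0, 0.0, 0.0)
                conf.SetAtomPosition(a, xyz)
            mol.AddConformer(conf)
        if self.name:
            mol.SetProp("_Name", self.name)
        return mol

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<MolecularGraph {self.name!r}: {self.n_atoms} atoms, "
            f"{self.n_bonds} bonds, net {self.net_charge:+d}>"
        )


# ---------------------------------------------------------------------------
# molecule I/O


def read_molecule(source: str, fmt: str = "smiles", name: str = "") -> MolecularGraph:
    """Parse a molecule from text in the given format (``smiles`` or ``sdf``).

    Hydrogens are made explicit if absent; the result is validated.  For
    SDF, ``source`` is a single V2000 record (molblock plus optional data
    fields); partial charges are read from a ``PARTIAL_CHARGES`` field.
    """
    fmt = fmt.lower()
    if fmt == "smiles":
        return _from_smiles(source, name)
    if fmt == "sdf":
        return _from_sdf_record(source, name)
    raise ValueError(f"unknown format {fmt!r} (expected 'smiles' or 'sdf')")


def load_molecule(path: str, fmt: Optional[str] = None) -> MolecularGraph:
    """Read the first molecule from a file, inferring the format from the name."""
    if fmt is None:
        fmt = "sdf" if str(path).lower().endswith((".sdf", ".mol")) else "smiles"
    with open(path) as fh:
        text = fh.read()
    if fmt == "smiles":
        text = text.strip().splitlines()[0].split()[0] if text.strip() else ""
    return read_molecule(text, fmt)


def _from_smiles(smiles: str, name: str = "") -> MolecularGraph:
    if not smiles or not smiles.strip():
        raise MoleculeParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles.strip())
    if mol is None:
        raise MoleculeParseError(f"could not parse SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    out = MolecularGraph.from_rdkit(mol, name or smiles.strip())
    out.validate()
    return out


def _from_sdf_record(record: str, name: str = "") -> MolecularGraph:
    if not record.strip():
        raise MoleculeParseError("empty SDF record")
    lines = record.splitlines()
    # molblock runs through the line reading "M  END"
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip() == "M  END")
    except StopIteration:
        raise MoleculeParseError("SDF record has no 'M  END' line") from None
    block = "\n".join(lines[: end + 1]) + "\n"
    mol = Chem.MolFromMolBlock(block, removeHs=False)
    if mol is None:
        raise MoleculeParseError("RDKit could not parse the molblock")
    n_before = mol.GetNumAtoms()
    mol = Chem.AddHs(mol)
    title = lines[0].strip() or name
    out = MolecularGraph.from_rdkit(mol, title)
    charges = _parse_data_field(lines[end + 1:], "PARTIAL_CHARGES")
    if charges is not None:
        vals = [float(tok) for tok in charges.split()]
        if len(vals) != n_before and len(vals) != out.n_atoms:
            raise MoleculeParseError(
                f"PARTIAL_CHARGES has {len(vals)} values for {out.n_atoms} atoms"
            )
        for a, q in enumerate(vals):
            out.set_partial_charge(a, q)
        if len(vals) == out.n_atoms:
            out.net_charge = int(round(sum(vals)))
    out.validate()
    return out


def _parse_data_field(lines: list[str], key: str) -> Optional[str]:
    """Extract one SDF data field (``>  <KEY>`` ... blank line)."""
    out: list[str] = []
    grabbing = False
    for ln in lines:
        if ln.startswith(">") and f"<{key}>" in ln:
            grabbing = True
            continue
        if grabbing:
            if not ln.strip() or ln.strip() == "$$$$":
                return "\n".join(out)
            out.append(ln)
    return "\n".join(out) if grabbing else None


def to_molblock(g: MolecularGraph) -> str:
    """Render a molecule as a V2000 molblock (kekulized when possible)."""
    mol = g.to_rdkit()
    try:
        return Chem.MolToMolBlock(mol)
    except Exception:
        return Chem.MolToMolBlock(mol, kekulize=False)


def to_sdf_record(g: MolecularGraph) -> str:
    """Render one SDF record, with charges in a PARTIAL_CHARGES data field."""
    parts = [to_molblock(g).rstrip("\n")]
    charges = [g.partial_charge(a) for a in g.atoms]
    if all(q is not None for q in charges) and charges:
        body = "\n".join(f"{q:.{CHARGE_DECIMALS}f}" for q in charges)
        parts.append(f">  <PARTIAL_CHARGES>\n{body}\n")
    if g.cap_atoms:
        parts.append(">  <CAP_ATOMS>\n" + " ".join(map(str, g.cap_atoms)) + "\n")
    parts.append("$$$$")
    return "\n".join(parts) + "\n"


def write_sdf(mols: MolecularGraph | Iterable[MolecularGraph], path: str) -> None:
    if isinstance(mols, MolecularGraph):
        mols = [mols]
    with open(path, "w") as fh:
        for g in mols:
            fh.write(to_sdf_record(g))


# ---------------------------------------------------------------------------
# fragment library


@dataclass
class LibraryEntry:
    """One reference molecule: every atom carries a partial charge."""

    library_id: str
    molecule: MolecularGraph
    name: str = ""
    #: atom ids that are synthetic caps, never used as charge sources
    cap_atoms: frozenset[int] = frozenset()


@dataclass
class FragmentLibrary:
    """A collection of fully charged reference molecules with unique ids."""

    entries: list[LibraryEntry] = field(default_factory=list)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        self._index = {}
        for e in self.entries:
            if e.library_id in self._index:
                raise ValidationError(f"duplicate library_id {e.library_id!r}")
            self._index[e.library_id] = e

    def add(self, entry: LibraryEntry) -> None:
        if entry.library_id in self._index:
            raise ValidationError(f"duplicate library_id {entry.library_id!r}")
        self.entries.append(entry)
        self._index[entry.library_id] = entry

    def __getitem__(self, library_id: str) -> LibraryEntry:
        return self._index[library_id]

    def __contains__(self, library_id: str) -> bool:
        return library_id in self._index

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self) -> None:
        for i, e in enumerate(self.entries):
            mol = e.molecule
            mol.validate()
            for a in mol.atoms:
                if mol.partial_charge(a) is None:
                    raise ValidationError(
                        f"/entries/{i}/atoms/{a}: missing partial charge "
                        f"(library_id {e.library_id!r})"
                    )


_ORDER_TO_JSON = {1.0: 1, 2.0: 2, 3.0: 3, AROMATIC: "ar"}
_ORDER_FROM_JSON = {1: 1.0, 2: 2.0, 3: 3.0, "ar": AROMATIC}


def write_library(lib: FragmentLibrary, path: str) -> None:
    lib.validate()
    doc = {"schema_version": lib.schema_version, "entries": []}
    for e in lib.entries:
        mol = e.molecule
        entry = {
            "library_id": e.library_id,
            "name": e.name or mol.name,
            "net_charge": mol.net_charge,
            "atoms": [
                {
                    "id": a,
                    "element": mol.element(a),
                    "charge": round(mol.partial_charge(a), CHARGE_DECIMALS),
                }
                for a in mol.atoms
            ],
            "bonds": [[a, b, _ORDER_TO_JSON[float(o)]] for a, b, o in mol.bonds],
        }
        if e.cap_atoms:
            entry["cap_atoms"] = sorted(e.cap_atoms)
        doc["entries"].append(entry)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _schema_fail(pointer: str, msg: str) -> None:
    raise ValidationError(f"{pointer}: {msg}")


def read_library(path: str) -> FragmentLibrary:
    """Load a fragment library from its JSON serialization.

    Unknown ``schema_version`` values produce a warning and a best-effort
    parse; structural violations raise :class:`ValidationError` with a
    JSON-pointer-style location.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise MoleculeParseError(f"invalid JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        _schema_fail("", "library document must be a JSON object")
    version = doc.get("schema_version")
    if version is None:
        _schema_fail("/schema_version", "missing")
    if str(version) != SCHEMA_VERSION:
        warnings.warn(
            f"unknown library schema_version {version!r}; parsing best-effort",
            stacklevel=2,
        )
    entries = doc.get("entries")
    if not isinstance(entries, list):
        _schema_fail("/entries", "must be a list")
    lib = FragmentLibrary(schema_version=SCHEMA_VERSION)
    for i, raw in enumerate(entries):
        ptr = f"/entries/{i}"
        if not isinstance(raw, dict):
            _schema_fail(ptr, "entry must be an object")
        for key in ("library_id", "atoms", "bonds"):
            if key not in raw:
                _schema_fail(f"{ptr}/{key}", "missing")
        mol = MolecularGraph(
            name=str(raw.get("name", "")), net_charge=int(raw.get("net_charge", 0))
        )
        for j, atom in enumerate(raw["atoms"]):
            aptr = f"{ptr}/atoms/{j}"
            if not isinstance(atom, dict) or "element" not in atom:
                _schema_fail(aptr, "atom must be an object with an 'element'")
            if atom.get("id") != j:
                _schema_fail(f"{aptr}/id", f"ids must be consecutive from 0, got {atom.get('id')!r}")
            if "charge" not in atom or atom["charge"] is None:
                _schema_fail(f"{aptr}/charge", "missing partial charge")
            mol.add_atom(str(atom["element"]), int(atom.get("formal_charge", 0)),
                         float(atom["charge"]))
        for j, bond in enumerate(raw["bonds"]):
            bptr = f"{ptr}/bonds/{j}"
            if not (isinstance(bond, list) and len(bond) == 3):
                _schema_fail(bptr, "bond must be [atom, atom, order]")
            a, b, order = bond
            if order not in _ORDER_FROM_JSON:
                _schema_fail(f"{bptr}/2", f"unknown bond order {order!r}")
            try:
                mol.add_bond(int(a), int(b), _ORDER_FROM_JSON[order])
            except (KeyError, ValidationError) as exc:
                _schema_fail(bptr, str(exc))
        try:
            mol.validate()
        except ValidationError as exc:
            _schema_fail(ptr, str(exc))
        caps = frozenset(int(c) for c in raw.get("cap_atoms", []))
        bad = caps - set(mol.atoms)
        if bad:
            _schema_fail(f"{ptr}/cap_atoms", f"unknown atom ids {sorted(bad)}")
        for c in caps:
            mol.g.nodes[c]["is_cap"] = True
        try:
            lib.add(LibraryEntry(str(raw["library_id"]), mol,
                                 str(raw.get("name", "")), caps))
        except ValidationError as exc:
            _schema_fail(f"{ptr}/library_id", str(exc))
    lib.validate()
    return lib
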