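import networkx as nx
import pytest

from fragcharge.envmatch import brute_force_k_mcf, match_library
from fragcharge.fixtures import builtin, make_self_library, synthetic_charges
from fragcharge.missing_frags import (
    CapGroup,
    CapRuleTable,
    MissingFragment,
    cap_fragment,
    close_region,
    default_cap_rules,
    exhaustive_cap_selection,
    group_missing,
    open_valences,
    select_caps_ilp,
    split_fragment,
    unmatched_atoms,
)
from fragcharge.molgraph import MolecularGraph, ValidationError, read_molecule


def chain(n):
    g = MolecularGraph(f"chain{n}")
    for i in range(n):
        g.add_atom("C")
        if i:
            g.add_bond(i - 1, i)
    return g


def fused_macrocycle(n=50):
    """Two fused rings, every bond cyclic (no acyclic cut exists)."""
    g = MolecularGraph("fused")
    for i in range(n):
        g.add_atom("C")
    for i in range(n):
        g.add_bond(i, (i + 1) % n)
    g.add_bond(0, n // 2)
    return g


class TestUnmatched:
    def test_self_library_has_no_missing_atoms(
        self, charged_paracetamol, paracetamol_library
    ):
        mr = match_library(charged_paracetamol, paracetamol_library, 3)
        assert unmatched_atoms(mr) == frozenset()

    def test_complement_of_oracle_coverage(self, phenol, charged_paracetamol):
        lib = make_self_library(charged_paracetamol, 1, seed=0)
        mr = match_library(phenol, lib, 3)
        entry = lib.entries[0]
        oracle = brute_force_k_mcf(
            phenol, entry.molecule, 3, exclude2=frozenset(entry.cap_atoms)
        )
        covered = set()
        for f in oracle:
            covered |= set(f.query_atoms)
        assert unmatched_atoms(mr) == frozenset(phenol.atoms) - covered


class TestGroupMissing:
    def test_empty(self, phenol):
        assert group_missing(phenol, frozenset(), 3) == []

    def test_single_atom_gets_its_shell(self, paracetamol):
        a = next(x for x in paracetamol.atoms if paracetamol.element(x) == "N")
        frags = group_missing(paracetamol, frozenset([a]), 3)
        assert len(frags) == 1
        f = frags[0]
        assert f.core_atoms == frozenset([a])
        assert paracetamol.k_ball(a, 3) - {a} <= f.shell_atoms

    def test_adjacent_unmatched_share_a_core(self, paracetamol):
        n = next(x for x in paracetamol.atoms if paracetamol.element(x) == "N")
        c = next(x for x in paracetamol.neighbors(n)
                 if paracetamol.element(x) == "C")
        frags = group_missing(paracetamol, frozenset([n, c]), 3)
        assert len(frags) == 1
        assert frags[0].core_atoms == frozenset([n, c])

    def test_overlapping_regions_merge(self, paracetamol):
        # two far-apart atoms whose 3-shells overlap are merged
        atoms = sorted(paracetamol.atoms)
        a, b = atoms[0], atoms[5]
        frags = group_missing(paracetamol, frozenset([a, b]), 3)
        cores = [f.core_atoms for f in frags]
        covered = set().union(*cores)
        assert {a, b} <= covered
        for i, ci in enumerate(cores):
            for j, cj in enumerate(cores):
                assert i == j or not (ci & cj)

    def test_region_closure_keeps_rings_whole(self, phenol):
        o = next(a for a in phenol.atoms if phenol.element(a) == "O")
        region = close_region(phenol, frozenset([o] + phenol.neighbors(o)))
        ring = [a for a in phenol.atoms if any(
            phenol.bond_order(a, n) == 1.5 for n in phenol.neighbors(a))]
        assert frozenset(ring) <= region

    def test_unknown_atoms_rejected(self, phenol):
        with pytest.raises(KeyError):
            group_missing(phenol, frozenset([999]), 3)


class TestSplit:
    def test_long_chain_splits_under_limit(self):
        g = chain(100)
        frag = MissingFragment(frozenset(g.atoms), frozenset(), k=3,
                               dangling=())
        pieces = split_fragment(g, frag, max_atoms=40)
        assert len(pieces) >= 3
        covered = set()
        for p in pieces:
            capped = len(p.atoms) + sum(v for _, v in p.dangling)
            assert capped <= 40
            covered |= p.core_atoms
        assert covered == frozenset(g.atoms)

    def test_small_fragment_unchanged(self, paracetamol):
        frags = group_missing(paracetamol, frozenset(list(paracetamol.atoms)[:3]), 3)
        for f in frags:
            assert split_fragment(paracetamol, f, max_atoms=40) == [f]

    def test_ring_protection_returns_oversized_whole(self):
        g = fused_macrocycle(50)
        frag = MissingFragment(frozenset(g.atoms), frozenset(), k=3, dangling=())
        pieces = split_fragment(g, frag, max_atoms=40)
        assert len(pieces) == 1
        assert pieces[0].atoms == frozenset(g.atoms)

    def test_never_cuts_cycle_bonds(self):
        """Cut bonds must be absent from an independent cycle basis."""
        g = chain(60)
        # add a ring in the middle
        g.add_bond(20, 29)
        frag = MissingFragment(frozenset(g.atoms), frozenset(), k=3, dangling=())
        pieces = split_fragment(g, frag, max_atoms=30)
        cycle_edges = set()
        for cyc in nx.cycle_basis(g.g):
            for x, y in zip(cyc, cyc[1:] + cyc[:1]):
                cycle_edges.add(frozenset((x, y)))
        for p in pieces:
            for x, y in g.g.edges:
                if frozenset((x, y)) in cycle_edges:
                    assert (x in p.atoms) == (y in p.atoms)

    def test_max_atoms_floor(self, paracetamol):
        frag = MissingFragment(frozenset(paracetamol.atoms), frozenset(), k=3)
        with pytest.raises(ValueError):
            split_fragment(paracetamol, frag, max_atoms=3)


class TestCapping:
    def test_sp3_carbon_three_hydrogens(self):
        g = read_molecule("CC", "smiles")  # ethane; keep one carbon + its H's
        c0 = next(a for a in g.atoms if g.element(a) == "C")
        region = frozenset([c0] + [n for n in g.neighbors(c0) if g.element(n) == "H"])
        frag = MissingFragment(region, frozenset(), k=0,
                               dangling=((c0, 1),))
        capped = cap_fragment(g, frag)
        assert len(capped.cap_atoms) == 1
        capped.validate()
        # a methyl radical region: the carbon had 1 severed bond -> 1 H cap
        assert all(capped.element(a) == "H" for a in capped.cap_atoms)
        assert all(capped.formal_charge(a) == 0 for a in capped.cap_atoms)

    def test_three_open_valences(self):
        g = read_molecule("CC", "smiles")
        c0, c1 = [a for a in g.atoms if g.element(a) == "C"]
        region = frozenset([c0, c1] + [n for n in g.neighbors(c1)
                                       if g.element(n) == "H"])
        # c0 lost its three hydrogens
        frag = MissingFragment(region, frozenset(), k=0, dangling=((c0, 3),))
        capped = cap_fragment(g, frag)
        assert len(capped.cap_atoms) == 3
        capped.validate()

    def test_complete_fragment_unchanged(self, phenol):
        frag = MissingFragment(frozenset(phenol.atoms), frozenset(), k=3)
        capped = cap_fragment(phenol, frag)
        assert capped.cap_atoms == []
        assert capped.n_atoms == phenol.n_atoms

    def test_aromatic_carbon_one_hydrogen(self, phenol):
        """Severing a ring C-H leaves one open valence filled by one H;
        the result is neutral and valence-valid."""
        h = next(a for a in phenol.atoms
                 if phenol.element(a) == "H"
                 and phenol.element(phenol.neighbors(a)[0]) == "C")
        region = frozenset(phenol.atoms) - {h}
        frags = group_missing(phenol, region, 0)
        # cap directly on the region
        frag = MissingFragment(region, frozenset(), k=0,
                               dangling=((phenol.neighbors(h)[0], 1),))
        capped = cap_fragment(phenol, frag)
        assert len(capped.cap_atoms) == 1
        capped.validate()
        assert sum(capped.formal_charge(a) for a in capped.atoms) == 0

    def test_missing_rule_is_an_error(self):
        g = chain(3)
        frag = MissingFragment(frozenset([0, 1]), frozenset(), k=0,
                               dangling=((1, 1),))
        empty = CapRuleTable({})
        with pytest.raises(ValidationError):
            cap_fragment(g, frag, empty)

    def test_capped_output_valence_valid_end_to_end(self, phenol, charged_paracetamol):
        lib = make_self_library(charged_paracetamol, 1, seed=0)
        mr = match_library(phenol, lib, 3)
        for f in group_missing(phenol, unmatched_atoms(mr), 3):
            for piece in split_fragment(phenol, f, 40):
                capped = cap_fragment(phenol, piece)
                capped.validate()
                assert all(capped.formal_charge(a) == 0 for a in capped.cap_atoms)


class TestCapSelection:
    RICH = [
        CapGroup("hydrogen", (("H", 1.0),), 1),
        CapGroup("methyl", (("C", 1.0), ("H", 1.0), ("H", 1.0), ("H", 1.0)), 1),
        CapGroup("dihydro", (("H", 1.0), ("H", 1.0)), 2),
    ]

    @pytest.mark.parametrize("trial", range(12))
    def test_ilp_matches_exhaustive(self, trial):
        import random

        rng = random.Random(400 + trial)
        n_dangling = rng.randrange(1, 7)
        open_vals = {a: rng.randrange(1, 4) for a in range(n_dangling)}
        groups = {a: self.RICH for a in open_vals}
        chosen = select_caps_ilp(open_vals, groups)
        heavy = sum(grp.n_heavy for grps in chosen.values() for grp in grps)
        hyd = sum(grp.n_hydrogen for grps in chosen.values() for grp in grps)
        best = exhaustive_cap_selection(open_vals, groups)
        assert best is not None
        assert (heavy, hyd) == best
        for a, v in open_vals.items():
            assert sum(grp.fill for grp in chosen[a]) == v

    def test_hydrogen_only_default(self):
        rules = default_cap_rules()
        groups = rules.groups_for("C")
        assert [g.name for g in groups] == ["hydrogen"]
        chosen = select_caps_ilp({0: 3}, {0: groups})
        assert len(chosen[0]) == 3
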