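import networkx as nx
import pytest

from fragcharge.envmatch import (
    atoms_compatible,
    brute_force_k_mcf,
    enumerate_k_mcf,
    match_library,
)
from fragcharge.fixtures import random_molecule
from fragcharge.molgraph import read_molecule

from conftest import amide_ring_carbon, hydroxyl_ipso_carbon, random_pair


class TestAtomCompatibility:
    def test_ipso_carbons_flip_between_k3_and_k4(self, phenol, paracetamol):
        """The hydroxyl-bearing ring carbons agree out to 3 bonds but
        differ at 4 (para substituent H vs N)."""
        a = hydroxyl_ipso_carbon(phenol)
        b = hydroxyl_ipso_carbon(paracetamol)
        assert atoms_compatible(phenol, a, paracetamol, b, 3)
        assert not atoms_compatible(phenol, a, paracetamol, b, 4)

    def test_symmetric(self, phenol, paracetamol):
        a = hydroxyl_ipso_carbon(phenol)
        b = hydroxyl_ipso_carbon(paracetamol)
        for k in range(5):
            assert atoms_compatible(phenol, a, paracetamol, b, k) == \
                atoms_compatible(paracetamol, b, phenol, a, k)

    def test_self_identity(self, paracetamol):
        for a in paracetamol.atoms:
            assert atoms_compatible(paracetamol, a, paracetamol, a, 4)

    def test_monotone_in_k(self):
        """Compatibility at k implies compatibility at every smaller k."""
        for trial in range(10):
            g1, g2 = random_pair(trial)
            for a in g1.atoms:
                for b in g2.atoms:
                    prev = True
                    for k in range(4):
                        cur = atoms_compatible(g1, a, g2, b, k)
                        assert prev or not cur
                        prev = cur

    def test_k0_is_label_equality(self):
        for trial in range(10):
            g1, g2 = random_pair(100 + trial)
            for a in g1.atoms:
                for b in g2.atoms:
                    assert atoms_compatible(g1, a, g2, b, 0) == (
                        g1.atom_label(a) == g2.atom_label(b)
                    )

    def test_against_networkx_rooted_isomorphism(self):
        """Independent oracle: rooted ball isomorphism via VF2 with the
        root distinguished by a temporary attribute."""
        for trial in range(15):
            g1, g2 = random_pair(200 + trial)
            k = trial % 4
            for a in sorted(g1.atoms)[:5]:
                for b in sorted(g2.atoms)[:5]:
                    b1 = g1.g.subgraph(g1.k_ball(a, k)).copy()
                    b2 = g2.g.subgraph(g2.k_ball(b, k)).copy()
                    for n in b1.nodes:
                        b1.nodes[n]["lab"] = (g1.atom_label(n), n == a)
                    for n in b2.nodes:
                        b2.nodes[n]["lab"] = (g2.atom_label(n), n == b)
                    expect = nx.is_isomorphic(
                        b1, b2, node_match=lambda x, y: x["lab"] == y["lab"]
                    )
                    assert atoms_compatible(g1, a, g2, b, k) == expect


class TestEnumeration:
    def test_phenol_paracetamol_three_atom_fragment(self, phenol, paracetamol):
        """The hydroxyl H, O and ipso C combine into the largest common
        fragment at shell size 3."""
        frags = enumerate_k_mcf(phenol, paracetamol, 3)
        top = frags[0]
        assert top.size == 3
        assert sorted(phenol.element(q) for q in top.query_atoms) == ["C", "H", "O"]
        ipso = hydroxyl_ipso_carbon(phenol)
        assert ipso in top.query_atoms

    def test_self_match_includes_whole_molecule(self, phenol):
        frags = enumerate_k_mcf(phenol, phenol, 3)
        top = frags[0]
        assert top.size == phenol.n_atoms
        assert all(q == r for q, r in top.mapping)

    def test_methane_ethane_single_hydrogens(self):
        """The carbons differ in their 1-neighborhoods, so only the four
        methane hydrogens match."""
        methane = read_molecule("C", "smiles")
        ethane = read_molecule("CC", "smiles")
        frags = enumerate_k_mcf(methane, ethane, 1)
        assert len(frags) == 4
        assert all(f.size == 1 for f in frags)
        assert all(
            methane.element(f.query_atoms[0]) == "H" for f in frags
        )

    def test_shell_atoms_are_k_ball_minus_core(self, phenol, paracetamol):
        for f in enumerate_k_mcf(phenol, paracetamol, 3):
            core = set(f.query_atoms)
            shell = set()
            for q in core:
                shell |= phenol.k_ball(q, 3)
            assert f.shell_atoms == frozenset(shell - core)

    def test_fragments_are_induced_isomorphisms(self, phenol, dpa):
        """Independent check: every returned mapping is an induced
        subgraph isomorphism with matching labels (networkx)."""
        for f in enumerate_k_mcf(phenol, dpa, 3):
            mp = dict(f.mapping)
            sub_q = phenol.g.subgraph(mp.keys())
            sub_r = dpa.g.subgraph(mp.values())
            assert sub_q.number_of_edges() == sub_r.number_of_edges()
            for (a, b) in sub_q.edges:
                assert sub_r.has_edge(mp[a], mp[b])
            for q, r in mp.items():
                assert phenol.atom_label(q) == dpa.atom_label(r)
            assert nx.is_connected(sub_q) or f.size == 1

    def test_no_fragment_is_submapping_of_another(self, phenol, paracetamol):
        raws = enumerate_k_mcf(phenol, paracetamol, 3, raw=True)
        for i, a in enumerate(raws):
            for j, b in enumerate(raws):
                assert i == j or not (a < b)

    def test_deterministic(self, phenol, dpa):
        one = enumerate_k_mcf(phenol, dpa, 3)
        two = enumerate_k_mcf(phenol, dpa, 3)
        assert [(f.mapping, f.shell_atoms) for f in one] == \
            [(f.mapping, f.shell_atoms) for f in two]

    @pytest.mark.parametrize("trial", range(30))
    def test_oracle_equivalence_random(self, trial):
        """Complete enumeration agrees with exhaustive growth both as
        raw maximal pair-sets and after collapsing to cores."""
        g1, g2 = random_pair(trial)
        k = trial % 4
        assert set(enumerate_k_mcf(g1, g2, k, raw=True)) == \
            set(brute_force_k_mcf(g1, g2, k, raw=True))
        en = [(f.query_atoms, f.mapping) for f in enumerate_k_mcf(g1, g2, k)]
        bf = [(f.query_atoms, f.mapping) for f in brute_force_k_mcf(g1, g2, k)]
        assert en == bf

    def test_brute_force_refuses_large_instances(self, paracetamol, dpa):
        with pytest.raises(ValueError, match="too large"):
            brute_force_k_mcf(paracetamol, dpa, 3)

    def test_single_atom_pair(self):
        c1 = random_molecule(1, ("C",), seed=1)
        c2 = random_molecule(1, ("C",), seed=2)
        frags = brute_force_k_mcf(c1, c2, 0)
        assert len(frags) == 1 and frags[0].size == 1


class TestMatchLibrary:
    def test_self_retrieval(self, charged_paracetamol, paracetamol_library):
        mr = match_library(charged_paracetamol, paracetamol_library, 3)
        assert mr.fragments[0].size >= charged_paracetamol.n_atoms - 1
        assert mr.missing == frozenset()

    def test_phenol_against_paracetamol_library(self, phenol, charged_paracetamol):
        from fragcharge.fixtures import make_self_library

        lib = make_self_library(charged_paracetamol, 1, seed=0)
        mr = match_library(phenol, lib, 3)
        assert mr.fragments[0].size == 3
        # fragment charge is the sum of mapped reference charges
        f = mr.fragments[0]
        mol = lib[f.library_id].molecule
        assert f.fragment_charge == pytest.approx(
            sum(mol.partial_charge(r) for _, r in f.mapping)
        )

    def test_matched_set_agrees_with_oracle(self, phenol, charged_paracetamol):
        from fragcharge.fixtures import make_self_library

        lib = make_self_library(charged_paracetamol, 1, seed=0)
        mr = match_library(phenol, lib, 3)
        entry = lib.entries[0]
        oracle = brute_force_k_mcf(
            phenol, entry.molecule, 3, exclude2=frozenset(entry.cap_atoms)
        )
        covered = set()
        for f in oracle:
            covered |= set(f.query_atoms)
        assert mr.matched == frozenset(covered)

    def test_empty_library_rejected(self, phenol):
        from fragcharge.molgraph import FragmentLibrary

        with pytest.raises(ValueError, match="empty"):
            match_library(phenol, FragmentLibrary(), 3)

    def test_ranking_and_report(self, phenol, charged_paracetamol):
        from fragcharge.fixtures import make_self_library

        lib = make_self_library(charged_paracetamol, 1, seed=0)
        mr = match_library(phenol, lib, 3)
        sizes = [f.size for f in mr.fragments]
        assert sizes == sorted(sizes, reverse=True)
        doc = mr.to_json()
        assert doc["shell_size"] == 3
        assert len(doc["atom_status"]) == phenol.n_atoms
        assert doc["fragments"][0]["size"] == sizes[0]


def test_amide_ring_carbon_fragment_is_single_atom(paracetamol, dpa):
    """Between paracetamol and N,2-diphenylacetamide the ring carbon
    bonded to the amide nitrogen matches alone: its neighbors' shells
    diverge (methyl vs benzyl/phenyl) within 3 bonds."""
    ring_c = amide_ring_carbon(paracetamol)
    frags = enumerate_k_mcf(paracetamol, dpa, 3)
    containing = [f for f in frags if ring_c in f.query_atoms]
    assert containing and max(f.size for f in containing) == 1
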