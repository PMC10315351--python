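import random

import pytest

from fragcharge.fixtures import (
    builtin,
    make_self_library,
    random_molecule,
    synthetic_charges,
)


@pytest.fixture(scope="session")
def phenol():
    return builtin("phenol")


@pytest.fixture(scope="session")
def paracetamol():
    return builtin("paracetamol")


@pytest.fixture(scope="session")
def dpa():
    return builtin("n2_diphenylacetamide")


@pytest.fixture(scope="session")
def paclitaxel():
    return builtin("paclitaxel")


@pytest.fixture(scope="session")
def charged_paracetamol():
    return synthetic_charges(builtin("paracetamol"), seed=5)


@pytest.fixture(scope="session")
def paracetamol_library(charged_paracetamol):
    return make_self_library(charged_paracetamol, 3, min_overlap=2, seed=2)


def random_pair(trial: int):
    """A deterministic random molecule pair for oracle comparisons."""
    rng = random.Random(9000 + trial)
    g1 = random_molecule(rng.randrange(2, 11), seed=2 * trial)
    g2 = random_molecule(rng.randrange(2, 11), seed=2 * trial + 1)
    return g1, g2


def amide_ring_carbon(g):
    """The aromatic carbon bonded to the amide nitrogen."""
    for a in g.atoms:
        if g.element(a) != "N":
            continue
        for n in g.neighbors(a):
            if g.element(n) == "C" and any(
                g.bond_order(n, x) == 1.5 for x in g.neighbors(n)
            ):
                return n
    raise AssertionError("no ring carbon bonded to an amide nitrogen")


def hydroxyl_ipso_carbon(g):
    """The ring carbon bearing the hydroxyl group."""
    for a in g.atoms:
        if g.element(a) == "O" and any(g.element(n) == "H" for n in g.neighbors(a)):
            return next(n for n in g.neighbors(a) if g.element(n) == "C")
    raise AssertionError("no hydroxyl group found")
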