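"""Charge transfer, conflict resolution, residual correction, symmetrization.

Charges transferred from different reference fragments can disagree on
atoms where fragments overlap (long-range effects and ESP-fit
uncertainty).  Each query atom therefore accumulates a list of
*candidate* charges with provenance; conflicts are resolved by
selecting one candidate, averaging the distinct values, or entering a
value manually.  Because the candidates come from independent
molecules, the finished sum rarely hits the target integer net charge
exactly; the difference (the *residual charge*) is removed by
subtracting residual/N from every atom.  An optional symmetrization
step averages charges over topologically equivalent atoms.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .envmatch import FragmentMatch, MatchResult, match_library
from .molgraph import FragmentLibrary, MolecularGraph

__all__ = [
    "Candidate",
    "ChargeState",
    "apply_fragment",
    "resolve_conflict",
    "resolve_all",
    "residual_charge",
    "redistribute_residual",
    "symmetrize",
    "equivalence_classes",
    "greedy_assign",
    "multi_seed_assign",
]

#: post-redistribution |sum - target| bound, elementary charge
RESIDUAL_TOL = 1e-6


@dataclass(frozen=True)
class Candidate:
    value: float
    provenance: str  # "library_id:ref_atom" or "manual"


@dataclass
class ChargeState:
    """Per-atom candidate charges, resolution status and final values."""

    n_atoms: int
    target_charge: int
    candidates: list[list[Candidate]] = field(default_factory=list)
    resolved: list[Optional[float]] = field(default_factory=list)
    status: list[str] = field(default_factory=list)  # unassigned|assigned|conflict|manual

    def __post_init__(self):
        if not self.candidates:
            self.candidates = [[] for _ in range(self.n_atoms)]
        if not self.resolved:
            self.resolved = [None] * self.n_atoms
        if not self.status:
            self.status = ["unassigned"] * self.n_atoms

    @classmethod
    def for_molecule(cls, g: MolecularGraph, target_charge: Optional[int] = None) -> "ChargeState":
        return cls(
            n_atoms=g.n_atoms,
            target_charge=g.net_charge if target_charge is None else int(target_charge),
        )

    def distinct_values(self, a: int) -> list[float]:
        seen: list[float] = []
        for c in self.candidates[a]:
            if c.value not in seen:
                seen.append(c.value)
        return seen

    @property
    def conflicts(self) -> list[int]:
        return [a for a, s in enumerate(self.status) if s == "conflict"]

    @property
    def unresolved(self) -> list[int]:
        return [a for a, q in enumerate(self.resolved) if q is None]

    def all_resolved(self) -> bool:
        return not self.unresolved

    def copy(self) -> "ChargeState":
        return ChargeState(
            n_atoms=self.n_atoms,
            target_charge=self.target_charge,
            candidates=[list(c) for c in self.candidates],
            resolved=list(self.resolved),
            status=list(self.status),
        )


def apply_fragment(state: ChargeState, match: FragmentMatch, lib: FragmentLibrary) -> ChargeState:
    """Transfer reference charges from a matched fragment onto the query.

    Each mapped reference atom's charge is appended as a candidate for
    the corresponding query atom.  Equal values collapse, so re-applying
    a fragment is idempotent; a second *distinct* value puts the atom in
    conflict until resolved.
    """
    if match.library_id is None or match.library_id not in lib:
        raise KeyError(f"unknown library_id {match.library_id!r}")
    mol = lib[match.library_id].molecule
    for q, r in match.mapping:
        if q >= state.n_atoms:
            raise KeyError(f"query atom {q} outside charge state")
        value = mol.partial_charge(r)
        cand = Candidate(value, f"{match.library_id}:{r}")
        if cand not in state.candidates[q]:
            state.candidates[q].append(cand)
        if state.status[q] == "manual":
            continue  # manual entry outranks transferred values
        distinct = state.distinct_values(q)
        if len(distinct) == 1:
            state.resolved[q] = distinct[0]
            state.status[q] = "assigned"
        else:
            state.resolved[q] = None
            state.status[q] = "conflict"
    return state


def resolve_conflict(state: ChargeState, atom: int, policy) -> ChargeState:
    """Resolve one atom per policy: ``("select", i)``, ``"average"`` or
    ``("manual", value)``.

    ``select`` chooses among the *distinct* candidate values in entry
    order; ``average`` takes their arithmetic mean; ``manual`` accepts
    any atom, conflicted or not.
    """
    if atom < 0 or atom >= state.n_atoms:
        raise KeyError(f"unknown atom {atom}")
    if isinstance(policy, tuple) and policy[0] == "manual":
        value = float(policy[1])
        state.candidates[atom].append(Candidate(value, "manual"))
        state.resolved[atom] = value
        state.status[atom] = "manual"
        return state
    distinct = state.distinct_values(atom)
    if not distinct:
        raise ValueError(f"atom {atom} has no candidate charges")
    if policy == "average":
        state.resolved[atom] = math.fsum(distinct) / len(distinct)
    elif isinstance(policy, tuple) and policy[0] == "select":
        idx = int(policy[1])
        if not 0 <= idx < len(distinct):
            raise IndexError(
                f"select index {idx} out of range for {len(distinct)} candidates"
            )
        state.resolved[atom] = distinct[idx]
    else:
        raise ValueError(f"unknown policy {policy!r}")
    state.status[atom] = "assigned"
    return state


def resolve_all(state: ChargeState, policy: str = "average") -> ChargeState:
    """Resolve every conflicted atom with the same policy."""
    for a in list(state.conflicts):
        resolve_conflict(state, a, policy)
    return state


def residual_charge(state: ChargeState) -> float:
    """sum(resolved) - target: positive means excess positive charge."""
    if not state.all_resolved():
        raise ValueError(f"unresolved atoms: {state.unresolved}")
    return math.fsum(state.resolved) - state.target_charge


def redistribute_residual(state: ChargeState) -> ChargeState:
    """Subtract residual/N from every atom so the sum hits the target.

    Idempotent after the first application (the residual becomes ~0 at
    machine precision, far below :data:`RESIDUAL_TOL`).
    """
    if state.n_atoms == 0:
        raise ValueError("cannot redistribute over zero atoms")
    res = residual_charge(state)
    if res == 0.0:
        return state
    per_atom = res / state.n_atoms
    state.resolved = [q - per_atom for q in state.resolved]
    # absorb the last floating-point crumbs on the first atom
    leftover = math.fsum(state.resolved) - state.target_charge
    if leftover != 0.0:
        state.resolved[0] -= leftover
    return state


# ---------------------------------------------------------------------------
# topological symmetry


def equivalence_classes(g: MolecularGraph, exact_limit: int = 150) -> list[frozenset[int]]:
    """Orbits of topologically equivalent atoms.

    Refinement classes are computed first; for molecules up to
    ``exact_limit`` atoms each class is then confirmed by an exact
    automorphism search (two atoms stay together only if some
    label-preserving automorphism maps one onto the other), which
    removes the rare refinement false-merges.
    """
    from .envmatch import _extend_embedding  # local import avoids cycle at import time

    colors = g.wl_colors()
    classes: dict[int, list[int]] = {}
    for a in g.atoms:
        classes.setdefault(colors[a], []).append(a)
    if g.n_atoms > exact_limit:
        return [frozenset(v) for v in classes.values()]
    out: list[frozenset[int]] = []
    all_atoms = frozenset(g.atoms)
    for members in classes.values():
        groups: list[list[int]] = []
        for a in members:
            placed = False
            for grp in groups:
                rep = grp[0]
                if _extend_embedding(
                    g, all_atoms, g, {rep: a},
                    prefer_identity=True, budget=50 * g.n_atoms + 5000,
                ) is not None:
                    grp.append(a)
                    placed = True
                    break
            if not placed:
                groups.append([a])
        out.extend(frozenset(grp) for grp in groups)
    return out


def symmetrize(state: ChargeState, g: MolecularGraph) -> ChargeState:
    """Average resolved charges within each topological equivalence class.

    Idempotent; the total charge is unchanged (class means preserve the
    sum).
    """
    if not state.all_resolved():
        raise ValueError(f"unresolved atoms: {state.unresolved}")
    for cls in equivalence_classes(g):
        if len(cls) < 2:
            continue
        mean = math.fsum(state.resolved[a] for a in cls) / len(cls)
        for a in cls:
            state.resolved[a] = mean
    return state


# ---------------------------------------------------------------------------
# automated (greedy) assignment protocol


def greedy_assign(
    query: MolecularGraph,
    lib: FragmentLibrary,
    k: int = 3,
    seed: int = 0,
    policy: str = "average",
    target_charge: Optional[int] = None,
    do_symmetrize: bool = False,
    match_result: Optional[MatchResult] = None,
    manual_charges: Optional[dict[int, float]] = None,
) -> tuple[ChargeState, list[dict]]:
    """Automated stand-in for interactive fragment selection.

    Starting from a seeded random atom, repeatedly pick an unassigned
    atom and apply the largest fragment covering it, preferring
    fragments that do not overlap atoms already assigned (falling back
    to the largest covering fragment when every candidate overlaps).
    Conflicts are then resolved by ``policy`` and the residual charge is
    redistributed uniformly.  Returns the finished state and a log with
    one record per fragment decision.
    """
    mr = match_result if match_result is not None else match_library(query, lib, k)
    state = ChargeState.for_molecule(query, target_charge)
    manual = dict(manual_charges or {})
    rng = random.Random(seed)
    log: list[dict] = []
    covered: set[int] = set()
    applied: set[int] = set()

    def candidates_for(atom: int) -> list[int]:
        return [i for i in mr.per_atom[atom] if i not in applied]

    while True:
        open_atoms = sorted(
            a for a in query.atoms
            if a not in covered and a not in manual and mr.per_atom[a]
        )
        if not open_atoms:
            break
        start = rng.choice(open_atoms)
        cand = candidates_for(start)
        if not cand:
            covered.add(start)  # every covering fragment already applied
            continue
        # take the largest covering fragment; among equally large ones
        # prefer those not overlapping already-assigned atoms
        top = mr.fragments[cand[0]].size
        tied = [i for i in cand if mr.fragments[i].size == top]
        non_overlap = [
            i for i in tied
            if not (set(mr.fragments[i].query_atoms) & covered)
        ]
        pick = non_overlap[0] if non_overlap else cand[0]  # lists are rank-ordered
        frag = mr.fragments[pick]
        apply_fragment(state, frag, lib)
        applied.add(pick)
        covered.update(frag.query_atoms)
        log.append(
            {
                "fragment": pick,
                "library_id": frag.library_id,
                "size": frag.size,
                "fragment_charge": round(frag.fragment_charge, 6)
                if frag.fragment_charge is not None else None,
                "start_atom": start,
                "overlap": bool(not non_overlap),
            }
        )
    for a, v in manual.items():
        resolve_conflict(state, a, ("manual", v))
    resolve_all(state, policy)
    if not state.all_resolved():
        raise ValueError(
            "atoms without any matching fragment and no manual charge: "
            f"{state.unresolved}"
        )
    redistribute_residual(state)
    if do_symmetrize:
        symmetrize(state, query)
    return state, log


def multi_seed_assign(
    query: MolecularGraph,
    lib: FragmentLibrary,
    seeds: Sequence[int],
    k: int = 3,
    policy: str = "average",
    target_charge: Optional[int] = None,
    do_symmetrize: bool = False,
) -> dict:
    """Run the greedy protocol once per seed and report per-atom spread.

    Returns per-seed charge vectors plus the per-atom mean and standard
    deviation across seeds — the multi-start consistency check.
    """
    mr = match_library(query, lib, k)
    runs = []
    for s in seeds:
        state, log = greedy_assign(
            query, lib, k, seed=s, policy=policy, target_charge=target_charge,
            do_symmetrize=do_symmetrize, match_result=mr,
        )
        runs.append({"seed": s, "charges": list(state.resolved), "log": log})
    n = query.n_atoms
    mean, std = [], []
    for a in range(n):
        vals = [r["charges"][a] for r in runs]
        if min(vals) == max(vals):  # exact agreement across starts
            mean.append(vals[0])
            std.append(0.0)
            continue
        m = math.fsum(vals) / len(vals)
        mean.append(m)
        std.append(math.sqrt(math.fsum((v - m) ** 2 for v in vals) / len(vals)))
    return {"seeds": list(seeds), "runs": runs, "mean": mean, "std": std}
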