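"""Valence-constrained molecule-editing Markov decision process.

A state is a pair ``(m, t)`` of a valid molecule (canonical SMILES, ``""``
for the empty molecule) and the number of edit steps taken so far; episodes
terminate when ``t`` reaches the horizon ``T``.  Actions are the single-step
graph edits that keep the molecule chemically valid:

* **atom addition** — attach a new atom of the allowed element set to any
  atom with free valence, with every valence-allowed bond order (additions
  replace implicit hydrogens);
* **bond addition** — create a bond between two atoms with free valence, or
  raise an existing non-aromatic bond's order;
* **bond removal** — lower or delete an existing non-aromatic bond, kept
  only when the product has at most one disconnected atom (which is then
  deleted, so products are always single fragments);
* **no modification** — keep the molecule unchanged for one step.

Two chemistry heuristics restrict bond addition: pairs of atoms that are
both in rings may not gain a bond (high-strain products), and any new ring
must have a whitelisted size.  Aromatic bonds are never edited directly,
although aromatic systems can still form (via alternating single/double
additions) or break (via edits elsewhere) and are re-perceived on
sanitization.

Every action is represented by its product: the successor molecule's
canonical SMILES is the action's identity, so symmetry-equivalent edits
collapse to one action.  The transition function is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from rdkit import Chem

from .chem import (
    BOND_TYPES,
    MAX_VALENCE,
    canonicalize,
    mol_from_smiles,
    sanitize_ok,
)

__all__ = [
    "ActionKind",
    "Action",
    "MoleculeState",
    "MDPConfig",
    "StateError",
    "ActionError",
    "enumerate_atom_additions",
    "enumerate_bond_additions",
    "enumerate_bond_removals",
    "valid_actions",
    "step",
    "clear_action_cache",
]


class StateError(RuntimeError):
    """An operation was applied to a state that cannot accept it."""


class ActionError(ValueError):
    """An action was used on a state whose valid set does not contain it."""


class ActionKind(str, Enum):
    ATOM_ADDITION = "atom_addition"
    BOND_ADDITION = "bond_addition"
    BOND_REMOVAL = "bond_removal"
    NO_MODIFICATION = "no_modification"


@dataclass(frozen=True, order=True)
class Action:
    """One valence-legal edit, identified by the molecule it produces."""

    result_molecule: str
    kind: ActionKind = field(compare=False)

    def to_json_dict(self) -> dict:
        return {"kind": self.kind.value, "result_smiles": self.result_molecule}


@dataclass(frozen=True)
class MoleculeState:
    """MDP state ``s = (m, t)``: canonical SMILES plus step counter."""

    molecule: str = ""
    steps_taken: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "molecule", canonicalize(self.molecule))
        if self.steps_taken < 0:
            raise ValueError("steps_taken must be non-negative")

    def is_terminal(self, config: "MDPConfig") -> bool:
        return self.steps_taken >= config.max_steps


@dataclass(frozen=True)
class MDPConfig:
    """Static description of one editing environment.

    Parameters
    ----------
    element_set:
        Elements available for atom addition.
    max_steps:
        Episode horizon ``T``.
    allowed_ring_sizes:
        Sizes a *newly formed* ring may have.  Larger rings can still arise
        indirectly, e.g. by bridging and then removing the bridge bond.
    ring_pair_rule:
        Which atom pairs the in-ring strain heuristic forbids from gaining
        bonds: ``"both"`` (default; both endpoints already in rings),
        ``"either"`` (at least one endpoint in a ring), or ``"none"``.
    """

    element_set: frozenset = frozenset({"C", "O", "N"})
    max_steps: int = 40
    allowed_ring_sizes: frozenset = frozenset({5, 6})
    allow_atom_addition: bool = True
    allow_bond_addition: bool = True
    allow_bond_removal: bool = True
    allow_no_modification: bool = True
    start_molecule: str = ""
    ring_pair_rule: str = "both"

    def __post_init__(self) -> None:
        object.__setattr__(self, "element_set", frozenset(self.element_set))
        object.__setattr__(self, "allowed_ring_sizes", frozenset(self.allowed_ring_sizes))
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        if self.allow_atom_addition and not self.element_set:
            raise ValueError("element_set must be non-empty when atom addition is on")
        if not self.allowed_ring_sizes <= {3, 4, 5, 6, 7, 8}:
            raise ValueError("allowed_ring_sizes must be a subset of {3..8}")
        if self.ring_pair_rule not in {"both", "either", "none"}:
            raise ValueError("ring_pair_rule must be 'both', 'either' or 'none'")
        unknown = self.element_set - MAX_VALENCE.keys()
        if unknown:
            raise ValueError(f"unsupported elements: {sorted(unknown)}")
        # fail early on a bad start molecule
        canonicalize(self.start_molecule)


def _free_valence_atoms(mol: Chem.Mol) -> dict[int, list[int]]:
    """Atom indices with at least 1, 2 or 3 replaceable hydrogens.

    Free valence is the default element valence minus the explicit
    bond-order sum, which for the neutral standard-valence molecules this
    MDP produces equals the (implicit + explicit) hydrogen count.
    """
    return {
        order: [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= order]
        for order in (1, 2, 3)
    }


def enumerate_atom_additions(smiles: str, config: MDPConfig) -> set[Action]:
    """All single-atom attachments that sanitize, one per distinct product.

    From the empty molecule the only additions are the single-atom seed
    molecules of the element set.
    """
    mol = mol_from_smiles(smiles)
    if mol is None:
        return {
            Action(canonicalize(e), ActionKind.ATOM_ADDITION)
            for e in config.element_set
        }
    free = _free_valence_atoms(mol)
    products: set[str] = set()
    for element in config.element_set:
        for order in range(1, min(MAX_VALENCE[element], 3) + 1):
            for idx in free[order]:
                edited = Chem.RWMol(mol)
                new_idx = edited.AddAtom(Chem.Atom(element))
                edited.AddBond(idx, new_idx, BOND_TYPES[order])
                if sanitize_ok(edited):
                    products.add(Chem.MolToSmiles(edited))
    return {Action(p, ActionKind.ATOM_ADDITION) for p in products}


def _ring_pair_forbidden(mol: Chem.Mol, a1: int, a2: int, rule: str) -> bool:
    in1 = mol.GetAtomWithIdx(a1).IsInRing()
    in2 = mol.GetAtomWithIdx(a2).IsInRing()
    if rule == "both":
        return in1 and in2
    if rule == "either":
        return in1 or in2
    return False


def enumerate_bond_additions(smiles: str, config: MDPConfig) -> set[Action]:
    """Bond creations and order increases between atoms with free valence.

    Excluded: pairs caught by the in-ring strain rule, new rings whose size
    is not whitelisted, aromatic bonds, and any product that fails
    sanitization.  (No bond -> single/double/triple, single -> double/triple,
    double -> triple.)
    """
    mol = mol_from_smiles(smiles)
    if mol is None:
        return set()
    free = _free_valence_atoms(mol)
    products: set[str] = set()
    for order in (1, 2, 3):
        for a1, a2 in itertools.combinations(free[order], 2):
            if _ring_pair_forbidden(mol, a1, a2, config.ring_pair_rule):
                continue
            bond = mol.GetBondBetweenAtoms(a1, a2)
            edited = Chem.RWMol(mol)
            # Work on the Kekulé form so bond orders are explicit; aromatic
            # systems are re-perceived by sanitization afterwards.
            Chem.Kekulize(edited, clearAromaticFlags=True)
            if bond is not None:
                if bond.GetBondType() not in BOND_TYPES:
                    continue  # aromatic bond: never edited directly
                new_order = BOND_TYPES.index(bond.GetBondType()) + order
                if new_order >= len(BOND_TYPES):
                    continue
                edited.GetBondWithIdx(bond.GetIdx()).SetBondType(BOND_TYPES[new_order])
            else:
                # bond creation closes a ring of |shortest path| atoms
                path = Chem.rdmolops.GetShortestPath(mol, a1, a2)
                if len(path) not in config.allowed_ring_sizes:
                    continue
                edited.AddBond(a1, a2, BOND_TYPES[order])
            if sanitize_ok(edited):
                products.add(Chem.MolToSmiles(edited))
    return {Action(p, ActionKind.BOND_ADDITION) for p in products}


def enumerate_bond_removals(smiles: str) -> set[Action]:
    """Bond-order decreases and removals of existing non-aromatic bonds.

    Complete removal is kept only when the product has zero or one
    disconnected atom; a single disconnected atom is deleted from the
    product, so no multi-fragment molecule is ever emitted.
    """
    mol = mol_from_smiles(smiles)
    if mol is None:
        return set()
    products: set[str] = set()
    for decrement in (1, 2, 3):
        for bond in mol.GetBonds():
            if bond.GetBondType() not in BOND_TYPES:
                continue  # aromatic bond: never broken directly
            new_order = BOND_TYPES.index(bond.GetBondType()) - decrement
            if new_order < 0:
                continue
            edited = Chem.RWMol(mol)
            Chem.Kekulize(edited, clearAromaticFlags=True)
            a1, a2 = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if new_order > 0:
                edited.GetBondBetweenAtoms(a1, a2).SetBondType(BOND_TYPES[new_order])
            else:
                edited.RemoveBond(a1, a2)
            if not sanitize_ok(edited):
                continue
            frags = Chem.GetMolFrags(edited)
            if len(frags) == 1:
                products.add(Chem.MolToSmiles(edited))
            elif len(frags) == 2:
                sizes = sorted(len(f) for f in frags)
                if sizes[0] == 1 and sizes[1] > 1:
                    lone_atom = min(frags, key=len)[0]
                    edited.RemoveAtom(lone_atom)
                    if sanitize_ok(edited):
                        products.add(Chem.MolToSmiles(edited))
            # >2 fragments cannot occur from removing one bond
    return {Action(p, ActionKind.BOND_REMOVAL) for p in products}


# Enumerating the action set of a molecule is the hot loop of every rollout;
# states recur constantly across episodes, so results are memoized.
_ACTION_CACHE: dict[tuple[str, MDPConfig], tuple[Action, ...]] = {}
_ACTION_CACHE_MAX = 150_000


def clear_action_cache() -> None:
    _ACTION_CACHE.clear()


def valid_actions(state: MoleculeState, config: MDPConfig) -> tuple[Action, ...]:
    """The full valid action set of a non-terminal state.

    The union of the three edit families (gated by the config flags) plus
    the no-op, deduplicated by canonical successor SMILES (the first family
    in atom-addition, bond-addition, bond-removal order labels a duplicated
    product) and sorted by successor SMILES for deterministic indexing.
    """
    if state.is_terminal(config):
        raise StateError(f"state at t={state.steps_taken} is terminal")
    key = (state.molecule, config)
    cached = _ACTION_CACHE.get(key)
    if cached is not None:
        return cached

    by_product: dict[str, Action] = {}

    def _merge(actions: Iterable[Action]) -> None:
        for action in sorted(actions):
            by_product.setdefault(action.result_molecule, action)

    if config.allow_atom_addition:
        _merge(enumerate_atom_additions(state.molecule, config))
    if config.allow_bond_addition:
        _merge(enumerate_bond_additions(state.molecule, config))
    if config.allow_bond_removal:
        _merge(enumerate_bond_removals(state.molecule))
    if config.allow_no_modification:
        by_product.setdefault(
            state.molecule, Action(state.molecule, ActionKind.NO_MODIFICATION)
        )
    if not by_product:
        # Degenerate configs (all families off, or a saturated molecule with
        # everything disabled) still need a non-empty action set.
        by_product[state.molecule] = Action(state.molecule, ActionKind.NO_MODIFICATION)

    result = tuple(sorted(by_product.values()))
    if len(_ACTION_CACHE) >= _ACTION_CACHE_MAX:
        _ACTION_CACHE.clear()
    _ACTION_CACHE[key] = result
    return result


def step(state: MoleculeState, action: Action, config: MDPConfig) -> MoleculeState:
    """Deterministic transition: apply ``action`` and advance the clock.

    ``action`` must be a member of ``valid_actions(state, config)``.
    """
    if state.is_terminal(config):
        raise StateError("cannot step a terminal state")
    allowed = {a.result_molecule for a in valid_actions(state, config)}
    if action.result_molecule not in allowed:
        raise ActionError(
            f"action -> {action.result_molecule!r} is not valid for {state.molecule!r}"
        )
    return MoleculeState(action.result_molecule, state.steps_taken + 1)
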