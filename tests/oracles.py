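"""Independent brute-force oracle for the action space.

Instead of prefiltering by free valence, the oracle attempts *every*
conceivable single edit — each element attached to each atom with each
bond order, every bond order between every atom pair, every decrement of
every bond — applies the chemistry heuristics as written (no new bonds
between two in-ring atoms, new-ring-size whitelist, no aromatic-bond
edits, the one-disconnected-atom cleanup), and keeps the products that
survive RDKit sanitization.  Deduplication is by canonical SMILES.
"""

import itertools

from rdkit import Chem

_ORDERS = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def _sanitized_smiles(rwmol):
    if Chem.SanitizeMol(rwmol, catchErrors=True) != Chem.SanitizeFlags.SANITIZE_NONE:
        return None
    # neutral standard-valence chemistry only: sanitization's cleanup step can
    # rescue hypervalent edits by introducing formal charges (e.g. nitrile
    # N-oxides); those are outside the action space
    if any(a.GetFormalCharge() != 0 or a.GetNumRadicalElectrons() != 0
           for a in rwmol.GetAtoms()):
        return None
    return Chem.MolToSmiles(rwmol)


def brute_force_atom_additions(smiles, elements):
    if not smiles:
        return {Chem.CanonSmiles(e) for e in elements}
    mol = Chem.MolFromSmiles(smiles)
    products = set()
    for element, order, idx in itertools.product(
        elements, (1, 2, 3), range(mol.GetNumAtoms())
    ):
        rw = Chem.RWMol(mol)
        new_idx = rw.AddAtom(Chem.Atom(element))
        rw.AddBond(idx, new_idx, _ORDERS[order])
        smi = _sanitized_smiles(rw)
        if smi is not None:
            products.add(smi)
    return products


def brute_force_bond_additions(smiles, allowed_ring_sizes):
    if not smiles:
        return set()
    mol = Chem.MolFromSmiles(smiles)
    products = set()
    n = mol.GetNumAtoms()
    for a1, a2 in itertools.combinations(range(n), 2):
        if mol.GetAtomWithIdx(a1).IsInRing() and mol.GetAtomWithIdx(a2).IsInRing():
            continue
        existing = mol.GetBondBetweenAtoms(a1, a2)
        if existing is not None and existing.GetBondType() not in _ORDERS.values():
            continue  # aromatic bond: not edited
        current = (list(_ORDERS.values()).index(existing.GetBondType()) + 1
                   if existing is not None else 0)
        if existing is None:
            path = Chem.rdmolops.GetShortestPath(mol, a1, a2)
            if len(path) not in allowed_ring_sizes:
                continue
        for target in range(current + 1, 4):
            rw = Chem.RWMol(mol)
            Chem.Kekulize(rw, clearAromaticFlags=True)
            if existing is not None:
                rw.GetBondBetweenAtoms(a1, a2).SetBondType(_ORDERS[target])
            else:
                rw.AddBond(a1, a2, _ORDERS[target])
            smi = _sanitized_smiles(rw)
            if smi is not None:
                products.add(smi)
    return products


def brute_force_bond_removals(smiles):
    if not smiles:
        return set()
    mol = Chem.MolFromSmiles(smiles)
    products = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() not in _ORDERS.values():
            continue  # aromatic bond: not broken
        current = list(_ORDERS.values()).index(bond.GetBondType()) + 1
        a1, a2 = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for target in range(current):
            rw = Chem.RWMol(mol)
            Chem.Kekulize(rw, clearAromaticFlags=True)
            if target > 0:
                rw.GetBondBetweenAtoms(a1, a2).SetBondType(_ORDERS[target])
                smi = _sanitized_smiles(rw)
                if smi is not None:
                    products.add(smi)
                continue
            rw.RemoveBond(a1, a2)
            if Chem.SanitizeMol(rw, catchErrors=True) != Chem.SanitizeFlags.SANITIZE_NONE:
                continue
            frags = Chem.GetMolFrags(rw)
            if len(frags) == 1:
                products.add(Chem.MolToSmiles(rw))
            elif len(frags) == 2 and sorted(map(len, frags)) != [1, 1]:
                sizes = sorted(map(len, frags))
                if sizes[0] == 1:
                    rw.RemoveAtom(min(frags, key=len)[0])
                    smi = _sanitized_smiles(rw)
                    if smi is not None:
                        products.add(smi)
    return products


def brute_force_valid_actions(smiles, elements, allowed_ring_sizes, no_op=True):
    products = (
        brute_force_atom_additions(smiles, elements)
        | brute_force_bond_additions(smiles, allowed_ring_sizes)
        | brute_force_bond_removals(smiles)
    )
    if no_op:
        products.add(smiles)
    return products
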