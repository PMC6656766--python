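"""Small RDKit helpers shared across the package.

All molecule handling in this package goes through canonical SMILES without
stereochemistry: the edit operators are stereo-agnostic, so stereo marks on
input molecules are dropped (with a logged warning) rather than propagated
inconsistently through edits.
"""

from __future__ import annotations

import logging
from functools import lru_cache

from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about every failed sanitization; the action enumerator
# probes many illegal edits on purpose.
RDLogger.DisableLog("rdApp.*")

#: Bond order -> RDKit bond type. Index 0 (no bond) is a placeholder.
BOND_TYPES = [None, Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE]

#: Default (neutral, lowest) valences of the elements the editor supports.
MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1}


class InvalidMoleculeError(ValueError):
    """Raised when an input SMILES does not parse or sanitize."""


def mol_from_smiles(smiles: str) -> Chem.Mol | None:
    """Parse a SMILES string; '' denotes the empty molecule and returns None.

    Raises :class:`InvalidMoleculeError` for strings that do not parse or do
    not survive valence/aromaticity sanitization.
    """
    if not smiles:
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"SMILES does not parse/sanitize: {smiles!r}")
    return mol


@lru_cache(maxsize=200_000)
def canonicalize(smiles: str) -> str:
    """Canonical SMILES without stereochemistry ('' stays '')."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return ""
    if Chem.FindMolChiralCenters(mol, includeUnassigned=False) or any(
        b.GetStereo() != Chem.BondStereo.STEREONONE for b in mol.GetBonds()
    ):
        logger.warning("dropping stereochemistry from %r", smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def sanitize_ok(mol: Chem.RWMol) -> bool:
    """True when an edited molecule passes full RDKit sanitization."""
    return Chem.SanitizeMol(mol, catchErrors=True) == Chem.SanitizeFlags.SANITIZE_NONE


def is_valid_smiles(smiles: str) -> bool:
    """True when the SMILES parses and sanitizes ('' counts as valid)."""
    if not smiles:
        return True
    return Chem.MolFromSmiles(smiles) is not None
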