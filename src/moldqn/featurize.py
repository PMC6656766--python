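"""State featurization for the Q-network.

A state ``(m, t)`` is encoded as the radius-3 Morgan fingerprint of ``m``
(2048 binary bits) with the number of steps remaining ``T − t`` appended as
one raw numeric slot, for a total input length of 2049.  Appending the
clock makes the value function time-aware: with many steps left the network
can favor set-up moves, with few it must cash in.

Fingerprints are stored sparsely (on-bit indices) because replay buffers
hold tens of thousands of candidate states; ``StateFeatures.vector()`` and
:func:`dense_matrix` densify on demand.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from rdkit.Chem import rdFingerprintGenerator

from .chem import mol_from_smiles
from .mdp import MoleculeState

__all__ = ["FINGERPRINT_RADIUS", "FINGERPRINT_NBITS", "StateFeatures",
           "featurize", "featurize_smiles", "dense_matrix"]

FINGERPRINT_RADIUS = 3
FINGERPRINT_NBITS = 2048

_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_NBITS
)


@lru_cache(maxsize=500_000)
def _on_bits(smiles: str) -> np.ndarray:
    """Sorted on-bit indices of the binary Morgan fingerprint ('' -> none)."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return np.empty(0, dtype=np.int32)
    fp = _generator.GetFingerprint(mol)
    bits = np.array(fp.GetOnBits(), dtype=np.int32)
    bits.sort()
    return bits


@dataclass(frozen=True)
class StateFeatures:
    """Sparse fingerprint ⊕ steps-remaining encoding of one state."""

    on_bits: np.ndarray
    steps_remaining: int

    @property
    def length(self) -> int:
        return FINGERPRINT_NBITS + 1

    def vector(self) -> np.ndarray:
        """Dense float32 vector of length 2049 (fingerprint ⊕ clock)."""
        v = np.zeros(self.length, dtype=np.float32)
        v[self.on_bits] = 1.0
        v[-1] = self.steps_remaining
        return v

    def on_bit_list(self) -> list[int]:
        """JSON-friendly debug dump of the fingerprint's on bits."""
        return [int(b) for b in self.on_bits]


def featurize_smiles(smiles: str, steps_remaining: int) -> StateFeatures:
    if steps_remaining < 0:
        raise ValueError("steps_remaining must be non-negative")
    return StateFeatures(_on_bits(smiles), steps_remaining)


def featurize(state: MoleculeState, horizon: int) -> StateFeatures:
    """Encode ``(m, t)`` for a horizon-T episode; deterministic in both."""
    return featurize_smiles(state.molecule, horizon - state.steps_taken)


def dense_matrix(features: Sequence[StateFeatures]) -> np.ndarray:
    """Stack features into an (n, 2049) float32 design matrix."""
    if not features:
        return np.zeros((0, FINGERPRINT_NBITS + 1), dtype=np.float32)
    out = np.zeros((len(features), features[0].length), dtype=np.float32)
    for i, f in enumerate(features):
        out[i, f.on_bits] = 1.0
        out[i, -1] = f.steps_remaining
    return out
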