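"""Reward functions for molecule optimization.

Implements the property rewards used throughout the package — penalized
logP, QED, Tanimoto similarity — together with the reward *shapes* built on
them: scalarized multi-objective rewards ``w^T r``, the similarity-
constrained reward with penalty weight λ, range-targeting rewards, and the
reversed-discount convention ``γ^(T−t)`` that weights late-episode states
most heavily.

Penalized logP
--------------
``logP − SA − max(0, largest_ring − 6)``.  By default each of the three
terms is z-standardized with the ZINC250k statistics that the JT-VAE/GCPN
molecule-optimization benchmark established; that is the scale on which
published scores (e.g. a value of ~11 for a long alkyl chain) live.  Pass
``standardize=False`` for the raw difference.

Conventions
-----------
The empty molecule has no properties; every property scorer returns 0.0 for
it by explicit convention (the empty state is never the object of interest,
only a possible episode start).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, QED
from rdkit.Chem import rdFingerprintGenerator

from .chem import mol_from_smiles
from .sascore import calculate_sa_score

__all__ = [
    "RewardKind",
    "RewardSpec",
    "penalized_logp",
    "qed",
    "similarity",
    "scalarize",
    "constrained_reward",
    "discounted_step_reward",
    "relative_improvement",
    "range_target_reward",
    "make_reward",
    "PROPERTY_FUNCTIONS",
]

# ZINC250k moments of logP, SA and the long-cycle count, as fixed by the
# JT-VAE/GCPN benchmark definition of penalized logP.
_LOGP_MEAN, _LOGP_STD = 2.4570953396190123, 1.434324401111988
_SA_MEAN, _SA_STD = 3.0525811293166134, 0.8335207024513095
_CYCLE_MEAN, _CYCLE_STD = 0.0485696876403053, 0.2860212110245455

#: Morgan-fingerprint radius for Tanimoto similarity (radius 2 = ECFP4).
SIMILARITY_RADIUS = 2
SIMILARITY_NBITS = 2048

_sim_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=SIMILARITY_RADIUS, fpSize=SIMILARITY_NBITS
)


class RewardKind(str, Enum):
    SINGLE_PROPERTY = "single_property"
    MULTI_OBJECTIVE = "multi_objective"
    CONSTRAINED = "constrained"
    RANGE_TARGET = "range_target"


def _largest_ring_size(mol: Chem.Mol) -> int:
    return max((len(ring) for ring in mol.GetRingInfo().AtomRings()), default=0)


def cycle_penalty(smiles: str, mode: str = "max_ring") -> float:
    """Long-cycle penalty term of penalized logP.

    ``"max_ring"`` (default, the benchmark definition): ``max(0, largest
    ring size − 6)``.  ``"count"``: the number of rings larger than 6 atoms,
    the literal count-of-long-cycles reading.
    """
    mol = mol_from_smiles(smiles)
    if mol is None:
        return 0.0
    if mode == "max_ring":
        return float(max(0, _largest_ring_size(mol) - 6))
    if mode == "count":
        return float(sum(len(r) > 6 for r in mol.GetRingInfo().AtomRings()))
    raise ValueError(f"unknown cycle penalty mode: {mode!r}")


@lru_cache(maxsize=500_000)
def penalized_logp(
    smiles: str, standardize: bool = True, cycle_mode: str = "max_ring"
) -> float:
    """logP minus SA score minus the long-cycle penalty (empty molecule: 0)."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return 0.0
    log_p = Descriptors.MolLogP(mol)
    sa = calculate_sa_score(mol)
    cycles = cycle_penalty(smiles, cycle_mode)
    if not standardize:
        return log_p - sa - cycles
    return (
        (log_p - _LOGP_MEAN) / _LOGP_STD
        - (sa - _SA_MEAN) / _SA_STD
        - (cycles - _CYCLE_MEAN) / _CYCLE_STD
    )


@lru_cache(maxsize=500_000)
def qed(smiles: str) -> float:
    """Quantitative Estimate of Drug-likeness, in [0, 1] (empty molecule: 0)."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return 0.0
    return QED.qed(mol)


@lru_cache(maxsize=500_000)
def _sim_fingerprint(smiles: str):
    return _sim_generator.GetFingerprint(mol_from_smiles(smiles))


def similarity(smiles: str, reference: str) -> float:
    """Tanimoto coefficient on radius-2 Morgan bit fingerprints."""
    if not reference:
        raise ValueError("similarity reference molecule must be non-empty")
    if not smiles:
        return 0.0
    return DataStructs.TanimotoSimilarity(
        _sim_fingerprint(smiles), _sim_fingerprint(reference)
    )


def scalarize(reward_vector: Sequence[float], weights: Sequence[float]) -> float:
    """Scalarized multi-objective reward ``w^T r`` (dot product)."""
    r = np.asarray(reward_vector, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.shape != w.shape:
        raise ValueError(f"length mismatch: reward {r.shape} vs weights {w.shape}")
    return float(w @ r)


def discounted_step_reward(raw: float, t: int, gamma: float, horizon: int) -> float:
    """Reversed-discount step reward ``raw * γ^(T−t)``.

    Unlike the usual RL convention the exponent shrinks toward the episode
    end, so the terminal state (t = T) is rewarded undiscounted and early
    states are down-weighted.
    """
    if not 0 <= t <= horizon:
        raise ValueError(f"step index {t} outside [0, {horizon}]")
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    return raw * gamma ** (horizon - t)


def relative_improvement(smiles: str, reference: str) -> float:
    """(QED(m) − QED(m0)) / (1 − QED(m0)): achieved over achievable QED gain."""
    q0 = qed(reference)
    if q0 >= 1.0:
        raise ValueError("reference molecule already has QED 1; improvement undefined")
    return (qed(smiles) - q0) / (1.0 - q0)


@dataclass(frozen=True)
class RewardSpec:
    """Declarative description of a reward function.

    ``kind`` selects the shape; the remaining fields parameterize it:

    * SINGLE_PROPERTY — ``property_names[0]`` scored directly.
    * MULTI_OBJECTIVE — vector of properties scalarized with ``weights``.
    * CONSTRAINED — property value, penalized by ``lam * (delta − SIM)``
      whenever Tanimoto similarity to ``reference`` drops below ``delta``.
    * RANGE_TARGET — negative distance of the property to ``target_range``.

    ``gamma`` and ``horizon`` define the reversed step discount γ^(T−t).
    """

    kind: RewardKind = RewardKind.SINGLE_PROPERTY
    property_names: tuple[str, ...] = ("qed",)
    weights: tuple[float, ...] = ()
    lam: float = 100.0
    delta: float = 0.6
    reference: str = ""
    target_range: tuple[float, float] = (0.0, 0.0)
    gamma: float = 0.9
    horizon: int = 40

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", RewardKind(self.kind))
        object.__setattr__(self, "property_names", tuple(self.property_names))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if self.kind is RewardKind.MULTI_OBJECTIVE:
            if len(self.weights) != len(self.property_names):
                raise ValueError("weights and property_names must have equal length")
        if self.kind is RewardKind.CONSTRAINED:
            if not self.reference:
                raise ValueError("constrained reward needs a reference molecule")
            mol_from_smiles(self.reference)  # must sanitize
            if not 0.0 <= self.delta <= 1.0:
                raise ValueError("delta must be in [0, 1]")
            if self.lam < 0:
                raise ValueError("lambda must be non-negative")
        if self.kind is RewardKind.RANGE_TARGET:
            lo, hi = self.target_range
            if lo > hi:
                raise ValueError(f"inverted target range: {self.target_range}")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")

    def to_json_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "property_names": list(self.property_names),
            "weights": list(self.weights),
            "lam": self.lam,
            "delta": self.delta,
            "reference": self.reference,
            "target_range": list(self.target_range),
            "gamma": self.gamma,
            "horizon": self.horizon,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RewardSpec":
        data = dict(data)
        if "target_range" in data:
            data["target_range"] = tuple(data["target_range"])
        return cls(**data)


#: Named property scorers usable in ``RewardSpec.property_names``.  A name
#: prefixed pair ("similarity", reference) is resolved by make_reward.
PROPERTY_FUNCTIONS: dict[str, Callable[[str], float]] = {
    "qed": qed,
    "penalized_logp": penalized_logp,
    "plogp": penalized_logp,
    "logp": lambda s: Descriptors.MolLogP(mol_from_smiles(s)) if s else 0.0,
    "sa": lambda s: calculate_sa_score(mol_from_smiles(s)) if s else 0.0,
}


def _resolve_property(name: str, spec: RewardSpec) -> Callable[[str], float]:
    if name in ("similarity", "sim"):
        if not spec.reference:
            raise ValueError("similarity property needs spec.reference")
        return lambda s: similarity(s, spec.reference)
    try:
        return PROPERTY_FUNCTIONS[name]
    except KeyError:
        raise ValueError(f"unknown property: {name!r}") from None


def constrained_reward(smiles: str, spec: RewardSpec) -> float:
    """Similarity-constrained reward.

    ``prop(m) − λ (δ − SIM(m, m0))`` when similarity is below the threshold
    δ, plain ``prop(m)`` otherwise (the boundary SIM = δ is unpenalized).
    The property defaults to penalized logP.
    """
    if spec.kind is not RewardKind.CONSTRAINED:
        raise ValueError("spec.kind must be CONSTRAINED")
    prop = _resolve_property(spec.property_names[0], spec)
    value = prop(smiles)
    sim = similarity(smiles, spec.reference) if smiles else 0.0
    if sim < spec.delta:
        return value - spec.lam * (spec.delta - sim)
    return value


def range_target_reward(smiles: str, spec: RewardSpec) -> float:
    """Negative distance of the property value to the target interval.

    Zero (the maximum) anywhere inside ``[lo, hi]``, ``−|value − edge|``
    outside, so moving toward the interval never decreases the reward.
    """
    if spec.kind is not RewardKind.RANGE_TARGET:
        raise ValueError("spec.kind must be RANGE_TARGET")
    lo, hi = spec.target_range
    value = _resolve_property(spec.property_names[0], spec)(smiles)
    if value < lo:
        return value - lo
    if value > hi:
        return hi - value
    return 0.0


def make_reward(spec: RewardSpec) -> Callable[[str], float]:
    """Compile a RewardSpec into a raw (undiscounted) SMILES -> float scorer."""
    if spec.kind is RewardKind.SINGLE_PROPERTY:
        return _resolve_property(spec.property_names[0], spec)
    if spec.kind is RewardKind.MULTI_OBJECTIVE:
        props = [_resolve_property(name, spec) for name in spec.property_names]
        weights = spec.weights
        return lambda s: scalarize([p(s) for p in props], weights)
    if spec.kind is RewardKind.CONSTRAINED:
        return lambda s: constrained_reward(s, spec)
    if spec.kind is RewardKind.RANGE_TARGET:
        return lambda s: range_target_reward(s, spec)
    raise ValueError(f"unhandled reward kind: {spec.kind}")
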