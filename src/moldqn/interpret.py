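"""Per-action value landscapes and trajectory summaries.

These are the numeric layers behind decision-making visualizations: the
Q-value of every valid action at a state (min-max rescaled to [0, 1] for
display) and per-step property traces of a finished episode, including
non-monotone steps where the policy sacrifices immediate property value
for a better end point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .agent import DQNAgent
from .featurize import featurize_smiles
from .mdp import MDPConfig, MoleculeState, valid_actions
from .rewards import qed
from .training import EpisodeRecord

logger = logging.getLogger(__name__)

__all__ = ["ActionValueMap", "action_value_map", "trajectory_summary"]


@dataclass(frozen=True)
class ActionValueMap:
    """Raw and [0, 1]-rescaled Q-values of every action at one state."""

    actions: tuple[str, ...]
    raw_q: tuple[float, ...]
    rescaled_q: tuple[float, ...]
    chosen_index: int

    def to_json_dict(self) -> dict:
        return {
            "chosen_index": self.chosen_index,
            "entries": [
                {"action": a, "q": q, "q_rescaled": r}
                for a, q, r in zip(self.actions, self.raw_q, self.rescaled_q)
            ],
        }

    def dump_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))


def _rescale(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        # degenerate all-equal map: every action is "the best"
        logger.info("all Q-values equal (%g); rescaling to 1.0", hi)
        return np.ones_like(raw)
    return (raw - lo) / (hi - lo)


def action_value_map(
    state: MoleculeState,
    agent: DQNAgent,
    config: MDPConfig,
    head: int = 0,
    ensemble_mean: bool = False,
) -> ActionValueMap:
    """Q-value of each valid action, min-max rescaled to [0, 1].

    ``ensemble_mean`` averages the raw values over all bootstrap heads
    instead of reading a single evaluation head.
    """
    actions = valid_actions(state, config)  # raises StateError when terminal
    T = config.max_steps
    feats = [featurize_smiles(a.result_molecule, T - (state.steps_taken + 1))
             for a in actions]
    if ensemble_mean:
        from .featurize import dense_matrix

        raw = agent.online.forward(dense_matrix(feats)).mean(axis=1)
    else:
        raw = agent.q_values(feats, head)
    raw = np.asarray(raw, dtype=float)
    return ActionValueMap(
        actions=tuple(a.result_molecule for a in actions),
        raw_q=tuple(raw.tolist()),
        rescaled_q=tuple(_rescale(raw).tolist()),
        chosen_index=int(np.argmax(raw)),
    )


def trajectory_summary(
    episode: EpisodeRecord,
    property_fn: Callable[[str], float] = qed,
    property_name: str = "qed",
) -> pd.DataFrame:
    """Per-step property trace of an episode.

    One row per step with the property value after the step, the per-step
    delta, and a flag for non-monotone steps (the property decreased even
    though the trajectory may improve overall).  The frame's ``attrs`` carry
    the total improvement (final − initial), which telescopes to the sum of
    the deltas.
    """
    initial = episode.steps[0].state if episode.steps else episode.final_molecule
    values = [property_fn(initial) if initial else 0.0]
    molecules = [initial]
    for step_record in episode.steps:
        m = step_record.action.result_molecule
        molecules.append(m)
        values.append(property_fn(m) if m else 0.0)
    deltas = np.diff(values)
    frame = pd.DataFrame({
        "step": np.arange(1, len(values)),
        "molecule": molecules[1:],
        property_name: values[1:],
        "delta": deltas,
        "decreasing": deltas < 0,
    })
    frame.attrs["initial_value"] = values[0]
    frame.attrs["total_improvement"] = values[-1] - values[0]
    return frame
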