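"""Episode orchestration: DQN training loops, baseline policies, evaluation.

The three reward-driven baselines mirror the standard comparison set for
this optimization task:

* ``random`` — a uniform choice over the valid action set at every step;
* ``greedy`` — the action whose successor has the highest raw reward
  (myopic exploitation, ties broken toward the lexicographically lowest
  canonical SMILES);
* ``eps_greedy`` — the random policy with probability ε, greedy otherwise.

Baselines rank candidate successors by their property reward; the empty
molecule has no properties and is ranked below every real molecule, which
is what lets a greedy rollout leave the empty starting state even though
all one-atom molecules score poorly.

DQN training rolls out ε-greedy episodes driven by one uniformly sampled
bootstrap head, stores discounted step rewards with per-sample bootstrap
masks in the replay buffer, and interleaves masked double-Q regression
steps.  Reports aggregate the last terminal states of training (the method
has no separate evaluation phase for its headline numbers); uniqueness by
canonical SMILES is applied before ranking.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .agent import DQNAgent, Transition
from .chem import is_valid_smiles
from .featurize import StateFeatures, featurize_smiles
from .mdp import Action, MDPConfig, MoleculeState, step, valid_actions
from .rewards import (
    RewardKind,
    RewardSpec,
    make_reward,
    penalized_logp,
    qed,
    similarity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StepRecord",
    "EpisodeRecord",
    "RunReport",
    "run_baseline",
    "train",
    "train_two_step_qed",
    "evaluate",
    "constrained_experiment",
    "read_smiles_file",
]


@dataclass(frozen=True)
class StepRecord:
    state: str
    action: Action
    raw_reward: float
    discounted_reward: float
    q_values: tuple[float, ...] | None = None  # per-candidate, argmax order
    candidates: tuple[str, ...] | None = None


@dataclass(frozen=True)
class EpisodeRecord:
    steps: tuple[StepRecord, ...]
    final_molecule: str
    final_properties: dict = field(default_factory=dict)

    @property
    def episode_return(self) -> float:
        return sum(s.discounted_reward for s in self.steps)


@dataclass(frozen=True)
class RunReport:
    """Aggregate over the terminal states of a run's last episodes."""

    terminal_molecules: tuple[str, ...]
    terminal_scores: tuple[float, ...]
    returns: tuple[float, ...]
    validity_fraction: float

    def top_unique(self, k: int = 3) -> list[tuple[str, float]]:
        """Best-k distinct terminal molecules by score (order-invariant)."""
        best: dict[str, float] = {}
        for smiles, score in zip(self.terminal_molecules, self.terminal_scores):
            if smiles not in best or score > best[smiles]:
                best[smiles] = score
        ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:k]

    def to_json_dict(self) -> dict:
        return {
            "top_unique": [
                {"smiles": s, "score": v} for s, v in self.top_unique(3)
            ],
            "validity_fraction": self.validity_fraction,
            "n_terminals": len(self.terminal_molecules),
            "terminal_molecules": list(self.terminal_molecules),
            "terminal_scores": list(self.terminal_scores),
            "returns": list(self.returns),
        }


def read_smiles_file(path: str | Path) -> list[str]:
    """One molecule per line; an optional whitespace-separated name is
    ignored; blank lines denote the empty molecule."""
    out = []
    for line in Path(path).read_text().splitlines():
        fields = line.split()
        out.append(fields[0] if fields else "")
    return out


def _score_successor(reward_fn: Callable[[str], float], smiles: str) -> float:
    # the empty molecule has no properties: rank it below everything real
    return reward_fn(smiles) if smiles else float("-inf")


def _greedy_index(actions: Sequence[Action], reward_fn) -> int:
    scores = [_score_successor(reward_fn, a.result_molecule) for a in actions]
    best = max(scores)
    # actions are sorted by canonical SMILES, so the first maximal index is
    # also the lexicographically lowest tie-break
    return scores.index(best)


def _make_chooser(policy_name: str, reward_fn, epsilon: float):
    if policy_name == "random":
        return lambda actions, rng: int(rng.integers(len(actions)))
    if policy_name == "greedy":
        return lambda actions, rng: _greedy_index(actions, reward_fn)
    if policy_name == "eps_greedy":
        def chooser(actions, rng):
            if rng.random() < epsilon:
                return int(rng.integers(len(actions)))
            return _greedy_index(actions, reward_fn)
        return chooser
    raise ValueError(f"unknown baseline policy: {policy_name!r}")


def _baseline_episode(chooser, config: MDPConfig, reward_fn, gamma: float,
                      rng, start: str) -> EpisodeRecord:
    state = MoleculeState(start, 0)
    T = config.max_steps
    steps: list[StepRecord] = []
    for t in range(T):
        actions = valid_actions(state, config)
        action = actions[chooser(actions, rng)]
        raw = reward_fn(action.result_molecule)
        disc = raw * gamma ** (T - (t + 1))
        steps.append(StepRecord(state.molecule, action, raw, disc))
        state = step(state, action, config)
    return EpisodeRecord(tuple(steps), state.molecule)


def _report(episodes: Sequence[EpisodeRecord], reward_fn, last_n: int) -> RunReport:
    window = list(episodes)[-last_n:]
    terminals = [e.final_molecule for e in window]
    return RunReport(
        terminal_molecules=tuple(terminals),
        terminal_scores=tuple(reward_fn(s) if s else 0.0 for s in terminals),
        returns=tuple(e.episode_return for e in window),
        validity_fraction=(
            float(np.mean([is_valid_smiles(s) for s in terminals])) if terminals else 1.0
        ),
    )


def run_baseline(
    policy_name: str,
    config: MDPConfig,
    reward_spec: RewardSpec,
    n_episodes: int,
    seed: int = 0,
    epsilon: float = 0.1,
    last_n: int = 100,
    return_episodes: bool = False,
):
    """Roll out one of the reward-driven baseline policies.

    Aggregates the last ``min(last_n, n_episodes)`` terminal states into a
    :class:`RunReport`.  ``epsilon`` only applies to ``eps_greedy`` (the
    published comparison uses 0.1).
    """
    reward_fn = make_reward(reward_spec)
    chooser = _make_chooser(policy_name, reward_fn, epsilon)
    rng = np.random.default_rng(seed)
    episodes = [
        _baseline_episode(chooser, config, reward_fn, reward_spec.gamma, rng,
                          config.start_molecule)
        for _ in range(n_episodes)
    ]
    report = _report(episodes, reward_fn, last_n)
    return (report, episodes) if return_episodes else report


# ---------------------------------------------------------------------------
# DQN training
# ---------------------------------------------------------------------------


def _train_episode(
    agent: DQNAgent,
    config: MDPConfig,
    reward_fn,
    gamma: float,
    epsilon: float,
    head: int,
    start: str,
    learn: bool = True,
) -> EpisodeRecord:
    """One ε-greedy rollout that feeds the replay buffer and train steps."""
    T = config.max_steps
    state = MoleculeState(start, 0)
    steps: list[StepRecord] = []
    pending: tuple[StateFeatures, float] | None = None
    for t in range(T):
        actions = valid_actions(state, config)
        cand_feats = [
            featurize_smiles(a.result_molecule, T - (t + 1)) for a in actions
        ]
        if pending is not None:
            agent.buffer.add(Transition(pending[0], pending[1],
                                        tuple(cand_feats), False,
                                        agent.sample_mask()))
        idx = agent.select_action(cand_feats, epsilon, head)
        action = actions[idx]
        raw = reward_fn(action.result_molecule)
        disc = raw * gamma ** (T - (t + 1))
        steps.append(StepRecord(state.molecule, action, raw, disc))
        state = step(state, action, config)
        pending = (cand_feats[idx], disc)
        agent.env_steps += 1
        if (learn and agent.env_steps > agent.config.warmup_steps
                and agent.env_steps % agent.config.train_every == 0):
            agent.train_step()
    agent.buffer.add(Transition(pending[0], pending[1], (), True,
                                agent.sample_mask()))
    agent.episodes_seen += 1
    return EpisodeRecord(tuple(steps), state.molecule)


def train(
    config: MDPConfig,
    reward_spec: RewardSpec,
    agent: DQNAgent,
    n_episodes: int,
    seed: int | None = None,
    start_molecules: Sequence[str] | None = None,
    last_n: int = 100,
    checkpoint_path: str | Path | None = None,
    log_csv: str | Path | None = None,
    return_episodes: bool = False,
):
    """Train the agent for ``n_episodes`` episodes of ε-greedy exploration.

    Each episode draws a uniform bootstrap head and, when
    ``start_molecules`` is given, a uniform starting molecule.  ε follows
    the agent's piecewise-linear schedule across the episode budget.  The
    report covers the last ``min(last_n, n_episodes)`` terminal states.
    """
    if reward_spec.horizon != config.max_steps:
        raise ValueError(
            f"horizon mismatch: reward_spec.horizon={reward_spec.horizon} "
            f"vs config.max_steps={config.max_steps}"
        )
    if seed is not None:
        agent.rng = np.random.default_rng(seed)
    reward_fn = make_reward(reward_spec)
    episodes: list[EpisodeRecord] = []
    log_rows = []
    denom = max(n_episodes - 1, 1)
    for ep in range(n_episodes):
        epsilon = agent.epsilon_schedule.value(ep / denom)
        head = agent.sample_head()
        if start_molecules:
            start = start_molecules[int(agent.rng.integers(len(start_molecules)))]
        else:
            start = config.start_molecule
        record = _train_episode(agent, config, reward_fn, reward_spec.gamma,
                                epsilon, head, start)
        episodes.append(record)
        log_rows.append({
            "episode": agent.episodes_seen,
            "epsilon": epsilon,
            "head": head,
            "final_molecule": record.final_molecule,
            "final_score": reward_fn(record.final_molecule)
            if record.final_molecule else 0.0,
            "episode_return": record.episode_return,
        })
    if log_csv is not None:
        pd.DataFrame(log_rows).to_csv(log_csv, index=False)
    if checkpoint_path is not None:
        agent.save(str(checkpoint_path))
    report = _report(episodes, reward_fn, last_n)
    return (report, episodes) if return_episodes else report


def train_two_step_qed(
    config: MDPConfig,
    agent: DQNAgent,
    seed: int | None = None,
    n_episodes_phase1: int = 5000,
    n_episodes_phase2: int = 5000,
    last_n: int = 100,
    gamma: float = 0.9,
) -> RunReport:
    """Two-phase QED maximization with restarts.

    Phase 1 trains from the empty molecule.  Phase 2 keeps training the
    same agent but starts each episode uniformly from the (up to) five
    distinct highest-QED terminal molecules phase 1 found; if fewer than
    five distinct molecules exist, all available ones are used (logged).
    The returned report merges both phases' terminal states.
    """
    spec = RewardSpec(kind=RewardKind.SINGLE_PROPERTY, property_names=("qed",),
                      gamma=gamma, horizon=config.max_steps)
    report1, eps1 = train(config, spec, agent, n_episodes_phase1, seed=seed,
                          last_n=n_episodes_phase1, return_episodes=True)
    top5 = [s for s, _ in report1.top_unique(5) if s]
    if len(top5) < 5:
        logger.warning("phase 1 produced only %d unique molecules", len(top5))
    if not top5:
        top5 = [config.start_molecule]
    report2, eps2 = train(config, spec, agent, n_episodes_phase2, seed=None,
                          start_molecules=top5, last_n=n_episodes_phase2,
                          return_episodes=True)
    return _report(eps1 + eps2, make_reward(spec), last_n)


# ---------------------------------------------------------------------------
# Evaluation rollouts
# ---------------------------------------------------------------------------

_EVAL_MODES = ("argmax", "per_episode_head", "softmax_q", "eps")


def _evaluation_index(q: np.ndarray, mode: str, epsilon: float, rng) -> int:
    if mode == "argmax" or mode == "per_episode_head":
        return int(np.argmax(q))
    if mode == "softmax_q":
        # sample proportionally to Q after shifting by the minimum
        # (Q-values may be negative); a flat vector degenerates to uniform
        shifted = q - q.min()
        total = shifted.sum()
        if total <= 0:
            return int(rng.integers(len(q)))
        return int(rng.choice(len(q), p=shifted / total))
    if mode == "eps":
        if rng.random() < epsilon:
            return int(rng.integers(len(q)))
        return int(np.argmax(q))
    raise ValueError(f"unknown diversity mode: {mode!r} (choose from {_EVAL_MODES})")


def evaluate(
    agent: DQNAgent | str,
    config: MDPConfig,
    reward_spec: RewardSpec,
    start_molecule: str = "",
    diversity_mode: str = "argmax",
    n_episodes: int = 1,
    seed: int = 0,
    epsilon: float = 0.0,
    head: int = 0,
) -> list[EpisodeRecord]:
    """Greedy or diversity-sampled rollouts of a trained policy.

    ``argmax`` with a fixed head is fully deterministic (two runs give the
    same single molecule).  ``per_episode_head`` redraws the bootstrap head
    each episode; ``softmax_q`` samples actions with probability
    proportional to the (min-shifted) Q-values; ``eps`` mixes in uniform
    actions with probability ``epsilon`` (ε = 0 reduces to ``argmax``).
    """
    if isinstance(agent, str):
        agent = DQNAgent.load(agent)
    if diversity_mode not in _EVAL_MODES:
        raise ValueError(f"unknown diversity mode: {diversity_mode!r}")
    reward_fn = make_reward(reward_spec)
    rng = np.random.default_rng(seed)
    T = config.max_steps
    records = []
    for _ in range(n_episodes):
        ep_head = (int(rng.integers(agent.num_heads))
                   if diversity_mode == "per_episode_head" else head)
        state = MoleculeState(start_molecule, 0)
        steps = []
        for t in range(T):
            actions = valid_actions(state, config)
            cand_feats = [featurize_smiles(a.result_molecule, T - (t + 1))
                          for a in actions]
            q = agent.q_values(cand_feats, ep_head)
            idx = _evaluation_index(q, diversity_mode, epsilon, rng)
            action = actions[idx]
            raw = reward_fn(action.result_molecule)
            disc = raw * reward_spec.gamma ** (T - (t + 1))
            steps.append(StepRecord(state.molecule, action, raw, disc,
                                    q_values=tuple(float(v) for v in q),
                                    candidates=tuple(a.result_molecule
                                                     for a in actions)))
            state = step(state, action, config)
        records.append(EpisodeRecord(
            tuple(steps), state.molecule,
            final_properties={"reward": reward_fn(state.molecule)
                              if state.molecule else 0.0},
        ))
    return records


# ---------------------------------------------------------------------------
# Similarity-constrained optimization
# ---------------------------------------------------------------------------


def constrained_experiment(
    start_molecules: Sequence[str] | str | Path,
    agent: DQNAgent,
    config: MDPConfig,
    delta: float = 0.6,
    lam: float = 100.0,
    n_train_episodes: int = 5000,
    seed: int = 0,
    gamma: float = 0.9,
) -> pd.DataFrame:
    """Similarity-constrained improvement over a set of lead molecules.

    Trains one model whose episodes start uniformly from the supplied
    molecules, each episode rewarded by the constrained reward anchored at
    its own starting molecule (penalty λ(δ − SIM) whenever similarity to the
    start drops below δ).  Evaluation runs one deterministic argmax episode
    per molecule; improvement is measured in penalized logP and success is
    SIM ≥ δ at the end of the episode.
    """
    if isinstance(start_molecules, (str, Path)):
        start_molecules = read_smiles_file(start_molecules)
    starts = [s for s in start_molecules]
    if not starts or all(not s for s in starts):
        raise ValueError("constrained experiment needs at least one start molecule")
    if seed is not None:
        agent.rng = np.random.default_rng(seed)

    T = config.max_steps
    denom = max(n_train_episodes - 1, 1)
    for ep in range(n_train_episodes):
        epsilon = agent.epsilon_schedule.value(ep / denom)
        head = agent.sample_head()
        start = starts[int(agent.rng.integers(len(starts)))]
        spec = RewardSpec(kind=RewardKind.CONSTRAINED,
                          property_names=("penalized_logp",),
                          lam=lam, delta=delta, reference=start,
                          gamma=gamma, horizon=T)
        _train_episode(agent, config, make_reward(spec), gamma, epsilon, head, start)

    rows = []
    for start in starts:
        spec = RewardSpec(kind=RewardKind.CONSTRAINED,
                          property_names=("penalized_logp",),
                          lam=lam, delta=delta, reference=start,
                          gamma=gamma, horizon=T)
        [record] = evaluate(agent, config, spec, start_molecule=start,
                            diversity_mode="argmax", n_episodes=1)
        final = record.final_molecule
        sim = similarity(final, start) if final else 0.0
        rows.append({
            "start": start,
            "final": final,
            "improvement": penalized_logp(final) - penalized_logp(start),
            "similarity": sim,
            "success": bool(sim >= delta),
        })
    return pd.DataFrame(rows)
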