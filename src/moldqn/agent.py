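"""Bootstrapped double deep-Q-learning agent.

The learner keeps two copies of the multi-head value network: online
parameters θ updated every training step, and target parameters θ⁻ synced
on a fixed cadence.  Because actions are parameterized by their successor
states, ``Q(s, a)`` is simply the network evaluated on the featurized
successor, and ``V(s) = max_a Q(s, a)`` is a max over the candidate set.

Targets use double-Q decoupling: the online network chooses the best
successor action, the target network evaluates it.  The step rewards stored
in transitions already carry the episode discount γ^(T−t), so no further
discount enters the target.

Exploration combines ε-greedy (ε annealed piecewise-linearly from 1 to
0.01 over training) with randomized value functions: the network has H
bootstrap heads sharing all hidden layers, each trained only on the
transitions whose Bernoulli bootstrap mask selects it, and one uniformly
drawn head drives each episode.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .featurize import StateFeatures, dense_matrix
from .network import Adam, QNetwork, QNetworkSpec, clip_global_norm, huber, huber_grad

logger = logging.getLogger(__name__)

__all__ = ["Transition", "ReplayBuffer", "EpsilonSchedule", "AgentConfig", "DQNAgent"]


@dataclass(frozen=True)
class Transition:
    """One replay record.

    ``action_features`` encode the successor state the action produced (the
    network's input for Q(s, a)); ``next_candidates`` are the features of
    every action available *from* that successor, needed for the max in the
    bootstrap target.  ``reward`` already includes the γ^(T−t) factor.
    """

    action_features: StateFeatures
    reward: float
    next_candidates: tuple[StateFeatures, ...]
    terminal: bool
    mask: np.ndarray  # H booleans: which heads train on this sample


class ReplayBuffer:
    """Fixed-capacity FIFO experience store with uniform sampling."""

    def __init__(self, capacity: int = 5000):
        self._data: deque[Transition] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._data)

    @property
    def capacity(self) -> int:
        return self._data.maxlen

    def add(self, transition: Transition) -> None:
        self._data.append(transition)

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Transition]:
        idx = rng.integers(0, len(self._data), size=batch_size)
        return [self._data[i] for i in idx]


class EpsilonSchedule:
    """Piecewise-linear ε(progress) with progress in [0, 1] over training."""

    def __init__(self, points: Sequence[tuple[float, float]] = ((0.0, 1.0), (1.0, 0.01))):
        pts = sorted((float(x), float(e)) for x, e in points)
        if len(pts) < 2:
            raise ValueError("schedule needs at least two knots")
        self._x = np.array([p[0] for p in pts])
        self._e = np.array([p[1] for p in pts])
        if np.any(np.diff(self._e) > 0):
            raise ValueError("epsilon schedule must be non-increasing")

    def value(self, progress: float) -> float:
        return float(np.interp(np.clip(progress, 0.0, 1.0), self._x, self._e))


@dataclass(frozen=True)
class AgentConfig:
    """Learner hyperparameters.

    The network shape, learning rate and the 1 → 0.01 ε annealing follow
    the method's published settings; the replay/bootstrap machinery
    (capacity, batch size, target-sync cadence, warm-up, mask probability)
    is standard DQN practice and fully exposed here.
    """

    network: QNetworkSpec = field(default_factory=QNetworkSpec)
    learning_rate: float = 1e-4
    replay_capacity: int = 5000
    batch_size: int = 128
    target_sync_every: int = 20  # training steps between θ⁻ ← θ copies
    train_every: int = 1  # environment steps per training step
    warmup_steps: int = 50  # environment steps before training starts
    mask_prob: float = 0.5  # Bernoulli bootstrap-mask probability
    grad_clip: float = 10.0  # global-norm gradient clip
    epsilon_points: tuple[tuple[float, float], ...] = ((0.0, 1.0), (1.0, 0.01))


class DQNAgent:
    """Multi-head double-DQN learner over successor-state features."""

    def __init__(self, config: AgentConfig = AgentConfig(), seed: int = 0):
        self.config = config
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.online = QNetwork(config.network, self.rng)
        self.target = QNetwork(config.network, self.rng)
        self.target.copy_from(self.online)
        self.optimizer = Adam(lr=config.learning_rate)
        self.buffer = ReplayBuffer(config.replay_capacity)
        self.epsilon_schedule = EpsilonSchedule(config.epsilon_points)
        self.train_steps = 0
        self.env_steps = 0
        self.episodes_seen = 0

    # -- policy -------------------------------------------------------------

    @property
    def num_heads(self) -> int:
        return self.config.network.num_heads

    def sample_head(self) -> int:
        """Uniform bootstrap head for one episode."""
        return int(self.rng.integers(self.num_heads))

    def sample_mask(self) -> np.ndarray:
        return self.rng.random(self.num_heads) < self.config.mask_prob

    def q_values(
        self,
        candidates: Sequence[StateFeatures],
        head: int,
        network: str = "online",
    ) -> np.ndarray:
        """One Q-value per candidate successor, from the selected head."""
        if not candidates:
            raise ValueError("candidate list must be non-empty")
        net = self.online if network == "online" else self.target
        return net.forward(dense_matrix(candidates))[:, head].astype(float)

    def select_action(
        self,
        candidates: Sequence[StateFeatures],
        epsilon: float,
        head: int,
        rng: np.random.Generator | None = None,
    ) -> int:
        """ε-greedy pick: uniform with probability ε, else the head's argmax.

        Greedy ties break toward the lowest candidate index, so evaluation
        with ε = 0 is deterministic.
        """
        rng = rng if rng is not None else self.rng
        if rng.random() < epsilon:
            return int(rng.integers(len(candidates)))
        return int(np.argmax(self.q_values(candidates, head)))

    # -- learning -----------------------------------------------------------

    def double_q_target(self, transition: Transition, head: int) -> float:
        """y = r for terminal moves, else r + Q_θ⁻(a*, head), a* from θ.

        The stored reward already carries the episode discount, so the
        target adds no extra γ factor.
        """
        if transition.terminal:
            return float(transition.reward)
        online_q = self.q_values(transition.next_candidates, head, "online")
        best = int(np.argmax(online_q))
        target_q = self.q_values(transition.next_candidates, head, "target")
        return float(transition.reward + target_q[best])

    def _batch_targets(self, batch: list[Transition]) -> np.ndarray:
        """(B, H) double-Q targets, vectorized over the batch."""
        H = self.num_heads
        y = np.array([[t.reward] * H for t in batch], dtype=np.float64)
        live = [(i, t) for i, t in enumerate(batch) if not t.terminal]
        if not live:
            return y
        all_cands = [f for _, t in live for f in t.next_candidates]
        online_all = self.online.forward(dense_matrix(all_cands))
        target_all = self.target.forward(dense_matrix(all_cands))
        offset = 0
        for i, t in live:
            n = len(t.next_candidates)
            sl = slice(offset, offset + n)
            best = np.argmax(online_all[sl], axis=0)  # per-head online argmax
            y[i] += target_all[sl][best, np.arange(H)]
            offset += n
        return y

    def train_step(self, batch: list[Transition] | None = None) -> float | None:
        """One masked-Huber regression step on a replay batch.

        Each head regresses only the transitions whose bootstrap mask bit
        selects it.  Returns the scalar loss, or None when the buffer is
        still smaller than the batch size (logged no-op).
        """
        if batch is None:
            if len(self.buffer) < self.config.batch_size:
                logger.debug("replay buffer %d < batch %d; skipping train step",
                             len(self.buffer), self.config.batch_size)
                return None
            batch = self.buffer.sample(self.config.batch_size, self.rng)

        X = dense_matrix([t.action_features for t in batch])
        y = self._batch_targets(batch)
        mask = np.stack([t.mask for t in batch]).astype(np.float64)
        n_active = mask.sum()
        if n_active == 0:
            return 0.0

        q, cache = self.online.forward(X, return_cache=True)
        residual = y - q
        loss = float((huber(residual) * mask).sum() / n_active)
        # d loss / d q = -huber'(y - q) * mask / n_active
        d_q = (-huber_grad(residual) * mask / n_active).astype(np.float32)
        grads_w, grads_b = self.online.backward(cache, d_q)
        grads = grads_w + grads_b
        if self.config.grad_clip > 0:
            grads = clip_global_norm(grads, self.config.grad_clip)
        params = self.online.weights + self.online.biases
        self.optimizer.step(params, grads)

        self.train_steps += 1
        if self.train_steps % self.config.target_sync_every == 0:
            self.sync_target()
        return loss

    def sync_target(self) -> None:
        self.target.copy_from(self.online)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str) -> None:
        """Checkpoint θ, θ⁻, optimizer state and counters to an .npz file."""
        arrays: dict[str, np.ndarray] = {}
        for tag, net in (("online", self.online), ("target", self.target)):
            for i, p in enumerate(net.get_params()):
                arrays[f"{tag}_{i}"] = p
        opt = self.optimizer.state_dict()
        for i, a in enumerate(opt["m"]):
            arrays[f"adam_m_{i}"] = a
        for i, a in enumerate(opt["v"]):
            arrays[f"adam_v_{i}"] = a
        meta = {
            "network": {
                "input_dim": self.config.network.input_dim,
                "hidden_sizes": list(self.config.network.hidden_sizes),
                "num_heads": self.config.network.num_heads,
            },
            "learning_rate": self.config.learning_rate,
            "replay_capacity": self.config.replay_capacity,
            "batch_size": self.config.batch_size,
            "target_sync_every": self.config.target_sync_every,
            "train_every": self.config.train_every,
            "warmup_steps": self.config.warmup_steps,
            "mask_prob": self.config.mask_prob,
            "grad_clip": self.config.grad_clip,
            "epsilon_points": [list(p) for p in self.config.epsilon_points],
            "seed": self.seed,
            "adam_t": opt["t"],
            "n_adam": len(opt["m"]),
            "train_steps": self.train_steps,
            "env_steps": self.env_steps,
            "episodes_seen": self.episodes_seen,
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "DQNAgent":
        try:
            data = np.load(path)
            meta = json.loads(bytes(data["meta"]).decode())
        except Exception as exc:  # corrupt or wrong-format file
            raise IOError(f"cannot load checkpoint {path!r}: {exc}") from exc
        config = AgentConfig(
            network=QNetworkSpec(
                input_dim=meta["network"]["input_dim"],
                hidden_sizes=tuple(meta["network"]["hidden_sizes"]),
                num_heads=meta["network"]["num_heads"],
            ),
            learning_rate=meta["learning_rate"],
            replay_capacity=meta["replay_capacity"],
            batch_size=meta["batch_size"],
            target_sync_every=meta["target_sync_every"],
            train_every=meta["train_every"],
            warmup_steps=meta["warmup_steps"],
            mask_prob=meta["mask_prob"],
            grad_clip=meta["grad_clip"],
            epsilon_points=tuple(tuple(p) for p in meta["epsilon_points"]),
        )
        agent = cls(config, seed=meta["seed"])
        n_params = len(agent.online.get_params())
        agent.online.set_params([data[f"online_{i}"] for i in range(n_params)])
        agent.target.set_params([data[f"target_{i}"] for i in range(n_params)])
        n_adam = meta["n_adam"]
        agent.optimizer.load_state_dict({
            "t": meta["adam_t"],
            "m": [data[f"adam_m_{i}"] for i in range(n_adam)],
            "v": [data[f"adam_v_{i}"] for i in range(n_adam)],
        })
        agent.train_steps = meta["train_steps"]
        agent.env_steps = meta["env_steps"]
        agent.episodes_seen = meta["episodes_seen"]
        return agent
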