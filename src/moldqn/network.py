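"""A minimal fully-connected Q-network in NumPy.

The value model is a multi-head MLP: shared ReLU hidden layers (default
sizes 1024-512-128-32) over the 2049-long state features, and a linear
output layer with one scalar per bootstrap head.  Forward, backward and the
Adam update are written directly against NumPy arrays; the training loss is
the Huber (smooth-L1) function with unit transition point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["huber", "huber_grad", "QNetwork", "Adam", "QNetworkSpec"]


def huber(x: np.ndarray | float) -> np.ndarray | float:
    """Huber loss: ½x² for |x| < 1, |x| − ½ otherwise."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1.0, 0.5 * x * x, np.abs(x) - 0.5)
    return out if out.ndim else float(out)


def huber_grad(x: np.ndarray | float) -> np.ndarray | float:
    """d/dx of the Huber loss: x clipped to [−1, 1]."""
    x = np.asarray(x, dtype=float)
    out = np.clip(x, -1.0, 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class QNetworkSpec:
    """Shape of the value network."""

    input_dim: int = 2049
    hidden_sizes: tuple[int, ...] = (1024, 512, 128, 32)
    num_heads: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))
        if self.num_heads < 1:
            raise ValueError("num_heads must be positive")


class QNetwork:
    """Multi-head ReLU MLP with manual backprop.

    Parameters are kept as lists of (W, b) float32 arrays; the last layer's
    columns are the private per-head parameters, everything before it is
    shared by all heads.
    """

    def __init__(self, spec: QNetworkSpec, rng: np.random.Generator):
        self.spec = spec
        sizes = (spec.input_dim, *spec.hidden_sizes, spec.num_heads)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU layers
            self.weights.append(
                (rng.standard_normal((fan_in, fan_out)) * scale).astype(np.float32)
            )
            self.biases.append(np.zeros(fan_out, dtype=np.float32))

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, return_cache: bool = False):
        """Head values for a batch of state vectors: (n, num_heads)."""
        X = np.asarray(X, dtype=np.float32)
        activations = [X]
        h = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < last:
                h = np.maximum(h, 0.0)
            activations.append(h)
        return (h, activations) if return_cache else h

    def backward(self, cache: list[np.ndarray], d_out: np.ndarray):
        """Gradients of sum(out * d_out) w.r.t. every weight and bias."""
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = np.asarray(d_out, dtype=np.float32)
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w[i] = cache[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * (cache[i] > 0)
        return grads_w, grads_b

    # -- parameter plumbing -------------------------------------------------

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for p in (*self.weights, *self.biases)]

    def set_params(self, params: list[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [np.asarray(p, dtype=np.float32).copy() for p in params[:n]]
        self.biases = [np.asarray(p, dtype=np.float32).copy() for p in params[n:]]

    def copy_from(self, other: "QNetwork") -> None:
        self.set_params(other.get_params())


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [a.copy() for a in (self._m or [])],
            "v": [a.copy() for a in (self._v or [])],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self._m = [np.asarray(a, dtype=np.float32) for a in state["m"]] or None
        self._v = [np.asarray(a, dtype=np.float32) for a in state["v"]] or None


def clip_global_norm(grads: list[np.ndarray], max_norm: float) -> list[np.ndarray]:
    """Rescale gradients so their joint L2 norm is at most ``max_norm``."""
    total = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
    if total > max_norm > 0:
        scale = max_norm / total
        return [g * scale for g in grads]
    return grads
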