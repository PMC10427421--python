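"""Compact feed-forward Q-network with hand-written gradients.

Architecture: a 256-unit fully connected ReLU layer processes the classifier's
feature vector; its output is concatenated with the classifier's logits and
multiclass probabilities (both part of the RL state) and fed to a linear head
with one output per action.  Passing the probabilities directly to the head
matters: the expected reward of an action is linear in the predictive
distribution, so the exact Q-function is representable by the head alone and
the hidden branch only needs to model residual structure.  Dropout (p = 0.05)
is applied to the hidden layer during training only.

Training minimizes the Huber loss of the temporal-difference residual with
Adam.  The network is small enough that explicit numpy backpropagation is
faster here than a deep-learning framework's dispatch overhead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QNetworkSpec", "QNetwork", "Adam", "PolyakAverage", "huber_grad"]


@dataclass(frozen=True)
class QNetworkSpec:
    feature_dim: int
    n_actions: int
    passthrough_dim: int = 14  # logits (7) + probabilities (7) fed around the branch
    hidden: int = 256
    dropout_rate: float = 0.05


class QNetwork:
    """q(s) = W2 @ [relu(W1 f + b1) ‖ logits ‖ probabilities] + b2."""

    def __init__(self, spec: QNetworkSpec, rng: np.random.Generator):
        self.spec = spec
        h, f, a = spec.hidden, spec.feature_dim, spec.n_actions
        # He initialization on the ReLU branch, small head
        self.W1 = rng.standard_normal((f, h)) * np.sqrt(2.0 / f)
        self.b1 = np.zeros(h)
        self.W2 = rng.standard_normal((h + spec.passthrough_dim, a)) * np.sqrt(
            1.0 / (h + spec.passthrough_dim))
        self.b2 = np.zeros(a)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def copy_from(self, other: "QNetwork") -> None:
        for p, q in zip(self.params, other.params):
            p[...] = q

    def clone(self) -> "QNetwork":
        out = QNetwork(self.spec, np.random.default_rng(0))
        out.copy_from(self)
        return out

    def forward(self, features: np.ndarray, passthrough: np.ndarray,
                training: bool = False, rng: np.random.Generator | None = None):
        """Q-values (n, A); returns (q, cache) when training for backprop."""
        pre = features @ self.W1 + self.b1
        hid = np.maximum(pre, 0.0)
        mask = None
        if training and self.spec.dropout_rate > 0:
            assert rng is not None
            keep = 1.0 - self.spec.dropout_rate
            mask = (rng.random(hid.shape) < keep) / keep  # inverted dropout
            hid = hid * mask
        z = np.concatenate([hid, passthrough], axis=1)
        q = z @ self.W2 + self.b2
        if not training:
            return q
        return q, (features, pre, mask, z)

    def backward(self, dq: np.ndarray, cache) -> list[np.ndarray]:
        """Gradients [dW1, db1, dW2, db2] for upstream dL/dq."""
        features, pre, mask, z = cache
        h = self.spec.hidden
        dW2 = z.T @ dq
        db2 = dq.sum(axis=0)
        dz = dq @ self.W2.T
        dhid = dz[:, :h]
        if mask is not None:
            dhid = dhid * mask
        dpre = dhid * (pre > 0)
        dW1 = features.T @ dpre
        db1 = dpre.sum(axis=0)
        return [dW1, db1, dW2, db2]


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PolyakAverage:
    """Exponential moving average of network weights.

    Minibatch temporal-difference updates with sampled rewards leave the
    weights wandering in a noise ball around the optimum; reading out the
    tail-averaged weights (Ruppert–Polyak averaging) removes most of that
    steady-state variance without touching the training dynamics.
    """

    def __init__(self, params: list[np.ndarray], decay: float = 0.999):
        self.decay = decay
        self.shadow = [p.copy() for p in params]

    def update(self, params: list[np.ndarray]) -> None:
        d = self.decay
        for s, p in zip(self.shadow, params):
            s *= d
            s += (1 - d) * p

    def install(self, net: QNetwork) -> None:
        for p, s in zip(net.params, self.shadow):
            p[...] = s


def huber_grad(residual: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """d/dr of the Huber loss: r inside the quadratic zone, ±delta outside."""
    return np.clip(residual, -delta, delta)
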