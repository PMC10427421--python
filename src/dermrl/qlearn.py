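"""Deep Q-learning over classifier states with expert reward tables.

The decision layer treats each lesion's classifier output as the state of a
Markov decision process whose actions are either diagnoses or management
decisions and whose reward is looked up in an expert table at the lesion's
ground truth.  Training follows the classic deep Q-learning recipe: ε-greedy
interaction, a FIFO replay buffer, minibatch temporal-difference updates under
the Huber loss, and a target network synchronized at a lower rate.  Because the
lesion shown next does not depend on the action taken, rewards are immediate
and the default discount is zero; the machinery still supports γ > 0.

Lesion-level episodes are fixed-length random draws from the training pool.
Patient-centered episodes consist of all lesions of one patient, each state
vector divided position-wise by the patient's mean state vector and the lesions
ordered by descending malignancy probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (CLASS_CODES, CLASS_ORDER, DiagnosisLabel, ManagementAction,
                   RewardTable, ScenarioSpec, SCENARIOS, malignancy_probability)
from .network import Adam, PolyakAverage, QNetwork, QNetworkSpec, huber_grad
from .records import ClassifierState, LesionRecord, PatientCohort

__all__ = ["TrainConfig", "ReplayBuffer", "TrainedPolicy", "build_state",
           "order_episode", "train_q", "state_matrix"]

N = 7  # classes


@dataclass(frozen=True)
class TrainConfig:
    """Q-learning hyperparameters.

    Defaults follow the reference training setup: Adam at 0.025 on the Huber
    loss, replay capacity 10,000, a gradient update every 4 environment steps
    and a target-network copy every 8,000 (35 and 5,800 for the patient
    scenario), constant ε = 0.2, and episode lengths in [12, 250] for
    lesion-level training.  ``max_steps`` counts environment steps; an
    evaluation on the held-out 20% split is logged every ``eval_period`` steps,
    with optional early stopping when the validation mean reward has not
    improved for ``early_stop_patience`` evaluations.
    """

    learning_rate: float = 0.025
    huber_delta: float = 1.0
    replay_capacity: int = 10_000
    q_update_period: int = 4
    target_sync_period: int = 8_000
    epsilon: float = 0.2
    episode_length: int = 50
    discount: float = 0.0
    minibatch_size: int = 32
    max_steps: int = 60_000
    polyak_decay: float = 0.999
    eval_period: int = 2_000
    early_stop_patience: int | None = None
    val_fraction: float = 0.2
    dropout_rate: float = 0.05
    hidden: int = 256
    seed: int = 0

    def __post_init__(self):
        if min(self.q_update_period, self.target_sync_period) < 1:
            raise ValueError("update periods must be >= 1")
        if self.replay_capacity < self.minibatch_size:
            raise ValueError("replay capacity must cover a minibatch")
        if not (12 <= self.episode_length <= 250):
            raise ValueError("episode_length outside [12, 250]")
        if not (0.0 <= self.discount <= 1.0):
            raise ValueError("discount must be in [0, 1]")

    @classmethod
    def patient_defaults(cls, **overrides) -> "TrainConfig":
        base = dict(q_update_period=35, target_sync_period=5_800)
        base.update(overrides)
        return cls(**base)


class ReplayBuffer:
    """Bounded FIFO of transitions; insertion beyond capacity evicts the oldest."""

    def __init__(self, capacity: int, state_dim: int):
        self.capacity = capacity
        self.states = np.empty((capacity, state_dim))
        self.actions = np.empty(capacity, dtype=np.int64)
        self.rewards = np.empty(capacity)
        self.next_states = np.empty((capacity, state_dim))
        self.terminal = np.empty(capacity, dtype=bool)
        self._next = 0
        self._size = 0

    def __len__(self) -> int:
        return self._size

    def push(self, s, a, r, s_next, terminal) -> None:
        i = self._next
        self.states[i] = s
        self.actions[i] = a
        self.rewards[i] = r
        self.next_states[i] = s_next
        self.terminal[i] = terminal
        self._next = (i + 1) % self.capacity
        self._size = min(self._size + 1, self.capacity)

    def sample(self, batch: int, rng: np.random.Generator):
        idx = rng.integers(0, self._size, size=batch)
        return (self.states[idx], self.actions[idx], self.rewards[idx],
                self.next_states[idx], self.terminal[idx])


# ---------------------------------------------------------------- state layout

def state_vector(s: ClassifierState) -> np.ndarray:
    """Concatenation convention: features ‖ logits ‖ probabilities."""
    return np.concatenate([s.features, s.logits, s.probabilities])


def build_state(s: ClassifierState, mode: str = "lesion",
                patient_context: Sequence[ClassifierState] | None = None) -> np.ndarray:
    """State vector for one lesion, optionally patient-normalized.

    ``patient_normalized`` divides each position by the mean of that position
    across all of the patient's lesion vectors; positions whose mean magnitude
    is below 1e-8 are left at their raw value.
    """
    v = state_vector(s)
    if mode == "lesion":
        return v
    if mode != "patient_normalized":
        raise ValueError(f"unknown state mode {mode!r}")
    if not patient_context:
        raise ValueError("patient_normalized mode needs the patient's state list")
    ctx = np.stack([state_vector(c) for c in patient_context])
    if ctx.shape[1] != v.shape[0]:
        raise ValueError("dimension mismatch within patient context")
    mean = ctx.mean(axis=0)
    safe = np.abs(mean) >= 1e-8
    out = v.copy()
    out[safe] = v[safe] / mean[safe]
    return out


def normalize_patient_states(states: np.ndarray) -> np.ndarray:
    """Vectorized patient normalization of an (n, D) block of state vectors."""
    mean = states.mean(axis=0)
    safe = np.abs(mean) >= 1e-8
    out = states.copy()
    out[:, safe] = states[:, safe] / mean[safe]
    return out


def order_episode(lesions: Sequence[LesionRecord]) -> list[LesionRecord]:
    """Sort a patient's lesions by descending malignancy probability (stable)."""
    if not lesions:
        raise ValueError("empty episode")
    keys = [-malignancy_probability(r.state.probabilities) for r in lesions]
    order = np.argsort(keys, kind="stable")
    return [lesions[i] for i in order]


def state_matrix(records: Sequence[LesionRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(n, F+14) state matrix and (n,) true-label index vector."""
    X = np.stack([state_vector(r.state) for r in records])
    y = np.array([r.true_label.index for r in records])
    return X, y


# ---------------------------------------------------------------- trained policy

@dataclass
class TrainedPolicy:
    """A trained Q-function plus everything needed to query and reproduce it."""

    network: QNetwork
    scenario: ScenarioSpec
    config: TrainConfig
    feature_dim: int
    state_mode: str
    history: list[dict] = field(default_factory=list)
    class_order: tuple[str, ...] = CLASS_CODES
    # rewards are normalized to max |entry| = 1 during training so the unit
    # Huber zone covers typical residuals; Q-values are reported in the
    # original reward units by rescaling on readout
    reward_scale: float = 1.0

    def _split(self, states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # features go through the hidden branch; logits + probabilities bypass it
        states = np.atleast_2d(states)
        f = self.feature_dim
        return states[:, :f], states[:, f:]

    def q_values_batch(self, states: np.ndarray) -> np.ndarray:
        feats, passthrough = self._split(states)
        if feats.shape[1] != self.feature_dim:
            raise ValueError("state dimension does not match training dimension")
        return self.reward_scale * self.network.forward(feats, passthrough, training=False)

    def q_values(self, s: ClassifierState,
                 patient_context: Sequence[ClassifierState] | None = None) -> np.ndarray:
        vec = build_state(s, self.state_mode, patient_context)
        return self.q_values_batch(vec[None, :])[0]

    def _greedy_from_q(self, q: np.ndarray) -> int:
        best = np.flatnonzero(q >= q.max())
        if self.scenario.is_management:
            ranks = [self.scenario.action_set[i].safety_rank for i in best]
            return int(best[int(np.argmax(ranks))])
        return int(best.min())  # lowest canonical diagnosis index

    def greedy_actions_batch(self, states: np.ndarray) -> np.ndarray:
        q = self.q_values_batch(states)
        return np.array([self._greedy_from_q(row) for row in q])

    def greedy_action(self, s: ClassifierState,
                      patient_context: Sequence[ClassifierState] | None = None):
        q = self.q_values(s, patient_context)
        return self.scenario.action_set[self._greedy_from_q(q)]

    def predictive_distribution(self, s: ClassifierState) -> np.ndarray:
        """Normalized exponential of the Q-vector (diagnosis policies only)."""
        if self.scenario.is_management:
            raise ValueError("predictive distributions exist only for diagnosis policies")
        q = self.q_values(s)
        z = q - q.max()
        e = np.exp(z)
        return e / e.sum()

    def predictive_distribution_batch(self, states: np.ndarray) -> np.ndarray:
        if self.scenario.is_management:
            raise ValueError("predictive distributions exist only for diagnosis policies")
        q = self.q_values_batch(states)
        z = q - q.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "scenario": self.scenario.name,
            "feature_dim": self.feature_dim,
            "state_mode": self.state_mode,
            "class_order": list(self.class_order),
            "config": asdict(self.config),
            "history": self.history,
            "reward_scale": self.reward_scale,
        }
        np.savez(path, W1=self.network.W1, b1=self.network.b1,
                 W2=self.network.W2, b2=self.network.b2,
                 meta=np.array(json.dumps(meta)))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPolicy":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if tuple(meta["class_order"]) != CLASS_CODES:
                raise ValueError("policy archive was trained under a different class order")
            scenario = SCENARIOS[meta["scenario"]]
            spec = QNetworkSpec(meta["feature_dim"], len(scenario.action_set),
                                hidden=z["W1"].shape[1],
                                dropout_rate=meta["config"]["dropout_rate"])
            net = QNetwork(spec, np.random.default_rng(0))
            net.W1[...], net.b1[...] = z["W1"], z["b1"]
            net.W2[...], net.b2[...] = z["W2"], z["b2"]
            cfg = TrainConfig(**meta["config"])
            return cls(net, scenario, cfg, meta["feature_dim"], meta["state_mode"],
                       meta["history"], reward_scale=meta.get("reward_scale", 1.0))


# ---------------------------------------------------------------- training

def _episode_states_lesion(X, y, pool, length, rng):
    idx = rng.choice(pool, size=length, replace=True)
    return X[idx], y[idx]


def _prepare_patient_episodes(cohort: PatientCohort):
    """Per-patient (normalized, ordered) state blocks and label vectors."""
    episodes = []
    for pid, lesions in cohort.patients:
        ordered = order_episode(list(lesions))
        X, y = state_matrix(ordered)
        episodes.append((normalize_patient_states(X), y))
    return episodes


def train_q(data: Sequence[LesionRecord] | PatientCohort, rewards: RewardTable,
            cfg: TrainConfig, scenario: ScenarioSpec) -> TrainedPolicy:
    """Train a Q-policy by ε-greedy replay-buffer deep Q-learning.

    ``data`` is a flat lesion list for the lesion-level scenarios or a
    :class:`PatientCohort` for the patient-centered one.  The reward table's
    columns must match the scenario's action set; per step the reward is the
    table entry at (true label, chosen action).  An 80/20 split (by patient in
    patient mode) provides the validation stream logged in ``history``.
    """
    rewards = rewards.reordered_for(scenario)
    R = rewards.values  # (7, A), original units: used for logged evaluations
    scale = float(np.max(np.abs(R))) or 1.0
    R_train = R / scale  # unit-Huber zone then covers typical TD residuals
    n_actions = len(scenario.action_set)
    if n_actions == 0:
        raise ValueError("empty action set")
    rng = np.random.default_rng(cfg.seed)

    patient_mode = isinstance(data, PatientCohort)
    if patient_mode:
        episodes = _prepare_patient_episodes(data)
        if not episodes:
            raise ValueError("empty cohort")
        perm = rng.permutation(len(episodes))
        n_val = max(1, int(round(cfg.val_fraction * len(episodes))))
        val_eps = [episodes[i] for i in perm[:n_val]]
        train_eps = [episodes[i] for i in perm[n_val:]] or val_eps
        X_val = np.concatenate([e[0] for e in val_eps])
        y_val = np.concatenate([e[1] for e in val_eps])
        state_dim = X_val.shape[1]
        feature_dim = state_dim - 2 * N
        state_mode = "patient_normalized"
    else:
        records = list(data)
        if not records:
            raise ValueError("no training records")
        X, y = state_matrix(records)
        state_dim = X.shape[1]
        feature_dim = state_dim - 2 * N
        perm = rng.permutation(len(records))
        n_val = max(1, int(round(cfg.val_fraction * len(records))))
        val_pool, train_pool = perm[:n_val], perm[n_val:]
        if train_pool.size == 0:
            train_pool = val_pool
        X_val, y_val = X[val_pool], y[val_pool]
        state_mode = "lesion"

    spec = QNetworkSpec(feature_dim, n_actions, passthrough_dim=2 * N,
                        hidden=cfg.hidden, dropout_rate=cfg.dropout_rate)
    net = QNetwork(spec, rng)
    target = net.clone()
    opt = Adam(net.params, cfg.learning_rate)
    avg = PolyakAverage(net.params, cfg.polyak_decay)
    buf = ReplayBuffer(cfg.replay_capacity, state_dim)
    policy = TrainedPolicy(net, scenario, cfg, feature_dim, state_mode,
                           reward_scale=scale)

    def greedy_batch(states):
        q = policy.q_values_batch(states)
        return np.array([policy._greedy_from_q(row) for row in q])

    def evaluate(step):
        a = greedy_batch(X_val)
        mean_r = float(R[y_val, a].mean())
        policy.history.append({"step": step, "val_mean_reward": mean_r})
        return mean_r

    step = 0
    best_val, since_best = -np.inf, 0
    stop = False
    while step < cfg.max_steps and not stop:
        if patient_mode:
            ep_X, ep_y = train_eps[rng.integers(len(train_eps))]
        else:
            ep_X, ep_y = _episode_states_lesion(X, y, train_pool, cfg.episode_length, rng)
        # action choice does not affect which lesion is shown next, so the whole
        # episode's greedy actions can be computed in one batched forward pass
        acts = greedy_batch(ep_X)
        explore = rng.random(len(acts)) < cfg.epsilon
        acts[explore] = rng.integers(0, n_actions, size=int(explore.sum()))
        ep_r = R_train[ep_y, acts]
        L = len(ep_X)
        for i in range(L):
            terminal = i == L - 1
            nxt = ep_X[i] if terminal else ep_X[i + 1]
            buf.push(ep_X[i], acts[i], ep_r[i], nxt, terminal)
            step += 1
            if step % cfg.q_update_period == 0 and len(buf) >= cfg.minibatch_size:
                s_b, a_b, r_b, sn_b, t_b = buf.sample(cfg.minibatch_size, rng)
                if cfg.discount > 0:
                    fn, pn = sn_b[:, :feature_dim], sn_b[:, feature_dim:]
                    q_next = target.forward(fn, pn, training=False).max(axis=1)
                    y_td = r_b + cfg.discount * np.where(t_b, 0.0, q_next)
                else:
                    y_td = r_b
                f_b, p_b = s_b[:, :feature_dim], s_b[:, feature_dim:]
                q_b, cache = net.forward(f_b, p_b, training=True, rng=rng)
                resid = q_b[np.arange(len(a_b)), a_b] - y_td
                dq = np.zeros_like(q_b)
                dq[np.arange(len(a_b)), a_b] = huber_grad(resid, cfg.huber_delta) / len(a_b)
                opt.step(net.backward(dq, cache))
                avg.update(net.params)
            if step % cfg.target_sync_period == 0:
                target.copy_from(net)
            if step % cfg.eval_period == 0:
                val = evaluate(step)
                if cfg.early_stop_patience is not None:
                    if val > best_val + 1e-9:
                        best_val, since_best = val, 0
                    else:
                        since_best += 1
                        if since_best >= cfg.early_stop_patience:
                            stop = True
            if step >= cfg.max_steps or stop:
                break
    # deploy the tail-averaged weights: same trajectory, far less gradient noise
    avg.install(net)
    if not policy.history or policy.history[-1]["step"] != step:
        evaluate(step)
    return policy
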