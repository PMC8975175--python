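"""Dueling double deep Q-network over window states.

Two interchangeable trunks estimate the action values: ``standard`` uses
plain 1-D convolutions; ``separable`` replaces each with a depthwise-then-
pointwise pair, shrinking the parameter count and per-step arithmetic at the
same receptive field.  The head is dueling — a scalar state value V and a
3-vector advantage A combined as ``Q = V + A - mean(A)`` — and training uses
the double-DQN target with a Polyak-averaged target network.
"""

from __future__ import annotations

import collections
import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Deque, List, Optional, Sequence, Tuple

import numpy as np

from . import _nn
from .env import Action, WindowState, N_CHANNELS

CHECKPOINT_FORMAT = "dqnxdrop-ckpt-1"


@dataclass(frozen=True)
class QValues:
    q_forward: float
    q_insertion: float
    q_deletion: float

    def as_array(self) -> np.ndarray:
        return np.array([self.q_forward, self.q_insertion, self.q_deletion])


@dataclass(frozen=True)
class Experience:
    state: WindowState
    action: Action
    reward: int
    next_state: WindowState
    terminal: bool


@dataclass
class NetworkConfig:
    """Architecture + training hyperparameters.

    ``literal_double_dqn`` switches training-time action selection to the
    target network's Q-values (instead of the main network's), the literal
    reading of the training procedure this package descends from; standard
    double DQN is the default.
    """

    window_size: int = 100
    conv_variant: str = "separable"  # or "standard"
    channels: Tuple[int, ...] = (16, 16)
    kernel: int = 3
    hidden: int = 64
    gamma: float = 0.99
    learning_rate: float = 1e-3
    tau: float = 1e-3
    eps_start: float = 1.0
    eps_end: float = 0.05
    eps_decay_fraction: float = 0.5  # fraction of inner steps to anneal over
    buffer_capacity: int = 100_000
    batch_size: int = 32
    literal_double_dqn: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0,1]")
        if self.conv_variant not in ("standard", "separable"):
            raise ValueError(f"unknown conv_variant {self.conv_variant!r}")


def encode_batch(states: Sequence[WindowState]) -> np.ndarray:
    """Stack WindowStates into a (B, 10, W) array: 2 sequences x 5 channels."""
    out = np.empty((len(states), 2 * N_CHANNELS, states[0].W))
    for i, s in enumerate(states):
        enc = s.encoded()  # (2, W, 5)
        out[i] = enc.transpose(0, 2, 1).reshape(2 * N_CHANNELS, s.W)
    return out


class QNetwork:
    """The Q-function: conv trunk -> dense -> dueling V/A heads."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator) -> None:
        self.config = config
        c_in = 2 * N_CHANNELS
        trunk: List[_nn.Layer] = []
        for c_out in config.channels:
            if config.conv_variant == "standard":
                trunk.append(_nn.Conv1d(c_in, c_out, config.kernel, rng))
            else:
                trunk.append(_nn.DepthwiseConv1d(c_in, config.kernel, rng))
                trunk.append(_nn.Conv1d(c_in, c_out, 1, rng))
            trunk.append(_nn.ReLU())
            c_in = c_out
        trunk.append(_nn.Flatten())
        trunk.append(_nn.Dense(c_in * config.window_size, config.hidden, rng))
        trunk.append(_nn.ReLU())
        self.trunk = trunk
        self.head_v = _nn.Dense(config.hidden, 1, rng)
        self.head_a = _nn.Dense(config.hidden, 3, rng)
        self._optimizer: Optional[_nn.Adam] = None

    # -- plumbing ---------------------------------------------------------
    @property
    def layers(self) -> List[_nn.Layer]:
        return [*self.trunk, self.head_v, self.head_a]

    @property
    def optimizer(self) -> _nn.Adam:
        if self._optimizer is None:
            self._optimizer = _nn.Adam(
                self.layers, lr=self.config.learning_rate)
        return self._optimizer

    def n_parameters(self) -> int:
        return _nn.n_parameters(self.layers)

    def parameters(self):
        return _nn.parameter_vector(self.layers)

    def clone(self) -> "QNetwork":
        """Independent copy with identical weights; optimizer state is fresh."""
        other = copy.deepcopy(self)
        other._optimizer = None
        return other

    def copy_weights_from(self, other: "QNetwork") -> None:
        mine, theirs = self.parameters(), other.parameters()
        if mine.keys() != theirs.keys():
            raise ValueError("architecture mismatch")
        for k in mine:
            mine[k][...] = theirs[k]

    # -- forward / backward -----------------------------------------------
    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        """(B, 10, W) -> (B, 3) Q-values with dueling aggregation."""
        f = x
        for layer in self.trunk:
            f = layer.forward(f)
        v = self.head_v.forward(f)        # (B, 1)
        a = self.head_a.forward(f)        # (B, 3)
        return v + a - a.mean(axis=1, keepdims=True)

    def backward_batch(self, dq: np.ndarray) -> None:
        da = dq - dq.mean(axis=1, keepdims=True)
        dv = dq.sum(axis=1, keepdims=True)
        df = self.head_v.backward(dv) + self.head_a.backward(da)
        for layer in reversed(self.trunk):
            df = layer.backward(df)

    def q_batch(self, states: Sequence[WindowState]) -> np.ndarray:
        return self.forward_batch(encode_batch(states))

    def q_values(self, state: WindowState) -> QValues:
        if state.W != self.config.window_size:
            raise ValueError(
                f"state window {state.W} != network window "
                f"{self.config.window_size}")
        q = self.q_batch([state])[0]
        return QValues(*map(float, q))

    # -- checkpointing -----------------------------------------------------
    def save(self, path, metadata: Optional[dict] = None) -> None:
        arrays = {k: v for k, v in self.parameters().items()}
        meta = {"format": CHECKPOINT_FORMAT,
                "config": asdict(self.config),
                "metadata": metadata or {}}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "QNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognized checkpoint format in {path}")
            cfg_dict = meta["config"]
            cfg_dict["channels"] = tuple(cfg_dict["channels"])
            config = NetworkConfig(**cfg_dict)
            net = cls(config, np.random.default_rng(0))
            params = net.parameters()
            for k in params:
                params[k][...] = data[k]
        return net


class ReplayBuffer:
    """Bounded FIFO of transitions with uniform sampling."""

    def __init__(self, capacity: int) -> None:
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._items: Deque[Experience] = collections.deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._items)

    def add(self, exp: Experience) -> None:
        self._items.append(exp)

    def extend(self, exps: Sequence[Experience]) -> None:
        for e in exps:
            self.add(e)

    def sample(self, n: int, rng: np.random.Generator) -> List[Experience]:
        if len(self._items) < n:
            raise ValueError(f"buffer holds {len(self._items)} < batch {n}")
        idx = rng.integers(0, len(self._items), size=n)
        return [self._items[int(i)] for i in idx]


def select_action(q: QValues, epsilon: float,
                  rng: Optional[np.random.Generator] = None) -> Action:
    """ε-greedy: argmax with fixed tie order FORWARD > INSERTION > DELETION."""
    if epsilon > 0:
        if rng is None:
            raise ValueError("epsilon > 0 requires an rng")
        if rng.random() < epsilon:
            return Action(int(rng.integers(0, 3)))
    return Action(int(np.argmax(q.as_array())))


def double_dqn_target(batch: Sequence[Experience], gamma: float,
                      main_net: QNetwork, target_net: QNetwork,
                      literal: bool = False) -> np.ndarray:
    """Per-item regression targets r + γ·Q_target(s', a*).

    a* is the argmax under the main network (standard double DQN); with
    ``literal=True`` the target network picks a* as well.
    """
    if not batch:
        raise ValueError("batch must be non-empty")
    rewards = np.array([e.reward for e in batch], dtype=float)
    terminal = np.array([e.terminal for e in batch])
    targets = rewards.copy()
    live = ~terminal
    if gamma > 0 and live.any():
        next_states = [e.next_state for e, alive in zip(batch, live) if alive]
        q_tgt = target_net.q_batch(next_states)
        selector = q_tgt if literal else main_net.q_batch(next_states)
        a_star = np.argmax(selector, axis=1)
        targets[live] += gamma * q_tgt[np.arange(len(next_states)), a_star]
    return targets


def soft_update_target(main_net: QNetwork, target_net: QNetwork,
                       tau: float) -> None:
    """Polyak step θ_t ← τ·θ_m + (1−τ)·θ_t, in place on the target."""
    mine, theirs = target_net.parameters(), main_net.parameters()
    if mine.keys() != theirs.keys():
        raise ValueError("architecture mismatch")
    for k in mine:
        mine[k][...] = tau * theirs[k] + (1.0 - tau) * mine[k]


def train_step(main_net: QNetwork, target_net: QNetwork,
               buffer: ReplayBuffer, config: NetworkConfig,
               rng: np.random.Generator) -> Optional[float]:
    """One squared-error gradient step on a uniform batch; returns pre-step loss.

    Returns None (no-op) while the buffer is smaller than the batch size.
    """
    if len(buffer) < config.batch_size:
        return None
    batch = buffer.sample(config.batch_size, rng)
    targets = double_dqn_target(batch, config.gamma, main_net, target_net,
                                literal=config.literal_double_dqn)
    x = encode_batch([e.state for e in batch])
    q = main_net.forward_batch(x)
    actions = np.array([int(e.action) for e in batch])
    picked = q[np.arange(len(batch)), actions]
    err = picked - targets
    loss = float(np.mean(err**2))
    dq = np.zeros_like(q)
    dq[np.arange(len(batch)), actions] = 2.0 * err / len(batch)
    main_net.backward_batch(dq)
    main_net.optimizer.step()
    soft_update_target(main_net, target_net, config.tau)
    return loss
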