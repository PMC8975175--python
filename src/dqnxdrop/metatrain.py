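"""Meta-training across a distribution of mutation environments.

The outer loop samples a mutation environment (SNP rate, indel rate, maximum
indel length), generates an ancestor/descendant sequence pair from it, and
hands a copy of the current outer network to an inner loop that trains it on
that pair with ordinary ε-greedy double-DQN updates.  The inner-trained
network is then evaluated greedily on a *held-out* pair from the same
environment; those evaluation trajectories (never the inner-training ones)
populate the outer replay buffer, from which the outer network takes its
gradient steps.  A final fine-tuning stage continues the same update rule on
pairs drawn from user-supplied real sequences.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .env import (Action, AlignmentColumn, AlignmentPosition, ScoringScheme,
                  apply_action, episode_terminal, extract_state)
from .qnet import (Experience, NetworkConfig, QNetwork, ReplayBuffer,
                   select_action, train_step)
from .simulate import (EnvironmentPair, MutationModel, encode_sequence,
                       make_environment_pair)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnvironmentDistribution:
    """Independent uniform ranges for the mutation-model parameters."""

    p_snp_range: Tuple[float, float] = (0.0, 0.3)
    p_indel_range: Tuple[float, float] = (0.0, 0.1)
    max_indel_range: Tuple[int, int] = (1, 10)
    zipf_s: float = 1.5

    def sample(self, rng: np.random.Generator) -> MutationModel:
        return MutationModel(
            p_snp=float(rng.uniform(*self.p_snp_range)),
            p_indel=float(rng.uniform(*self.p_indel_range)),
            zipf_s=self.zipf_s,
            max_indel=int(rng.integers(self.max_indel_range[0],
                                       self.max_indel_range[1] + 1)),
        )


@dataclass
class MetaConfig:
    outer_iterations: int = 30        # M
    inner_steps: int = 500            # N
    sequence_length: int = 1000
    inner_capacity: int = 100_000
    outer_capacity: int = 100_000
    outer_update_steps: int = 50      # gradient steps per outer iteration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_iterations < 1 or self.inner_steps < 0:
            raise ValueError("require outer_iterations >= 1, inner_steps >= 0")


@dataclass(frozen=True)
class EvalSummary:
    total_reward: int
    identity: float
    steps: int


def _epsilon(step: int, total: int, cfg: NetworkConfig) -> float:
    """Linear anneal eps_start -> eps_end over the first decay fraction."""
    horizon = max(1, int(total * cfg.eps_decay_fraction))
    frac = min(1.0, step / horizon)
    return cfg.eps_start + frac * (cfg.eps_end - cfg.eps_start)


def inner_loop_train(initial_net: QNetwork, env_pair: EnvironmentPair,
                     n_steps: int, rng: np.random.Generator,
                     scoring: ScoringScheme = ScoringScheme(),
                     model: Optional[MutationModel] = None,
                     buffer_capacity: int = 100_000,
                     ) -> Tuple[QNetwork, ReplayBuffer]:
    """Train a copy of ``initial_net`` for ``n_steps`` on one sequence pair.

    Episodes that hit a sequence end restart at (0,0); when ``model`` is
    given, each restart draws a fresh pair from the same environment,
    otherwise the original pair is reused.  ``initial_net`` is untouched.
    """
    net = initial_net.clone()
    target = initial_net.clone()
    cfg = net.config
    buffer = ReplayBuffer(buffer_capacity)
    s1, s2 = env_pair.s1, env_pair.s2
    c1, c2 = encode_sequence(s1), encode_sequence(s2)
    pos = AlignmentPosition(0, 0)
    for step in range(n_steps):
        if episode_terminal(s1, s2, pos):
            if model is not None:
                fresh = make_environment_pair(model, len(env_pair.s1), rng)
                s1, s2 = fresh.s1, fresh.s2
                c1, c2 = encode_sequence(s1), encode_sequence(s2)
            pos = AlignmentPosition(0, 0)
        state = extract_state(c1, c2, pos, cfg.window_size)
        eps = _epsilon(step, n_steps, cfg)
        action = select_action(net.q_values(state), eps, rng)
        new_pos, reward, _col = apply_action(s1, s2, pos, action, scoring)
        terminal = episode_terminal(s1, s2, new_pos)
        next_state = extract_state(c1, c2, new_pos, cfg.window_size)
        buffer.add(Experience(state, action, reward, next_state, terminal))
        train_step(net, target, buffer, cfg, rng)
        pos = new_pos
    return net, buffer


def rollout_greedy(net: QNetwork, s1: str, s2: str,
                   scoring: ScoringScheme = ScoringScheme(),
                   ) -> Tuple[List[Experience], List[AlignmentColumn]]:
    """Greedy (ε=0) rollout from (0,0) to the first sequence end."""
    cfg = net.config
    c1, c2 = encode_sequence(s1), encode_sequence(s2)
    pos = AlignmentPosition(0, 0)
    trajectory: List[Experience] = []
    columns: List[AlignmentColumn] = []
    while not episode_terminal(s1, s2, pos):
        state = extract_state(c1, c2, pos, cfg.window_size)
        action = Action(int(np.argmax(net.q_batch([state])[0])))
        new_pos, reward, col = apply_action(s1, s2, pos, action, scoring)
        terminal = episode_terminal(s1, s2, new_pos)
        next_state = extract_state(c1, c2, new_pos, cfg.window_size)
        trajectory.append(Experience(state, action, reward, next_state,
                                     terminal))
        columns.append(col)
        pos = new_pos
    return trajectory, columns


def evaluate_policy(net: QNetwork, s1_eval: str, s2_eval: str,
                    scoring: ScoringScheme = ScoringScheme(),
                    ) -> Tuple[List[Experience], EvalSummary]:
    """Greedy rollout on a held-out pair; the caller owns the trajectory."""
    trajectory, columns = rollout_greedy(net, s1_eval, s2_eval, scoring)
    total = sum(e.reward for e in trajectory)
    matches = sum(1 for c in columns if c.op == "M")
    identity = matches / len(columns) if columns else 0.0
    return trajectory, EvalSummary(total, identity, len(trajectory))


def meta_train(dist: EnvironmentDistribution, meta: MetaConfig,
               netcfg: NetworkConfig,
               scoring: ScoringScheme = ScoringScheme(),
               ) -> QNetwork:
    """The outer/inner training loop; returns the final outer network."""
    root = np.random.default_rng(meta.seed)
    rng_init, rng_env, rng_inner, rng_outer = root.spawn(4)
    outer_net = QNetwork(netcfg, rng_init)
    outer_target = outer_net.clone()
    outer_buffer = ReplayBuffer(meta.outer_capacity)
    for outer in range(meta.outer_iterations):
        model = dist.sample(rng_env)
        pair = make_environment_pair(model, meta.sequence_length, rng_env)
        trained, _inner_buf = inner_loop_train(
            outer_net, pair, meta.inner_steps, rng_inner, scoring,
            model=model, buffer_capacity=meta.inner_capacity)
        trajectory, summary = evaluate_policy(
            trained, pair.s1_eval, pair.s2_eval, scoring)
        outer_buffer.extend(trajectory)
        losses = []
        for _ in range(meta.outer_update_steps):
            loss = train_step(outer_net, outer_target, outer_buffer, netcfg,
                              rng_outer)
            if loss is not None:
                losses.append(loss)
        logger.info(
            "outer %d/%d: env(p_snp=%.3f p_indel=%.3f maxI=%d) "
            "eval reward=%d identity=%.3f buffer=%d loss=%s",
            outer + 1, meta.outer_iterations, model.p_snp, model.p_indel,
            model.max_indel, summary.total_reward, summary.identity,
            len(outer_buffer),
            f"{np.mean(losses):.4f}" if losses else "n/a")
    return outer_net


def fine_tune(net: QNetwork, sequences: Sequence[str], steps: int,
              rng: np.random.Generator,
              scoring: ScoringScheme = ScoringScheme(),
              buffer_capacity: int = 100_000) -> QNetwork:
    """Continue DQN training on all unordered pairs of real sequences.

    The pairs are cycled; each pair hosts episodes restarting at (0,0) until
    its share of the step budget is spent.  ``net`` is untouched.
    """
    if len(sequences) < 2:
        raise ValueError("fine_tune needs at least 2 sequences")
    tuned = net.clone()
    target = net.clone()
    cfg = tuned.config
    buffer = ReplayBuffer(buffer_capacity)
    pair_cycle = itertools.cycle(
        list(itertools.combinations(range(len(sequences)), 2)))
    step = 0
    while step < steps:
        i, j = next(pair_cycle)
        s1, s2 = sequences[i], sequences[j]
        c1, c2 = encode_sequence(s1), encode_sequence(s2)
        pos = AlignmentPosition(0, 0)
        # spend one episode (or the remaining budget) on this pair
        while step < steps and not episode_terminal(s1, s2, pos):
            state = extract_state(c1, c2, pos, cfg.window_size)
            eps = _epsilon(step, steps, cfg)
            action = select_action(tuned.q_values(state), eps, rng)
            new_pos, reward, _col = apply_action(s1, s2, pos, action, scoring)
            terminal = episode_terminal(s1, s2, new_pos)
            next_state = extract_state(c1, c2, new_pos, cfg.window_size)
            buffer.add(Experience(state, action, reward, next_state, terminal))
            train_step(tuned, target, buffer, cfg, rng)
            pos = new_pos
            step += 1
    return tuned
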