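import numpy as np
import pytest

import dqnxdrop as d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scoring():
    return d.ScoringScheme()  # (1, -1, -2)


@pytest.fixture
def tiny_netcfg():
    return d.NetworkConfig(window_size=6, channels=(4,), hidden=8)


@pytest.fixture
def tiny_net(tiny_netcfg):
    return d.QNetwork(tiny_netcfg, np.random.default_rng(7))


def desk_scale_network_config():
    """The small architecture used for CPU-scale training runs."""
    return d.NetworkConfig(window_size=10, channels=(8, 8), hidden=32,
                           learning_rate=1e-3)


@pytest.fixture(scope="session")
def meta_trained_net():
    """Meta-trained policy at desk scale: M=30 outer, N=500 inner, 1 kb pairs."""
    dist = d.EnvironmentDistribution()
    meta = d.MetaConfig(outer_iterations=30, inner_steps=500,
                        sequence_length=1000, seed=1)
    return d.meta_train(dist, meta, desk_scale_network_config())


class RandomPolicy:
    """Stub: arbitrary but reproducible Q-values per call."""

    def __init__(self, seed=0):
        self._rng = np.random.default_rng(seed)

    def q_values(self, state):
        return d.QValues(*self._rng.normal(size=3))


class GapAfterPolicy:
    """Stub: FORWARD for the first ``p`` decisions, then DELETION forever."""

    def __init__(self, p):
        self.p = p
        self.calls = 0

    def q_values(self, state):
        self.calls += 1
        if self.calls <= self.p:
            return d.QValues(1.0, 0.0, 0.0)
        return d.QValues(0.0, 0.0, 1.0)


def assert_xdrop_sound(result, X, scoring):
    """Re-simulate a recorded extension path and check the drop rule held."""
    score = 0
    best = 0
    for idx, col in enumerate(result.path):
        assert score > best - X, f"drop rule violated before step {idx}"
        score += scoring.column_score(col.op)
        best = max(best, score)
    assert best == result.best
    assert score == result.score
    prefix = result.path[:result.best_prefix_len]
    assert sum(scoring.column_score(c.op) for c in prefix) == result.best
    if result.terminated_by == "xdrop":
        assert not score > best - X
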