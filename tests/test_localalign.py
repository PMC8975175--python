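import numpy as np
import pytest

import dqnxdrop as d
from dqnxdrop.env import score_columns
from dqnxdrop.localalign import make_dqn_extender

from conftest import GapAfterPolicy, RandomPolicy, assert_xdrop_sound

ORIGIN = d.AlignmentPosition(0, 0)


def exhaustive_extension_best(s1, s2, sc):
    """Brute-force full-matrix extension DP: best score over all cells."""
    n, m = len(s1), len(s2)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        H[i, 0] = i * sc.score_gap
    for j in range(1, m + 1):
        H[0, j] = j * sc.score_gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = sc.score_match if s1[i - 1] == s2[j - 1] \
                else sc.score_mismatch
            H[i, j] = max(H[i - 1, j - 1] + sub, H[i - 1, j] + sc.score_gap,
                          H[i, j - 1] + sc.score_gap)
    return int(H.max())


class TestFindSeeds:
    def test_self_match_merges_to_one_full_seed(self, rng):
        s = d.generate_random_sequence(80, rng)
        seeds = d.find_seeds(s, s, k=12)
        diag0 = [x for x in seeds if x.diagonal == 0]
        assert diag0[0].x == 0 and diag0[0].k == 80

    def test_no_common_kmer_gives_empty(self):
        assert d.find_seeds("A" * 30, "C" * 30, k=8) == []

    def test_k_larger_than_sequence_gives_empty(self):
        assert d.find_seeds("ACGTACGT", "ACGTACGT", k=12) == []

    def test_k_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            d.find_seeds("ACGTACGT", "ACGTACGT", k=3)

    def test_n_hit_filter_enumeration(self, rng):
        """Two co-diagonal hits within d survive; a lone hit is dropped."""
        k = 8
        w1 = d.generate_random_sequence(k, rng)
        w2 = d.generate_random_sequence(k, rng)
        lone = d.generate_random_sequence(k, rng)
        pad = lambda n: d.generate_random_sequence(n, rng)
        # diagonal 0: w1 at 0 and w2 at 50 (distance 50 < d=100)
        s1 = w1 + pad(50 - k) + w2 + pad(30)
        s2 = w1 + pad(50 - k) + w2 + pad(23) + lone
        # lone hit on another diagonal
        s1 = s1 + lone
        seeds = d.find_seeds(s1, s2, k=k, n_hit=2, diag_window=100)
        diags = {s.diagonal for s in seeds}
        assert 0 in diags
        spans = [(sd.x, sd.x + sd.k) for sd in seeds if sd.diagonal == 0]
        assert any(lo <= 0 < hi for lo, hi in spans)        # w1 seed kept
        assert any(lo <= 50 and hi >= 58 for lo, hi in spans)  # w2 seed kept
        assert all(dg == 0 for dg in diags)  # the lone off-diagonal hit died


class TestDqnXdropExtend:
    def test_forced_forward_on_identical_sequences(self, rng):
        s = d.generate_random_sequence(60, rng)
        params = d.XdropParams(X=5, W=4)
        res = d.dqn_xdrop_extend(s, s, ORIGIN, d.ForwardPolicy(), params)
        assert res.terminated_by == "end"
        assert res.best == 60 * params.scoring.score_match
        assert res.best_prefix_len == 60

    def test_gap_after_p_hand_trace(self, rng):
        """With gap=-2 and X=4 the loop stops exactly 2 gaps past the best."""
        s = d.generate_random_sequence(40, rng)
        p = 10
        res = d.dqn_xdrop_extend(s, s, ORIGIN, GapAfterPolicy(p),
                                 d.XdropParams(X=4, W=4))
        assert res.terminated_by == "xdrop"
        assert res.best == p and res.best_prefix_len == p
        assert len(res.path) == p + 2 and res.score == p - 4

    def test_start_at_end_gives_empty_result(self, rng):
        s = d.generate_random_sequence(10, rng)
        res = d.dqn_xdrop_extend(s, s, d.AlignmentPosition(10, 10),
                                 d.ForwardPolicy(), d.XdropParams(X=5, W=4))
        assert res.path == [] and res.score == 0 and res.steps == 0

    def test_score_conservation_and_soundness_random_policies(self, rng,
                                                              scoring):
        params = d.XdropParams(X=6, W=4)
        for trial in range(30):
            s1 = d.generate_random_sequence(50, rng)
            s2 = d.generate_random_sequence(50, rng)
            res = d.dqn_xdrop_extend(s1, s2, ORIGIN, RandomPolicy(trial),
                                     params)
            assert_xdrop_sound(res, params.X, scoring)
            assert score_columns(res.alignment, scoring) == res.best


class TestGreedyXdropExtend:
    def test_matches_exhaustive_oracle_without_drop(self, rng, scoring):
        params = d.XdropParams(X=None, W=4)
        for _ in range(60):
            s1 = d.generate_random_sequence(int(rng.integers(1, 31)), rng)
            s2 = d.generate_random_sequence(int(rng.integers(1, 31)), rng)
            res = d.greedy_xdrop_extend(s1, s2, ORIGIN, params)
            assert res.best == exhaustive_extension_best(s1, s2, scoring)
            assert score_columns(res.alignment, scoring) == res.best

    def test_identical_sequences_pure_diagonal(self, rng):
        s = d.generate_random_sequence(45, rng)
        res = d.greedy_xdrop_extend(s, s, ORIGIN, d.XdropParams(X=20, W=4))
        assert all(c.op == "M" for c in res.alignment)
        assert res.best == 45

    def test_cells_grow_with_x_on_divergent_pairs(self, rng):
        """The pruned-DP search area expands with X; the policy loop's
        step count barely moves — the complexity separation in miniature."""
        from dqnxdrop.analysis import make_benchmark_pair
        model = d.MutationModel(p_snp=0.1)
        s1, s2 = make_benchmark_pair(model, 150, 600, rng)
        cells = []
        dqn_steps = []
        for X in (25, 100, 400):
            params = d.XdropParams(X=X, W=6)
            cells.append(d.greedy_xdrop_extend(s1, s2, ORIGIN, params).steps)
            dqn_steps.append(d.dqn_xdrop_extend(
                s1, s2, ORIGIN, d.ForwardPolicy(), params).steps)
        assert cells[2] / cells[0] > (dqn_steps[2] / dqn_steps[0]) * 2
        assert cells == sorted(cells)


class TestExtendBidirectional:
    def test_seed_spanning_identical_sequences(self, rng):
        s = d.generate_random_sequence(50, rng)
        seed = d.SeedHit(0, 0, 50)
        aln = d.extend_bidirectional(s, s, seed, d.greedy_xdrop_extend,
                                     d.XdropParams(X=10, W=4))
        assert aln.identity == 1.0
        assert aln.coverage1 == aln.coverage2 == 1.0
        assert (aln.start1, aln.end1) == (0, 50)

    def test_seed_at_origin_has_empty_upstream(self, rng):
        s = d.generate_random_sequence(60, rng)
        seed = d.SeedHit(0, 0, 12)
        aln = d.extend_bidirectional(s, s, seed, d.greedy_xdrop_extend,
                                     d.XdropParams(X=10, W=4))
        assert aln.start1 == 0 and aln.start2 == 0

    def test_score_additivity(self, rng, scoring):
        m = d.MutationModel(p_snp=0.1, p_indel=0.02, max_indel=3)
        pair = d.make_environment_pair(m, 200, rng)
        seeds = d.find_seeds(pair.s1, pair.s2, k=10)
        assert seeds
        seed = seeds[0]
        params = d.XdropParams(X=20, W=6)
        up = d.greedy_xdrop_extend(pair.s1[:seed.x][::-1],
                                   pair.s2[:seed.y][::-1], ORIGIN, params)
        down = d.greedy_xdrop_extend(pair.s1[seed.x + seed.k:],
                                     pair.s2[seed.y + seed.k:], ORIGIN,
                                     params)
        aln = d.extend_bidirectional(pair.s1, pair.s2, seed,
                                     d.greedy_xdrop_extend, params)
        assert aln.score == up.best + seed.k * scoring.score_match + down.best
        assert score_columns(aln.columns, scoring) == aln.score


class TestAlignPair:
    def test_identical_sequences_single_full_alignment(self, rng):
        s = d.generate_random_sequence(120, rng)
        alns = d.align_pair(s, s, d.greedy_xdrop_extend,
                            d.XdropParams(X=20, W=6), k=12)
        assert len(alns) >= 1
        best = alns[0]
        assert best.identity == 1.0
        assert best.coverage1 == best.coverage2 == 1.0

    def test_unrelated_sequences_give_no_alignment(self, rng):
        # expected k-mer collisions: ~ (500-k+1)^2 / 4^12 << 1 raw hits,
        # and the n-hit filter needs two co-diagonal hits
        s1 = d.generate_random_sequence(500, rng)
        s2 = d.generate_random_sequence(500, rng)
        alns = d.align_pair(s1, s2, d.greedy_xdrop_extend,
                            d.XdropParams(X=20, W=6), k=12)
        assert alns == []

    def test_output_sorted_by_score(self, rng):
        m = d.MutationModel(p_snp=0.05)
        pair = d.make_environment_pair(m, 300, rng)
        alns = d.align_pair(pair.s1, pair.s2, d.greedy_xdrop_extend,
                            d.XdropParams(X=15, W=6), k=10)
        scores = [a.score for a in alns]
        assert scores == sorted(scores, reverse=True)

    def test_dqn_extender_through_pipeline(self, rng):
        s = d.generate_random_sequence(100, rng)
        alns = d.align_pair(s, s, make_dqn_extender(d.ForwardPolicy()),
                            d.XdropParams(X=10, W=6), k=12)
        assert alns and alns[0].identity == 1.0
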