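"""Analytic complexity/error evaluators and the desk-scale benchmark harness.

The step-error analysis treats one windowed decision as a tiny ungapped
alignment problem governed by Karlin–Altschul (Gumbel) statistics with
parameters K and λ: the probability that the locally best move is wrong
decays like W²·exp(−λ·W·score_avg) with the window size W.  Combined with
the Zipfian indel-length model, the expected extension length reachable
before an x-drop-terminating indel gives a window–X relation W ∝ ln X.

The benchmark harness replaces wall-clock time with step counts (decision
steps for the policy extender, DP cells for the greedy baseline), which are
hardware-independent observables of the same complexity claims.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import zeta as _scipy_zeta

from .env import AlignmentPosition, ScoringScheme
from .localalign import Extender, XdropParams, align_pair
from .simulate import MutationModel, generate_random_sequence, mutate


@dataclass(frozen=True)
class GumbelParams:
    """Karlin–Altschul extreme-value parameters of the scoring scheme.

    Defaults are the commonly tabulated values for ungapped +1/-1 DNA
    scoring; they are placeholders to be replaced with values fitted to the
    actual scheme when calibrated statistics matter.
    """

    K: float = 0.711
    lam: float = 1.33

    def __post_init__(self) -> None:
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("require K > 0 and lambda > 0")


@dataclass(frozen=True)
class ComplexityInputs:
    """Inputs of the step-error and window-size formulas."""

    p_snp: float
    p_indel: float
    scoring: ScoringScheme = ScoringScheme()
    score_avg: Optional[float] = None  # default: divergence-based estimate
    W: int = 100
    X: int = 100
    s: float = 1.5
    B: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.p_snp <= 1 and 0 <= self.p_indel <= 1):
            raise ValueError("probabilities must lie in [0,1]")
        if self.W < 1 or self.X <= 0:
            raise ValueError("require W >= 1 and X > 0")

    def effective_score_avg(self) -> float:
        """Expected per-column score at the pair's divergence, if not given."""
        if self.score_avg is not None:
            return self.score_avg
        return ((1.0 - self.p_snp) * self.scoring.score_match
                + self.p_snp * self.scoring.score_mismatch)


def step_error_probability(inp: ComplexityInputs, g: GumbelParams) -> float:
    """Probability that one windowed decision picks a suboptimal move.

    Evaluates
    ``(p_indel·K·(e^{λ·gap} + ¼·e^{λ·match} + ¾·e^{λ·mismatch})
    + 2·p_snp·K·e^{λ·gap}) · W² / e^{λ·W·score_avg}``,
    which vanishes as W grows provided the expected per-column score is
    positive.
    """
    s_avg = inp.effective_score_avg()
    if s_avg <= 0:
        raise ValueError("score_avg must be positive; the bound diverges")
    lam, K = g.lam, g.K
    sc = inp.scoring
    indel_term = inp.p_indel * K * (
        math.exp(lam * sc.score_gap)
        + 0.25 * math.exp(lam * sc.score_match)
        + 0.75 * math.exp(lam * sc.score_mismatch))
    snp_term = 2.0 * inp.p_snp * K * math.exp(lam * sc.score_gap)
    if indel_term + snp_term == 0.0:
        return 0.0
    # W^2 / e^{lam W s_avg} in log space: underflows to 0 for huge W
    log_w_factor = 2.0 * math.log(inp.W) - lam * inp.W * s_avg
    return (indel_term + snp_term) * math.exp(log_w_factor)


def zipf_zeta(s: float) -> float:
    """Riemann ζ(s) for s > 1 (normalizer of the Zipfian length law)."""
    if s <= 1.0:
        raise ValueError("zeta(s) diverges for s <= 1")
    return float(_scipy_zeta(s, 1))


def xdrop_gap_count(X: int, scoring: ScoringScheme) -> int:
    """X_g = ceil(X / |score_gap|): gap columns that force termination.

    The gap score is negative; the magnitude is used so X_g is the positive
    count of consecutive gap columns after which the drop rule must fire.
    """
    return math.ceil(X / abs(scoring.score_gap))


def expected_length_bound(X: int, scoring: ScoringScheme, p_indel: float,
                          s: float) -> float:
    """Upper bound X_g^s·ζ(s)/p_indel on the expected extension length.

    An indel of length ≥ X_g unconditionally terminates the extension, so
    the expected length is below the waiting time for such an indel.
    ``p_indel = 0`` makes the bound infinite, signalled as ``math.inf``.
    """
    if s <= 1.0:
        raise ValueError("require s > 1")
    if p_indel < 0 or p_indel > 1:
        raise ValueError("p_indel must lie in [0,1]")
    if p_indel == 0:
        return math.inf
    return xdrop_gap_count(X, scoring)**s * zipf_zeta(s) / p_indel


def required_window(X: float, s: float, B: float, alpha: float,
                    score_gap: int) -> float:
    """Window size keeping the total error vanishing: (s/B)·ln X_g + α.

    Expanded as ``(s/B)·ln X − (s/B)·ln |score_gap| + α``; grows
    logarithmically in X, which is what makes the policy extender's
    per-step cost scale gently with the drop threshold.
    """
    if B <= 0 or alpha < 0 or X <= 0:
        raise ValueError("require B > 0, alpha >= 0, X > 0")
    return (s / B) * math.log(X) - (s / B) * math.log(abs(score_gap)) + alpha


def total_error_bound(X: int, inp: ComplexityInputs, g: GumbelParams) -> float:
    """L(X)-compounded step error: expected_length_bound · step_error.

    Evaluated along W = required_window(X, ...) this product vanishes as X
    grows, which is the consistency property tying the two formulas together.
    """
    return (expected_length_bound(X, inp.scoring, inp.p_indel, inp.s)
            * step_error_probability(inp, g))


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkRecord:
    aligner: str
    X: int
    W: int
    length: int
    aln_columns: int
    seed: int
    steps: int
    identity: float
    coverage: float
    terminated_by: str


def make_benchmark_pair(model: MutationModel, core_length: int,
                        tail_length: int, rng: np.random.Generator
                        ) -> Tuple[str, str]:
    """A homologous core followed by unrelated random tails.

    Extension from (0,0) runs through the mutated-copy core and into random
    sequence, where the score drifts down and the x-drop rule fires — the
    regime in which step counts actually depend on X.
    """
    core = generate_random_sequence(core_length, rng)
    mutated, _ = mutate(core, model, rng)
    t1 = generate_random_sequence(tail_length, rng)
    t2 = generate_random_sequence(tail_length, rng)
    return core + t1, mutated + t2


def run_benchmark(extenders: Dict[str, Extender], Xs: Sequence[int],
                  model: MutationModel, core_length: int, seeds: Sequence[int],
                  W: int = 10, scoring: ScoringScheme = ScoringScheme(),
                  tail_length: Optional[int] = None) -> pd.DataFrame:
    """Step-count scaling experiment over the x-drop parameter grid.

    For every (extender, X, seed): simulate a core+tail pair, extend from
    (0,0), record steps/identity/coverage.  The companion
    :func:`fit_loglog_slopes` fits d log(steps) / d log(X) per extender.
    """
    records: List[BenchmarkRecord] = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        # tails long enough that termination is by x-drop, not sequence end
        tail = 4 * max(Xs) + 200 if tail_length is None else tail_length
        s1, s2 = make_benchmark_pair(model, core_length, tail, rng)
        for X in Xs:
            params = XdropParams(X=X, W=W, scoring=scoring)
            for name, extender in extenders.items():
                res = extender(s1, s2, AlignmentPosition(0, 0), params)
                cols = res.alignment
                matches = sum(1 for c in cols if c.op == "M")
                identity = matches / len(cols) if cols else 0.0
                cov = (sum(c.consumes1 for c in cols) / len(s1)
                       if len(s1) else 0.0)
                records.append(BenchmarkRecord(
                    name, X, W, len(s1), len(cols), seed, res.steps,
                    identity, cov, res.terminated_by))
    return pd.DataFrame([r.__dict__ for r in records])


def fit_loglog_slopes(bench: pd.DataFrame) -> Dict[str, float]:
    """Least-squares slope of log(mean steps) vs log(X) per aligner."""
    slopes: Dict[str, float] = {}
    for name, grp in bench.groupby("aligner"):
        means = grp.groupby("X")["steps"].mean()
        lx = np.log(means.index.to_numpy(dtype=float))
        ly = np.log(means.to_numpy(dtype=float))
        slopes[name] = float(np.polyfit(lx, ly, 1)[0])
    return slopes


def fit_linear_step_bound(bench: pd.DataFrame, aligner: str) -> pd.Series:
    """Per-record constant c in steps <= c·(L + 2X), L = alignment columns.

    For the policy extender the step count is the alignment length plus the
    post-peak walk down to the drop threshold, so c should sit near 1 and,
    crucially, stay flat as X grows.
    """
    grp = bench[bench["aligner"] == aligner]
    return grp["steps"] / (grp["aln_columns"] + 2 * grp["X"])


# ---------------------------------------------------------------------------
# all-vs-all statistics
# ---------------------------------------------------------------------------

def pairwise_best_table(records: Sequence[Tuple[str, str]],
                        extender: Extender, params: XdropParams,
                        k: int = 12, n_hit: int = 2, diag_window: int = 100,
                        ) -> pd.DataFrame:
    """Best-alignment row for every unordered pair: exactly n(n-1)/2 rows.

    Pairs with no surviving seed still get a row, with zero score/identity
    and no coordinates, so the row count is purely combinatorial.
    """
    rows = []
    for (id1, s1), (id2, s2) in itertools.combinations(records, 2):
        alns = align_pair(s1, s2, extender, params, k=k, n_hit=n_hit,
                          diag_window=diag_window)
        if alns:
            best = alns[0]
            rows.append({"query_id": id1, "subject_id": id2,
                         "score": best.score, "identity": best.identity,
                         "coverage_q": best.coverage1,
                         "coverage_s": best.coverage2,
                         "n_alignments": len(alns)})
        else:
            rows.append({"query_id": id1, "subject_id": id2,
                         "score": 0, "identity": 0.0,
                         "coverage_q": 0.0, "coverage_s": 0.0,
                         "n_alignments": 0})
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "score",
                                       "identity", "coverage_q", "coverage_s",
                                       "n_alignments"])


def pairwise_stats(pairs: pd.DataFrame,
                   groups: Optional[Dict[str, str]] = None,
                   bins: int = 10) -> Dict[str, pd.DataFrame]:
    """Per-group identity/coverage distribution summaries.

    ``groups`` maps sequence id -> group label; a pair belongs to a group
    label "A-B" (sorted) derived from its two members, or "all" without
    groups.  Returns ``{"summary": ..., "histogram": ...}``.
    """
    df = pairs.copy()
    if groups is None:
        df["group"] = "all"
    else:
        def pair_group(row):
            a = groups.get(row["query_id"], "?")
            b = groups.get(row["subject_id"], "?")
            return "intra:" + a if a == b else "inter:" + "-".join(sorted((a, b)))
        df["group"] = df.apply(pair_group, axis=1)
    summaries = []
    hists = []
    edges = np.linspace(0.0, 1.0, bins + 1)
    for g, grp in df.groupby("group"):
        for metric in ("identity", "coverage_q", "coverage_s"):
            vals = grp[metric].to_numpy(dtype=float)
            summaries.append({
                "group": g, "metric": metric, "n_pairs": len(grp),
                "mean": float(np.mean(vals)), "median": float(np.median(vals)),
            })
            counts, _ = np.histogram(vals, bins=edges)
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                hists.append({"group": g, "metric": metric,
                              "bin_lo": float(lo), "bin_hi": float(hi),
                              "count": int(c)})
    return {"summary": pd.DataFrame(summaries),
            "histogram": pd.DataFrame(hists)}
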