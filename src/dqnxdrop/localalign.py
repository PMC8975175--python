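"""Seed-and-extend local alignment with x-drop termination.

Seeding is exact k-mer matching with an n-hit diagonal filter (candidate
hits survive only when enough hits share their diagonal nearby), standing in
for a full repeat-miner preprocessing stage.  Each surviving seed is extended
in both directions, either by the classical greedy x-drop baseline — a pruned
antidiagonal dynamic program — or by the DQN extension loop, which repeatedly
windows the two sequences, asks a policy for the best action, applies it, and
stops once the running score falls more than X below the best score seen.

The DQN extender is policy-agnostic: anything exposing
``q_values(WindowState) -> QValues`` drives it, so deterministic stub
policies exercise every branch without training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .env import (Action, AlignmentColumn, AlignmentPosition, ScoringScheme,
                  WindowState, apply_action, episode_terminal, extract_state)
from .qnet import QValues
from .simulate import encode_sequence

_NEG = np.int64(-(2**40))


@dataclass(frozen=True)
class SeedHit:
    """Exact match S1[x:x+k] == S2[y:y+k]; ``diagonal`` = x - y."""

    x: int
    y: int
    k: int

    @property
    def diagonal(self) -> int:
        return self.x - self.y


@dataclass(frozen=True)
class XdropParams:
    """Extension parameters: drop threshold X, window W, scoring scheme.

    ``X=None`` disables the drop rule (exhaustive extension; testing only).
    """

    X: Optional[int] = 100
    W: int = 100
    scoring: ScoringScheme = ScoringScheme()

    def __post_init__(self) -> None:
        if self.X is not None and self.X <= 0:
            raise ValueError("X must be > 0")
        if self.W < 1:
            raise ValueError("W must be >= 1")


@dataclass
class ExtensionResult:
    """One x-drop extension: the full path, its best prefix, and counters.

    ``path[:best_prefix_len]`` is the returned alignment (score == ``best``);
    ``score`` is the running score when the loop stopped; ``steps`` counts
    decision steps (DQN) or DP cells evaluated (greedy).
    """

    path: List[AlignmentColumn]
    score: int
    best: int
    best_prefix_len: int
    steps: int
    terminated_by: str  # "xdrop" | "end"

    @property
    def alignment(self) -> List[AlignmentColumn]:
        return self.path[:self.best_prefix_len]

    def consumed(self) -> Tuple[int, int]:
        cols = self.alignment
        return (sum(c.consumes1 for c in cols),
                sum(c.consumes2 for c in cols))


@dataclass
class LocalAlignment:
    """A merged bidirectional extension around one seed."""

    start1: int
    end1: int
    start2: int
    end2: int
    columns: List[AlignmentColumn]
    score: int
    identity: float
    coverage1: float
    coverage2: float
    steps: int
    terminated_by: str

    def matches(self) -> int:
        return sum(1 for c in self.columns if c.op == "M")


class ForwardPolicy:
    """Stub policy that always advances both cursors (pure diagonal)."""

    def q_values(self, state: WindowState) -> QValues:
        return QValues(1.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def find_seeds(s1: str, s2: str, k: int = 12, n_hit: int = 2,
               diag_window: int = 100) -> List[SeedHit]:
    """Exact k-mer seeds filtered by the n-hit rule and merged per diagonal.

    A raw hit survives when at least ``n_hit`` hits (itself included) share
    its diagonal within ``diag_window`` positions; surviving overlapping hits
    on one diagonal merge into a single longer seed.
    """
    if k < 4:
        raise ValueError("seed length k must be >= 4")
    if k > min(len(s1), len(s2)):
        return []
    index: Dict[str, List[int]] = {}
    for x in range(len(s1) - k + 1):
        index.setdefault(s1[x:x + k], []).append(x)
    by_diag: Dict[int, List[int]] = {}
    for y in range(len(s2) - k + 1):
        for x in index.get(s2[y:y + k], ()):
            by_diag.setdefault(x - y, []).append(x)
    seeds: List[SeedHit] = []
    for diag, xs in by_diag.items():
        xs.sort()
        kept: List[int] = []
        lo = 0
        hi = 0
        for i, x in enumerate(xs):
            while xs[lo] < x - diag_window:
                lo += 1
            while hi < len(xs) and xs[hi] <= x + diag_window:
                hi += 1
            if hi - lo >= n_hit:
                kept.append(x)
        # merge overlapping/adjacent surviving hits on this diagonal
        i = 0
        while i < len(kept):
            start = kept[i]
            end = start + k
            j = i + 1
            while j < len(kept) and kept[j] <= end:
                end = max(end, kept[j] + k)
                j += 1
            seeds.append(SeedHit(start, start - diag, end - start))
            i = j
    seeds.sort(key=lambda s: (-s.k, s.x, s.y))
    return seeds


# ---------------------------------------------------------------------------
# DQN x-drop extension
# ---------------------------------------------------------------------------

def dqn_xdrop_extend(s1: str, s2: str, start: AlignmentPosition, policy,
                     params: XdropParams) -> ExtensionResult:
    """Greedy policy rollout terminated by the x-drop rule.

    Loop: window the sequences at the cursor, take the policy's argmax
    action, score the emitted column, and track the best-scoring prefix;
    stop when the running score is no longer above ``best - X`` or a
    sequence end is reached (end termination wins a tie).
    """
    c1, c2 = encode_sequence(s1), encode_sequence(s2)
    pos = start
    path: List[AlignmentColumn] = []
    score = 0
    best = 0
    best_len = 0
    steps = 0
    scoring = params.scoring
    while True:
        if episode_terminal(s1, s2, pos):
            reason = "end"
            break
        if params.X is not None and not score > best - params.X:
            reason = "xdrop"
            break
        state = extract_state(c1, c2, pos, params.W)
        q = policy.q_values(state)
        action = Action(int(np.argmax(q.as_array())))
        pos, reward, col = apply_action(s1, s2, pos, action, scoring)
        path.append(col)
        score += reward
        steps += 1
        if score > best:
            best = score
            best_len = len(path)
    return ExtensionResult(path, score, best, best_len, steps, reason)


# ---------------------------------------------------------------------------
# greedy x-drop baseline (pruned antidiagonal DP)
# ---------------------------------------------------------------------------

def greedy_xdrop_extend(s1: str, s2: str, start: AlignmentPosition,
                        params: XdropParams) -> ExtensionResult:
    """Classical x-drop extension: banded DP pruned at ``best - X``.

    Cells are visited antidiagonal by antidiagonal; a cell whose score is not
    above ``best - X`` is dead, and the band shrinks to the outermost live
    cells.  The search area (and hence ``steps``, the number of cells
    evaluated) grows with X; with ``X=None`` the full extension matrix is
    evaluated.  Returns the best cell's score and a traceback path.
    """
    a = encode_sequence(s1)[start.x:]
    b = encode_sequence(s2)[start.y:]
    n, m = len(a), len(b)
    scoring = params.scoring
    if n == 0 or m == 0:
        return ExtensionResult([], 0, 0, 0, 0, "end")
    gap = scoring.score_gap
    rows: List[Optional[Tuple[int, np.ndarray]]] = [(0, np.zeros(1, np.int64))]
    best = 0
    best_cell = (0, 0)
    cells = 1
    reason = "end"
    for k in range(1, n + m + 1):
        i_min = max(0, k - m)
        i_max = min(n, k)
        width = i_max - i_min + 1
        cand = np.full(width, _NEG, dtype=np.int64)

        def fold(src_lo: int, src: np.ndarray, shift: int, add) -> None:
            # candidate i-range of this move is [src_lo+shift, src_lo+shift+len-1]
            t_lo = max(i_min, src_lo + shift)
            t_hi = min(i_max, src_lo + shift + len(src) - 1)
            if t_lo > t_hi:
                return
            s_off = t_lo - (src_lo + shift)
            seg = src[s_off:s_off + (t_hi - t_lo + 1)] + add
            sl = slice(t_lo - i_min, t_hi - i_min + 1)
            np.maximum(cand[sl], seg, out=cand[sl])

        prev1 = rows[k - 1]
        if prev1 is not None:
            lo1, S1 = prev1
            fold(lo1, S1, 1, gap)                       # up: consume S1
            fold(lo1, S1, 0, gap)                       # left: consume S2
        if k >= 2 and rows[k - 2] is not None:
            lo2, S2 = rows[k - 2]
            t_lo = max(i_min, lo2 + 1, 1)
            t_hi = min(i_max, lo2 + len(S2), k - 1)
            if t_lo <= t_hi:
                ai = a[t_lo - 1:t_hi]
                bi = b[k - 1 - t_hi:k - t_lo][::-1]
                sub = np.where((ai == bi) & (ai < 4) & (bi < 4),
                               scoring.score_match, scoring.score_mismatch
                               ).astype(np.int64)
                s_off = t_lo - (lo2 + 1)
                seg = S2[s_off:s_off + (t_hi - t_lo + 1)] + sub
                sl = slice(t_lo - i_min, t_hi - i_min + 1)
                np.maximum(cand[sl], seg, out=cand[sl])
        reachable = cand > _NEG // 2
        if not reachable.any():
            rows.append(None)
            if prev1 is None:
                reason = "xdrop"
                break
            continue
        cells += int(reachable.sum())
        row_max = int(cand[reachable].max())
        if row_max > best:
            best = row_max
            i_best = i_min + int(np.flatnonzero(
                reachable & (cand == row_max))[0])
            best_cell = (i_best, k - i_best)
        if params.X is not None:
            alive = reachable & (cand > best - params.X)
        else:
            alive = reachable
        idx = np.flatnonzero(alive)
        if len(idx) == 0:
            rows.append(None)
            if prev1 is None:
                reason = "xdrop"
                break
            continue
        lo_new = i_min + int(idx[0])
        seg = cand[idx[0]:idx[-1] + 1].copy()
        seg[~alive[idx[0]:idx[-1] + 1]] = _NEG  # pruned cells must not propagate
        rows.append((lo_new, seg))

    path = _traceback(rows, best_cell, a, b, scoring)
    return ExtensionResult(path, best, best, len(path), cells, reason)


def _row_value(rows, k: int, i: int) -> Optional[int]:
    if k < 0 or k >= len(rows) or rows[k] is None:
        return None
    lo, arr = rows[k]
    if lo <= i < lo + len(arr):
        v = int(arr[i - lo])
        return None if v <= int(_NEG // 2) else v
    return None


def _traceback(rows, cell: Tuple[int, int], a: np.ndarray, b: np.ndarray,
               scoring: ScoringScheme) -> List[AlignmentColumn]:
    i, j = cell
    v = _row_value(rows, i + j, i)
    cols: List[AlignmentColumn] = []
    while (i, j) != (0, 0):
        k = i + j
        moved = False
        if i >= 1 and j >= 1:
            pv = _row_value(rows, k - 2, i - 1)
            if pv is not None:
                is_match = a[i - 1] == b[j - 1] and a[i - 1] < 4 and b[j - 1] < 4
                sub = scoring.score_match if is_match else scoring.score_mismatch
                if pv + sub == v:
                    cols.append(AlignmentColumn("M" if is_match else "X"))
                    i, j, v = i - 1, j - 1, pv
                    moved = True
        if not moved and i >= 1:
            pv = _row_value(rows, k - 1, i - 1)
            if pv is not None and pv + scoring.score_gap == v:
                cols.append(AlignmentColumn("D"))
                i, v = i - 1, pv
                moved = True
        if not moved and j >= 1:
            pv = _row_value(rows, k - 1, i)
            if pv is not None and pv + scoring.score_gap == v:
                cols.append(AlignmentColumn("I"))
                j, v = j - 1, pv
                moved = True
        if not moved:  # pragma: no cover - DP invariant
            raise AssertionError("traceback lost the DP path")
    cols.reverse()
    return cols


# ---------------------------------------------------------------------------
# bidirectional assembly
# ---------------------------------------------------------------------------

Extender = Callable[[str, str, AlignmentPosition, XdropParams],
                    ExtensionResult]


def extend_bidirectional(s1: str, s2: str, seed: SeedHit,
                         extender: Extender,
                         params: XdropParams) -> LocalAlignment:
    """Extend a seed upstream and downstream and merge the three parts.

    The upstream extension runs the same extender on the reversed prefixes,
    so one policy serves both directions.
    """
    down = extender(s1[seed.x + seed.k:], s2[seed.y + seed.k:],
                    AlignmentPosition(0, 0), params)
    up = extender(s1[:seed.x][::-1], s2[:seed.y][::-1],
                  AlignmentPosition(0, 0), params)
    up_cols = list(reversed(up.alignment))
    down_cols = down.alignment
    u1, u2 = up.consumed()
    d1, d2 = down.consumed()
    columns = up_cols + [AlignmentColumn("M")] * seed.k + down_cols
    score = up.best + seed.k * params.scoring.score_match + down.best
    matches = sum(1 for c in columns if c.op == "M")
    start1, end1 = seed.x - u1, seed.x + seed.k + d1
    start2, end2 = seed.y - u2, seed.y + seed.k + d2
    return LocalAlignment(
        start1=start1, end1=end1, start2=start2, end2=end2,
        columns=columns, score=score,
        identity=matches / len(columns),
        coverage1=(end1 - start1) / len(s1) if len(s1) else 0.0,
        coverage2=(end2 - start2) / len(s2) if len(s2) else 0.0,
        steps=up.steps + down.steps,
        terminated_by=f"{up.terminated_by}/{down.terminated_by}")


def align_pair(s1: str, s2: str, extender: Extender, params: XdropParams,
               k: int = 12, n_hit: int = 2, diag_window: int = 100,
               overlap_fraction: float = 0.5) -> List[LocalAlignment]:
    """Full pipeline: seed, filter, extend each uncovered seed, sort by score.

    A seed is skipped when at least ``overlap_fraction`` of its S1 span lies
    inside an already-accepted alignment.
    """
    seeds = find_seeds(s1, s2, k=k, n_hit=n_hit, diag_window=diag_window)
    accepted: List[LocalAlignment] = []
    for seed in seeds:
        span = seed.k
        covered = 0
        for aln in accepted:
            lo = max(seed.x, aln.start1)
            hi = min(seed.x + seed.k, aln.end1)
            covered = max(covered, hi - lo)
        if covered >= overlap_fraction * span:
            continue
        accepted.append(extend_bidirectional(s1, s2, seed, extender, params))
    accepted.sort(key=lambda a: -a.score)
    return accepted


def make_dqn_extender(policy) -> Extender:
    def _ext(s1, s2, start, params):
        return dqn_xdrop_extend(s1, s2, start, policy, params)
    return _ext


def alignments_to_table(alignments: List[LocalAlignment], query_id: str,
                        subject_id: str) -> pd.DataFrame:
    """BLAST-tabular-style rows, coordinates 0-based half-open."""
    rows = [{
        "query_id": query_id, "subject_id": subject_id,
        "q_start": a.start1, "q_end": a.end1,
        "s_start": a.start2, "s_end": a.end2,
        "score": a.score, "identity": a.identity,
        "coverage_q": a.coverage1, "coverage_s": a.coverage2,
        "steps": a.steps, "terminated_by": a.terminated_by,
    } for a in alignments]
    cols = ["query_id", "subject_id", "q_start", "q_end", "s_start", "s_end",
            "score", "identity", "coverage_q", "coverage_s", "steps",
            "terminated_by"]
    return pd.DataFrame(rows, columns=cols)


def columns_to_strings(s1: str, s2: str, aln: LocalAlignment
                       ) -> Tuple[str, str]:
    """Render an alignment as two gapped strings for --emit-alignments."""
    x, y = aln.start1, aln.start2
    top, bot = [], []
    for c in aln.columns:
        top.append(s1[x] if c.consumes1 else "-")
        bot.append(s2[y] if c.consumes2 else "-")
        x += c.consumes1
        y += c.consumes2
    return "".join(top), "".join(bot)
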