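"""The alignment Markov decision process.

At every decision step the agent sees a :class:`WindowState` — the next ``W``
symbols of each sequence from the current position, PAD-filled past either
end — and picks one of three actions: FORWARD consumes one base from both
sequences (emitting a match or mismatch column), INSERTION consumes one base
from the second sequence only (a gap in the first), DELETION consumes one base
from the first sequence only.  Rewards are the scoring-scheme values of the
emitted column, so the summed reward of any trajectory *is* the alignment
score of its columns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .simulate import encode_sequence

#: code points used in window symbol vectors
CODE_A, CODE_C, CODE_G, CODE_T, CODE_N, CODE_PAD = 0, 1, 2, 3, 4, 5
N_CHANNELS = 5  # one-hot over {A,C,G,T,PAD}; N encodes as all-zeros


class Action(enum.IntEnum):
    FORWARD = 0
    INSERTION = 1
    DELETION = 2


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/gap scores; also the per-column rewards."""

    score_match: int = 1
    score_mismatch: int = -1
    score_gap: int = -2

    def __post_init__(self) -> None:
        if not (self.score_match > 0 > self.score_gap):
            raise ValueError("require score_match > 0 > score_gap")
        if not self.score_match > self.score_mismatch:
            raise ValueError("require score_match > score_mismatch")

    def column_score(self, op: str) -> int:
        if op == "M":
            return self.score_match
        if op == "X":
            return self.score_mismatch
        if op in ("I", "D"):
            return self.score_gap
        raise ValueError(f"unknown column op {op!r}")


@dataclass(frozen=True)
class AlignmentPosition:
    """0-based cursor pair: ``x`` into S1, ``y`` into S2."""

    x: int
    y: int


@dataclass(frozen=True)
class AlignmentColumn:
    """One emitted alignment column.

    ``op`` is M (match), X (mismatch), I (gap in S1, consumes S2) or
    D (gap in S2, consumes S1).
    """

    op: str

    @property
    def consumes1(self) -> int:
        return 1 if self.op in ("M", "X", "D") else 0

    @property
    def consumes2(self) -> int:
        return 1 if self.op in ("M", "X", "I") else 0


@dataclass(frozen=True)
class WindowState:
    """The RL observation: two length-W symbol code vectors."""

    window1: np.ndarray  # uint8 codes, length W
    window2: np.ndarray

    @property
    def W(self) -> int:
        return len(self.window1)

    def encoded(self) -> np.ndarray:
        """Numeric encoding of shape (2, W, 5).

        Real bases are one-hot in channels 0-3, PAD is channel 4, and N is
        all-zeros so the network sees ambiguity as the absence of evidence.
        """
        out = np.zeros((2, self.W, N_CHANNELS), dtype=np.float32)
        for row, win in enumerate((self.window1, self.window2)):
            base = win < 4
            out[row, np.flatnonzero(base), win[base]] = 1.0
            pad = win == CODE_PAD
            out[row, np.flatnonzero(pad), 4] = 1.0
        return out


def extract_state(s1: str | np.ndarray, s2: str | np.ndarray,
                  pos: AlignmentPosition, W: int) -> WindowState:
    """Window the next W symbols of each sequence at ``pos``, PAD past ends."""
    if W < 1:
        raise ValueError("window size W must be >= 1")
    c1 = encode_sequence(s1) if isinstance(s1, str) else s1
    c2 = encode_sequence(s2) if isinstance(s2, str) else s2
    w1 = np.full(W, CODE_PAD, dtype=np.uint8)
    w2 = np.full(W, CODE_PAD, dtype=np.uint8)
    n1 = min(W, len(c1) - pos.x)
    n2 = min(W, len(c2) - pos.y)
    if n1 > 0:
        w1[:n1] = c1[pos.x:pos.x + n1]
    if n2 > 0:
        w2[:n2] = c2[pos.y:pos.y + n2]
    return WindowState(w1, w2)


def episode_terminal(s1: Sequence, s2: Sequence, pos: AlignmentPosition) -> bool:
    """True once either cursor has consumed its whole sequence."""
    return pos.x >= len(s1) or pos.y >= len(s2)


def apply_action(s1: str, s2: str, pos: AlignmentPosition, action: Action,
                 scoring: ScoringScheme
                 ) -> Tuple[AlignmentPosition, int, AlignmentColumn]:
    """Advance the cursors by one action; reward = score of the new column.

    N bases act as universal mismatches.  Consuming past a sequence end is a
    caller error here; drive termination with :func:`episode_terminal`.
    """
    x, y = pos.x, pos.y
    if action == Action.FORWARD:
        if x >= len(s1) or y >= len(s2):
            raise IndexError("FORWARD past a sequence end")
        a, b = s1[x], s2[y]
        if a == b and a != "N":
            col = AlignmentColumn("M")
        else:
            col = AlignmentColumn("X")
        new = AlignmentPosition(x + 1, y + 1)
    elif action == Action.INSERTION:
        if y >= len(s2):
            raise IndexError("INSERTION past the end of S2")
        col = AlignmentColumn("I")
        new = AlignmentPosition(x, y + 1)
    elif action == Action.DELETION:
        if x >= len(s1):
            raise IndexError("DELETION past the end of S1")
        col = AlignmentColumn("D")
        new = AlignmentPosition(x + 1, y)
    else:  # pragma: no cover
        raise ValueError(f"unknown action {action!r}")
    return new, scoring.column_score(col.op), col


def score_columns(columns: List[AlignmentColumn], scoring: ScoringScheme) -> int:
    """Alignment score recomputed from emitted columns."""
    return sum(scoring.column_score(c.op) for c in columns)
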