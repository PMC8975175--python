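"""Synthetic DNA evolution: random sequences and mutated copies.

The mutation model is the one the training environment assumes: independent
single-base substitutions at rate ``p_snp`` and indel events initiating at rate
``p_indel`` per source position, with indel lengths following a Zipfian
(power-law) distribution truncated at ``max_indel``.  Every mutated copy comes
with an event log that replays exactly from the source sequence, so tests and
downstream consumers can recover ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate("ACGTN")}


class FastaError(ValueError):
    """Raised for FASTA records that violate the DNA alphabet contract."""


@dataclass(frozen=True)
class MutationModel:
    """SNP + Zipfian-indel evolution model.

    Parameters
    ----------
    p_snp : float
        Per-base substitution probability.  Substitutions always change the
        base (uniform over the other three), so this is the realized
        divergence rate.
    p_indel : float
        Per-base indel-initiation probability; insertion vs deletion is an
        equiprobable coin flip (``p_insertion`` below).
    zipf_s : float
        Exponent of the Zipfian length distribution, ``P(l) ∝ 1/l**s``.
    max_indel : int
        Truncation point of the length distribution.
    """

    p_snp: float = 0.0
    p_indel: float = 0.0
    zipf_s: float = 1.5
    max_indel: int = 1
    p_insertion: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_snp <= 1.0:
            raise ValueError(f"p_snp must be in [0,1], got {self.p_snp}")
        if not 0.0 <= self.p_indel <= 1.0:
            raise ValueError(f"p_indel must be in [0,1], got {self.p_indel}")
        if self.zipf_s <= 1.0:
            raise ValueError(f"zipf_s must be > 1, got {self.zipf_s}")
        if int(self.max_indel) < 1:
            raise ValueError(f"max_indel must be >= 1, got {self.max_indel}")
        if not 0.0 <= self.p_insertion <= 1.0:
            raise ValueError("p_insertion must be in [0,1]")


@dataclass(frozen=True)
class MutationEvent:
    """One ground-truth edit: ``substitution``, ``insertion`` or ``deletion``.

    ``position`` is the 0-based index on the *source* sequence.  Insertions are
    placed immediately before ``position``; deletions remove
    ``position .. position+length-1`` (clipped at the end).  ``payload`` holds
    the inserted bases, or the replacement base for a substitution.
    """

    kind: str
    position: int
    length: int = 1
    payload: str = ""


@dataclass
class EnvironmentPair:
    """Training-environment quadruple: one pair to train on, one held out."""

    s1: str
    s2: str
    s1_eval: str
    s2_eval: str
    events: List[MutationEvent] = field(default_factory=list)
    events_eval: List[MutationEvent] = field(default_factory=list)


def generate_random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform i.i.d. DNA sequence of exactly ``length`` bases."""
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    if length == 0:
        return ""
    codes = rng.integers(0, 4, size=length)
    return "".join(ALPHABET[c] for c in codes)


def zipf_pmf(s: float, max_indel: int | None) -> np.ndarray:
    """Normalized truncated-Zipf probabilities on 1..max_indel.

    ``max_indel=None`` gives the untruncated distribution's first 10**6 terms
    plus an integral tail correction folded into the normalizer — used only by
    tests probing the closed-form limit.
    """
    if s <= 1.0:
        raise ValueError("zipf exponent must exceed 1")
    if max_indel is None:
        from scipy.special import zeta

        ls = np.arange(1, 10**6 + 1, dtype=float)
        return (1.0 / ls**s) / zeta(s)
    ls = np.arange(1, int(max_indel) + 1, dtype=float)
    w = 1.0 / ls**s
    return w / w.sum()


def sample_indel_length(model: MutationModel, rng: np.random.Generator,
                        size: int | None = None) -> int | np.ndarray:
    """Draw indel length(s) l ∝ 1/l**s truncated to 1..max_indel."""
    pmf = zipf_pmf(model.zipf_s, model.max_indel)
    draw = rng.choice(np.arange(1, model.max_indel + 1), size=size, p=pmf)
    if size is None:
        return int(draw)
    return draw


def _substitute(base: str, rng: np.random.Generator) -> str:
    others = [b for b in ALPHABET if b != base]
    return others[int(rng.integers(0, 3))]


def draw_mutation_events(seq: str, model: MutationModel,
                         rng: np.random.Generator) -> List[MutationEvent]:
    """Draw indel events position-wise, then substitutions for surviving bases.

    Indel initiation is an independent Bernoulli(p_indel) per source position,
    so the event count is exactly Binomial(len(seq), p_indel).  Substitution
    decisions are made only for bases the indels leave standing, so the
    substituted fraction of emitted source bases is exactly Bernoulli(p_snp).
    """
    L = len(seq)
    events: List[MutationEvent] = []
    if L == 0:
        return events
    indel_hits = rng.random(L) < model.p_indel
    for pos in np.flatnonzero(indel_hits):
        pos = int(pos)
        length = int(sample_indel_length(model, rng))
        if rng.random() < model.p_insertion:
            payload = generate_random_sequence(length, rng)
            events.append(MutationEvent("insertion", pos, length, payload))
        else:
            events.append(MutationEvent("deletion", pos, length))
    # substitutions for source positions that survive the deletions
    del_until = 0
    ev_by_pos = {e.position: e for e in events}
    for i in range(L):
        e = ev_by_pos.get(i)
        if e is not None and e.kind == "deletion" and i >= del_until:
            del_until = max(del_until, i + e.length)
        if i < del_until:
            continue
        if rng.random() < model.p_snp:
            events.append(MutationEvent("substitution", i, 1,
                                        _substitute(seq[i], rng)))
    events.sort(key=lambda e: (e.position, e.kind != "insertion"))
    return events


def replay_events(seq: str, events: Iterable[MutationEvent]) -> str:
    """Apply an event log to ``seq``; the inverse witness for :func:`mutate`."""
    ins: dict[int, str] = {}
    dele: dict[int, int] = {}
    sub: dict[int, str] = {}
    for e in events:
        if e.kind == "insertion":
            ins[e.position] = ins.get(e.position, "") + e.payload
        elif e.kind == "deletion":
            dele[e.position] = max(dele.get(e.position, 0), e.length)
        elif e.kind == "substitution":
            sub[e.position] = e.payload
        else:  # pragma: no cover - guarded by MutationEvent construction
            raise ValueError(f"unknown event kind {e.kind!r}")
    out: List[str] = []
    del_until = 0
    for i in range(len(seq)):
        if i in ins:
            out.append(ins[i])
        if i in dele and i >= del_until:
            del_until = max(del_until, i + dele[i])
        if i < del_until:
            continue
        out.append(sub.get(i, seq[i]))
    # insertions logged at position len(seq) attach at the very end
    if len(seq) in ins:
        out.append(ins[len(seq)])
    return "".join(out)


def mutate(seq: str, model: MutationModel,
           rng: np.random.Generator) -> Tuple[str, List[MutationEvent]]:
    """Mutated copy of ``seq`` plus the exact event log that produced it."""
    if len(seq) == 0:
        raise ValueError("cannot mutate an empty sequence")
    events = draw_mutation_events(seq, model, rng)
    return replay_events(seq, events), events


def make_environment_pair(model: MutationModel, length: int,
                          rng: np.random.Generator) -> EnvironmentPair:
    """Two independent ancestor/descendant pairs from one environment.

    The first pair feeds inner-loop training; the second is held out for
    evaluation and never sees a gradient.
    """
    if length <= 0:
        raise ValueError(f"length must be > 0, got {length}")
    s1 = generate_random_sequence(length, rng)
    s2, events = mutate(s1, model, rng)
    s1e = generate_random_sequence(length, rng)
    s2e, events_eval = mutate(s1e, model, rng)
    return EnvironmentPair(s1, s2, s1e, s2e, events, events_eval)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string (A,C,G,T,N) to uint8 codes 0..4."""
    try:
        return np.fromiter((_BASE_TO_CODE[b] for b in seq), dtype=np.uint8,
                           count=len(seq))
    except KeyError as exc:  # pragma: no cover - callers validate first
        raise FastaError(f"illegal symbol {exc.args[0]!r}") from exc


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read a (multi-)FASTA file into ``(identifier, sequence)`` tuples.

    Lowercase input is uppercased; symbols outside {A,C,G,T,N} raise a
    :class:`FastaError` naming the offending record.
    """
    records: List[Tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FastaError(
                f"record {rec.id!r} contains non-DNA symbols {sorted(bad)}")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Sequence[Tuple[str, str]], path) -> None:
    """Write ``(identifier, sequence)`` tuples as FASTA."""
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path), "fasta")
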