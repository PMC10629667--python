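"""Approximate primer matching within terminal read windows.

The ONT direct-cDNA kit decorates each cDNA strand with two primers: primer 1
(oligo-dT side, first-strand synthesis) and primer 2 (strand-switch side,
second-strand synthesis).  Strand inference reduces to asking, for each read,
whether a primer (or its reverse complement) sits near one of the read's
ends.  The matcher is a Hamming-distance sliding scan over a terminal window
(default: first/last 100 bp, at most 2 mismatches on the 14-mer primers) —
substitutions only, no indels; 'N' in the read always counts as a mismatch.

`positional_profile` aggregates best-hit start coordinates across a library,
the classic diagnostic for where a primer is enriched relative to read ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal

import numpy as np

from .seqio import SeqRead, reverse_complement

__all__ = [
    "Criterion",
    "PrimerConfig",
    "PrimerHit",
    "PositionalProfile",
    "find_terminal_match",
    "positional_profile",
    "DEFAULT_P1",
    "DEFAULT_P2",
]

#: Kit primer sequences (first-strand primer and strand-switch primer).
DEFAULT_P1 = "GCTCTATCTTCTTT"
DEFAULT_P2 = "CTGATATTGCTGGG"


class Criterion(str, Enum):
    """The four terminal primer placements used for strand classification."""

    P1_HEAD = "P1_HEAD"  # primer 1 in the head window
    RC_P2_TAIL = "RC_P2_TAIL"  # reverse complement of primer 2 in the tail window
    P2_HEAD = "P2_HEAD"  # primer 2 in the head window
    RC_P1_TAIL = "RC_P1_TAIL"  # reverse complement of primer 1 in the tail window


#: The "3-criteria" default: primer 1, rc(primer 2) and primer 2; adding
#: RC_P1_TAIL gives the 4-criteria configuration.
DEFAULT_CRITERIA = frozenset(
    {Criterion.P1_HEAD, Criterion.RC_P2_TAIL, Criterion.P2_HEAD}
)
ALL_CRITERIA = frozenset(Criterion)


@dataclass(frozen=True)
class PrimerConfig:
    """Primer sequences and matching parameters.

    Defaults follow the standard direct-cDNA configuration: 100 bp terminal
    windows, 2 mismatches, 3 active criteria.  ``rc_p1``/``rc_p2`` are always
    derived, never stored.
    """

    p1: str = DEFAULT_P1
    p2: str = DEFAULT_P2
    window: int = 100
    max_mismatch: int = 2
    criteria: frozenset[Criterion] = DEFAULT_CRITERIA

    def __post_init__(self) -> None:
        for name, primer in (("p1", self.p1), ("p2", self.p2)):
            if not primer or set(primer) - set("ACGT"):
                raise ValueError(f"{name} must be non-empty over ACGT: {primer!r}")
        if self.window < max(len(self.p1), len(self.p2)):
            raise ValueError("window must be >= the longest primer")
        if self.max_mismatch >= min(len(self.p1), len(self.p2)):
            raise ValueError("max_mismatch must be < the shortest primer length")
        object.__setattr__(self, "criteria", frozenset(Criterion(c) for c in self.criteria))

    @property
    def rc_p1(self) -> str:
        return reverse_complement(self.p1)

    @property
    def rc_p2(self) -> str:
        return reverse_complement(self.p2)


@dataclass(frozen=True)
class PrimerHit:
    """Best approximate occurrence of a primer in a terminal window.

    ``offset`` is 0-based from the start of the searched window (head window
    starts at the read's first base; tail window at ``len(read) - window``).
    """

    offset: int
    mismatches: int
    criterion: Criterion | None = None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_terminal_match(
    sequence: str,
    pattern: str,
    end: Literal["head", "tail"] = "head",
    window: int = 100,
    max_mismatch: int = 2,
) -> PrimerHit | None:
    """Hamming sliding-window scan of ``pattern`` against a terminal window.

    Returns the hit with the fewest mismatches (ties broken by smallest
    offset), or ``None`` if no offset achieves ``<= max_mismatch``.  Reads
    shorter than the window are searched over their full length; reads
    shorter than the pattern yield ``None``.
    """
    sequence = sequence.upper()
    w = min(window, len(sequence))
    segment = sequence[:w] if end == "head" else sequence[len(sequence) - w :]
    if len(pattern) > len(segment):
        return None
    seg = _encode(segment)
    pat = _encode(pattern.upper())
    windows = np.lib.stride_tricks.sliding_window_view(seg, len(pat))
    mismatches = (windows != pat).sum(axis=1)
    best = int(np.argmin(mismatches))  # argmin ties resolve to smallest offset
    if int(mismatches[best]) > max_mismatch:
        return None
    return PrimerHit(offset=best, mismatches=int(mismatches[best]))


@dataclass
class PositionalProfile:
    """Per-coordinate counts of best-hit start positions for one pattern.

    ``head``/``tail`` are count vectors of length ``max_pos`` anchored at the
    respective read end; ``prevalence`` is the fraction of reads with a hit at
    either end.
    """

    head: np.ndarray
    tail: np.ndarray
    n_reads: int
    prevalence: float


def positional_profile(
    reads: Iterable[SeqRead],
    pattern: str,
    max_mismatch: int = 2,
    max_pos: int = 100,
) -> PositionalProfile:
    """Profile where ``pattern`` lands relative to read ends across a library."""
    if max_pos < len(pattern):
        raise ValueError("max_pos must be >= pattern length")
    head = np.zeros(max_pos, dtype=np.int64)
    tail = np.zeros(max_pos, dtype=np.int64)
    n = 0
    with_hit = 0
    for read in reads:
        n += 1
        any_hit = False
        for end, counts in (("head", head), ("tail", tail)):
            hit = find_terminal_match(
                read.sequence, pattern, end=end, window=max_pos, max_mismatch=max_mismatch
            )
            if hit is not None:
                counts[hit.offset] += 1
                any_hit = True
        if any_hit:
            with_hit += 1
    return PositionalProfile(
        head=head,
        tail=tail,
        n_reads=n,
        prevalence=(with_hit / n) if n else 0.0,
    )
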