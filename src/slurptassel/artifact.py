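"""Palindrome-artifact detection and supplementary-alignment filtering.

During cDNA synthesis the reverse transcriptase can switch template onto its
own nascent strand and continue copying, producing a read whose second half
is the reverse complement of its first half.  Such reads carry primer 1 at
the head *and* rc(primer 1) at the tail — a configuration impossible under
normal library chemistry — and map twice to the same locus in opposite
directions, the second alignment flagged supplementary (SAM flag 2048),
doubling apparent coverage.

Detection has two stages:

1. A terminal primer-pair screen: primer 1 within the head window and its
   reverse complement within the tail window.  The screen uses edit distance
   (edlib, infix mode) with the same mismatch budget as the stranding scan:
   ONT indels routinely corrupt a 14-mer primer copy, and a substitution-only
   scan would silently miss a large fraction of true palindromes.
2. A self-folding test: the first half of the read is globally aligned
   (match +1, mismatch -1, gap -2) against the reverse complement of the
   second half.  Aligned matching columns become nested base pairs, written
   in dot-bracket notation; the paired-base fraction of a true palindrome
   approaches 1, while unstructured reads stay far below.  The running
   +1/-1/0 sum over the structure gives the "mountain" profile, rescaled to
   a fixed number of bins for meta-read plots.

A read is called an artifact when both stages agree: terminal primer pair
present and paired fraction at or above the threshold (default 0.7).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
from numba import njit

from .primer_scan import PrimerConfig
from .seqio import SeqRead, reverse_complement

__all__ = [
    "DotBracket",
    "PalindromeReport",
    "SamRecord",
    "detect_terminal_primer_pair",
    "self_fold",
    "mountain_profile",
    "assess_palindrome",
    "estimate_prevalence",
    "filter_supplementary",
    "coverage_profile",
    "read_sam",
    "write_sam",
    "SUPPLEMENTARY_FLAG",
    "DEFAULT_PAIRED_FRACTION_THRESHOLD",
]

SUPPLEMENTARY_FLAG = 2048
DEFAULT_PAIRED_FRACTION_THRESHOLD = 0.7

# ---------------------------------------------------------------------------
# dot-bracket structures


@dataclass(frozen=True)
class DotBracket:
    """A balanced, nested pairing structure over a read.

    '(' marks a base paired downstream, ')' paired upstream, '.' unpaired.
    Construction validates balance and the prefix property (no ')' before
    its '('); nesting is guaranteed by the monotone alignment that produces
    these structures.
    """

    structure: str

    def __post_init__(self) -> None:
        depth = 0
        for i, ch in enumerate(self.structure):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError(f"unbalanced ')' at position {i}")
            elif ch != ".":
                raise ValueError(f"invalid character {ch!r} at position {i}")
        if depth != 0:
            raise ValueError(f"unbalanced structure: {depth} unclosed '('")

    def __len__(self) -> int:
        return len(self.structure)

    @property
    def paired_fraction(self) -> float:
        if not self.structure:
            return 0.0
        paired = sum(1 for ch in self.structure if ch != ".")
        return paired / len(self.structure)


@dataclass
class PalindromeReport:
    """Per-read artifact evidence."""

    read_id: str
    terminal_primer_pair: bool
    paired_fraction: float
    mountain_scaled: np.ndarray
    is_artifact: bool


# ---------------------------------------------------------------------------
# terminal primer-pair screen


def _edit_within(pattern: str, segment: str, budget: int) -> bool:
    if not segment:
        return False
    res = edlib.align(pattern, segment, mode="HW", task="distance", k=budget)
    return res["editDistance"] != -1


def detect_terminal_primer_pair(read: SeqRead, config: PrimerConfig | None = None) -> bool:
    """True iff primer 1 occurs in the head window AND rc(primer 1) in the
    tail window, each within ``config.max_mismatch`` edits."""
    if config is None:
        config = PrimerConfig()
    seq = read.sequence
    if len(seq) < len(config.p1):
        return False
    w = min(config.window, len(seq))
    return _edit_within(config.p1, seq[:w], config.max_mismatch) and _edit_within(
        config.rc_p1, seq[len(seq) - w :], config.max_mismatch
    )


# ---------------------------------------------------------------------------
# self-folding: global alignment of first half vs rc(second half)

_BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODES[ord(_b)] = _i


def _encode_bases(seq: str) -> np.ndarray:
    return _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _nw_matched_columns(a, b, match, mismatch, gap):  # pragma: no cover - jitted
    """Needleman-Wunsch with linear gaps.

    Returns (optimal score, matched column pairs (i, j)).  Code 4 ('N')
    never matches.  Tie-break preference: diagonal, then up (gap in b),
    then left (gap in a) — deterministic.
    """
    m = a.size
    n = b.size
    dp = np.empty((m + 1, n + 1), dtype=np.int32)
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    dp[0, 0] = 0
    for i in range(1, m + 1):
        dp[i, 0] = i * gap
        ptr[i, 0] = 1
    for j in range(1, n + 1):
        dp[0, j] = j * gap
        ptr[0, j] = 2
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            best = dp[i - 1, j - 1] + s
            p = 0
            up = dp[i - 1, j] + gap
            if up > best:
                best = up
                p = 1
            left = dp[i, j - 1] + gap
            if left > best:
                best = left
                p = 2
            dp[i, j] = best
            ptr[i, j] = p
    out = np.empty((min(m, n), 2), dtype=np.int64)
    k = 0
    i = m
    j = n
    while i > 0 or j > 0:
        p = ptr[i, j]
        if i > 0 and j > 0 and p == 0:
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                out[k, 0] = i - 1
                out[k, 1] = j - 1
                k += 1
            i -= 1
            j -= 1
        elif i > 0 and (p == 1 or j == 0):
            i -= 1
        else:
            j -= 1
    return dp[m, n], out[:k]


def self_fold(
    sequence: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> DotBracket:
    """Fold a read against itself to expose palindromic structure.

    The first half ``s[:n//2]`` is globally aligned against the reverse
    complement of the second half; every aligned matching column (i, j)
    pairs base i with base n-1-j, emitting '(' and ')'.  Monotonicity of the
    alignment makes the pairing nested by construction; odd-length reads
    leave the middle base unpaired.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < 2:
        raise ValueError("self_fold requires a sequence of length >= 2")
    h = n // 2
    a = _encode_bases(sequence[:h])
    b = _encode_bases(reverse_complement(sequence[h:]))
    _score, pairs = _nw_matched_columns(a, b, match, mismatch, gap)
    chars = ["."] * n
    for i, j in pairs:
        k = n - 1 - int(j)
        if int(i) < k:
            chars[int(i)] = "("
            chars[k] = ")"
    return DotBracket("".join(chars))


def mountain_profile(structure: DotBracket | str, bins: int = 100) -> np.ndarray:
    """Running pairing depth, rescaled to a fixed-length meta-read.

    Per-base score: +1 for '(', -1 for ')', 0 for '.'; the cumulative sum is
    the mountain (0 at both termini for a balanced structure, peak where
    pairing is deepest).  The mountain is averaged within ``bins``
    equal-width position bins; structures shorter than ``bins`` are linearly
    interpolated instead.
    """
    s = structure.structure if isinstance(structure, DotBracket) else structure
    if bins < 1:
        raise ValueError("bins must be >= 1")
    L = len(s)
    if L == 0:
        return np.zeros(bins)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    scores = np.zeros(L, dtype=np.int64)
    scores[arr == ord("(")] = 1
    scores[arr == ord(")")] = -1
    mountain = np.cumsum(scores)
    if L < bins:
        return np.interp(np.linspace(0, L - 1, bins), np.arange(L), mountain)
    edges = (np.arange(bins) * L) // bins
    sums = np.add.reduceat(mountain, edges)
    counts = np.diff(np.append(edges, L))
    return sums / counts


def assess_palindrome(
    read: SeqRead,
    config: PrimerConfig | None = None,
    threshold: float = DEFAULT_PAIRED_FRACTION_THRESHOLD,
    bins: int = 100,
) -> PalindromeReport:
    """Full artifact assessment of one read.

    ``is_artifact`` requires both the terminal primer pair and a paired
    fraction at or above ``threshold``.
    """
    if config is None:
        config = PrimerConfig()
    primer_pair = detect_terminal_primer_pair(read, config)
    if len(read.sequence) >= 2:
        structure = self_fold(read.sequence)
        pf = structure.paired_fraction
        mountain = mountain_profile(structure, bins=bins)
    else:
        pf = 0.0
        mountain = np.zeros(bins)
    return PalindromeReport(
        read_id=read.id,
        terminal_primer_pair=primer_pair,
        paired_fraction=pf,
        mountain_scaled=mountain,
        is_artifact=primer_pair and pf >= threshold,
    )


def estimate_prevalence(
    reads: Iterable[SeqRead],
    config: PrimerConfig | None = None,
    threshold: float = DEFAULT_PAIRED_FRACTION_THRESHOLD,
) -> tuple[float, list[PalindromeReport]]:
    """Assess every read; return (artifact fraction, per-read reports)."""
    reports = [assess_palindrome(r, config, threshold) for r in reads]
    if not reports:
        return 0.0, reports
    return sum(r.is_artifact for r in reports) / len(reports), reports


# ---------------------------------------------------------------------------
# SAM records: supplementary filtering and coverage


@dataclass
class SamRecord:
    """Minimal alignment record; ``pos`` is 1-based as on disk."""

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    raw: str | None = None

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & SUPPLEMENTARY_FLAG)


def read_sam(path: str | Path) -> tuple[str, list[SamRecord]]:
    """Read a text SAM file via pysam; returns (header text, records)."""
    import pysam

    records: list[SamRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        header = str(sam.header)
        for rec in sam:
            records.append(
                SamRecord(
                    qname=rec.query_name or "*",
                    flag=rec.flag,
                    rname=rec.reference_name if rec.reference_name is not None else "*",
                    pos=(rec.reference_start + 1) if rec.reference_start is not None and rec.reference_start >= 0 else 0,
                    mapq=rec.mapping_quality,
                    cigar=rec.cigarstring or "*",
                    raw=rec.to_string(),
                )
            )
    return header, records


def write_sam(path: str | Path, header: str, records: Iterable[SamRecord]) -> None:
    """Write records back out, passing the header through unchanged."""
    with open(path, "w") as handle:
        if header and not header.endswith("\n"):
            header += "\n"
        handle.write(header)
        for rec in records:
            if rec.raw is not None:
                handle.write(rec.raw.rstrip("\n") + "\n")
            else:
                handle.write(
                    f"{rec.qname}\t{rec.flag}\t{rec.rname}\t{rec.pos}\t"
                    f"{rec.mapq}\t{rec.cigar}\t*\t0\t0\t*\t*\n"
                )


def filter_supplementary(records: Sequence[SamRecord]) -> list[SamRecord]:
    """Drop records with SAM flag bit 2048 set, preserving order.

    This is the record-level equivalent of ``samtools view -F 2048`` and
    removes the duplicate half of palindromic-read alignments.
    """
    out: list[SamRecord] = []
    for i, rec in enumerate(records):
        if not isinstance(rec.flag, int) or rec.flag < 0:
            raise ValueError(f"record {i} ({rec.qname!r}): unparseable flag {rec.flag!r}")
        if not rec.flag & SUPPLEMENTARY_FLAG:
            out.append(rec)
    return out


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def coverage_profile(
    records: Iterable[SamRecord], chrom: str, start: int, end: int
) -> np.ndarray:
    """Per-base depth over a 1-based inclusive reference interval.

    M/=/X and D blocks add depth; N (intron) blocks and clips do not.
    Unmapped records (flag 0x4 or CIGAR '*') contribute nothing.
    """
    if end < start:
        raise ValueError("end must be >= start")
    depth = np.zeros(end - start + 1, dtype=np.int64)
    for rec in records:
        if rec.rname != chrom or rec.cigar == "*" or rec.flag & 0x4:
            continue
        consumed = sum(len(m.group(0)) for m in _CIGAR_RE.finditer(rec.cigar))
        if consumed != len(rec.cigar):
            raise ValueError(f"record {rec.qname!r}: invalid CIGAR {rec.cigar!r}")
        ref = rec.pos  # 1-based walking position
        for m in _CIGAR_RE.finditer(rec.cigar):
            length, op = int(m.group(1)), m.group(2)
            if op in "M=XD":
                lo = max(ref, start)
                hi = min(ref + length - 1, end)
                if lo <= hi:
                    depth[lo - start : hi - start + 1] += 1
                ref += length
            elif op == "N":
                ref += length
            # I, S, H, P consume no reference
    return depth
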