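"""FASTQ/FASTA input-output and basic sequence primitives.

Long-read cDNA libraries arrive as 4-line FASTQ (optionally gzipped).  This
module provides the read container used throughout the package, exact
round-trip FASTQ I/O, FASTA access for reference/transcript sequences, and
the two primitives the stranding pipeline is built from: reverse
complementation and first-wins deduplication by read id.

Sequences are defined over the 5-letter alphabet {A, C, G, T, N}; lowercase
input is uppercased on ingest and anything else is rejected, because primer
matching downstream is defined on that alphabet.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "SeqRead",
    "reverse_complement",
    "reverse_complement_read",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "dedup_by_id",
    "DEFAULT_FILL_QUALITY",
]

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Quality character used when writing reads that carry no qualities.
DEFAULT_FILL_QUALITY = "I"

#: Tag toggled by :func:`reverse_complement_read` so downstream evaluation
#: can recover each read's final orientation relative to how it was presented.
ORIENTATION_FLIPPED_TAG = "orientation_flipped"


class FastqFormatError(ValueError):
    """Malformed FASTQ input; the message names the offending line number."""


@dataclass
class SeqRead:
    """A single long read.

    Parameters
    ----------
    id:
        Read identifier, unique within a library.
    sequence:
        DNA over {A, C, G, T, N}; lowercase is uppercased on construction.
    qualities:
        Optional Phred string, same length as ``sequence``.
    tags:
        Free-form string metadata (e.g. simulator truth: source transcript,
        presented orientation, artifact flag).
    """

    id: str
    sequence: str
    qualities: str | None = None
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        invalid = set(self.sequence) - VALID_BASES
        if invalid:
            raise ValueError(
                f"read {self.id!r}: invalid characters in sequence: "
                f"{sorted(invalid)!r}"
            )
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over {A, C, G, T, N}; N maps to N."""
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def reverse_complement_read(read: SeqRead) -> SeqRead:
    """Return the read re-oriented to the opposite strand.

    The sequence is reverse complemented, qualities are reversed, the id is
    preserved, and the ``orientation_flipped`` tag is toggled so truth-based
    evaluation can track the net number of flips applied.
    """
    tags = dict(read.tags)
    flipped = tags.get(ORIENTATION_FLIPPED_TAG, "0")
    tags[ORIENTATION_FLIPPED_TAG] = "0" if flipped == "1" else "1"
    return SeqRead(
        id=read.id,
        sequence=reverse_complement(read.sequence),
        qualities=None if read.qualities is None else read.qualities[::-1],
        tags=tags,
    )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> list[SeqRead]:
    """Parse a 4-line FASTQ file (optionally gzipped) into reads.

    Order is preserved; the id is the header token before the first
    whitespace.  Malformed records raise :class:`FastqFormatError` naming the
    line number.
    """
    reads: list[SeqRead] = []
    with _open_text(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if header == "":
                break
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"line {lineno}: expected '@' header, got {header[:30]!r}"
                )
            seq = handle.readline()
            sep = handle.readline()
            qual = handle.readline()
            if qual == "":
                raise FastqFormatError(
                    f"line {lineno}: truncated record for {header[:30]!r}"
                )
            seq = seq.rstrip("\n")
            sep = sep.rstrip("\n")
            qual = qual.rstrip("\n")
            if not sep.startswith("+"):
                raise FastqFormatError(
                    f"line {lineno + 2}: expected '+' separator, got {sep[:30]!r}"
                )
            if len(qual) != len(seq):
                raise FastqFormatError(
                    f"line {lineno + 3}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            reads.append(SeqRead(id=read_id, sequence=seq, qualities=qual))
            lineno += 3
    return reads


def write_fastq(
    reads: Iterable[SeqRead],
    path: str | Path,
    fill_quality: str = DEFAULT_FILL_QUALITY,
) -> None:
    """Write canonical 4-line FASTQ records in input order.

    Reads lacking qualities are written with ``fill_quality`` repeated over
    the sequence length (a constant, for determinism).
    """
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = read.qualities
            if qual is None:
                qual = fill_quality * len(read.sequence)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA (wrapped or unwrapped) into an ordered id -> sequence map."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write FASTA wrapped at ``width`` columns."""
    with _open_text(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def dedup_by_id(reads: Iterable[SeqRead]) -> list[SeqRead]:
    """Keep the first occurrence of each read id, preserving order.

    First-wins survivorship mirrors the branch order of the stranding
    pipeline, where a read collected by an earlier criterion is not revisited
    by a later one.
    """
    seen: set[str] = set()
    out: list[SeqRead] = []
    for read in reads:
        if read.id not in seen:
            seen.add(read.id)
            out.append(read)
    return out
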