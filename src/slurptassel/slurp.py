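"""SLURP: Stranding Long Unstranded Reads using Primers.

ONT cDNA sequencing presents either cDNA strand to the pore, so reads arrive
in a ~50/50 mix of orientations with no strand-of-origin record.  SLURP
recovers it from the kit primers left at read termini.  In the convention
used throughout this package, a read presenting the *second* (sense) strand
carries primer 1 at its head and the reverse complement of primer 2 at its
tail; a read presenting the *first* (antisense) strand is the reverse
complement of that, i.e. primer 2 at its head.

Classification evaluates the enabled criteria in a fixed precedence order:

1. ``P1_HEAD``    — primer 1 in the head window        -> KEEP
2. ``RC_P2_TAIL`` — rc(primer 2) in the tail window    -> KEEP
3. ``P2_HEAD``    — primer 2 in the head window        -> REVCOMP
4. ``RC_P1_TAIL`` — rc(primer 1) in the tail window    -> REVCOMP
   (only in the 4-criteria configuration)

The first satisfied criterion decides; reads satisfying criteria of both
orientation classes are flagged as conflicts but still resolved by
precedence.  Reads matching nothing are unstranded and dropped.  The default
output is a uniformly oriented second-strand library; a first-strand library
is its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .primer_scan import Criterion, PrimerConfig, PrimerHit, find_terminal_match
from .seqio import SeqRead, dedup_by_id, reverse_complement_read

__all__ = [
    "StrandDecision",
    "StrandingReport",
    "RestrandCheck",
    "classify_read",
    "strand_library",
    "restrand_check",
    "CRITERION_PRECEDENCE",
    "KEEP_CRITERIA",
    "REVCOMP_CRITERIA",
]

#: Branch order of the stranding pipeline; decides conflicts deterministically.
CRITERION_PRECEDENCE: tuple[Criterion, ...] = (
    Criterion.P1_HEAD,
    Criterion.RC_P2_TAIL,
    Criterion.P2_HEAD,
    Criterion.RC_P1_TAIL,
)

KEEP_CRITERIA = frozenset({Criterion.P1_HEAD, Criterion.RC_P2_TAIL})
REVCOMP_CRITERIA = frozenset({Criterion.P2_HEAD, Criterion.RC_P1_TAIL})


@dataclass(frozen=True)
class StrandDecision:
    """Outcome of classifying one read.

    ``conflict`` is true when criteria of both orientation classes matched;
    the label still follows precedence.
    """

    label: Literal["KEEP", "REVCOMP", "UNSTRANDED"]
    matched_criterion: Criterion | None
    conflict: bool = False


@dataclass
class StrandingReport:
    """Library-level stranding statistics."""

    total_reads: int = 0
    criterion_counts: dict[Criterion, int] = field(default_factory=dict)
    stranded_count: int = 0
    stranding_rate: float = 0.0
    conflict_count: int = 0
    prevalence_p1: float = 0.0
    prevalence_p2: float = 0.0


@dataclass(frozen=True)
class RestrandCheck:
    """Fraction of an already-stranded library re-classified as KEEP."""

    fraction_keep: float
    n_reads: int


def _criterion_target(criterion: Criterion, config: PrimerConfig) -> tuple[str, str]:
    """(pattern, end) searched by a criterion."""
    return {
        Criterion.P1_HEAD: (config.p1, "head"),
        Criterion.RC_P2_TAIL: (config.rc_p2, "tail"),
        Criterion.P2_HEAD: (config.p2, "head"),
        Criterion.RC_P1_TAIL: (config.rc_p1, "tail"),
    }[criterion]


def _criterion_hit(read: SeqRead, criterion: Criterion, config: PrimerConfig) -> PrimerHit | None:
    pattern, end = _criterion_target(criterion, config)
    hit = find_terminal_match(
        read.sequence, pattern, end=end, window=config.window,
        max_mismatch=config.max_mismatch,
    )
    if hit is None:
        return None
    return PrimerHit(offset=hit.offset, mismatches=hit.mismatches, criterion=criterion)


def classify_read(read: SeqRead, config: PrimerConfig) -> StrandDecision:
    """Decide a read's orientation from terminal primer evidence.

    All enabled criteria are evaluated (so conflicts can be counted); the
    first satisfied criterion in precedence order determines the label.
    """
    hits = {
        c: h
        for c in CRITERION_PRECEDENCE
        if c in config.criteria and (h := _criterion_hit(read, c, config)) is not None
    }
    if not hits:
        return StrandDecision(label="UNSTRANDED", matched_criterion=None)
    deciding = next(c for c in CRITERION_PRECEDENCE if c in hits)
    label = "KEEP" if deciding in KEEP_CRITERIA else "REVCOMP"
    conflict = bool(hits.keys() & KEEP_CRITERIA) and bool(hits.keys() & REVCOMP_CRITERIA)
    return StrandDecision(label=label, matched_criterion=deciding, conflict=conflict)


def strand_library(
    reads: Sequence[SeqRead],
    config: PrimerConfig | None = None,
    output_orientation: Literal["second_strand", "first_strand"] = "second_strand",
    exclude_ids: set[str] | None = None,
) -> tuple[list[SeqRead], StrandingReport]:
    """Strand a library: orient every classifiable read consistently.

    KEEP reads are emitted as-is, REVCOMP reads reverse-complemented,
    unstranded reads dropped; the result is deduplicated by id (first wins).
    ``output_orientation="first_strand"`` additionally reverse-complements
    every emitted read.  ``exclude_ids`` drops the named reads up-front
    (used by the CLI's --drop-artifacts).
    """
    if config is None:
        config = PrimerConfig()
    report = StrandingReport(criterion_counts={c: 0 for c in CRITERION_PRECEDENCE})
    emitted: list[SeqRead] = []
    for read in reads:
        report.total_reads += 1
        # Primer prevalence is tallied over all reads regardless of the
        # enabled criteria set (library-level diagnostic).
        if find_terminal_match(read.sequence, config.p1, "head",
                               config.window, config.max_mismatch):
            report.prevalence_p1 += 1
        if find_terminal_match(read.sequence, config.p2, "head",
                               config.window, config.max_mismatch):
            report.prevalence_p2 += 1
        if exclude_ids is not None and read.id in exclude_ids:
            continue
        decision = classify_read(read, config)
        if decision.label == "UNSTRANDED":
            continue
        report.criterion_counts[decision.matched_criterion] += 1
        if decision.conflict:
            report.conflict_count += 1
        emitted.append(
            read if decision.label == "KEEP" else reverse_complement_read(read)
        )
    emitted = dedup_by_id(emitted)
    if output_orientation == "first_strand":
        emitted = [reverse_complement_read(r) for r in emitted]
    report.stranded_count = len(emitted)
    if report.total_reads:
        report.stranding_rate = report.stranded_count / report.total_reads
        report.prevalence_p1 /= report.total_reads
        report.prevalence_p2 /= report.total_reads
    return emitted, report


def restrand_check(
    stranded: Iterable[SeqRead], config: PrimerConfig | None = None
) -> RestrandCheck:
    """Re-classify an already-stranded library and report the KEEP fraction.

    On a correctly stranded library every read that still carries primer
    evidence should classify as KEEP.  An empty input reports 1.0 with a
    zero read count.
    """
    if config is None:
        config = PrimerConfig()
    n = 0
    keep = 0
    for read in stranded:
        n += 1
        if classify_read(read, config).label == "KEEP":
            keep += 1
    return RestrandCheck(fraction_keep=(keep / n) if n else 1.0, n_reads=n)
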