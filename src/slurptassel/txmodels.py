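"""GTF transcript models and assembly-comparison machinery.

Transcripts are stranded exon chains.  On disk (GTF) coordinates are 1-based
inclusive; internally everything is 0-based half-open, and the conversion is
confined to :func:`parse_gtf` / :func:`write_gtf`.

Comparison follows the class-code vocabulary used for assembly benchmarking
(the gffcompare convention), restricted to the codes that matter for
strand-aware merging:

    '='  same strand, identical intron chain (mono-exon: reciprocal
         overlap >= 0.8)
    'c'  query contained in the reference (contiguous intron sub-chain,
         span within span; mono-exon query inside a reference exon)
    'k'  reference contained in the query (reverse of 'c')
    'j'  at least one shared intron, not any of the above
    'o'  same-strand exonic overlap only
    's'  exonic overlap with an opposite-strand reference only
    'i'  query span inside a reference intron, no exonic overlap
    'u'  intergenic

Precedence is '=' > 'c' > 'k' > 'j' > 'o' > 's' > 'i' > 'u'; ties within a
code go to the reference with the largest exonic overlap.  On top of class
codes the module derives transcript- and locus-level sensitivity/precision,
TSS/TTS end-proximity distributions, and the segmentation count used to
quantify how many gene models are fragments of a larger merged span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Exon",
    "Transcript",
    "ClassCode",
    "ComparisonSummary",
    "GtfParseError",
    "parse_gtf",
    "write_gtf",
    "exonic_overlap",
    "classify_against_reference",
    "compare_sets",
    "end_distances",
    "end_proximity_summary",
    "count_segmented",
    "consolidate_spans",
    "CODE_PRECEDENCE",
]

CODE_PRECEDENCE = ("=", "c", "k", "j", "o", "s", "i", "u")
_CODE_RANK = {c: i for i, c in enumerate(CODE_PRECEDENCE)}


class GtfParseError(ValueError):
    """Malformed GTF input; the message names the offending line number."""


@dataclass(frozen=True)
class Exon:
    """Internal 0-based half-open exon interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"exon start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """A stranded chain of non-overlapping exons on one chromosome."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id!r} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.id!r}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        for e in exons:
            if e.chrom != self.chrom or e.strand != self.strand:
                raise ValueError(
                    f"transcript {self.id!r}: exon on {e.chrom}/{e.strand} "
                    f"differs from transcript {self.chrom}/{self.strand}"
                )
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def tss(self) -> int:
        """Strand-respecting 5' end (half-open convention)."""
        return self.start if self.strand != "-" else self.end

    def tts(self) -> int:
        """Strand-respecting 3' end (half-open convention)."""
        return self.end if self.strand != "-" else self.start


@dataclass(frozen=True)
class ClassCode:
    """Relation of a query transcript to its closest reference."""

    code: str
    matched_ref: str | None

    def __post_init__(self) -> None:
        if (self.code == "u") != (self.matched_ref is None):
            raise ValueError("code 'u' iff matched_ref is None")


# ---------------------------------------------------------------------------
# GTF I/O


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            raise GtfParseError(f"line {lineno}: malformed attribute {part!r}")
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gtf(path: str | Path) -> list[Transcript]:
    """Parse exon features of a GTF file into transcripts.

    Exons are grouped by ``transcript_id`` (first-seen order preserved) and
    sorted; disk coordinates (1-based inclusive) become 0-based half-open.
    Non-exon features are ignored; ``cov``/``TPM`` and any other attributes
    present on exon lines are retained on the transcript.
    """
    groups: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr_text = fields
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr_text, lineno)
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon missing transcript_id")
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon missing gene_id")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            tid = attrs["transcript_id"]
            entry = groups.setdefault(
                tid,
                {"gene_id": attrs["gene_id"], "chrom": chrom, "strand": strand,
                 "exons": [], "attributes": {}, "lineno": lineno},
            )
            if entry["chrom"] != chrom or entry["strand"] != strand:
                raise GtfParseError(
                    f"line {lineno}: transcript {tid!r} has exons on mixed "
                    f"chrom/strand"
                )
            entry["exons"].append(Exon(chrom=chrom, start=start_i - 1, end=end_i, strand=strand))
            for key, value in attrs.items():
                if key not in ("gene_id", "transcript_id"):
                    entry["attributes"].setdefault(key, value)
    return [
        Transcript(
            id=tid,
            gene_id=entry["gene_id"],
            chrom=entry["chrom"],
            strand=entry["strand"],
            exons=tuple(entry["exons"]),
            attributes=entry["attributes"],
        )
        for tid, entry in groups.items()
    ]


def write_gtf(
    transcripts: Iterable[Transcript], path: str | Path, source: str = "slurptassel"
) -> None:
    """Write transcript + exon lines; coordinates converted back to 1-based.

    Attribute order is gene_id, transcript_id, then remaining attributes in
    insertion order.
    """
    with open(path, "w") as handle:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.id}";'
            for key, value in tx.attributes.items():
                attrs += f' {key} "{value}";'
            handle.write(
                f"{tx.chrom}\t{source}\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
                f"{tx.strand}\t.\t{attrs}\n"
            )
            for exon in tx.exons:
                handle.write(
                    f"{tx.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# class codes


def exonic_overlap(a: Transcript, b: Transcript) -> int:
    """Total overlapping exonic bases between two transcripts (any strand)."""
    if a.chrom != b.chrom:
        return 0
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start))
    return total


def _chain_contiguous_subchain(sub: tuple, sup: tuple) -> bool:
    """Is ``sub`` a contiguous slice of ``sup``?  (Both non-empty.)"""
    k = len(sub)
    if k == 0 or k > len(sup):
        return False
    return any(sup[i : i + k] == sub for i in range(len(sup) - k + 1))


def _span_in_intron(q: Transcript, r: Transcript) -> bool:
    return any(s <= q.start and q.end <= e for s, e in r.intron_chain)


def _mono_inside_exon(q: Transcript, r: Transcript) -> bool:
    qs, qe = q.start, q.end
    return any(e.start <= qs and qe <= e.end for e in r.exons)


def _pair_code(q: Transcript, r: Transcript, mono_overlap: float) -> str | None:
    """Best class code relating query ``q`` to one reference ``r``."""
    if q.chrom != r.chrom:
        return None
    ov = exonic_overlap(q, r)
    if q.strand == r.strand:
        q_multi, r_multi = q.is_multi_exon, r.is_multi_exon
        if q_multi and r_multi and q.intron_chain == r.intron_chain:
            return "="
        if not q_multi and not r_multi:
            if (
                ov >= mono_overlap * q.exonic_length
                and ov >= mono_overlap * r.exonic_length
            ):
                return "="
        # containment of the query ('c')
        if not q_multi:
            if _mono_inside_exon(q, r):
                return "c"
        elif r_multi and _chain_contiguous_subchain(q.intron_chain, r.intron_chain):
            if r.start <= q.start and q.end <= r.end:
                return "c"
        # containment of the reference ('k')
        if not r_multi:
            if _mono_inside_exon(r, q):
                return "k"
        elif q_multi and _chain_contiguous_subchain(r.intron_chain, q.intron_chain):
            if q.start <= r.start and r.end <= q.end:
                return "k"
        if set(q.intron_chain) & set(r.intron_chain):
            return "j"
        if ov > 0:
            return "o"
        if _span_in_intron(q, r):
            return "i"
        return None
    # opposite strand
    if ov > 0:
        return "s"
    if _span_in_intron(q, r):
        return "i"
    return None


def classify_against_reference(
    query: Transcript,
    reference: Iterable[Transcript],
    mono_overlap: float = 0.8,
) -> ClassCode:
    """Assign the query its best class code over all references.

    Precedence decides between references yielding different codes; ties
    within a code go to the largest exonic overlap (then reference id, for
    determinism).
    """
    best: tuple[int, int, str, str] | None = None  # (rank, -overlap, ref_id, code)
    for ref in reference:
        code = _pair_code(query, ref, mono_overlap)
        if code is None:
            continue
        key = (_CODE_RANK[code], -exonic_overlap(query, ref), ref.id, code)
        if best is None or key < best:
            best = key
    if best is None:
        return ClassCode(code="u", matched_ref=None)
    return ClassCode(code=best[3], matched_ref=best[2])


# ---------------------------------------------------------------------------
# set-level comparison


def _overlap_components(transcripts: Sequence[Transcript]) -> list[list[int]]:
    """Connected components of same-strand exonic overlap (index lists)."""
    parent = list(range(len(transcripts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    order = sorted(range(len(transcripts)), key=lambda i: (transcripts[i].chrom, transcripts[i].strand, transcripts[i].start))
    for a_pos, i in enumerate(order):
        ti = transcripts[i]
        for j in order[a_pos + 1 :]:
            tj = transcripts[j]
            if (tj.chrom, tj.strand) != (ti.chrom, ti.strand) or tj.start >= ti.end:
                break
            if exonic_overlap(ti, tj) > 0:
                union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(len(transcripts)):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


@dataclass
class ComparisonSummary:
    """Per-code counts plus transcript- and locus-level sensitivity/precision.

    Percentages are in [0, 100].  A zero denominator yields 0.0 and sets the
    corresponding ``*_undefined`` flag.
    """

    code_counts: dict[str, int]
    transcript_sensitivity: float
    transcript_precision: float
    locus_sensitivity: float
    locus_precision: float
    n_query: int
    n_reference: int
    per_query: list[tuple[str, str | None, str]]
    sensitivity_undefined: bool = False
    precision_undefined: bool = False


def compare_sets(
    query: Sequence[Transcript],
    reference: Sequence[Transcript],
    mono_overlap: float = 0.8,
) -> ComparisonSummary:
    """Benchmark a query assembly against a reference annotation.

    Transcript level: TP = reference transcripts matched '=' by >= 1 query
    (sensitivity) and queries coded '=' (precision).  Locus level: reference
    loci are connected components of same-strand exonic overlap; a locus is
    detected when >= 1 query overlaps it exonically on the same strand, and a
    query locus is matched when it overlaps any reference transcript.
    """
    codes = [classify_against_reference(q, reference, mono_overlap) for q in query]
    code_counts = {c: 0 for c in CODE_PRECEDENCE}
    for cc in codes:
        code_counts[cc.code] += 1
    matched_refs = {
        cc.matched_ref for q, cc in zip(query, codes) if cc.code == "="
    }
    n_q, n_r = len(query), len(reference)
    tx_sens = 100.0 * len(matched_refs) / n_r if n_r else 0.0
    tx_prec = 100.0 * code_counts["="] / n_q if n_q else 0.0

    def _locus_overlaps(locus: list[Transcript], others: Sequence[Transcript]) -> bool:
        return any(
            t.strand == o.strand and exonic_overlap(t, o) > 0
            for t in locus
            for o in others
        )

    ref_loci = [[reference[i] for i in comp] for comp in _overlap_components(reference)]
    query_loci = [[query[i] for i in comp] for comp in _overlap_components(query)]
    detected = sum(1 for locus in ref_loci if _locus_overlaps(locus, query))
    matched_q_loci = sum(1 for locus in query_loci if _locus_overlaps(locus, reference))
    locus_sens = 100.0 * detected / len(ref_loci) if ref_loci else 0.0
    locus_prec = 100.0 * matched_q_loci / len(query_loci) if query_loci else 0.0
    return ComparisonSummary(
        code_counts=code_counts,
        transcript_sensitivity=tx_sens,
        transcript_precision=tx_prec,
        locus_sensitivity=locus_sens,
        locus_precision=locus_prec,
        n_query=n_q,
        n_reference=n_r,
        per_query=[(q.id, cc.matched_ref, cc.code) for q, cc in zip(query, codes)],
        sensitivity_undefined=n_r == 0,
        precision_undefined=n_q == 0,
    )


# ---------------------------------------------------------------------------
# end proximity


def end_distances(
    query: Sequence[Transcript],
    reference: Sequence[Transcript],
    which: Literal["TSS", "TTS"] = "TSS",
) -> np.ndarray:
    """Signed distance from each query end to the nearest same-strand
    reference end of the same kind (TSS or TTS).

    The array aligns with ``query`` order; queries with no same-strand
    reference on their chromosome get NaN.
    """
    getter = Transcript.tss if which == "TSS" else Transcript.tts
    ref_ends: dict[tuple[str, str], np.ndarray] = {}
    for r in reference:
        ref_ends.setdefault((r.chrom, r.strand), []).append(getter(r))  # type: ignore[attr-defined]
    ref_ends = {k: np.sort(np.asarray(v)) for k, v in ref_ends.items()}
    out = np.full(len(query), np.nan)
    for i, q in enumerate(query):
        ends = ref_ends.get((q.chrom, q.strand))
        if ends is None:
            continue
        qe = getter(q)
        j = int(np.argmin(np.abs(ends - qe)))
        out[i] = qe - int(ends[j])
    return out


def end_proximity_summary(
    distances: np.ndarray, thresholds: Sequence[int] = (50, 100, 500, 1000)
) -> dict[int, float]:
    """Cumulative fraction of |distance| within each threshold (NaNs excluded)."""
    d = np.abs(distances[~np.isnan(distances)])
    if d.size == 0:
        return {t: 0.0 for t in thresholds}
    return {t: float(np.mean(d <= t)) for t in thresholds}


# ---------------------------------------------------------------------------
# segmentation


def consolidate_spans(transcripts: Sequence[Transcript]) -> list[Transcript]:
    """Strand-aware union of transcript spans into mono-exon span models.

    Overlapping spans on the same chromosome and strand merge into one
    interval — the gene-level consolidation used before segmentation
    counting.
    """
    by_key: dict[tuple[str, str], list[Transcript]] = {}
    for t in transcripts:
        by_key.setdefault((t.chrom, t.strand), []).append(t)
    out: list[Transcript] = []
    n = 0
    for (chrom, strand) in sorted(by_key):
        txs = sorted(by_key[(chrom, strand)], key=lambda t: t.start)
        cur_s, cur_e = txs[0].start, txs[0].end
        spans: list[tuple[int, int]] = []
        for t in txs[1:]:
            if t.start < cur_e:
                cur_e = max(cur_e, t.end)
            else:
                spans.append((cur_s, cur_e))
                cur_s, cur_e = t.start, t.end
        spans.append((cur_s, cur_e))
        for s, e in spans:
            n += 1
            out.append(
                Transcript(
                    id=f"span.{n}",
                    gene_id=f"span.{n}",
                    chrom=chrom,
                    strand=strand,
                    exons=(Exon(chrom=chrom, start=s, end=e, strand=strand),),
                )
            )
    return out


def count_segmented(
    original_genes: Sequence[Transcript], merged_spans: Sequence[Transcript]
) -> int:
    """Count original genes that share a merged span with another gene.

    A gene is "segmented" when a same-strand merged span it overlaps
    exonically also overlaps at least one other original gene — i.e. the
    merged annotation reveals that several gene models are pieces of one
    transcription unit.
    """
    segmented: set[str] = set()
    for span in merged_spans:
        hits = [
            g
            for g in original_genes
            if g.strand == span.strand and exonic_overlap(g, span) > 0
        ]
        if len(hits) >= 2:
            segmented.update(g.id for g in hits)
    return len(segmented)
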