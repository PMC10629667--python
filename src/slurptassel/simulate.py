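"""Synthetic ONT direct-cDNA data with ground truth.

The generator emulates the study design this package's methods are built
for: a random genome with ~200 genes (cheRNA-like: mono-exonic genes are
long, multi-exon genes have 2-8 short exons), a 92-transcript mono-exonic
spike-in ladder at 2-fold concentration steps, and a long-read cDNA library
with kit primer decoration on both strands, ~50/50 strand presentation,
3'-anchored truncation, i.i.d. substitution/insertion/deletion errors and a
configurable rate of palindromic RT template-switch artifacts.  Two derived
assembly fixtures mimic the platforms being merged: a "short-read-like" GTF
(fragmented models with trimmed ends) and a "long-read-like" GTF
(5'-truncated models, a fraction on the wrong strand).

Strand convention (a constant of the simulator, not a claim about kit
biochemistry): the *second* strand is sense to the source transcript and is
rendered as ``p1 + sense + polyA + rc(p2)``; the first strand is its
reverse complement.  An artifact read is a p1-headed rendering followed by
its own reverse complement, so it carries p1 at the head and rc(p1) at the
tail and is exactly palindromic before error injection.

Every generator is a pure function of (config, seed); distinct fixed stream
keys keep the genome, annotation, reads and assembly fixtures independently
reproducible.  The truth table (one row per read) drives all property tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import SeqRead, reverse_complement
from .txmodels import Exon, Transcript

__all__ = [
    "SimConfig",
    "AnnotationBundle",
    "StrandingEvaluation",
    "make_genome",
    "make_spikeins",
    "make_annotation",
    "transcript_sequence",
    "simulate_reads",
    "simulate_library",
    "make_fragmented_assembly",
    "make_unstranded_truncated_assembly",
    "evaluate_stranding",
]

# Fixed stream keys so each generator draws from an independent, seeded RNG.
_STREAM_GENOME = 0
_STREAM_ANNOTATION = 1
_STREAM_SPIKEINS = 2
_STREAM_READS = 3
_STREAM_FRAGMENT = 4
_STREAM_LONGREAD = 5


@dataclass(frozen=True)
class SimConfig:
    """All simulator knobs; see the methods note for rationale of defaults."""

    seed: int = 0
    genome_size: int = 2_000_000
    n_genes: int = 200
    exon_count: tuple[int, int] = (1, 8)
    isoform_prob: float = 0.3
    expression_mu: float = 1.0
    expression_sigma: float = 1.0
    n_spikeins: int = 92
    spikein_length_range: tuple[int, int] = (250, 2000)
    n_reads: int = 20_000
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.02
    full_length_prob: float = 0.6
    truncation_p: float = 0.002
    artifact_rate: float = 0.06
    strand_presentation: float = 0.5
    mode: Literal["direct_cDNA", "direct_RNA"] = "direct_cDNA"
    polya_len: int = 30
    p1: str = "GCTCTATCTTCTTT"
    p2: str = "CTGATATTGCTGGG"
    # assembly-fixture parameters
    split_prob: float = 0.7
    frag_gap_range: tuple[int, int] = (100, 200)
    end_trim_range: tuple[int, int] = (50, 200)
    lr_truncate_prob: float = 0.5
    strand_flip_frac: float = 0.07

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "full_length_prob",
                     "artifact_rate", "strand_presentation", "isoform_prob",
                     "split_prob", "lr_truncate_prob", "strand_flip_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_spikeins < 1:
            raise ValueError("n_spikeins must be >= 1")


@dataclass
class AnnotationBundle:
    """Truth annotation: genomic genes plus the spike-in ladder."""

    transcripts: list[Transcript]
    sequences: dict[str, str]
    spikein_transcripts: list[Transcript]
    spikein_sequences: dict[str, str]
    concentrations: pd.DataFrame
    expression: dict[str, float]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def make_genome(config: SimConfig) -> dict[str, str]:
    """Uniform-random genome; identical for identical (seed, size)."""
    rng = _rng(config, _STREAM_GENOME)
    return {"chr1": _random_seq(rng, config.genome_size)}


def make_spikeins(config: SimConfig) -> tuple[dict[str, str], list[Transcript], pd.DataFrame]:
    """Mono-exonic spike-in ladder on dedicated contigs.

    Transcripts are grouped into 2-fold concentration steps (groups of four,
    ERCC-style), lengths uniform over ``spikein_length_range``.
    """
    rng = _rng(config, _STREAM_SPIKEINS)
    lo, hi = config.spikein_length_range
    seqs: dict[str, str] = {}
    txs: list[Transcript] = []
    rows = []
    group_size = 4
    for i in range(config.n_spikeins):
        name = f"SPIKE_{i + 1:03d}"
        length = int(rng.integers(lo, hi + 1))
        seqs[name] = _random_seq(rng, length)
        group = i // group_size
        conc = float(2.0 ** group)
        txs.append(
            Transcript(
                id=name,
                gene_id=name,
                chrom=name,
                strand="+",
                exons=(Exon(chrom=name, start=0, end=length, strand="+"),),
            )
        )
        rows.append({"transcript_id": name, "length": length, "group": group,
                     "attomoles": conc})
    return seqs, txs, pd.DataFrame(rows)


def make_annotation(config: SimConfig, genome: Mapping[str, str] | None = None) -> AnnotationBundle:
    """Place genes on the genome and attach the spike-in ladder.

    Genes never overlap another gene on the same strand.  Mono-exonic genes
    are long (0.5-5 kb, cheRNA-like); multi-exon genes have 100-500 bp exons
    separated by 100-2000 bp introns.  Multi-exon genes with >= 3 exons gain
    a second isoform (sharing all but the first intron) with probability
    ``isoform_prob``.  Expression is log-normal per transcript.
    """
    if genome is None:
        genome = make_genome(config)
    rng = _rng(config, _STREAM_ANNOTATION)
    chrom = next(iter(genome))
    size = len(genome[chrom])
    occupied: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    transcripts: list[Transcript] = []
    expression: dict[str, float] = {}
    lo_exons, hi_exons = config.exon_count
    for g in range(config.n_genes):
        placed = False
        for _attempt in range(200):
            strand = "+" if rng.random() < 0.5 else "-"
            k = int(rng.integers(lo_exons, hi_exons + 1))
            if k == 1:
                exon_lens = [int(rng.integers(500, 5001))]
                intron_lens: list[int] = []
            else:
                exon_lens = [int(x) for x in rng.integers(100, 501, size=k)]
                intron_lens = [int(x) for x in rng.integers(100, 2001, size=k - 1)]
            span = sum(exon_lens) + sum(intron_lens)
            if span >= size:
                continue
            start = int(rng.integers(0, size - span))
            end = start + span
            if any(s < end and start < e for s, e in occupied[strand]):
                continue
            occupied[strand].append((start, end))
            exons = []
            pos = start
            for j, el in enumerate(exon_lens):
                exons.append(Exon(chrom=chrom, start=pos, end=pos + el, strand=strand))
                pos += el
                if j < len(intron_lens):
                    pos += intron_lens[j]
            gene_id = f"G{g + 1:04d}"
            tid = f"{gene_id}.1"
            transcripts.append(
                Transcript(id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
                           exons=tuple(exons))
            )
            expression[tid] = float(rng.lognormal(config.expression_mu,
                                                  config.expression_sigma))
            if k >= 3 and rng.random() < config.isoform_prob:
                iso_id = f"{gene_id}.2"
                transcripts.append(
                    Transcript(id=iso_id, gene_id=gene_id, chrom=chrom,
                               strand=strand, exons=tuple(exons[1:]))
                )
                expression[iso_id] = float(rng.lognormal(config.expression_mu,
                                                         config.expression_sigma))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"genome of size {size} too small to place {config.n_genes} genes"
            )
    spike_seqs, spike_txs, conc = make_spikeins(config)
    return AnnotationBundle(
        transcripts=transcripts,
        sequences=dict(genome),
        spikein_transcripts=spike_txs,
        spikein_sequences=spike_seqs,
        concentrations=conc,
        expression=expression,
    )


def transcript_sequence(tx: Transcript, sequences: Mapping[str, str]) -> str:
    """Spliced sense (5'->3') sequence of a transcript."""
    seq = "".join(sequences[tx.chrom][e.start : e.end] for e in tx.exons)
    return reverse_complement(seq) if tx.strand == "-" else seq


def _mutate(seq: str, rng: np.random.Generator, sub: float, ins: float, dele: float) -> str:
    """Apply i.i.d. per-base substitution/insertion/deletion errors."""
    if sub == ins == dele == 0.0 or not seq:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    # map ACGT -> 0..3
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[codes]
    r = rng.random(codes.size)
    sub_mask = r < sub
    del_mask = (r >= sub) & (r < sub + dele)
    ins_mask = (r >= sub + dele) & (r < sub + dele + ins)
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum())).astype(np.uint8)
        codes[sub_mask] = (codes[sub_mask] + shift) % 4
    counts = np.ones(codes.size, dtype=np.int64)
    counts[del_mask] = 0
    counts[ins_mask] = 2  # base followed by a random inserted base
    rep = np.repeat(np.arange(codes.size), counts)
    out = codes[rep]
    dup = np.flatnonzero(np.diff(rep) == 0) + 1
    if dup.size:
        out[dup] = rng.integers(0, 4, size=dup.size)
    return _BASES[out].tobytes().decode("ascii")


def simulate_reads(
    config: SimConfig,
    transcripts: Sequence[Transcript],
    sequences: Mapping[str, str],
    weights: Mapping[str, float] | None = None,
) -> tuple[list[SeqRead], pd.DataFrame]:
    """Draw a long-read library from an annotation with full ground truth.

    Each read samples a transcript proportional to its weight, keeps the
    full molecule with ``full_length_prob`` or truncates geometrically from
    the 5' end (the polyA-anchored 3' end always survives), renders one of
    the two cDNA strands, optionally palindromizes it (direct_cDNA mode
    only), then applies base errors.  Direct-RNA mode emits primer-free
    sense fragments and never produces artifacts.

    Returns the reads and a truth table with one row per read:
    read_id, transcript_id, orientation ("first"/"second" as presented),
    artifact flag, and the covered transcript interval (5'->3', pre-error).
    """
    rng = _rng(config, _STREAM_READS)
    if weights is None:
        weights = {t.id: 1.0 for t in transcripts}
    w = np.array([max(weights.get(t.id, 0.0), 0.0) for t in transcripts])
    if w.sum() <= 0:
        raise ValueError("all transcript weights are zero")
    w = w / w.sum()
    sense_cache = {t.id: transcript_sequence(t, sequences) for t in transcripts}
    polya = "A" * config.polya_len
    rc_p2 = reverse_complement(config.p2)
    choices = rng.choice(len(transcripts), size=config.n_reads, p=w)
    is_rna = config.mode == "direct_RNA"

    reads: list[SeqRead] = []
    rows = []
    for i in range(config.n_reads):
        tx = transcripts[int(choices[i])]
        sense = sense_cache[tx.id]
        length = len(sense)
        trunc = 0
        if rng.random() >= config.full_length_prob and length > 100:
            trunc = min(int(rng.geometric(config.truncation_p)), length - 100)
        frag = sense[trunc:]
        artifact = False
        if is_rna:
            seq = frag + polya
            orientation = "second"
        else:
            second = config.p1 + frag + polya + rc_p2
            if config.artifact_rate > 0 and rng.random() < config.artifact_rate:
                # RT template switch: p1-headed strand plus its own rc.
                seq = second + reverse_complement(second)
                orientation = "second"
                artifact = True
            elif rng.random() < config.strand_presentation:
                seq = reverse_complement(second)
                orientation = "first"
            else:
                seq = second
                orientation = "second"
        seq = _mutate(seq, rng, config.sub_rate, config.ins_rate, config.del_rate)
        read_id = f"r{i:06d}"
        reads.append(
            SeqRead(
                id=read_id,
                sequence=seq,
                qualities="I" * len(seq),
                tags={
                    "transcript_id": tx.id,
                    "orientation": orientation,
                    "artifact": "1" if artifact else "0",
                },
            )
        )
        rows.append(
            {
                "read_id": read_id,
                "transcript_id": tx.id,
                "orientation": orientation,
                "artifact": artifact,
                "span_start": trunc,
                "span_end": length,
            }
        )
    return reads, pd.DataFrame(rows)


def simulate_library(
    config: SimConfig,
    bundle: AnnotationBundle | None = None,
    which: Literal["spikeins", "genes", "all"] = "spikeins",
) -> tuple[list[SeqRead], pd.DataFrame, AnnotationBundle]:
    """Convenience wrapper: build (or reuse) an annotation and draw reads.

    ``which`` selects the source transcripts: the spike-in ladder (weights =
    ladder concentrations), the genomic genes (weights = expression), or
    both.
    """
    if bundle is None:
        if which == "spikeins":
            spike_seqs, spike_txs, conc = make_spikeins(config)
            bundle = AnnotationBundle(
                transcripts=[], sequences={}, spikein_transcripts=spike_txs,
                spikein_sequences=spike_seqs, concentrations=conc, expression={},
            )
        else:
            bundle = make_annotation(config)
    conc_map = dict(
        zip(bundle.concentrations["transcript_id"], bundle.concentrations["attomoles"])
    )
    txs: list[Transcript] = []
    seqs: dict[str, str] = {}
    weights: dict[str, float] = {}
    if which in ("spikeins", "all"):
        txs += bundle.spikein_transcripts
        seqs.update(bundle.spikein_sequences)
        weights.update({t.id: conc_map.get(t.id, 1.0) for t in bundle.spikein_transcripts})
    if which in ("genes", "all"):
        txs += bundle.transcripts
        seqs.update(bundle.sequences)
        weights.update({t.id: bundle.expression.get(t.id, 1.0) for t in bundle.transcripts})
    reads, truth = simulate_reads(config, txs, seqs, weights)
    return reads, truth, bundle


# ---------------------------------------------------------------------------
# assembly fixtures


def _exonic_slice(tx: Transcript, a: int, b: int) -> tuple[Exon, ...]:
    """Exons covering the genomic-order exonic interval [a, b) of ``tx``."""
    out = []
    off = 0
    for e in tx.exons:
        lo = max(a, off)
        hi = min(b, off + len(e))
        if lo < hi:
            out.append(
                Exon(chrom=e.chrom, start=e.start + (lo - off),
                     end=e.start + (hi - off), strand=e.strand)
            )
        off += len(e)
    return tuple(out)


def make_fragmented_assembly(
    truth: Sequence[Transcript],
    config: SimConfig,
    expression: Mapping[str, float] | None = None,
) -> list[Transcript]:
    """Short-read-like assembly: split models with trimmed, ambiguous ends.

    With probability ``split_prob`` a (long enough) transcript is cut into
    2-3 pieces separated by >= 100-base exonic gaps; every model loses
    50-200 exonic bases at each end.  Strand is preserved and a ``cov``
    attribute is set from expression.
    """
    rng = _rng(config, _STREAM_FRAGMENT)
    t_lo, t_hi = config.end_trim_range
    g_lo, g_hi = config.frag_gap_range
    out: list[Transcript] = []
    for tx in truth:
        E = tx.exonic_length
        cov = (expression or {}).get(tx.id, 1.0) * 10.0
        if E >= 600:
            t5 = min(int(rng.integers(t_lo, t_hi + 1)), (E - 200) // 2)
            t3 = min(int(rng.integers(t_lo, t_hi + 1)), (E - 200) // 2)
        else:
            t5 = t3 = 0
        lo, hi = t5, E - t3
        pieces: list[tuple[int, int]] = []
        if rng.random() < config.split_prob and hi - lo >= 800:
            k = 2 if rng.random() < 0.7 else 3
            cuts = sorted(
                lo + int((hi - lo) * (j + rng.uniform(-0.25, 0.25)) / k)
                for j in range(1, k)
            )
            prev = lo
            for cut in cuts:
                gap = int(rng.integers(g_lo, g_hi + 1))
                a, b = prev, max(prev, cut - gap // 2)
                if b - a >= 100:
                    pieces.append((a, b))
                prev = cut + (gap + 1) // 2
            if hi - prev >= 100:
                pieces.append((prev, hi))
            if len(pieces) < 2:
                pieces = [(lo, hi)]
        else:
            pieces = [(lo, hi)]
        for n, (a, b) in enumerate(pieces, start=1):
            exons = _exonic_slice(tx, a, b)
            if not exons:
                continue
            suffix = f".f{n}" if len(pieces) > 1 else ".f1"
            out.append(
                Transcript(
                    id=tx.id + suffix,
                    gene_id=tx.gene_id + suffix,
                    chrom=tx.chrom,
                    strand=tx.strand,
                    exons=exons,
                    attributes={"cov": f"{cov:.2f}"},
                )
            )
    return out


def make_unstranded_truncated_assembly(
    truth: Sequence[Transcript],
    config: SimConfig,
    expression: Mapping[str, float] | None = None,
) -> list[Transcript]:
    """Long-read-like assembly: 5'-truncated models, some strand-flipped.

    With probability ``lr_truncate_prob`` a model loses a geometric number
    of exonic bases from its 5' end (3'-anchored, like the reads); a
    fraction ``strand_flip_frac`` is assigned the wrong strand, emulating
    assembly from unstranded reads.  Coverage is set low (long-read depth).
    """
    rng = _rng(config, _STREAM_LONGREAD)
    out: list[Transcript] = []
    for tx in truth:
        E = tx.exonic_length
        trunc = 0
        if rng.random() < config.lr_truncate_prob and E > 100:
            trunc = min(int(rng.geometric(config.truncation_p)), E - 100)
        if tx.strand == "-":
            exons = _exonic_slice(tx, 0, E - trunc)
        else:
            exons = _exonic_slice(tx, trunc, E)
        strand = tx.strand
        if rng.random() < config.strand_flip_frac:
            strand = "-" if strand == "+" else "+"
            exons = tuple(replace(e, strand=strand) for e in exons)
        cov = (expression or {}).get(tx.id, 1.0) * 1.0
        out.append(
            Transcript(
                id=tx.id + ".lr",
                gene_id=tx.gene_id + ".lr",
                chrom=tx.chrom,
                strand=strand,
                exons=exons,
                attributes={"cov": f"{cov:.2f}"},
            )
        )
    return out


# ---------------------------------------------------------------------------
# stranding evaluation against truth


@dataclass
class StrandingEvaluation:
    """Orientation accuracy of an emitted library against simulator truth."""

    accuracy: float
    n_evaluated: int
    n_correct: int
    confusion: dict[tuple[str, str], int]


def evaluate_stranding(
    stranded: Iterable[SeqRead],
    truth: pd.DataFrame,
    expected_orientation: str = "second",
    exclude_artifacts: bool = False,
) -> StrandingEvaluation:
    """Fraction of emitted reads whose final orientation matches truth.

    Each read's final orientation is its presented orientation (from the
    truth table) flipped once per reverse complement applied by the
    stranding pipeline (the ``orientation_flipped`` tag).  Artifact reads
    can be excluded from the denominator (mirroring --drop-artifacts).
    """
    table = truth.set_index("read_id")
    n = 0
    correct = 0
    confusion: dict[tuple[str, str], int] = {}
    for read in stranded:
        if read.id not in table.index:
            raise ValueError(f"emitted read {read.id!r} missing from truth table")
        row = table.loc[read.id]
        if exclude_artifacts and bool(row["artifact"]):
            continue
        presented = str(row["orientation"])
        flipped = read.tags.get("orientation_flipped", "0") == "1"
        final = presented
        if flipped:
            final = "first" if presented == "second" else "second"
        n += 1
        if final == expected_orientation:
            correct += 1
        confusion[(presented, final)] = confusion.get((presented, final), 0) + 1
    return StrandingEvaluation(
        accuracy=(correct / n) if n else 0.0,
        n_evaluated=n,
        n_correct=correct,
        confusion=confusion,
    )
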