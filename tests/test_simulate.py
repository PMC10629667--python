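"""Simulator determinism, geometry and sampling properties."""

import numpy as np
import pytest

from slurptassel.primer_scan import PrimerConfig
from slurptassel.seqio import reverse_complement
from slurptassel.simulate import (
    SimConfig,
    make_annotation,
    make_fragmented_assembly,
    make_genome,
    make_spikeins,
    make_unstranded_truncated_assembly,
    simulate_library,
    transcript_sequence,
)
from slurptassel.txmodels import classify_against_reference


def test_genome_deterministic_and_sized():
    cfg = SimConfig(seed=1, genome_size=1000)
    g1 = make_genome(cfg)
    g2 = make_genome(cfg)
    assert g1 == g2
    assert len(g1["chr1"]) == 1000
    other = make_genome(SimConfig(seed=2, genome_size=1000))
    assert other != g1


def test_genome_gc_fraction():
    cfg = SimConfig(seed=3, genome_size=100_000)
    seq = make_genome(cfg)["chr1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.5) < 0.05


def test_spikein_ladder():
    seqs, txs, conc = make_spikeins(SimConfig(seed=1))
    assert len(txs) == 92
    assert len(seqs) == 92
    assert all(len(t.exons) == 1 for t in txs)
    lo, hi = 250, 2000
    assert all(lo <= len(s) <= hi for s in seqs.values())
    # 2-fold ladder across groups
    by_group = conc.groupby("group")["attomoles"].first()
    ratios = by_group.values[1:] / by_group.values[:-1]
    assert np.allclose(ratios, 2.0)


def test_annotation_geometry():
    cfg = SimConfig(seed=5, genome_size=800_000, n_genes=80)
    bundle = make_annotation(cfg)
    size = len(bundle.sequences["chr1"])
    spans = {"+": [], "-": []}
    for t in bundle.transcripts:
        assert 0 <= t.start < t.end <= size
        if t.id.endswith(".1"):
            spans[t.strand].append((t.start, t.end))
    for strand_spans in spans.values():
        strand_spans.sort()
        for (s1, e1), (s2, e2) in zip(strand_spans, strand_spans[1:]):
            assert e1 <= s2  # no same-strand gene overlap
    # isoforms share at least one intron with the primary transcript
    primaries = {t.id: t for t in bundle.transcripts}
    for t in bundle.transcripts:
        if t.id.endswith(".2"):
            primary = primaries[t.id[:-2] + ".1"]
            assert set(t.intron_chain) & set(primary.intron_chain)


def test_annotation_errors_when_genome_too_small():
    with pytest.raises(ValueError, match="too small"):
        make_annotation(SimConfig(seed=1, genome_size=5_000, n_genes=100))


def test_reads_deterministic():
    cfg = SimConfig(seed=9, n_reads=200)
    r1, t1, _ = simulate_library(cfg, which="spikeins")
    r2, t2, _ = simulate_library(cfg, which="spikeins")
    assert [x.sequence for x in r1] == [x.sequence for x in r2]
    assert t1.equals(t2)


def test_truth_table_matches_reads(small_spike_library):
    _, reads, truth, _ = small_spike_library
    assert len(truth) == len(reads)
    assert truth["read_id"].is_unique
    assert set(truth["read_id"]) == {r.id for r in reads}


def test_clean_second_strand_geometry(clean_spike_library):
    """Before error injection, second-strand reads are p1 + sense + rc(p2)
    and first-strand reads their reverse complement."""
    cfg, reads, truth, bundle = clean_spike_library
    pc = PrimerConfig()
    seqs = {t.id: transcript_sequence(t, bundle.spikein_sequences)
            for t in bundle.spikein_transcripts}
    rows = truth.set_index("read_id")
    for read in reads[:200]:
        row = rows.loc[read.id]
        sense = seqs[row["transcript_id"]] + "A" * cfg.polya_len
        expected_second = pc.p1 + sense + pc.rc_p2
        if row["orientation"] == "second":
            assert read.sequence == expected_second
        else:
            assert read.sequence == reverse_complement(expected_second)


def test_artifact_reads_are_palindromic_before_errors():
    cfg = SimConfig(seed=13, n_reads=300, sub_rate=0, ins_rate=0, del_rate=0,
                    artifact_rate=0.3)
    reads, truth, _ = simulate_library(cfg, which="spikeins")
    pc = PrimerConfig()
    flagged = truth[truth["artifact"]]
    assert len(flagged) > 0
    by_id = {r.id: r for r in reads}
    for rid in flagged["read_id"][:20]:
        seq = by_id[rid].sequence
        n = len(seq)
        assert seq[n // 2:] == reverse_complement(seq[: n // 2])
        assert seq.startswith(pc.p1)
        assert seq.endswith(pc.rc_p1)


def test_artifact_rate_binomial_recovery(default_spike_library):
    _, _, truth, _ = default_spike_library
    frac = truth["artifact"].mean()
    n = len(truth)
    # 99% binomial CI around the configured 6% rate
    half_width = 2.576 * np.sqrt(0.06 * 0.94 / n)
    assert abs(frac - 0.06) < half_width


def test_direct_rna_mode_has_no_artifacts_or_primers():
    cfg = SimConfig(seed=21, n_reads=300, mode="direct_RNA", sub_rate=0,
                    ins_rate=0, del_rate=0, full_length_prob=1.0)
    reads, truth, bundle = simulate_library(cfg, which="spikeins")
    assert not truth["artifact"].any()
    pc = PrimerConfig()
    seqs = {t.id: transcript_sequence(t, bundle.spikein_sequences)
            for t in bundle.spikein_transcripts}
    rows = truth.set_index("read_id")
    for read in reads[:50]:
        tid = rows.loc[read.id, "transcript_id"]
        assert read.sequence == seqs[tid] + "A" * cfg.polya_len


def test_truncation_is_three_prime_anchored(small_spike_library):
    _, _, truth, _ = small_spike_library
    # every covered span ends at the transcript 3' end
    lengths = truth["span_end"] - truth["span_start"]
    assert (lengths > 0).all()
    truncated = truth[truth["span_start"] > 0]
    assert len(truncated) > 0


def test_fragmented_assembly_splits_and_respects_strand(genome_bundle):
    config, bundle = genome_bundle
    frag = make_fragmented_assembly(bundle.transcripts, config, bundle.expression)
    truth_by_id = {t.id: t for t in bundle.transcripts}
    n_pieces = {}
    for f in frag:
        orig = truth_by_id[f.id.rsplit(".f", 1)[0]]
        assert f.strand == orig.strand
        assert orig.start <= f.start and f.end <= orig.end
        n_pieces[orig.id] = n_pieces.get(orig.id, 0) + 1
    assert max(n_pieces.values()) >= 2  # some transcripts were split
    split = [tid for tid, k in n_pieces.items() if k >= 2]
    for tid in split[:10]:
        pieces = sorted(
            (f for f in frag if f.id.rsplit(".f", 1)[0] == tid),
            key=lambda t: t.start,
        )
        for a, b in zip(pieces, pieces[1:]):
            assert b.start - a.end >= 50  # separated by a real gap


def test_split_probability_zero_only_trims():
    cfg = SimConfig(seed=5, genome_size=800_000, n_genes=40, split_prob=0.0)
    bundle = make_annotation(cfg)
    frag = make_fragmented_assembly(bundle.transcripts, cfg, bundle.expression)
    assert len(frag) == len(bundle.transcripts)


def test_unstranded_assembly_flip_fraction(genome_bundle):
    config, bundle = genome_bundle
    truth_by_id = {t.id: t for t in bundle.transcripts}
    # flip fraction 0: all strands preserved
    cfg0 = SimConfig(seed=config.seed, genome_size=config.genome_size,
                     n_genes=config.n_genes, strand_flip_frac=0.0)
    lr0 = make_unstranded_truncated_assembly(bundle.transcripts, cfg0,
                                             bundle.expression)
    assert all(t.strand == truth_by_id[t.id[:-3]].strand for t in lr0)
    # flip fraction 1: everything classifies as antisense
    cfg1 = SimConfig(seed=config.seed, genome_size=config.genome_size,
                     n_genes=config.n_genes, strand_flip_frac=1.0,
                     lr_truncate_prob=0.0)
    lr1 = make_unstranded_truncated_assembly(bundle.transcripts, cfg1,
                                             bundle.expression)
    # each flipped model is antisense to its own source transcript
    for t in lr1:
        code = classify_against_reference(t, [truth_by_id[t.id[:-3]]]).code
        assert code == "s"
    # default ~7% of 200: binomial check on a bigger set
    cfg7 = SimConfig(seed=31, genome_size=2_000_000, n_genes=200)
    b7 = make_annotation(cfg7)
    lr7 = make_unstranded_truncated_assembly(b7.transcripts, cfg7, b7.expression)
    tb = {t.id: t for t in b7.transcripts}
    flipped = sum(t.strand != tb[t.id[:-3]].strand for t in lr7)
    n = len(lr7)
    assert abs(flipped / n - 0.07) < 2.576 * np.sqrt(0.07 * 0.93 / n) + 0.01
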