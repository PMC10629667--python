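"""GTF models, class codes (vs a literal-definition oracle), metrics."""

import numpy as np
import pytest

from slurptassel.txmodels import (
    CODE_PRECEDENCE,
    Exon,
    GtfParseError,
    Transcript,
    classify_against_reference,
    compare_sets,
    consolidate_spans,
    count_segmented,
    end_distances,
    end_proximity_summary,
    parse_gtf,
    write_gtf,
)


def tx(tid, exons, strand="+", chrom="chr1", gene=None, attrs=None):
    return Transcript(
        id=tid,
        gene_id=gene or tid,
        chrom=chrom,
        strand=strand,
        exons=tuple(Exon(chrom=chrom, start=s, end=e, strand=strand) for s, e in exons),
        attributes=attrs or {},
    )


# ---------------------------------------------------------------------------
# GTF I/O


def test_parse_gtf_coordinate_conversion(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(
        'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; cov "7.5";\n'
    )
    (t1,) = parse_gtf(p)
    assert [(e.start, e.end) for e in t1.exons] == [(100, 200), (300, 400)]
    assert t1.intron_chain == ((200, 300),)
    assert t1.attributes["cov"] == "7.5"


def test_gtf_round_trip_exact(tmp_path):
    txs = [
        tx("t1", [(100, 200), (300, 400)], attrs={"cov": "3.00", "TPM": "1.5"}),
        tx("t2", [(50, 900)], strand="-"),
    ]
    p = tmp_path / "w.gtf"
    write_gtf(txs, p)
    back = parse_gtf(p)
    assert [(t.id, t.strand, [(e.start, e.end) for e in t.exons]) for t in back] == [
        (t.id, t.strand, [(e.start, e.end) for e in t.exons]) for t in txs
    ]
    assert back[0].attributes["cov"] == "3.00"
    # non-exon features ignored, empty file gives empty set
    empty = tmp_path / "e.gtf"
    empty.write_text("# comment only\n")
    assert parse_gtf(empty) == []


def test_parse_gtf_errors_name_lines(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text('chr1\tx\texon\t1\t10\t.\t+\t.\tgene_id "g";\n')
    with pytest.raises(GtfParseError, match="line 1"):
        parse_gtf(p)
    p.write_text(
        'chr1\tx\texon\t1\t10\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        'chr2\tx\texon\t1\t10\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
    )
    with pytest.raises(GtfParseError, match="line 2"):
        parse_gtf(p)


# ---------------------------------------------------------------------------
# class codes: worked examples


REF = [
    tx("R1", [(1000, 1200), (1500, 1700), (2000, 2300)]),
    tx("R2", [(5000, 6000)]),
]


def test_identity_is_equals():
    assert classify_against_reference(REF[0], REF).code == "="
    assert classify_against_reference(REF[1], REF).code == "="


def test_mono_query_inside_reference_exon_is_contained():
    q = tx("q", [(2050, 2250)])
    cc = classify_against_reference(q, REF)
    assert (cc.code, cc.matched_ref) == ("c", "R1")


def test_strand_flip_is_antisense():
    q = tx("q", [(1000, 1200), (1500, 1700), (2000, 2300)], strand="-")
    assert classify_against_reference(q, REF).code == "s"


def test_query_inside_intron():
    q = tx("q", [(1250, 1450)])
    assert classify_against_reference(q, REF).code == "i"


def test_intergenic_is_u():
    q = tx("q", [(90_000, 91_000)])
    cc = classify_against_reference(q, REF)
    assert cc.code == "u" and cc.matched_ref is None


def test_shared_junction_is_j():
    q = tx("q", [(900, 1200), (1500, 1800)])  # shares intron (1200,1500) only
    assert classify_against_reference(q, REF).code == "j"


def test_containment_of_reference_is_k():
    # query extends R1 with an extra 3' exon; R1's chain is a contiguous
    # sub-chain and its span is contained
    q = tx("q", [(900, 1200), (1500, 1700), (2000, 2300), (2600, 2800)])
    assert classify_against_reference(q, REF).code == "k"


def test_identical_intron_chain_with_longer_span_is_equals():
    q = tx("q", [(900, 1200), (1500, 1700), (2000, 2400)])
    assert classify_against_reference(q, REF).code == "="


def test_mono_equal_requires_reciprocal_overlap():
    q = tx("q", [(5050, 5950)])  # 90% reciprocal
    assert classify_against_reference(q, REF).code == "="
    q2 = tx("q2", [(5500, 6000)])  # 50% of reference -> contained, not '='
    assert classify_against_reference(q2, REF).code == "c"


# ---------------------------------------------------------------------------
# class codes: brute-force oracle on random instances


def _bases(t):
    out = set()
    for e in t.exons:
        out.update(range(e.start, e.end))
    return out


def _introns(t):
    return {(a.end, b.start) for a, b in zip(t.exons, t.exons[1:])}


def oracle_pair_code(q, r, mono_overlap=0.8):
    """Literal application of the class-code definitions via base sets."""
    if q.chrom != r.chrom:
        return None
    qb, rb = _bases(q), _bases(r)
    ov = len(qb & rb)
    if q.strand == r.strand:
        qi = [(a.end, b.start) for a, b in zip(q.exons, q.exons[1:])]
        ri = [(a.end, b.start) for a, b in zip(r.exons, r.exons[1:])]
        if qi and ri and qi == ri:
            return "="
        if not qi and not ri and ov >= mono_overlap * len(qb) and ov >= mono_overlap * len(rb):
            return "="
        # query contained
        if not qi:
            if any(set(range(e.start, e.end)) >= qb for e in r.exons):
                return "c"
        elif ri and any(ri[i:i + len(qi)] == qi for i in range(len(ri) - len(qi) + 1)):
            if r.start <= q.start and q.end <= r.end:
                return "c"
        # reference contained
        if not ri:
            if any(set(range(e.start, e.end)) >= rb for e in q.exons):
                return "k"
        elif qi and any(qi[i:i + len(ri)] == ri for i in range(len(qi) - len(ri) + 1)):
            if q.start <= r.start and r.end <= q.end:
                return "k"
        if set(qi) & set(ri):
            return "j"
        if ov:
            return "o"
        if any(s <= q.start and q.end <= e for s, e in ri):
            return "i"
        return None
    if ov:
        return "s"
    if any(s <= q.start and q.end <= e for s, e in _introns(r)):
        return "i"
    return None


def oracle_classify(q, refs):
    rank = {c: i for i, c in enumerate(CODE_PRECEDENCE)}
    best = None
    for r in refs:
        code = oracle_pair_code(q, r)
        if code is None:
            continue
        key = (rank[code], -len(_bases(q) & _bases(r)), r.id)
        if best is None or key < best[0]:
            best = (key, code, r.id)
    return ("u", None) if best is None else (best[1], best[2])


def random_transcript(rng, tid):
    strand = "+" if rng.random() < 0.5 else "-"
    k = int(rng.integers(1, 4))
    pos = int(rng.integers(0, 1500))
    exons = []
    for _ in range(k):
        length = int(rng.integers(20, 200))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(20, 150))
    return tx(tid, exons, strand=strand)


def test_class_codes_match_bruteforce_oracle():
    rng = np.random.default_rng(99)
    for _ in range(30):
        refs = [random_transcript(rng, f"R{i}") for i in range(int(rng.integers(1, 50)))]
        queries = [random_transcript(rng, f"Q{i}") for i in range(20)]
        for q in queries:
            got = classify_against_reference(q, refs)
            want_code, want_ref = oracle_classify(q, refs)
            assert got.code == want_code, (q.id, got, want_code)
            assert got.matched_ref == want_ref


# ---------------------------------------------------------------------------
# set comparison


def test_compare_identical_sets_is_perfect():
    s = compare_sets(REF, REF)
    assert s.transcript_sensitivity == 100.0
    assert s.transcript_precision == 100.0
    assert s.locus_sensitivity == 100.0
    assert s.locus_precision == 100.0


def test_compare_half_matched():
    refs = [tx(f"R{i}", [(i * 10_000, i * 10_000 + 500)]) for i in range(10)]
    query = [tx(f"E{i}", [(i * 10_000, i * 10_000 + 500)]) for i in range(5)] + [
        tx(f"N{i}", [(500_000 + i * 10_000, 500_000 + i * 10_000 + 300)])
        for i in range(5)
    ]
    s = compare_sets(query, refs)
    assert s.transcript_sensitivity == 50.0
    assert s.transcript_precision == 50.0


def test_compare_empty_query_flagged():
    s = compare_sets([], REF)
    assert s.transcript_precision == 0.0
    assert s.precision_undefined


# ---------------------------------------------------------------------------
# end proximity


def test_end_distances_zero_for_identical():
    d = end_distances(REF, REF, "TSS")
    assert np.array_equal(d, [0, 0])


def test_end_distances_signed_shift_and_strand_convention():
    ref = [tx("r", [(1000, 2000)])]
    q = [tx("q", [(1100, 2000)])]  # 5' start shifted +100 on '+'
    assert end_distances(q, ref, "TSS")[0] == 100
    assert end_distances(q, ref, "TTS")[0] == 0
    ref_m = [tx("r", [(1000, 2000)], strand="-")]
    q_m = [tx("q", [(1000, 1900)], strand="-")]  # '-' TSS is the right end
    assert end_distances(q_m, ref_m, "TSS")[0] == -100
    summary = end_proximity_summary(np.array([10.0, -60.0, 400.0, 2000.0]))
    assert summary[50] == 0.25 and summary[100] == 0.5 and summary[1000] == 0.75


# ---------------------------------------------------------------------------
# segmentation


def test_count_segmented_examples():
    g1 = tx("g1", [(100, 400)])
    g2 = tx("g2", [(600, 900)])
    g3 = tx("g3", [(5000, 5400)])
    one_span = tx("m", [(50, 1000)])
    own_span = tx("m2", [(4900, 5500)])
    assert count_segmented([g1, g2, g3], [one_span, own_span]) == 2
    assert count_segmented([g1, g2, g3], [tx("m3", [(0, 6000)])]) == 3
    assert (
        count_segmented([g1, g3], [tx("a", [(100, 400)]), tx("b", [(5000, 5400)])])
        == 0
    )


def test_consolidate_spans_strand_aware():
    a = tx("a", [(100, 500)])
    b = tx("b", [(400, 900)])
    c = tx("c", [(450, 800)], strand="-")
    spans = consolidate_spans([a, b, c])
    by_strand = {(s.strand, s.start, s.end) for s in spans}
    assert by_strand == {("+", 100, 900), ("-", 450, 800)}
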