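"""TASSEL: strand-aware merging of transcript-model sets.

Short-read assemblies have depth but fragment transcripts and blur their
ends; stranded long-read assemblies have complete molecules but low depth
and 5' truncation.  TASSEL pools two or more GTF-derived transcript sets and
collapses them into a non-redundant consensus, never merging across strands
(transcripts of unknown '.' strand merge only among themselves).

The merge is defined by six deterministic rules applied within connected
components of same-chromosome, same-strand exonic overlap:

1. pool the inputs;
2. multi-exon transcripts with identical intron chains collapse to one
   model spanning [min start, max end];
3. a multi-exon transcript whose intron chain is a contiguous sub-chain of
   another's, with its span contained in the other's, is absorbed;
4. a mono-exon transcript contained in an exon of a retained transcript is
   absorbed;
5. remaining same-strand mono-exon transcripts merge transitively into
   their union span when they overlap by at least ``mono_overlap_frac`` of
   the shorter one;
6. survivors carry a ``sources`` attribute listing every contributing input
   (``consensus`` when >= 2 inputs contributed) and receive deterministic
   ids ``TSL.<n>`` in sorted genomic order.

Rules 3-5 iterate to a fixed point, which makes the merge idempotent and
insensitive to input order.  The minimum-coverage stringency (``min_cov``,
the ``-c`` sweep analog) filters the merged models, whose coverage is the
maximum over their contributors, so raising it can only shrink the output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .txmodels import Exon, Transcript, exonic_overlap

__all__ = ["MergeConfig", "filter_by_coverage", "merge_transcriptomes", "STRINGENCY_SWEEP"]

#: Canonical minimum-read-count sweep used for stringency curves.
STRINGENCY_SWEEP = (2, 4, 6, 8, 10, 15, 20, 25, 50, 75, 100, 150, 200, 250, 300)


@dataclass(frozen=True)
class MergeConfig:
    """Merging parameters.

    ``min_cov`` is the minimum value of the ``cov`` attribute for a
    transcript to enter the merge (0 admits everything, including
    transcripts without a ``cov``).  ``mono_overlap_frac`` is the fraction
    of the shorter transcript two mono-exon models must share to fuse.
    """

    min_cov: float = 0.0
    mono_overlap_frac: float = 0.3
    require_strand: bool = True
    track_sources: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.mono_overlap_frac <= 1.0):
            raise ValueError("mono_overlap_frac must be in (0, 1]")
        if self.min_cov < 0:
            raise ValueError("min_cov must be >= 0")


def filter_by_coverage(
    transcripts: Sequence[Transcript], min_cov: float
) -> list[Transcript]:
    """Retain transcripts with ``cov`` >= ``min_cov``.

    Transcripts lacking a ``cov`` attribute pass only when ``min_cov`` is 0.
    """
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    if min_cov == 0:
        return list(transcripts)
    out = []
    for t in transcripts:
        cov = t.attributes.get("cov")
        if cov is not None and float(cov) >= min_cov:
            out.append(t)
    return out


@dataclass
class _Item:
    tx: Transcript
    sources: set[int]
    cov: float | None = None


def _max_cov(items: Sequence["_Item"]) -> float | None:
    covs = [it.cov for it in items if it.cov is not None]
    return max(covs) if covs else None


def _chain_contiguous_subchain(sub: tuple, sup: tuple) -> bool:
    k = len(sub)
    if k == 0 or k > len(sup):
        return False
    return any(sup[i : i + k] == sub for i in range(len(sup) - k + 1))


def _rebuild_span(tx: Transcript, start: int, end: int) -> Transcript:
    """Extend a transcript's outer exons to a new [start, end) span,
    keeping the intron chain fixed."""
    exons = list(tx.exons)
    exons[0] = replace(exons[0], start=start)
    exons[-1] = replace(exons[-1], end=end)
    return replace(tx, exons=tuple(exons))


def _collapse_identical_chains(items: list[_Item]) -> tuple[list[_Item], bool]:
    groups: dict[tuple, list[_Item]] = {}
    monos: list[_Item] = []
    for it in items:
        if it.tx.is_multi_exon:
            groups.setdefault(it.tx.intron_chain, []).append(it)
        else:
            monos.append(it)
    changed = False
    out: list[_Item] = []
    for chain, members in groups.items():
        if len(members) == 1:
            out.append(members[0])
            continue
        changed = True
        start = min(m.tx.start for m in members)
        end = max(m.tx.end for m in members)
        keeper = min(members, key=lambda m: (m.tx.start, m.tx.end, m.tx.id))
        merged = _rebuild_span(keeper.tx, start, end)
        sources = set().union(*(m.sources for m in members))
        out.append(_Item(tx=merged, sources=sources, cov=_max_cov(members)))
    return out + monos, changed


def _absorb_contained(items: list[_Item]) -> tuple[list[_Item], bool]:
    """Rules 3 and 4: absorb sub-chain multi-exon and exon-contained
    mono-exon transcripts into a retained transcript."""
    # Prefer absorbing into the model with the most introns, then widest span.
    def host_rank(it: _Item):
        return (-len(it.tx.intron_chain), -(it.tx.end - it.tx.start), it.tx.start, it.tx.id)

    items = sorted(items, key=host_rank)
    removed: set[int] = set()
    changed = False
    for i, it in enumerate(items):
        if i in removed:
            continue
        for j, host in enumerate(items):
            if i == j or j in removed:
                continue
            t, h = it.tx, host.tx
            if t.is_multi_exon:
                if not h.is_multi_exon or len(h.intron_chain) <= len(t.intron_chain):
                    continue
                if (
                    _chain_contiguous_subchain(t.intron_chain, h.intron_chain)
                    and h.start <= t.start
                    and t.end <= h.end
                ):
                    host.sources |= it.sources
                    host.cov = _max_cov([host, it])
                    removed.add(i)
                    changed = True
                    break
            else:
                if any(e.start <= t.start and t.end <= e.end for e in h.exons):
                    host.sources |= it.sources
                    host.cov = _max_cov([host, it])
                    removed.add(i)
                    changed = True
                    break
    return [it for i, it in enumerate(items) if i not in removed], changed


def _merge_monos(items: list[_Item], frac: float) -> tuple[list[_Item], bool]:
    """Rule 5: transitively fuse overlapping mono-exon transcripts."""
    monos = [it for it in items if not it.tx.is_multi_exon]
    rest = [it for it in items if it.tx.is_multi_exon]
    if len(monos) < 2:
        return items, False
    parent = list(range(len(monos)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    changed = False
    for i in range(len(monos)):
        for j in range(i + 1, len(monos)):
            a, b = monos[i].tx, monos[j].tx
            ov = max(0, min(a.end, b.end) - max(a.start, b.start))
            shorter = min(a.end - a.start, b.end - b.start)
            if ov >= frac * shorter and ov > 0:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
                    changed = True
    groups: dict[int, list[_Item]] = {}
    for i, it in enumerate(monos):
        groups.setdefault(find(i), []).append(it)
    merged: list[_Item] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        start = min(m.tx.start for m in members)
        end = max(m.tx.end for m in members)
        keeper = min(members, key=lambda m: (m.tx.start, m.tx.end, m.tx.id))
        tx = replace(
            keeper.tx,
            exons=(Exon(chrom=keeper.tx.chrom, start=start, end=end, strand=keeper.tx.strand),),
        )
        merged.append(
            _Item(tx=tx, sources=set().union(*(m.sources for m in members)),
                  cov=_max_cov(members))
        )
    return rest + merged, changed


def _merge_component(items: list[_Item], config: MergeConfig) -> list[_Item]:
    # Rules 2-5 to a fixed point; each pass either shrinks the item list or
    # leaves it unchanged, so this terminates.
    while True:
        items, c2 = _collapse_identical_chains(items)
        items, c34 = _absorb_contained(items)
        items, c5 = _merge_monos(items, config.mono_overlap_frac)
        if not (c2 or c34 or c5):
            return items


def _components(items: list[_Item]) -> list[list[_Item]]:
    """Connected components of same-chrom, same-strand exonic overlap."""
    by_key: dict[tuple[str, str], list[_Item]] = {}
    for it in items:
        by_key.setdefault((it.tx.chrom, it.tx.strand), []).append(it)
    comps: list[list[_Item]] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda it: (it.tx.start, it.tx.end, it.tx.id))
        parent = list(range(len(group)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if group[j].tx.start >= group[i].tx.end:
                    break
                if exonic_overlap(group[i].tx, group[j].tx) > 0:
                    ra, rb = find(i), find(j)
                    if ra != rb:
                        parent[rb] = ra
        buckets: dict[int, list[_Item]] = {}
        for i, it in enumerate(group):
            buckets.setdefault(find(i), []).append(it)
        comps.extend(buckets.values())
    return comps


def merge_transcriptomes(
    inputs: Sequence[Sequence[Transcript]], config: MergeConfig | None = None
) -> list[Transcript]:
    """Merge one or more transcript sets into a non-redundant consensus.

    Returns transcripts with regenerated ids ``TSL.<n>`` in sorted genomic
    order, each carrying ``sources`` (comma-separated input indices) and
    ``consensus`` ("true" when >= 2 inputs contributed) attributes when
    source tracking is enabled.

    The stringency filter ``min_cov`` applies to the merged consensus
    models: a model's coverage is the maximum over its contributing input
    transcripts, so raising ``min_cov`` can only shrink the output
    (monotone, as a stringency sweep should be).  Use
    :func:`filter_by_coverage` for input-side filtering.
    """
    if config is None:
        config = MergeConfig()
    if not inputs:
        raise ValueError("merge requires at least one input set")
    pool: list[_Item] = []
    for idx, txs in enumerate(inputs):
        for t in txs:
            cov = t.attributes.get("cov")
            pool.append(
                _Item(tx=t, sources={idx}, cov=None if cov is None else float(cov))
            )
    merged: list[_Item] = []
    for comp in _components(pool):
        merged.extend(_merge_component(comp, config))
    if config.min_cov > 0:
        merged = [
            it for it in merged if it.cov is not None and it.cov >= config.min_cov
        ]
    merged.sort(key=lambda it: (it.tx.chrom, it.tx.start, it.tx.end, it.tx.strand))
    out: list[Transcript] = []
    for n, it in enumerate(merged, start=1):
        attrs = {
            k: v for k, v in it.tx.attributes.items() if k not in ("sources", "consensus")
        }
        if it.cov is not None:
            attrs["cov"] = f"{it.cov:g}"
        if config.track_sources:
            attrs["sources"] = ",".join(str(i) for i in sorted(it.sources))
            attrs["consensus"] = "true" if len(it.sources) >= 2 else "false"
        out.append(
            replace(it.tx, id=f"TSL.{n}", gene_id=f"TSL.{n}", attributes=attrs)
        )
    return out
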