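# Methods

This note records the models, conventions, parameter choices and known
limitations behind the package, at the level of detail a maintainer needs
to change them safely.

## Strand conventions

The simulator fixes the convention used everywhere: the *second strand* is
sense to the source transcript and is rendered
`P1 + sense + polyA + rc(P2)`; the *first strand* is its reverse
complement, `P2 + polyT + antisense + rc(P1)`.  This is a constant of the
package, not a claim about the kit's biochemistry — the stranding pipeline
is symmetric under exchanging the two labels, and `strand --first-strand`
emits the opposite orientation.  What the tests assert is internal
consistency: reads a stranding run emits must end up in one orientation,
and that orientation must match the simulator's truth tags.

Stranding evaluates criteria in a fixed precedence (`P1_HEAD`,
`RC_P2_TAIL`, `P2_HEAD`, then `RC_P1_TAIL` in 4-criteria mode), mirroring
the branch structure of a grep-style pipeline in which a read collected by
an earlier branch is deduplicated away from later ones (first-wins).
Conflicts (criteria of both orientation classes satisfied) are counted and
reported, never silently discarded; precedence still decides the label.
The 3-criteria default omits `RC_P1_TAIL` because that placement is also
the signature of the palindrome artifact: enabling it re-orients artifact
reads inconsistently.  A consequence worth knowing: the 3-criteria
configuration is *not* strand-symmetric (stranding the reverse-complemented
library is only guaranteed to give the same output multiset under 4crit),
and palindromic reads are their own reverse complement, so the symmetry
property is tested under 4crit on an artifact-free library.

## Primer matching

The terminal scan is a Hamming-distance sliding window (substitutions
only): deterministic, exactly reproducible, and fast as a vectorized
comparison.  Defaults: 100 bp windows, ≤ 2 mismatches on the 14-mer
primers, tie-break by fewest mismatches then smallest offset; `N` in a
read always counts as a mismatch; reads shorter than the window are
searched in full, reads shorter than the pattern yield no hit.  With ~6 %
total error a 14-mer primer copy survives a Hamming-2 scan ~80 % of the
time; the loss shows up as stranding *yield* (~83 % of simulated reads are
emitted), not as orientation errors, because a read whose primers are
destroyed is dropped rather than misassigned.  Indel-tolerant matching
would raise yield and is a reasonable extension, left configurable ground:
the Hamming choice is recorded as the package's matching metric.

The artifact screen is the one deliberate exception: it requires `P1` in
the head window *and* `rc(P1)` in the tail window, each within edit
distance 2 (edlib, infix mode).  Requiring two intact 14-mers under a
substitution-only metric would silently miss a large fraction of true
palindromes (one mid-primer indel per copy suffices); edit distance keeps
the per-end miss probability at the ~5 % implied by three or more error
events in 14 bases.  The detector therefore under-reports the injected
artifact rate by the two-ended survival factor (~0.9), e.g. ~5.4 %
estimated at 6 % injected on 20k reads — within a percentage point, which
is the guarantee the acceptance suite checks.

## Self-folding and the palindrome call

RNA-folding-based palindrome detection is replaced by a defined, testable
construction: global Needleman–Wunsch alignment (match +1, mismatch −1,
linear gap −2) of the first half of the read against the reverse
complement of its second half.  Each aligned matching column (i, j) pairs
base i with base n−1−j; monotonicity of the alignment makes the pairing
set nested, so the dot-bracket output is always balanced with a
non-negative mountain ending at zero — properties the tests assert on
random inputs.  The DP kernel is numba-jitted (int32 scores, deterministic
tie-break diagonal > up > left) and cross-checked in the tests against
Bio.Align.PairwiseAligner configured with the same scoring, which serves
as the independent oracle for the optimal score.

The artifact call is `terminal primer pair AND paired_fraction ≥ 0.7`.
The 0.7 threshold was placed against the two distributions the simulator
produces: exact palindromes score 1.0, palindromes at default error rates
score ~0.85–0.95, while the self-fold of unstructured random or ordinary
cDNA reads concentrates near 0.5 (an optimal alignment of two unrelated
halves still matches about half its columns by chance) with a 99th
percentile near 0.56.  The threshold sits in the gap, and because the
primer-pair screen already has a ~10⁻⁴-scale false-positive rate, the
combined false-positive rate on artifact-free and direct-RNA libraries is
effectively zero (< 0.5 % asserted).  Odd-length reads leave the middle
base unpaired.  The mountain profile averages the running sum within 100
equal-width bins; structures shorter than the bin count are linearly
interpolated instead.

## Supplementary filtering and coverage

`filter_supplementary` is the record-level equivalent of
`samtools view -F 2048`, preserving order and never touching records
without the bit.  Coverage counts M/=/X and D blocks as covering the
reference and N (intron) blocks and clips as not, matching spliced
read-to-genome alignment conventions, so the constructed palindromic
primary+supplementary pair shows exact pointwise halving after filtering.
SAM ingestion goes through pysam in text mode with header pass-through;
the CLI `filter-supp` streams lines and only parses the flag field, so
records it keeps are emitted byte-identically.

## Transcript models and class codes

GTF is 1-based inclusive on disk, 0-based half-open in memory; the
conversion lives only in `parse_gtf`/`write_gtf` and round-trips exactly.
Class codes are assigned per query in precedence order
`= > c > k > j > o > s > i > u`, ties within a code resolved by largest
exonic overlap.  Mono-exon equality uses reciprocal overlap ≥ 0.8 (the
threshold is an argument); `s` and `x` are collapsed into a single
antisense code; the codes e/p/r/y/m/n of the wider gffcompare vocabulary
are out of scope.  Loci are connected components of same-strand exonic
overlap, on both the reference side (sensitivity) and the query side
(precision).  TSS/TTS are the strand-respecting span ends in half-open
coordinates; end distances are signed (query − nearest same-strand
reference end), NaN when no same-strand reference exists on the
chromosome.

Segmentation counting: a gene model is *segmented* when a same-strand
merged span it overlaps also overlaps at least one other gene model.  The
before/after comparison in the tests scores both the fragmented input and
the merged output against the same truth-anchored span set
(`consolidate_spans(assembly + truth)`), so the two numbers are
comparable; merging strictly reduces the count on the fixture because
full-length long-read models absorb the fragments that previously
co-occupied a truth span.

## The merge

The six merge rules (pool → collapse identical chains to min/max span →
absorb contained sub-chains → absorb exon-contained mono-exon models →
transitively fuse overlapping mono-exon models at ≥ 30 % of the shorter →
re-id and annotate sources) are this package's definition of strand-aware
merging; they are iterated to a fixed point within each overlap component,
which is what makes the merge idempotent and input-order-insensitive
(output ids are regenerated deterministically in genomic sort order).
The 0.3 mono-exon fusion threshold is a middle ground: any-overlap fusion
over-fuses adjacent genes, containment-only under-fuses fragments.
Unknown-strand (`.`) models merge only among themselves.

Two consequences of the rules are worth stating plainly.  First, a
*contained isoform* — a transcript whose intron chain is a contiguous
sub-chain of a sibling's with its span inside the sibling's — is absorbed;
this is intended (it is how 5'-degraded long-read models are collapsed)
but it means the merged set can carry slightly fewer exact matches than a
long-read input that happened to model both isoforms.  The guarantee the
package makes, and tests, is against the fragmented input.  Second, the
coverage-stringency filter `min_cov` applies to the *merged* models, whose
coverage is the maximum over their contributors.  Filtering the inputs
instead is not monotone — removing a low-coverage model that bridges two
fragments can split one output model into two — whereas filtering the
merged set is monotone by construction, which is the defining property of
a stringency sweep.  `filter_by_coverage` remains available for explicit
input-side filtering.

## The simulator

What it emulates: kit-primer decoration on both strands, ~50/50 strand
presentation, polyadenylation, 3'-anchored truncation (the polyA end
always survives, matching the strong 3' coverage bias of cDNA long reads),
i.i.d. substitution/insertion/deletion errors at 3 %/1 %/2 %, palindrome
artifacts at a configurable rate (6 % default; forced to 0 in direct-RNA
mode, which also drops the primers), a 92-transcript mono-exonic spike-in
ladder in 23 groups of four at 2-fold concentration steps (lengths uniform
on 250–2000 nt), and ~200 genes on a 2 Mb random genome with no
same-strand overlap.  Mono-exonic genes are long (0.5–5 kb) and multi-exon
genes have 2–8 exons of 100–500 nt — the shape of the chromatin-enriched
lncRNA the methods target.  Genes with ≥ 3 exons gain a second isoform
(all but the first intron shared) with probability 0.3; expression is
log-normal (μ = 1, σ = 1 on the log scale).  The assembly fixtures trim
50–200 exonic bases from model ends, split models ≥ 800 exonic bases into
2–3 pieces with ≥ 100-base gaps (probability 0.7), 5'-truncate long-read
models geometrically (p = 0.002, mean ~500 nt) with probability 0.5, and
flip 7 % of long-read strands.

What it does not emulate, hence what passing tests do not show: ONT's
homopolymer-biased, quality-correlated error structure (errors here are
i.i.d.); chimeric/fused reads other than the palindrome artifact; internal
priming; abundance-dependent coverage shape beyond the truncation model;
real intron/exon length distributions or sequence composition.  Accuracy
numbers on simulated data are therefore upper bounds with respect to those
effects, while the structural guarantees (balance/nesting, monotone
sweeps, idempotence, strand separation) are data-independent.

All generators are pure functions of (config, seed); each one draws from
its own fixed stream (`default_rng([seed, k])`) so regenerating one output
never perturbs another.

## Problem sizes and numerical choices

The end-to-end checks run at the study's default size: 20,000 reads from
the spike-in ladder, seed 42; stranding takes a few seconds and the full
per-read fold of the artifact scan ~20 s (the DP is O((n/2)²) per read).
Fixture-level merge and comparison tests use an 80-gene, 0.8 Mb bundle.
Degenerate inputs are defined rather than rejected wherever a convention
exists: empty libraries report stranding rate 0 and restrand fraction 1.0
with a zero-count flag, zero-denominator sensitivities report 0 with an
`*_undefined` flag, reads shorter than the pattern simply do not match,
and reads shorter than 2 bases skip folding with paired fraction 0.

## Known limitations

- The Hamming-2 stranding scan trades ~17 % yield for exactness at default
  error rates; the artifact screen compensates with edit distance, but the
  detector still under-reports prevalence by the primer-survival factor.
- The merge has no abundance re-estimation; `cov` is propagated as a
  maximum, not recomputed from reads.
- Class-code parity with gffcompare is limited to the eight codes above;
  mono-exon `=` at 0.8 reciprocal overlap is a recorded convention, not a
  published constant.
- The palindrome fold asserts separation of paired-fraction distributions,
  not per-read equivalence with thermodynamic structure prediction.
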