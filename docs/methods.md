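# Methods

This note documents the models and algorithmic choices behind varbench:
what each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical/tie-breaking
decisions that make results deterministic.

## Coordinates and formats

`VariantRecord.pos` is 1-based (VCF); all region and depth arithmetic is
0-based half-open (BED). The conversion happens in exactly one place — the
`pos0` accessor used by variant↔region queries — so off-by-one errors
cannot accumulate. `RegionSet` is always maximally merged (sorted,
disjoint, non-adjacent), so two sets covering the same bases compare
equal; `DepthTrack` is a run-length encoding with equal-depth adjacent
runs merged and implicit depth 0 outside all runs.

VCF and SAM are parsed with pysam/htslib, FASTA with Biopython. By
default only records with FILTER `PASS` or `.` are evaluated (the
community default; `include_filtered` evaluates everything). Contig names
are matched exactly — no silent `chr` aliasing; the precheck diagnoses
prefix mismatches instead. Symbolic alleles (`<DEL>`, breakends, `*`) are
rejected with a clear error; only A/C/G/T/N sequence alleles are
evaluated.

Depth from alignments counts a base as covered when a read with
MAPQ ≥ `mapq_min` (default 60) spans it with a reference-consuming CIGAR
operation. M/=/X/D count toward depth — a spanning deletion is still
physical coverage, matching the default of standard depth tools — while N
(intron skip) advances without counting and I/S/H/P consume no reference.
Unmapped, secondary and supplementary alignments are excluded.

## Stratification

The default scheme is low [0,10), medium [10,31), high [31,∞) — i.e. the
inclusive depth bands 0–9, 10–30, >30. Strata must be contiguous from 0
and cover all depths, so every base belongs to exactly one stratum.
Quantized regions are intersected with the confident regions and, when
given, the capture target. Note the low stratum deliberately conflates
"few reads" with "many uncertain reads": under a MAPQ-60 filter, a
well-covered but ambiguously mapped region quantizes as low. No separate
mapping-uncertainty stratum exists.

A variant is assigned to the stratum of the 0-based position of its first
REF base (its anchor). Variants spanning a stratum boundary are not
duplicated or split — a single-anchor rule keeps per-stratum counts a
partition of the whole-region counts. Variants outside all strata are
excluded from evaluation entirely (not counted FP or FN); this is
standard practice for calls outside confident regions.

Truth variants are stratified with the *same* depth track as the queries,
so per-stratum FN counts are depth-conditional — without this, per-stratum
recall would be meaningless.

## Normalization

Atomization decomposes a complex replacement (both alleles longer than
one base) into SNVs and anchored indels via Needleman–Wunsch global
alignment of REF vs ALT with match +1, mismatch −1, gap −2, and traceback
preferring diagonal moves from the end so tied gaps land leftmost.
Mismatch columns become separate SNV atoms (no MNV atoms); each gap run
becomes one indel atom anchored on the preceding reference base and then
left-aligned, with the shift bounded by the previous atom of the same
record so atoms never collide. Applying all atoms of a record to the
reference reproduces applying the original record exactly (tested as a
property, and against bcftools `norm` as an independent oracle).

Multiallelic genotypes are projected per alt: supported twice → hom, once
with a ref partner → het, once with an other-alt partner → a *half-call*
("1/."). The half-call survives so that a wrong-alt genotype can be
counted as a genotype mismatch rather than silently passing. Projections
an observed genotype does not support are dropped as non-variants.

Deduplication removes atoms identical in (contig, pos, ref, alt,
genotype). Atoms identical in allele but differing in genotype both
survive — the source of `TP_query > TP_truth` when several records imply
the same truth allele.

## Haplotype-aware matching

Atoms within 30 bp of each other (transitive closure; `gap` parameter)
form a superlocus. Within each superlocus the comparator enumerates, per
side, every subset of distinct alleles and every placement of each
selected allele onto the two haplotypes allowed by its genotype —
genotyping mode: het on exactly one haplotype, hom on both, half-call on
one, missing genotype unconstrained; calling mode: any placement —
skipping placements where alleles overlap on one haplotype. Each
assignment yields a *diplotype*: the unordered pair of haplotype
sequences over the superlocus window (one base of context each side). A
query assignment matches a truth assignment when their diplotypes are
equal.

Among all matching pairs the comparator picks the one maximizing matched
truth atoms, then matched query atoms, then genotype-concordant pairs,
then the lexicographically smallest matched position set — a fully
deterministic tie-break. Unselected query atoms whose allele equals a
matched truth allele are still TP (duplicate counting); remaining
unmatched query atoms are FP and unmatched truth atoms FN. Genotype
concordance of a matched pair compares zygosity classes (het/hom/half);
when a match arises through two *different* but haplotype-equivalent
decompositions, per-atom concordance is taken as true in genotyping mode
(diplotype equality certifies the genotypes collectively) and left
undefined in calling mode, where it is excluded from the mismatch count.

Superloci with more than 8 distinct alleles on a side (cap, ~4^8
assignments) fall back to exact (pos, ref, alt) matching and are flagged
in the output. Phase sets are ignored and ploidy is fixed at 2.

The enumeration was validated against an independent brute-force oracle
(direct product over all assignment pairs) on hundreds of random
superloci. That oracle exposed one corner case worth documenting: a
smaller query atom set can match a *larger* equivalent truth decomposition,
making `tp_truth > tp_query` at atom level in that superlocus. Counts are
reported honestly rather than clamped; with both sides normalized the
same way the familiar `TP_query ≥ TP_truth` holds.

## Metrics

precision = TP_query/(TP_query+FP), recall = TP_truth/(TP_truth+FN),
F\* = TP_query/(TP_query+FP+FN). The genotype-mismatch fraction uses
calling-mode allele matches as its denominator: genotyping-mode TPs are
concordant almost by construction, so the calling-mode count is the
informative one; the raw counts are reported next to it so any other
denominator can be recomputed. Metrics with zero denominator serialize as
"." — an empty stratum must look empty, not perfect.

## Label association

For each variant that is an FP (FN) in at least one callset, a 2×L
contingency table counts callsets with/without that error per label
value; Pearson χ² without continuity correction gives a p-value with
L−1 df. Constant patterns (error everywhere or nowhere) carry no
information and are assigned p = 1; single-valued labels are skipped. The
table construction is an interpretation — the presence/absence-by-label
table is the natural reading of "testing the error pattern against the
labels" — and is documented here because other constructions (e.g.
per-pair) exist. No minimum-expected-count guard is applied: small tables
are the norm with tens of callsets, the exact p-value is still
well-defined, and the FDR correction absorbs the noise; tables with
expected counts < 5 are flagged (`low_expected`) rather than suppressed.

FDR control uses Benjamini–Yekutieli (q = min over j≥i of
m·c(m)·p(j)/j, c(m) = Σ 1/k), valid under the arbitrary dependence
expected between variants on the same or different haplotypes. The
correction family is one (label name, error kind) pair — the most
conservative scoping consistent with reporting one table per label. FP/FN
patterns are taken from calling-mode results, the superset view of
errors. Variants excluded from a callset's evaluated regions count as
error-absent, not missing.

## Synthetic fixtures

The generator emulates the shape of an exome-style benchmark at desk
scale: a uniform-random reference (default 100 kb), a diploid truth set
(default 500 variants, mix 70% SNV / 10% ins / 10% del / 10% complex,
60% het, ≥15 bp spacing), confident regions covering ~97% of the
reference with gaps that exclude some variants, and a depth track tiled
through the three strata in 300 bp runs (depths drawn from 0–9, 10–30,
31–60).

Callsets are derived from the truth by independent per-variant errors:
drops at per-stratum `fn_rate` (defaults 0.30/0.10/0.05 for
low/medium/high), spurious het/hom SNVs at per-stratum `fp_rate`
(defaults 0.15/0.05/0.02, drawn uniformly from confident in-stratum bases
away from truth variants), het↔hom genotype flips at `gt_error_rate`
(0.05), merging of adjacent same-genotype pairs into complex replacements
at `complex_merge_rate` (0.10), and right-shifted re-encoding of indels
at `right_shift_rate` (0.30). The last two change representation, not
content — they exercise atomization and left-alignment and must not change
any count. Planted label-associated FP sets are inserted verbatim into
every callset sharing a label value. Each artifact draws from its own
seed-derived stream, so adding a callset never perturbs another and
fixtures are byte-reproducible.

Because FPs are drawn from confident in-stratum bases and drops are
per-variant Bernoulli, the configured rates map onto closed-form
expectations — calling-mode recall = 1−fn, precision =
(1−fn)/(1−fn+fp), genotype-mismatch fraction = gt_error_rate — which the
test suite recovers within 3 binomial standard errors at 2000 truth
variants (simple-variant mix, so atoms correspond 1:1 to records and the
record-level rates are exact atom-level expectations). The planted-
association experiment uses 10 callsets, 200 truth variants and sparse
background errors (fp 0.01, fn 0.05 per stratum): with ~20–40 tests in
the FDR family, a perfectly caller-separated pattern (p ≈ 1.6·10⁻³ at
5 vs 5 callsets) clears q ≤ 0.05 after the BY penalty, which is what the
experiment is designed to demonstrate.

What the generator does **not** emulate: read-level sequencing error,
alignment artifacts, indel-rich repeat structure, GC bias, clustered
errors, population structure. Passing tests therefore demonstrate the
*accounting machinery* — normalization, stratification, matching,
counting, FDR control — not performance claims about real callers on real
genomes.

## Problem sizes

Test and acceptance runs use 100–2000 truth variants on 100–120 kb
references, hundreds of random superloci for oracle comparisons, and 10
callsets for association experiments — sizes chosen so the whole suite
exercises every code path in well under a minute while keeping binomial
error bars tight enough for 3-SE assertions.

## Known limitations

- Ploidy is fixed at 2; phase sets (PS) are ignored across superloci.
- Over-cap superloci (>8 distinct alleles per side) use exact-match
  fallback; dense clusters in repeats may be under-matched there (flagged
  per annotation).
- The genotype of a half-call matches only the present allele; concordance
  with a full het is counted as a mismatch by design.
- BED/BED-graph inputs must be 0-based half-open and non-overlapping
  (BED-graph); no liftover or contig aliasing is performed.
- An indel atom at the very first base of a contig cannot be
  left-anchored and is rejected.
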