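# Methods

## Problem and approach

Short-read SV callers disagree enough that asking "does any sample in a large
cohort show raw alignment support for this SV?" is often more robust than
comparing call sets.  `svidx` answers that question the way a population
evidence index does: per sample, every *discordant* alignment — a read pair
whose mapped separation, orientation or chromosome pair violates the fragment
model, or a read split across a junction — is extracted into a compact sorted
interval file; the per-sample files are combined into one searchable index;
and an SV query returns, for every sample, the count of alignments consistent
with that SV's breakpoints and strand signature.  Raw evidence counts across
a panel of normals then support downstream judgements such as "this tumor
call is a common germline variant, not somatic."

## Evidence model

An alignment is paired-end evidence when any of the following holds:

* mates map to different chromosomes;
* the genome-ordered strand configuration is not `+/-`;
* the outer span (rightmost end minus leftmost start) exceeds the
  *discordant distance* `D`.

`D` defaults to 500 bp and, when fit from data, is `round(mean + 2·sd)` of
the concordant fragment length distribution (computed with the population
form of the standard deviation; at the 10^5-pair sample sizes involved the
distinction from the n−1 form is immaterial).  An alignment carrying a
supplementary segment is additionally split-read evidence.  Secondary,
duplicate, and QC-fail records are dropped; no mapping-quality threshold is
applied by default.  Each template contributes at most one paired-end record
(emitted from the genome-leftmost primary, ties to read 1) while each
split-bearing read contributes its own split record.

**Breakpoint padding.** A discordant `+` alignment points downstream at a
junction that must lie within `D` of its start, and a `-` alignment points
upstream symmetrically.  Paired-end record end-intervals are therefore padded
— a `+` end to `[start, start + D)`, a `-` end to `[end − D, end)`, clamped
at zero — so that a breakpoint anywhere the fragment could span overlaps the
stored interval.  This makes the query-side extension rules sufficient to
recover all true support, which the zero-noise recovery tests verify
end-to-end.  When both ends of a `-/-` pair have unequal clipped spans the
padded starts can come out of genome order; ends are re-ordered after
padding (the strand pair is symmetric, so nothing else changes).  Split
record ends are exact segment spans, never padded.

Evidence files hold 9 tab-separated columns — left chrom/start/end/strand,
right chrom/start/end/strand (strands `1`/`-1`), class (`0` paired-end, `1`
split) — 0-based half-open, sorted by (left chromosome bytewise, left start,
left end), bgzip-compressed when the path ends in `.gz`.  Chromosome names
compare bytewise throughout (C-locale: `"10" < "2" < "X"`).

## Index

Per chromosome, end intervals are kept in arrays sorted by start with a
running maximum of interval ends; a probe prunes with two binary searches and
scans the remainder.  Each record is entered under *both* end intervals so
interchromosomal evidence is findable from either side; the query layer
deduplicates.  This is result-equivalent to an interval tree and trivially
auditable against the package's deliberately naive linear-scan twin
(`BruteForceSearcher`), which applies the same half-open overlap predicate to
every stored end.  The persisted form is a versioned directory of text
shards plus a JSON manifest; fidelity to any external index format is a
non-goal, only result equivalence.

## Query semantics

A query gives an SV type and two breakpoint intervals in genome order (the
left breakpoint on the bytewise-smaller chromosome or at the smaller
position; out-of-order BND input is swapped with a warning).  Breakpoints are
widened by a window `w` (default 500 bp, recommended equal to `D`):
deletions extend left downstream and right upstream; duplications the
opposite; inversions run two sub-queries, both breakpoints extended
downstream for the `+/+` sub-query and upstream for `-/-`; break-end probes
are unchanged.  A record supports the query when its left end overlaps the
widened left breakpoint, its right end overlaps the widened right
breakpoint, and its strand pair matches the type's signature (see the table
in `svidx.query_engine`).  The inversion sub-query sign is pinned only for
paired-end records; a split record (whose signature is `+/-` or `-/+`) is
accepted under whichever sub-query it overlaps, and per-record deduplication
ensures nothing is counted twice — across sub-queries or across the
double-entered index.  Every database sample appears in the result, zeros
included.

## Synthetic cohorts

The simulator is coordinate-level by design: strands and positions are
computed analytically from the haplotype→reference segment map, which is
deterministic, fast, and isolates index/query correctness from aligner
behaviour.  Per sample and haplotype, each chromosome becomes an ordered
segment list with the carried SVs applied; a carried break end adds a fusion
contig of 2 kb flanks from both partner chromosomes.  Fragments are placed
uniformly along each contig at `coverage/2` per haplotype, with lengths
`N(mean, sd)` truncated to `[max(2·read_length, mean − 3sd), mean + 3sd]` —
a standard truncation that also keeps the concordant tail from leaking past
the default discordant distance.  Reads crossing a junction with ≥ 20 bp on
both sides become split reads; shorter overhangs are clipped to the major
side, as an aligner would soft-clip them.  Noise replaces read 2 of a
configurable fraction of templates (default 4%, capped below 5%) with a
uniformly random placement and strand, emulating nonspecific discordant
alignments.

Defaults of the benchmark cohort (`default_test_cohort`): 20 samples, two
2-Mb chromosomes, 30 SVs (10 DEL, 10 DUP, 8 INV of 200–5,000 bp, 2
interchromosomal BND) spaced ≳ 120 kb apart, genotypes Hardy–Weinberg at
allele frequencies uniform in [0.05, 0.5], 10× coverage, 300 ± 50 bp
fragments, 100 bp reads, discordant distance 500.  Per-sample RNG streams
are keyed by `(seed, crc32(sample_id))`, so extending a cohort never
perturbs existing samples.

Simulated streams can be written as valid SAM (flags, RNEXT/PNEXT/MC,
SA-linked supplementary records, no sequence); extraction from the SAM round
trip is byte-identical to in-memory classification, and the vectorized
extraction used for large cohorts is byte-identical to both (tested).

**What the simulator does not model** — and hence what passing tests do not
show about real data: base errors and mappability (noise is uniform, not
locus-correlated), GC/coverage bias, micro-homology and imprecise breakpoints,
dispersed or inverted duplications, multi-allelic loci, and tumor
subclonality.  Real-data accuracy will be bounded by alignment artifacts
that cluster at specific loci, which uniform noise underestimates.

## Evaluation procedures

* **Classification**: for each known variant, samples with ≥ 1 supporting
  alignment are predicted carriers; P/N/TP/TN/FP/FN are pooled per SV type
  and accuracy, precision, sensitivity, specificity and F1 derived.
  Undefined ratios (zero denominators) are NaN and print as `NA`, never 0.
* **Reciprocal overlap**: `min(shared/len(a), shared/len(b))`, threshold 0.9
  boundary-inclusive, types compared separately; set intersection matches an
  element of A when *any* element of B passes (bedtools-style many-to-one,
  no assignment), verified against a quadratic scan.
* **Germline filtering**: tumor calls with fewer than a threshold (default 1)
  supporting cohort samples pass the filter; FP/TP/FN are scored against the
  somatic truth set at 0.9 reciprocal overlap.  Whether evidence in a single
  cohort sample should suffice is genuinely open; the threshold is a
  parameter.
* **Resolution sweep**: both breakpoints shifted jointly (preserving the SV
  span) in 50-bp steps to ±500 bp; support at each shift is expressed as a
  proportion of the unshifted query's supporting samples, and curves are
  summarized by per-shift medians.  Zero-support queries are undefined and
  excluded.  With window 500 and fragments capped at 450 bp, geometry forces
  the proportion to 0 beyond a 950 bp displacement — the sweep tests assert
  exactly that.

## Numerical and scale choices

Problem sizes used by the test suite and the acceptance script: the
benchmark cohort is ~4 × 10^6 templates and ~1.6 × 10^5 evidence records
(≈ 4.1% of templates, consistent with the < 5% discordant fraction typical
of short-read libraries); oracle equivalence uses 1,000 random probes and
1,000 random queries; noisy-recovery accuracy averages 5 independent
cohorts; germline filtering uses 50 + 50 calls over a 10-sample panel.  A
full pipeline run on one cohort takes a few seconds on one CPU; the entire
acceptance script completes in well under a minute.

Known limitations: insertion evidence is out of scope (deletions,
duplications, inversions and break ends are indexed); CRAM input is not
supported; genotype likelihoods, allele-frequency inference and copy-number
estimation are deliberately absent — the tool reports raw per-sample counts.
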