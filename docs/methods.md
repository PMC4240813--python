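# Methods

This note documents the models and procedures `indelqc` implements, the
defaults it ships, and the choices made where the design was genuinely open.

## Variant model and left-normalization

An `IndelCall` is a biallelic insertion or deletion in anchored VCF
representation: 1-based position of the anchor base, uppercase allele
strings, size = |len(ref) − len(alt)| ≥ 1.  SNP/MNP and symbolic-allele
records are rejected at construction and dropped (with counts) at VCF read.
"Large" means size > 5 bp, a strict inequality: a 5 bp call is not large.

Left-normalization uses the standard align-and-trim procedure: shared
trailing bases are removed, extending leftward from the reference whenever
an allele empties, then shared leading bases are trimmed down to one anchor
base.  The result is the unique maximally left-shifted, minimally trimmed
representation; the operation is idempotent and preserves the alternate
haplotype (both properties are tested against a brute-force enumeration
oracle on 1,000 random repeat-rich windows).  A variant abutting position 1
of a contig anchors on the base *after* the event, per VCF convention.
Matching and region membership always operate on normalized calls; the
match predicates refuse un-normalized input.

Coordinates are 1-based anchored (VCF) inside the data model and half-open
0-based (BED) in `RegionSet`; conversion happens only at those two
boundaries.  Region membership uses the anchored position only, not the
deleted span — the simplest defensible reading of positional intersection,
kept as a single convention.  Duplicate (chrom, pos, ref, alt) records
collapse keeping the record with the highest alternate coverage.

## Quality score and three-tier classification

The k-mer Chi-Square score compares observed per-allele coverages against a
balanced expectation C_e = (C_o^Ref + C_o^Alt)/2:

    chi2 = (C_o^Ref − C_e)²/C_e + (C_o^Alt − C_e)²/C_e

It is symmetric, non-negative, zero iff balanced, and algebraically equals
(C_o^Ref − C_o^Alt)²/(C_o^Ref + C_o^Alt).  The degenerate all-zero pair
scores 0 with a logged flag.  Tests cross-check the implementation against
scipy's equal-expectation goodness-of-fit statistic on a full integer grid.

Default tier cutoffs (`QualityThresholds`): high iff (C_o^Alt > 10 and
chi2 < 10.8) or (5 < C_o^Alt ≤ 10 and chi2 ≤ 4.5) or (C_o^Alt ≤ 5 and
chi2 ≤ 2); low iff C_o^Alt ≤ 10 and chi2 > 10.8; moderate otherwise.  The
boundary semantics are preserved exactly as the criteria were published —
strict "<" against 10.8 in the high tier, "≤" against 4.5 and 2 — so the
point (C_o^Alt = 11, chi2 = 10.8) is moderate, and a call with C_o^Alt > 10
can never be low no matter how large its score.  We deliberately did not
smooth this asymmetry; fidelity to the validated rule wins over elegance.
The cutoffs are constants of the shipped default, not re-derived; all five
are overridable.

PPV = 100·TP/(TP + FP), reported to one decimal.  The validity predicate
used against truth data is configurable: exact-match, position-match, or
validation-match (position plus the same variation type, the rule used when
scoring calls against amplicon re-sequencing truth).  The published error
rates behind the tier names (7% high, 51% low) were measured on wet-lab
validation data; this package applies the classification and can reproduce
those separations only on synthetic data with planted error rates.

## Concordance

`compare_callsets` reports intersection / A-specific / B-specific counts and
percentages over the union, to one decimal.  With a depth floor, loci whose
depth at the anchored position is below the floor in *either* set are
removed from both sides first; a locus missing from a depth map counts as
depth 0 (logged).  Per-locus depth is the depth at the anchor base, not
averaged over the deleted span.

In position mode, a position carrying k ≥ 2 distinct signatures in one set
counts once toward the intersection (when the other set also calls the
position) and contributes its k − 1 surplus signatures as set-specific, so
the three counts always partition the union.  Multi-sample summaries report
the unweighted mean and sample SD of per-sample rates; a single sample has
mean but undefined SD (`None`).

A *multiple-signature locus* is any position carrying ≥ 2 distinct
(ref, alt) pairs in a (union) call set; assuming at most one true variant
per position, surplus signatures are presumptive false calls.

## Repeat context

`find_homopolymers` reports maximal single-base runs ≥ 5 bp (N excluded).
`find_strs` reports maximal perfect tandem tracts with primitive 2–6 bp
motifs, ≥ 3 copies (fractional trailing copies count) and span ≥ 8 bp.
These declared defaults make the method self-contained; they approximate,
and do not reproduce, external STR reference catalogs.  Both detectors are
tested for equality with exhaustive brute-force oracles on 1,000 random
200 bp windows with planted (including edge-spanning) tracts.

`annotate_context` scans ±50 bp of reference around the variant interval
(deletions span the deleted bases; insertions are the point between anchor
and next base) and assigns exactly one of six labels: poly-A/C/G/T if the
interval intersects or lies within 1 bp of a homopolymer (largest-overlap
tract decides the base; ties break to the nearest, then leftmost), else
other-STR, else non-STR.  The 1 bp adjacency gap lets an insertion that
extends a tract count as inside it; it is a parameter.  The homopolymer base
is the reference-strand base — poly-A and poly-T stay distinct, with a
poly-A/T aggregate also reported.  Context derives from regional
intersection with reference tracts, not from the inserted/deleted allele
composition; the alternative (allele-based assignment) would differ mainly
for insertions of foreign sequence inside a tract.

Region helpers: `expand_regions(exons, pad=20)` builds capture targets
padded over splice sites; `flank_regions(calls, pad=25)` builds merged
±25 bp windows around call positions for coverage profiling.

## Coverage statistics

CV = 100·(1 + 1/(4n))·(s/x̄) with s the n−1 sample SD.  The small-sample
correction factor is kept for exactness but is negligible at the region
sizes the statistic is meant for (n > 10⁴, relative effect < 1/(4n)); a
Monte-Carlo test at n = 10⁶ confirms both the recovery of a known CV and the
vanishing correction.  CV requires n ≥ 2 and positive mean; both violations
are hard errors.  Coverage fraction at X is the proportion of bases with
depth ≥ X, non-increasing in X; profiles report the curve for X = 1..51.
Depth input is a plain (chrom, pos, depth) TSV — per-base positions are
1-based — with missing bases counted as depth 0 and logged; the statistics
take whatever depth file they are given (raw or duplicate-removed) and do
not second-guess its provenance.

## Downsampling sensitivity

Re-aligning and re-assembling reads at every coverage level is out of scope
by design.  The surrogate: each call's cov_ref and cov_alt are independently
binomially thinned at rate target_mean/full_mean, and a call is *detectable*
while cov_alt ≥ 3 (the usual micro-assembly minimum-coverage floor).  The
denominator of every curve is the set of truth calls detectable at full
coverage, so sensitivity at the full level is 1 by construction.  Curves
average a configurable number of thinning replicates (default 25) with SD.
Full coverage is an explicit input, never inferred.  This surrogate
reproduces the qualitative structure of read-level downsampling — curves
rise with coverage, heterozygous calls (alternate allele ≈ half the locus
depth) trail homozygous ones, and the coverage needed for 95% sensitivity is
higher for heterozygotes — but absolute coverage requirements measured on
real data (e.g. a specific X for 95%) are *not* claimed reproducible here.

## Synthetic-data generator

The generator exists so that every pipeline stage has a test surface with
known ground truth.

*Reference*: random uniform background, scrubbed of incidental repeat tracts
(a detected tract gets one interior base mutated until a fresh scan is
clean), then the requested (motif, span, count) tracts are planted with
≥ 12 bp spacing and boundary bases chosen to break the repeat.  Planted
tract coordinates therefore equal detector output exactly.

*Truth INDELs*: n calls with unique normalized positions.  Context mix
defaults to 12% poly-A, 12% poly-T, 2% poly-C, 2% poly-G, 12% other-STR,
60% non-STR — a homopolymer-A/T-heavy mix consistent with exonic INDEL
profiles.  Sizes default to geometric(p = 0.35) truncated to 1–100 bp,
spanning the 1–100 bp range with a realistic small-indel skew (~12% > 5 bp);
repeat-context deletions clip to their tract.  Zygosity is heterozygous with
probability 1000/1635 ≈ 0.61 (the ~1.6:1 het:hom ratio of diploid truth
sets).

*Platform call sets*: per-locus depth is negative binomial with the
profile's (mean, CV) — overdispersion reproduces capture skew; at or below
Poisson variance the model falls back to Poisson.  Heterozygous alternate
coverage is Binomial(depth, 0.5); homozygous calls take the full depth;
calls with zero surviving alternate coverage vanish.  Capture dropout
removes whole 1 kb windows at the profile's dropout fraction (depth 0);
large (> 5 bp) truth calls are additionally lost at the capture penalty.
False calls are injected per context at the profile's false-call fraction,
placed inside matching tracts, with reduced depth (0.3× mean — errors
concentrate where sequencing is poor) and a low alternate-allele fraction
(Binomial(depth, 0.12)) that inflates their Chi-Square scores.  Every
emitted call carries a hidden truth label.  Shipped profiles: WGS-like
(mean 71X, CV 39.4%), WES-like (mean 337X, CV 109.3%, 16% dropout, 70%
large-INDEL penalty, poly-A/T false-call fraction 0.45) and PCR-free-like
(50X, CV 35%, damped homopolymer error rates); the coverage figures follow
published exonic summaries of those platform types.

`generate_quality_benchmark` is a separate, smaller generator for the
classifier: coverage pairs are rejection-sampled until they land in the
requested quality tier (high-tier calls spread over all three coverage
bands), and truth labels are Bernoulli with the planted per-tier error rate
(defaults 7%/51%), so empirical per-tier PPV recovers the planted rates up
to binomial noise.

What the generator does **not** emulate: read-level errors, alignment and
assembly artifacts, imperfect/interrupted repeats, GC bias, real capture
geometry.  Passing tests on synthetic data therefore demonstrate the
correctness and the directional behaviour of the analyses (concordance
rising with depth floors, poly-A/T enrichment among low-quality calls,
zygosity-ordered sensitivity), not the absolute error or concordance rates
of any real platform.

## Problem sizes and determinism

Test and acceptance runs use desk-scale inputs chosen to make Monte-Carlo
assertions stable: 100 kb references with a few hundred planted tracts,
400-call truth sets, 500 calls per tier in the classifier benchmark, 1,000
truth calls × 25 replicates for sensitivity curves, and 1,000 random windows
per detector-oracle comparison.  All randomness flows through seeded numpy
Generators; generator outputs are byte-identical under a fixed seed, and the
CLI records every seed in its output manifests.

## Known limitations

- Haplotype-aware equivalence beyond left-normalization (variant
  decomposition/recomposition) is out of scope; two calls representing the
  same haplotype through different event combinations will not match.
- The STR detector models perfect tandems only.
- Zygosity is read from a configurable VCF field and may be unknown;
  unknown-zygosity calls are excluded (with a logged count) from stratified
  sensitivity.
- The sensitivity surrogate operates on coverages, not reads; see above.
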