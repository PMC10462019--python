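# Methods

This note documents the models behind each module, the defaults that
matter, the numerical choices, and the limits of what the synthetic
benchmarks demonstrate.

## Coordinate conventions

All internal coordinates are 0-based half-open; conversions to 1-based
inclusive conventions (`show-coords`-style tables, RepeatMasker `.out`,
VCF positions) happen only in `io_formats`. RepeatMasker's "C" strand is
normalized to "−", and per-copy divergence is taken from the `.out`
"% div" column as-is (no CpG or multiple-hit correction; if a corrected
column is wanted it can be substituted upstream, the analytics only see a
number per hit).

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
sequencing realism.

- **Background sequence** is i.i.d. with a chosen GC fraction (default
  0.40, a typical Drosophila euchromatin value). Randomness guarantees
  effectively unique flanks at the scales used.
- **Repeat copies** are a family consensus mutated by i.i.d. substitutions
  at target divergence *d* (no indels). Substitution-only mutation keeps
  divergence and coordinates exact, so truth records can state the realized
  divergence of every copy. Tandem arrays are head-to-tail monomer
  concatenations truncated to a length drawn uniformly from the configured
  range; the default 0.5–10 kb band matches the medium-length tandem arrays
  (ITRs) these analytics target. Copies overwrite the background in place,
  so planned coordinates never shift. Placement keeps a 2.5 kb clear margin
  between features by default, which also makes planted arrays eligible for
  the insertion caller's 1 kb clean-flank rule.
- **Inversions** replace a block with its reverse complement. Length is
  conserved exactly; base content is conserved up to the A↔T / C↔G swap a
  reverse complement implies. Blocks must be ≥ 2 kb so they survive the
  1 kb span filter and are detectable. Truth records the two block
  boundaries as breakpoints.
- **Sex-specific reads** are single-end, uniformly placed, with copy
  numbers female = {autosome 2, X 2, Y 0} and male = {2, 1, 1}; read counts
  are Poisson around depth × copies, positions uniform, strands random,
  substitution errors at 0.2 % per base by default. The expected
  female/male depth ratio is therefore 1 (autosome), 2 (X) and 0 (Y).
  There are no read pairs, quality profiles, or coverage biases, so these
  libraries validate ratio and k-mer logic, not mapping robustness.
- **Haplotypes** use a per-site categorical model rather than a coalescent:
  each site is independently a fixed between-population difference (prob.
  d_b), polymorphic within one population, or invariant. A within-
  population polymorphic site gets a derived-allele count uniform on
  1..n−1; the polymorphic-site rate is θ·3(n−1)/(n+1), which makes the
  expected pairwise diversity exactly θ (the mean heterozygosity of a
  uniform-count site is (n+1)/(3(n−1))). One category per site means
  mutation placements never collide. Note D_xy in this model equals d_b
  *plus* the cross-population contribution of within-population
  polymorphism (≈ θ/2 per population); recovery tests for D_xy therefore
  plant d_b with θ = 0. There is no linkage, recombination or demography —
  window-to-window variance is pure sampling noise.

Passing tests on these data show the estimators and callers implement
their definitions and recover planted parameters; they do not show
robustness to indels, structural noise, alignment error, or non-equilibrium
population structure.

## Segment alignment

A desk-scale anchor aligner stands in for a whole-genome aligner. Canonical
k-mers (k = 31) occurring exactly once in *each* genome are the anchors;
repeat-induced multi-copy seeds are discarded outright, so repeats cannot
seed spurious segments (the unique-anchor policy of anchor-based aligners).
Anchors sharing a diagonal merge into exact runs; runs chain greedily when
reference and query gaps are both ≤ 2 kb and query order is consistent with
the strand, ties broken by most matched bases then smallest start. Identity
is matched bases over the chained span. On substitution-free genome pairs
segments reach 100 % identity and abut breakpoints to within the seed
length; on diverged genomes the unique-anchor density, not the chainer, is
the limiting factor. The filter defaults — matches < 100 bp dropped, then
identity < 90 % or span < 1000 bp — read the span clause strictly: a
segment must reach 1 kb in *both* sequences to survive, which keeps
repeat-scale micro-segments away from the breakpoint caller.

## Rearrangement calling

Filtered segments are scanned per reference contig in reference order and
grouped into co-linear runs (same query contig, same strand, query gap
consistent with the reference gap to within 5 kb). A "−" run whose query
coordinates are reverse-co-linear, sitting in a same-query context, is an
inversion; a run on a different query contig than its neighbours, or a
displaced block without a strand flip, is a translocation (reciprocal
pairing of translocations is not attempted). A single long "−" segment
suffices for an inversion call — a clean inversion yields exactly one
reversed segment after chaining.

The breakpoint interval on each side is the span between the run's
outermost segment and its flanking segment, taken as (min, max) of the two
boundary coordinates: with junction micro-homology the aligner can extend a
few bases past the true breakpoint, and the min/max form makes the interval
cover the homologous stretch where the breakpoint is genuinely ambiguous.
Runs at contig edges get breakpoints clipped to [0, contig length] and a
`terminal` flag. An inversion whose query-side gap to a flank differs from
the reference-side gap by more than 1 kb is flagged `nested`: it sits
inside a wider rearranged context (e.g. composed inversions), which the
caller marks but does not attempt to resolve into an event series.

Calls from several strains against one reference merge into a
presence/absence matrix when both breakpoint intervals reciprocally
overlap, with a 100 bp slop so that zero-width (exactly pinned) intervals
from different strains can still match.

## Breakpoint element enrichment

Breakpoint intervals intersecting an annotated repeat are extended to the
repeat's full called extent, transitively to a fixed point, then merged.
Content percentages are intersection bp over total extended bp, computed on
merged intervals so overlapping annotation never exceeds 100 %. The
permutation test redraws each interval uniformly on its own contig at its
own length (same-contig matching controls composition confounding),
applies the same extension, and sums focal-family bp; permuted regions may
overlap each other. The one-sided p-value uses the add-one correction
p = (#{permuted ≥ observed} + 1)/(n + 1), so p is never 0 and equals
1/(n+1) when no permutation reaches the observed value. With heavily tied
statistics (e.g. few, equal-length elements) the add-one p is conservative
rather than uniform under the null; the calibration test uses
variable-length elements so the statistic is effectively continuous.

## Y/X/autosome classification

Two independent evidence axes per contig:

1. **k-mer subtraction** — canonical 15-mers with genome-wide count exactly
   one are the contig's single-copy set; the statistic is the percentage of
   that set absent from the female read k-mer set. Female k-mers are
   counted after masking bases below quality 5, and must occur ≥ 2 times —
   at 0.2 % error and ≥ 20× coverage, singleton error k-mers would
   otherwise rescue Y contigs. An empty single-copy set flags the statistic
   as undefined rather than 0.
2. **depth ratio** — per-base depth from an exact-seed placer (unique
   31-mers at up to three offsets per read, so one substitution error
   cannot unplace a read); ratio = mean female / mean male, undefined when
   male depth is 0. An external per-base depth TSV is accepted in place of
   the internal placer.

Call thresholds (Y: ratio ≤ 0.25, unmatched ≥ 75 %, ≥ 500 single-copy
k-mers; X: ratio 1.6–2.4 and unmatched ≤ 25 %; autosome: ratio 0.7–1.3 and
unmatched ≤ 25 %; anything else ambiguous) are package defaults chosen from
the simulator's separability and are deliberately config-overridable —
on real data the decision boundary is usually read off the joint
distribution, and conflicting evidence should surface as `ambiguous`, never
be silently forced.

## Repeat analytics

Landscapes weight by bp (genomic proportion), assigning each hit's bp to
bin ⌊divergence⌋ in 1 % bins over [0, 50); out-of-range divergences are
clamped with a warning. Genome proportions and window densities merge
overlapping same-subclass hits first, so each base counts once per subclass
and the conservation identities hold (bins sum to the subclass proportion
when hits do not overlap; window bp sums to merged subclass bp always).
Overlapping hits of *different* subclasses are both counted — no
arbitration, matching standard RepeatMasker accounting. Tandem-array
calling merges same-family hits with inter-hit gaps ≤ 500 bp (no published
value exists for this; 500 bp bridges annotation fragmentation while
keeping 0.5–10 kb arrays separate, and it is a parameter). Abundance
differences factor exactly as total = loci × mean length; the factor with
the larger |log| fold change is reported as dominant.

## Family novelty and polymorphic insertions

Cross-genome sequence search uses exact 12 bp seeds clustered by diagonal,
each candidate verified by edit-distance alignment (edlib), so every
reported hit carries an identity and is continuous by construction; for
partial-homology detection the query is scanned in 100 bp half-overlapping
windows. Clustering is greedy and length-sorted (ties by input order):
a sequence joins the first cluster whose representative aligns its full
shorter sequence at ≥ 80 % identity on either strand — the full-shorter-
sequence requirement is a conservative reading of an 80 % coverage rule.
The novelty gates run in order: homolog found (any other genome, hit
≥ 100 bp at ≤ 20 % divergence, divergence = 100 − alignment identity);
low abundance (< 5 kb of own-genome annotated copies); old copies
(bp-weighted mean copy divergence ≥ 10 % — bp-weighting chosen over
copy-count weighting as the interpretation of "average divergence" that
matches how landscapes weigh evidence).

The insertion caller excises an eligible locus (1 kb repeat-free flanks,
1 kb from contig ends), joins its 100 bp flanks into a 200 bp probe — the
intact, insertion-free site — and requires *every* other genome to contain
exactly one continuous probe match at ≥ 90 % identity. A genome carrying
the same insertion splits the probe and cannot produce a continuous match;
a duplicated flank produces two matches; both veto the call, so only
insertions private to the donor with unambiguous intact sites elsewhere
are reported.

## Windowed diversity and divergence

π and D_xy are ratios of summed pairwise differences to summed valid
pairwise comparisons over *all* sites in a window — invariant sites
contribute comparisons with zero differences, and missing calls are
excluded pair-wise, never imputed. Diploid genotypes split into two
alleles, and within-individual pairs count toward π (the standard
definition); multiallelic sites count every differing pair rather than
being collapsed to biallelic. Windows are non-overlapping, 20 kb by
default; the final short window of a contig is kept and flagged so window
sums reproduce contig-wide counts exactly, and a window with zero valid
comparisons is flagged rather than reported as 0. Group comparisons use
Mann–Whitney U, exact when both groups have ≤ 12 untied values, otherwise
the normal approximation with tie correction; all-tied input returns a
flagged p = 1.

## Problem sizes and determinism

The bundled analyses and the benchmark script run at desk scale: 100–200 kb
contigs, 20 replicate seeds for breakpoint resolution, 20× read depth for
sex classification, 100 kb / 8 haplotypes for estimator recovery, 200
replicates for permutation calibration. These sizes give the estimators
sampling errors well inside the tolerances being checked while keeping any
run in the minutes range on one CPU; all sizes are parameters, and the
algorithms are linear or near-linear in genome length. Every stochastic
component takes an explicit seed, and the pipeline manifest records content
hashes so a rerun with the same configuration is bit-identical.

## Known limitations

- No indel model anywhere in the simulator; real alignment slippage and
  divergence-with-indels are untested territory for the aligner.
- The aligner's unique-anchor policy gives no segments inside young,
  high-identity duplications; such regions are invisible to the breakpoint
  caller (as they are to any unique-anchor method).
- Translocation calling reports displaced blocks only; reciprocal pairs
  and event ordering for nested inversions are out of scope.
- The classification thresholds for sex linkage are simulator-calibrated
  defaults, not field constants.
- The permutation test conditions on the observed contig of each interval;
  genome-wide (cross-contig) placement nulls are not offered.
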