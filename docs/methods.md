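# Methods notes

This note records the model, the parameter choices, and the numerical
decisions behind `svhotspots`, including the places where the design was
genuinely open and a choice had to be made.

## Counting semantics

The unit of recurrence is the *sample*, not the SV call: a window's count is
the number of distinct samples with at least one SV targeting it, so
fragmented or duplicated calls within one sample cannot inflate a hotspot.
Duplications and deletions target their entire span (they change the copy
number of everything they contain); insertions, inversions, and
translocations target only their breakend positions — each breakend counted
on its own chromosome, so a translocation contributes to both partners.
Zero-length breakend intervals are widened to one base so a breakpoint at
position *p* counts in every window containing *p*. The recurrence
denominator is the number of distinct samples with ≥ 1 SV anywhere in the
input ("SV-harboring samples"), not the full cohort; with expression data
the cohort for association is the set of expression-profiled samples.

## Candidate peak calling

Raw counts are smoothed with a centered moving average (span 3 windows,
shrinking at chromosome ends); smoothing suppresses single-window jitter
before shape assessment while thresholds always use raw counts, so the
smoothing halo around a spike cannot create candidates of its own.

A window is a candidate when

1. its smoothed count ≥ median + `stdlim` · max(1.4826·MAD, 1) over the up
   to 2·`neighborhood` flanking windows (defaults `stdlim` = 3,
   `neighborhood` = 10, i.e. ±300 kb at the default step), and
2. its raw distinct-sample count ≥ `min_pct_samples` of SV-harboring
   samples (default 15%).

Two deliberate choices here. *Robust flank statistics* (median/MAD rather
than mean/sd): a real hotspot at the default geometry spans several hundred
kilobases of elevated windows, so the flanks of any window inside it are
contaminated by the hotspot's own shoulders; mean/sd statistics would raise
the threshold above the apex and the hotspot would mask itself, while the
median and MAD tolerate up to half the flank being elevated. The MAD floor
of 1 sample prevents zero-variance blowups on flat background. *No strict
local-maximum requirement*: every window of a hotspot plateau that clears
both rules is a candidate, not just the apex. A hotspot wider than one
window can only be covered by a merged run of adjacent candidate windows,
and the merge step below is defined on exactly such runs; restricting
candidates to the single apex window would cap every hotspot at one window
width. The hand-checkable isolated-spike case (counts 2,2,2,20,2,2,2 with
`neighborhood` = 3) gives the same answer under both statistics.

## Peak merging

Candidates are clustered by single linkage with inter-peak gap ≤
`merge_distance` (50 kb). Within a cluster, repeatedly: take the unconsumed
peak with the highest sample count (ties to the leftmost), walk outward
upstream then downstream over unconsumed peaks in coordinate order, merging
each whose count differs from the top count by < `delta` (5%, relative);
a direction stops after `k` (= 1) consecutive dissimilar peaks, or upon
reaching an already-consumed peak (the consumed region belongs to an earlier
merged peak and must not be walked across). Peaks left unconsumed seed
further rounds until the cluster is exhausted.

Because sliding windows overlap (s < w), two walk products from different
seeds can overlap genomically; overlapping outputs are unioned as a final
step so reported hotspots are disjoint intervals. Merged intervals are
window-aligned (span of constituent windows), not trimmed to SV breakpoints,
and a merged peak's sample set is the union over its members.

## Annotation

"Nearby" genes lie within `gene_flank` = 1 Mb of either peak edge
(closest-edge distance; overlap = 0; strand ignored). The 1-Mb default
reflects how far enhancer-targeting SVs are known to act — several hundred
kilobases in the motivating tandem-duplication cases — and is configurable.
Regulatory elements are reported only on direct overlap.

## Expression association

Twelve comparisons per (peak, gene) pair: {all SVs, DUP, DEL, INS, INV,
BND} × {unstratified, copy-neutral samples only}. The control group is
always "samples without *any* SV targeting the hotspot" (not merely without
that type); a sample with two SV types in a peak enters both type groups.
Tests are two-sided Wilcoxon rank-sum by default (exact null when the pooled
sample is ≤ 20 without ties, otherwise the normal approximation with tie
correction; an all-constant comparison returns p = 1) or Welch's *t*.
A comparison is undefined when either group has < `min_group` = 3 samples;
group sizes and means are reported regardless.

Gene-level copy number is the overlap-length-weighted mean of a sample's
segments across the gene body; gain ≥ 2.5, loss ≤ 1.5 on linear copy number
(diploid = 2), with an alternative log2-ratio mode (±0.3). Samples with no
segment over the gene are treated as neutral. Thresholds are configurable;
the defaults sit halfway between diploid and single-copy gain/loss.

Undefined comparisons are dropped from Fisher's combination and the degrees
of freedom adapt (imputing p = 1 would systematically deflate X²). Exact
zeros are clamped to the smallest positive float with a warning. BH FDR is
applied globally across all (peak, gene) pairs; undefined combined p-values
are excluded from the number of tests.

**Anticonservativeness, documented.** The twelve comparisons share samples
and are positively correlated, so Fisher's combination under the null is
inflated relative to its nominal χ² reference — by roughly a factor of two
at α = 0.05 in our mixed-SV-type null simulations, and more when the
battery degenerates to near-copies of a single test (one SV type, no CN
variation). The combination is applied regardless because it is the
procedure this pipeline defines; the per-comparison p < 0.05 retention rule
and the null-cohort tests keep the behavior visible rather than hidden.

## Peak families

Peaks associated with the same gene are tested pairwise for sample-set
dependency with a one-sided (enrichment) Fisher's exact test; edges at
p < `alpha_dep` = 0.05 (unadjusted — the pair count per gene is tiny) and
connected components of size ≥ 2 form families, giving a well-defined
partition even when dependency is not transitive. The representative is the
member with the highest sample count, ties to the leftmost.

## Retention filters and ranking

A pair survives when: peak length < 500 kb OR the gene is on the supplied
census list; peak recurrence ≥ 15% of SV-harboring samples (applied to the
*merged* peak's sample set — merging only grows sample sets, so this is the
stricter reading); FDR < 0.05; ≥ 1 individual comparison with p < 0.05; and
some group mean > 10 TPM within a significant comparison. No census data is
bundled (licensing); the exemption takes a plain symbol list. Ranking is by
sample count descending, then FDR ascending, then coordinate — an invented
but deterministic key, since "rank" otherwise has no canonical definition
here.

## Synthetic cohorts

The generator emulates what the method assumes about real data: uniform
background SVs (counts Poisson in genome length; default 0.03 SVs/sample/Mb,
the order of ~100 SVs per whole cancer genome, which puts an expected 0.3
background SVs per 100-kb window on a 100-sample cohort), implanted hotspots
hitting exactly round(penetrance × n) samples without replacement, DUP/DEL
hotspot events jittered within 20% of the hotspot length so merging must
aggregate heterogeneous events, log-normal TPM expression (positive support,
realistic skew) with effects expressed as shifts of the log-mean in SD
units, and diploid copy-number baselines with implanted gain/loss events.

It does **not** emulate: clustered/chromothriptic backgrounds, breakpoint
microhomology, purity/ploidy distortion of copy number, expression
covariates (site, purity), or inter-gene expression correlation. Passing
recovery tests on these cohorts therefore demonstrates correctness of the
machinery under the stated model, not performance on real tumor data.

The standard benchmark (100 samples, 6-Mb chromosome, one 120-kb DUP
hotspot at 40% penetrance, linked gene 300 kb downstream, +2 SD effect) is
deliberately desk-scale: recovery and null rates are measured over 100
seeds in seconds, and all acceptance-level checks run on one CPU in well
under a minute apiece.

## Numerical choices and degenerate inputs

- Flank windows truncate at chromosome ends; tracks shorter than the
  neighborhood use whatever flanks exist.
- Empty SV input yields empty peak sets, not errors; SVs on chromosomes
  without windows are counted as skipped.
- All coordinates are 0-based half-open throughout; chromosome names are
  verbatim, with a warning when inputs use disjoint vocabularies.
- Tie-breaks (top-peak selection, family representatives, gene ordering)
  always fall back to coordinate order for determinism; reports are
  byte-stable for fixed inputs.
- p-values are clipped to (0, 1]; χ² survival underflow for extreme
  combinations reports 0.0.

## Known limitations

- The candidate threshold couples to cohort size through `min_pct_samples`;
  very small cohorts (< ~10 SV samples) make the 15% rule trivially
  satisfiable and the local-background test dominates.
- Fisher's combination is anticonservative (above); combined p-values and
  FDRs should be read as ranking scores rather than calibrated error rates.
- Breakend imprecision intervals are taken at face value; confidence
  intervals around breakpoints are not modeled.
- The region figures are schematic (linear tracks, no circos-style
  whole-genome plot); a per-chromosome bar summary carries the same
  information with far less rendering machinery.
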