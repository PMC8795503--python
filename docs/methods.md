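# Methods

This note documents the models, conventions and default parameters behind
`txstress`, the choices made where several reasonable designs exist, and
what the synthetic-data tests do and do not establish about real data.

## Coordinates and gene anchors

All intervals are 0-based half-open (BED convention); 1-based inputs must
be converted at the reader boundary. A gene is anchored by its TSS and
TES. On the "+" strand `tss < tes` and the TSS is the interval start; on
the "−" strand `tss > tes` and the TSS is the *exclusive end* coordinate,
i.e. a minus-strand gene occupies `[tes, tss)`. This convention was chosen
because it makes every windowed statistic exactly mirror symmetric: the
promoter-proximal window is `[tss−30, tss+300)` on "+" and
`[tss−300, tss+30)` on "−", and reversing the genome (and its coverage)
leaves all traveling ratios bit-identical. The tests assert this symmetry.

## Traveling ratio and RoTR

The traveling ratio is the promoter-proximal RNAPII density (−30 to
+300 bp of the TSS, in transcription direction) divided by the density of
the remaining gene body (+300 bp to the TES):

    TR = (promoter_density + c) / (body_density + c)

with pseudocount `c = 0` by default. Zero-body-density genes and genes
whose TES lies within 300 bp of the TSS are excluded with a recorded
reason rather than patched; exclusion counts appear in the results object
and pipeline log because these silent filters shape the effective n of
any downstream comparison. A small configurable pseudocount is available
for robustness on sparse tracks.

Coverage is stored at a fixed bin width (default 10 bp, bedGraph
semantics: the value is signal per bp). Interval sums weight partial bins
by the contained fraction, so densities of piecewise-constant signals are
independent of the bin width; the unit tests check bin-width consistency
against a 1-bp-resolution oracle.

RoTR is TR(ChIP)/TR(input) per gene within a condition — the reading in
which an input-normalized pausing index is compared between conditions. A
condition-ratio mode (TR of one condition over another, via merging the
two per-gene tables) is equally supported; the package treats the choice
as an analysis option rather than asserting either as canonical, because
an input-normalized and a condition-normalized ratio answer slightly
different questions and genuinely ambiguous usage exists in the field.

Active genes are called by two thresholds: promoter ChIP density at least
`min_promoter_density` (default 0.3 signal/bp) and promoter input
enrichment at least `enrichment_threshold` (default 2.0). The defaults
were chosen so that, under the synthetic generator's default rates, the
planted "expressed" gene set is recovered essentially completely (the
tests require 100% on a fixed seed); on real data these thresholds must
be tuned to the library depth.

## Rank-sum comparison

Distribution comparisons use the two-sided Wilcoxon rank-sum
(Mann–Whitney U) test. For samples with at most 8 observations each, the
p-value is computed by full enumeration of all C(n1+n2, n1) group
assignments over the pooled mid-ranks (ties handled by construction); the
two-sided p is `min(1, 2·min(P(U ≤ u), P(U ≥ u)))`. Larger samples use
the tie-corrected normal approximation (scipy). When every pooled value
is identical the test is degenerate and p = 1. The acceptance suite
verifies the exact branch against an independent enumeration oracle for
all sample sizes up to 6×6, exhaustively over a binary value alphabet and
on random tied and continuous cases.

## Permutation overlap test

The null model re-places every query interval uniformly among its valid
start positions on its own chromosome, excluding masked spans (assembly
gaps) when a mask is supplied; placements are independent, so mutual
overlap among placed intervals is allowed. Preserved per draw: interval
count, the multiset of lengths, and chromosome assignment. A genome-wide
placement mode (chromosome chosen proportional to its number of valid
starts) is available for sensitivity analysis. Whether sex chromosomes or
gaps belong in the placement space is a data-preparation decision; both
are handled through the mask.

Reported quantities:

- `observed_kb`, null mean and sd, and the z-score on the permutation
  null with a **two-sided normal-tail p**. The parametric tail is the
  headline p because an empirical p is floored at 1/(n_perm+1), and
  overlap enrichments in this setting are routinely far beyond that
  floor.
- `p_empirical`: the two-sided empirical p,
  `min(1, 2·min(lower tail, upper tail))` with the +1 correction. The
  doubling matters: a one-sided tail in a direction chosen *from the
  data* is anti-conservative by up to a factor of two and fails
  calibration; the doubled version is super-uniform, and the acceptance
  suite checks that its rejection rate at α = 0.05 under the null
  placement model itself falls inside the exact binomial 99% band over
  500 independent tests.
- `p_empirical_directional`: the literal one-sided tail in the observed
  direction, for continuity with common practice; it should be read as
  descriptive, not calibrated.
- Degenerate nulls (sd = 0, e.g. features covering the whole genome) are
  flagged; z and the parametric p are reported as missing while the
  empirical p remains defined.

The calibration test's scenario uses features dense enough (25% coverage,
maximum gap 30 kb, query intervals 8–13 kb) that every placement overlaps
some feature: a null with a point mass (many placements at exactly zero
overlap) is heavily tied, which makes any empirical p conservative and
the rejection-rate check uninformative rather than wrong.

## Copy-number calling

The caller is deliberately elementary: a CNC is a maximal run of at least
`min_probes` (default 5) consecutive probes whose log2 ratio all clear
`±threshold_log2` (default 0.5); the call spans first to last probe of
the run and carries the run's mean ratio. It is *not* a segmentation
algorithm — no CBS, no HMM, no normalization — and it will fragment
segments whose probes dip below threshold. The trade is deliberate: every
call is exactly re-checkable probe by probe, planted segments of
amplitude ≥ 2×threshold are recovered with boundary error bounded by one
probe spacing, and the false-call probability on Gaussian noise is
analytically negligible (P(|N(0, 0.1)| ≥ 0.5)⁵ per window). Replicate
intersection keeps calls supported by a same-class (gain with gain, loss
with loss) overlap of ≥ 1 bp in the other replicate; a minimum
reciprocal-overlap fraction is available but defaults to 0.

"Genic" means ≥ 1 bp overlap with the TSS–TES body interval; promoter
flanks are not included. The expression-overlap permutation uses a gene
*count* statistic (number of differentially expressed genes overlapped)
rather than kb, since gene membership is the quantity of interest there.

## GC skew and stratification

Skew is (G − C)/(G + C) on the transcribed strand (reverse complement
applied first for minus-strand genes), so positive skew always means a
G-rich non-template strand — the R-loop-favouring orientation. N bases
are excluded from counts; windows that are majority-N, or contain no G/C
at all, are flagged undefined rather than zeroed.

Stratification thresholds are inclusive order statistics: the low
threshold is the largest sample value with at most the requested fraction
below-or-equal (numpy `method="lower"`), the high threshold the
symmetric counterpart (`method="higher"`); groups are
`{skew ≤ q_low}` and `{skew ≥ q_high}`, then intersected with the active
set. With this rule a universe of 100 distinct values at 10%/90% yields
tail groups of exactly 10 and 10. Gene-length groups use either the fixed
100-kb threshold (boundary genes, exactly 100,000 bp, count as short —
the strict inequalities of common usage leave the boundary open) or
shortest-20% / middle-40–60% / longest-20% quantile bands.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, at
desk scale (defaults: 2 chromosomes × 5 Mb, 300 genes, 50 CNCs, 10-bp
bins — every acceptance simulation finishes in minutes on one CPU):

- **Genome and genes.** Uniform random sequence; gene lengths log-normal
  (median 8 kb, σ = 0.8, floor 1 kb); genes placed without overlap with
  ≥ 430 bp margins so promoter windows never cross neighbours; strands
  random. Each promoter-proximal window is rewritten with an exact base
  composition hitting its assigned skew target (±0.4 by default, GC
  fraction 0.5), so measured skew lands within ±0.05 of target by
  construction rather than by sampling luck. Minus-strand promoters are
  inserted as reverse complements, preserving sense-strand skew.
- **Coverage.** Expressed genes (default 70%) put `expression_rate`
  (0.5 signal/bp) on the body and `expression_rate × π` on the promoter
  window, on top of a uniform background (0.02/bp); counts are Poisson
  per bin; input is uniform Poisson at 0.2/bp. The expected TR of an
  expressed gene is `(0.02 + 0.5π)/(0.52)` — within 1% of π at the
  default rates, and exactly π when the background is set to 0. The
  pausing factor can be a scalar or keyed by skew class, which is how
  skew-coupled pausing scenarios are built. Overdispersion
  (negative-binomial), fragment-size and GC bias are *not* modelled.
- **CNCs and features.** Disjoint feature intervals (25 × 20 kb) and
  disjoint CNC intervals (50 × 2 kb, half gains half losses); a
  controllable fraction of CNCs is planted fully inside features, the
  rest placed uniformly. The probe table (200-bp spacing) carries ±1.0
  log-ratio segments exactly at CNC positions plus optional Gaussian
  probe noise.
- **qPCR.** Ct = base − log2(abundance) + N(0, sd), technical replicates
  independent; abundance is the absolute fraction of material recovered,
  with input rows measuring the input aliquot itself, which makes
  percent-input recovery exact at sd = 0.

All randomness flows from one integer seed through named
`SeedSequence.spawn` streams, so every artefact is reproducible byte for
byte across platforms.

**What passing tests show — and don't.** The generator matches the
analyses' *assumptions*, so passing tests demonstrate correctness of the
implementations and recoverability of planted effects under those
assumptions: Poisson counting noise, uniform background, independent
genes, exactly engineered skew, clean rectangular CNC segments. They do
not demonstrate robustness to mappability artefacts, copy-number-coupled
coverage, overdispersion, correlated probes, amplification-efficiency
drift, or annotation error in real data.

## Acceptance problem sizes

The from-scratch acceptance computation uses: 1,000 random genomes
(≤ 100 kb) for overlap exactness; 500 null tests at 200 permutations for
calibration; 100 runs of the 50 × 2 kb planted-enrichment scenario on a
10-Mb genome; 300 genes for pausing-factor recovery (π 2 vs 4); 500
genes for the skew-coupled comparison (the synthetic skew distribution is
bimodal at ±0.4, so 40%/60% quantiles — which isolate the two planted
classes completely — replace the 10%/90% tails that a realistic unimodal
skew distribution would call for, keeping ≥ 200 genes in the comparison);
100 seeds of 10,000-probe noise tables for false-call control; and 1,000
replicate qPCR simulations for fold recovery.

## Known limitations

- The CNC caller is a testing-grade stand-in, not a reimplementation of
  any vendor's segmentation; absolute call sets on real arrays will
  differ.
- The genes-per-region count is a plain symmetric window around each
  region; it does not reproduce regulatory-domain models (basal plus
  extension) used by web tools for the same display.
- The permutation test offers only independent uniform re-placement
  (optionally genome-wide); circular rotation and local shuffling
  schemes are out of scope.
- bedGraph input must align to the declared bin grid; arbitrary-interval
  bedGraphs should be re-binned upstream.
- Percent input assumes equal amplification efficiency across primers;
  no standard-curve correction is implemented.
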