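# Methods

This note documents the statistical models implemented in `footprintkit`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Coordinates and cleavage placement

All coordinates are 0-based half-open (BED convention). A cleavage event is
placed at the 5′-most aligned base of a read on its own strand — for a
minus-strand read, the highest-coordinate aligned base. No inter-strand
offset is applied by default; `minus_offset` exists as a hook for
transposase-style chemistries whose two strands report staggered positions.
Reads flagged unmapped/secondary/supplementary/duplicate/QC-fail are
excluded; no mapping-quality floor is applied by default (`min_mapq`),
since "uniquely mapping" conventions vary by aligner.

## Cleavage bias and the expected rate

DNase I has a mild intrinsic sequence preference. It is modelled as a
relative rate per k-mer context, k = 6 with the cleaved base at offset 3
(three bases 5′, the base, two bases 3′) — the window over which the
empirical preference of the enzyme has been exhaustively characterised.
Learning is pure tallying:

    preference(m) = (cleavages in context m / occurrences of m)
                    / (total cleavages / total contexts)

with minus-strand cleavages counted against the reverse-complement context,
contexts containing N skipped, and the table re-normalised to unit mean
over observed k-mers. Contexts observed but never cleaved are clamped to a
small positive preference (1e-3 before normalisation) because downstream
code requires strictly positive rates.

The expected per-nucleotide rate redistributes locally observed counts by
context preference, per strand:

    E_i = (Σ_{j ∈ win(i)} obs_j) · b_i / (Σ_{j ∈ win(i)} b_j)

over a centred window of half-width `window_half` = 50 (101 bp), clipped at
interval edges. 101 bp keeps the rate adaptive at sub-DHS scale — local
chromatin structure is absorbed into the window total — while averaging
over far more positions than a footprint occupies. When the window spans
the whole interval the expected profile conserves the observed total
exactly; strand profiles are computed independently and summed for testing
(context bias is strand-specific, protection is not).

Because the window is fixed-width rather than conditioned on DHS
boundaries, positions within `window_half` of a sharp accessibility edge
have systematically mis-centred expectations (the window mixes accessible
and inaccessible chromatin). This heterogeneity is deliberately absorbed by
the dispersion model rather than corrected: it is one of the "additional
sources of technical variability" the per-sample variability model exists
to soak up, and it makes the fitted NB size parameter smaller (more
conservative) than the pure count-noise value.

## Dispersion model and depletion test

For each sample, observed counts are binned by the rounded expected rate;
each bin with ≥ `min_positions_per_bin` = 100 positions gets an NB(μ, r)
maximum-likelihood fit (the NB mean MLE is the sample mean, so only log r
is optimised, bounded in [1e-2, 1e8]). Two smooth trends are then fitted
across bins, weighted by bin occupancy:

* μ(n): least-squares line, slope clamped ≥ 0 (mean non-decreasing);
* r(n): linear fit of log r against log(1 + n).

Evaluation outside the fitted bin range is clamped to the endpoints. At
least 5 usable bins are required. The per-nucleotide protection test is the
lower tail `p = P(X ≤ obs)` under NB(μ(E), r(E)), including the observed
value — conservative on discrete counts, with no mid-p correction, because
false footprint calls are costlier than missed weak ones. Positions with
E < `min_expected` = 0.1 are never tested and can never seed a footprint.
Null counts for FDR calibration are drawn gamma-Poisson from the same
fitted NB (exact, stable for large r); a zero expected rate always draws
zero.

## De novo detection and empirical FDR

Per-position p-values are probit-transformed (untested positions capped at
z = +8.2) and combined over centred windows with Stouffer's method; the
statistic is the minimum combined z over window widths {3, 5, 7, 9, 11,
13}, which keeps short footprints sharp while still accumulating evidence
for wide ones. Significance is calibrated empirically: R = 20 null
replicates are sampled from the fitted dispersion model on the same
expected profile and pushed through the identical transformation, and

    FDR(t) = (#null ≤ t / R) / max(1, #obs ≤ t)

is clipped to [0, 1], monotonised step-up over increasing t, and evaluated
at each observed statistic, pooled across all analysed intervals of a run.
Because the nulls receive exactly the same windowing and min-over-widths
treatment, the estimate is valid for the composite statistic by
construction. R = 20 is the test-scale default; at genome scale a single
replicate already pools millions of positions.

Positions at FDR ≤ 1% are segmented into calls: runs separated by ≤ 3
failing positions merge, runs shorter than 6 bp are dropped (observed
footprints start around 7 bp). Call boundaries are then refined at
single-nucleotide resolution: the windowed statistic blurs edges by up to
half a window, so edges are trimmed to the outermost position whose own
depletion p-value is ≤ `boundary_p` = 0.25 and extended over contiguous
qualifying neighbours. Under the null a position qualifies with probability
0.25, bounding the expected false outward extension at ~⅓ bp, while truly
protected positions at detectable depths have p ≪ 0.1; set
`boundary_p=None` to disable. Each call is annotated with a protection
ratio estimated against the flank-normalised unprotected rate (the flank
window is clipped to the analysed core and masked of sibling calls, which
removes the downward bias the footprint itself induces on the smoothed
expectation).

Analysed intervals are padded by `window_half + k` so contexts and windows
are computable; pad positions are never tested. FDR is pooled per run (per
analysed interval set), not per DHS.

## Empirical-Bayes posterior and consensus index

Across N samples, the prior that nucleotide i is footprinted is the
Laplace-smoothed occurrence fraction (k_i + 1)/(N + 2), where k_i counts
samples whose independent de novo calls cover i — strictly inside (0, 1),
so a footprint unseen de novo can still be recovered in a deep sample. The
unoccupied likelihood is the NB pmf at the expected rate; the occupied
likelihood averages the pmf over a depletion-ratio grid δ ∈ {0.05, 0.10,
…, 0.75} (a flat mixture standing in for an unknown occupied-rate
distribution; isolated behind one function). The posterior is the usual
two-hypothesis combination, computed per sample; untested positions
inherit the prior and are flagged.

Per-sample segments (posterior > 0.99) are collated across samples by a
greedy max-support procedure: repeatedly take the position covered by the
most remaining segments (ties leftmost), gather every segment covering it,
emit [median start, median end] (even counts: lower-median start,
upper-median end), and remove the gathered segments. The result is
deterministic, order-invariant, and keeps abutting footprints distinct.
Motif hits are assigned to consensus footprints when overlap/motif-length
≥ 0.9, ranked by match score; hit scanning itself is out of scope (hits
are consumed as BED).

**Limitation.** At desk-scale cohorts (N ≤ 4, 15–30 expected
cleavages/bp), the per-nucleotide single-count likelihood ratio straddles
the 0.99 cutoff inside genuine footprints, so posterior segments fragment
and are *less* replicate-reproducible than windowed de novo calls
(measured Jaccard 0.06–0.14 vs 0.86–0.88 on 2-replicate simulations). The
reproducibility gain of consensus footprinting reported for hundreds-deep
cohorts relies on informative priors and a richer occupied-likelihood than
this per-position stand-in provides; with a handful of samples, treat the
posterior as a per-nucleotide annotation, not a segmentation device.

## Differential occupancy

At each testable position (expected ≥ 0.1 in ≥ `min_samples` samples per
group, default 10), counts are modelled as obs_s ~ NB(φ_g(s)·μ_s, r_s)
with μ_s, r_s taken from each sample's own dispersion model at its own
expected rate — depth, bias and per-sample technical variability enter as
offsets, exactly as size factors and gene-wise dispersions do in
differential expression testing. φ is profiled by golden-section search on
log φ ∈ [log 1e-3, log 10] (40 iterations, vectorised across positions;
interval width < 1e-6 at convergence), separately per group and shared;
the LRT 2(ℓ_free − ℓ_shared) is referred to χ²₁ and BH-corrected across
all tested positions of a run (pooled, not per DHS). Under permuted labels
the p-values are uniform (KS p ≈ 0.8 at 10⁴ positions, 20+20 samples).
DHS pre-selection keeps elements with ≥ 10 samples per group at normalised
density ≥ 1. A footprint is differential iff it contains a position with
q ≤ 0.05; a DHS iff it contains a differential footprint.

## Allelic imbalance

Reads of heterozygous samples overlapping a variant are tallied by the
base carried (base quality ≥ 20); variants need ≥ 35 informative (ref +
alt) reads — the threshold is applied after discarding third-allele bases.
The test is the two-sided exact binomial against an expected reference
fraction of 0.5, doubling the smaller tail and capping at 1 (conservative;
no mid-p). No reference-mapping-bias correction is applied; a measured
bias can be supplied as `expected_ratio`. BH correction runs over testable
variants; the imbalance flag requires q ≤ 0.2. Enrichment of imbalanced
variants in footprinted vs non-footprinted DHS positions is summarised
with fractions, their ratio and a Fisher exact p; empty partitions yield
NaN sentinels rather than errors.

## Synthetic cohorts

The generator draws, deterministically from a seed: a uniform-ACGT genome;
non-overlapping fixed-width DHSs (gaps ≥ 500 bp) with per-DHS rate
multipliers; footprints inside DHSs (edge margin 10 bp, spacing ≥ 8 bp)
with widths and depletion ratios drawn from configurable ranges; a
log-normal 6-mer bias table; per-sample depths; optional group-specific
footprints and footprint-linked heterozygous variants. The per-position
rate is

    λ_i = depth · dhs_multiplier · bias(context_i) · δ_i,

split equally between strands (and haplotypes for heterozygotes), each
component drawn NB with a proportional share of the size parameter so the
combined count is exactly NB(λ, r); r is constant (default 8). A
variant's allele modifier scales its footprint's *parent DHS* on that
haplotype — a chromatin-altering variant changes the accessibility of its
element, not just the footprint interior, and a footprint-local modifier
would be diluted below detectability by the 36-bp read span used to
attribute reads to alleles. Allele-informative counts at a variant are the
per-haplotype cleavages a 36-bp read overlapping the variant could carry.

Defaults describe the desk-scale study conditions every end-to-end
guarantee is measured under: 2 Mb genome, 500 × 200-bp DHSs, footprints
(width 8–30 bp, depletion 0.1–0.4) in half of them, bias sd 0.25, r = 8,
depth 20–30 expected cleavages/bp, two groups of two samples. The
generator intentionally shares no code with the fitting/testing path, so
it doubles as an independent oracle.

What it does **not** emulate: read-level artefacts (mappability, PCR
duplication, fragment-length structure), DHS shape (rates are flat within
a DHS up to bias), footprint shape (protection is a single multiplicative
step), copy-number variation, or genome-scale sequence composition.
Passing tests therefore demonstrate statistical correctness of the
machinery under its own generative assumptions, not robustness to every
artefact of real libraries.

## Numerical choices

* NB log-pmf via gammaln with `-r·log1p(μ/r)`, stable to r = 1e8 (the
  Poisson limit); NB CDF via the regularised incomplete beta (scipy).
* Per-bin r-MLE: bounded scalar minimisation on log r, xatol 1e-6;
  variance ≤ mean short-circuits to the Poisson-limit cap.
* Golden-section LRT optimisation is vectorised across positions; the LRT
  is clipped at 0 (free ≥ shared up to optimiser tolerance).
* Probit z-values are capped at +8.2 (untested/p→1) before windowing.
* Empirical FDR is computed on unique statistic values and monotonised by
  suffix-minimum, so ties share one FDR and the track is monotone in the
  statistic.
* Degenerate inputs: zero expected → untested/zero draws; zero-length
  runs and empty partitions return empty lists or NaN sentinels, never
  exceptions, wherever the contract allows.

## Problem sizes used by the test suite

The statistical guarantees are measured at the default study conditions
above (3 seeds × 4 samples for FDR control and width recovery); null
calibration uses 10⁵ positions, differential calibration 10⁴ positions ×
40 samples, and parameter recovery 10⁵ observed/expected pairs per size
value. These sizes give the binomial/KS assertions comfortable power while
keeping the full suite to a few minutes on one CPU.
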