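# Methods

## Quantification model

MALDI-TOF peptide intensities are relative: the ion yield per spot depends
on analyte load, matrix crystallization and detector saturation, and no
internal standard is used.  The pipeline therefore treats only the *shape*
of a peptide's dilution series as quantitative.  With dilution factor
f = 0.35 µL-equiv / (spotted µL-equiv), so the most concentrated spot has
f = 1, a peptide in the linear regime obeys I(f) = A / f, i.e. a line of
slope −1 in log–log coordinates.  The reported amplitude is the intercept
at log₁₀ f = 0 — the projected TIC-normalized intensity at dilution
factor 1.  Fitting across two orders of magnitude in log–log space also
makes the multiplicative character of spot noise explicit, which is why
ordinary least squares on the log scale is appropriate.

Gates, in order:

* **TIC normalization** per spot (sum of intensities = 1).  Normalization
  precedes merging, following the processing order of the original
  workflow description.
* **Replicate merge**: peaks chained across the ≤ 4 technical replicates
  by single-linkage on sorted m/z with tolerance `mz_tol` (default
  0.1 Da); a merged peak requires ≥ `min_observed_replicates` (default 3)
  members, at most one per replicate.  Merged m/z is intensity-weighted
  (stronger centroids are more precise); merged intensity is the plain
  mean over observed replicates.
* **Series assembly**: merged peaks are chained across dilution levels
  with the same tolerance; at most one point per dilution (nearest the
  series median m/z).
* **Regression with pruning**: iteratively remove the single worst point
  and refit.  The outlier score is the perpendicular distance from the
  OLS line after standardizing both coordinates to unit variance,
  expressed in units of the RMS of those distances over the current
  points, so the threshold `max_perp_dist` (default 2.0) reads as "2
  sigmas of the residual scatter".  Without the RMS scaling the dilution
  trend itself dominates the variance and even a 10× outlier never
  reaches 2 "unit-variance" units — the scaled form is the only reading
  under which the default threshold does the job the procedure exists
  for.  Pruning stops at `min_points` (default 6 of 12); colinear-to-
  machine-precision series are never pruned.  Ties in the outlier score
  are broken toward the lower dilution factor, making pruning
  deterministic and permutation-invariant.
* **Rejection**: series observed at fewer than 3 dilutions, or whose
  final slope is ≥ 0 in (log f, log I) — intensity must fall as dilution
  increases; saturated or artifactual series fail this.

An alternative reading of the original procedure prunes spot-level points
(up to 48) rather than merged dilution points (12); `min_points` is
configurable so either granularity can be expressed, but the merged mode
is the default and the only one exercised by the test suite.

## Feature matrix

All passed peptides of all samples are pooled, sorted by m/z and split
into bins wherever the gap between adjacent masses exceeds `bin_tol`
(default 0.1 Da — published per-feature mass SDs run 0.005–0.085 Da, so
0.1 Da absorbs centroid scatter while separating features ≥ 1 Da apart).
The global sort makes binning independent of sample order.  Undetected
entries are structural absences; they become 0 only when exported to
statistics/classifier input.  Frequency gates use strict inequalities
(> 10% of all samples, then > 25% in at least one patient group);
pool replicates count toward the overall gate only.

## Marker statistics

The Wilcoxon rank-sum test and the Mann–Whitney AUC U/(n₁n₂) are computed
with midrank tie handling on amplitudes *including zeros* — a feature can
discriminate through detection frequency as much as through amplitude.
Because rank statistics are invariant under strictly increasing
transforms, the natural-log transform matters only for the SVM inputs,
not for p or AUC.  For groups of ≤ 8 the permutation null of U is
enumerated exactly (correct under ties); otherwise the tie-corrected
normal approximation is used without continuity correction, which makes
the two-group case coincide exactly with the Kruskal–Wallis chi-square —
a cross-check the test suite exploits.  Reported AUCs are max-oriented
(max(AUC, 1−AUC)) for parity with clinical tables; the signed orientation
is kept internally.  Fold changes are rounded half-up to 2 decimals, the
convention of printed tables (banker's rounding would alter boundary
cells such as 30/48 = 0.625).

Pool variability: per pool type with ≥ 2 replicates, CV = sample SD /
mean of the replicate amplitudes (zeros included); the feature score is
the mean over pool types.  Features undetected in more than half of all
pool replicates score +∞ (unusable for ranking).

## Classifier

Inputs are ln(1 + a·x) with a = 10⁴ on the TIC-normalized projected
amplitudes — the pre-scale puts typical detected values (~10⁻⁴–10⁻³)
well above the +1 offset that keeps non-detected zeros finite; the
original workflow does not state its zero handling, so this choice is
ours.  Features are standardized on training rows only.  The SVM is an
RBF kernel with C = 1 and gamma = 1/(panel size) — the original software
names only "SVM", so defaults were chosen for small-n stability and
determinism; both are configurable.  Pool replicates train with their
source-class labels (AKI pool → positive; non-AKI and normal pools →
negative), the study's "variance stabilization".  The decision score is
the signed SVM decision value; score > −0.05 calls AKI, matching the
published cutoff convention, and the cutoff is configurable.

Panel selection: candidates are features with p < 0.05, ranked by the
combined rank of (p ascending, pool CV ascending; undefined CVs last).
Greedy forward: a candidate is kept iff the panel's LOOCV AUC does not
drop by more than 0.001.  Selection runs on the full cohort *before*
cross-validation, as in the original study; the suite demonstrates on
pure-null data that this inflates LOOCV AUC well above 0.5, so pipeline
AUCs must be read as within-cohort, optimistically biased estimates.

Evaluation: LOOCV scores (pools held out in turn too), empirical ROC,
DeLong variance for the 95% CI and for a z-test of AUC against 0.5 (at
these sample sizes indistinguishable from a t-test), confusion counts at
the cutoff as integer percentages, repeatability rates over repeated pool
analyses, a two-covariate maximum-likelihood logistic combiner of two
classifier scores (L2-penalized fallback under perfect separation) with
Youden-index thresholding, and Kruskal–Wallis subgroup confounding
checks.

## Peptide masses

Neutral monoisotopic masses: sum of standard residue masses plus one
water (18.010565 Da); lowercase `p` is hydroxyproline (Pro + 15.994915
Da), ubiquitous in urinary collagen fragments.  All seven published
sequence-derived panel masses reproduce to the printed 3 decimals.
MALDI-to-reference matching uses an absolute tolerance (default 0.2 Da)
rather than ppm because consensus-centroid scatter (~0.17 Da at worst)
dominates calibration error; calibrant checks, by contrast, are in ppm
(≤ 10 ppm per calibrant).  Matching is one-to-one greedy by smallest
|Δm|, ties to the lower mass, hence order-independent.

## Synthetic cohort generator

The generator emulates the study design: 17 cases + 17 controls, three
urine pools (normal, AKI, non-AKI) × 4 replicate analyses, 12-step
geometric dilution series (0.35 → 0.0035 µL-equiv) spotted in
quadruplicate.

* **Amplitudes**: per (sample, peptide), detection is Bernoulli with the
  group's published frequency; detected amplitudes are log-normal with
  moments matched so the *zero-inflated* distribution reproduces the
  published including-zeros mean and SD (log-normal because amplitudes
  are positive, right-skewed, and published SDs often exceed means).
  Defaults are the 39-marker published statistics; 200 null background
  peptides with identical group distributions (mean 600, SD 600,
  frequency 0.5, masses ≥ 0.5 Da from any marker) exercise selection
  specificity.  Peptides are drawn independently; real urinary collagen
  fragments are co-regulated, so cross-feature correlation is one
  realistic property the generator does not emulate.
* **Spots**: raw peptide intensity min(A/f, saturation)·(1+ε) with
  ε ~ N(0, noise_cv²) (default CV 0.1); gross outliers (×10 or ×0.1)
  with probability 0.05 per point; per-spot m/z jitter SD 0.02 Da;
  detection drop-out at high dilution via a logistic in log₁₀ f
  (midpoint 1.5, scale 0.3 — peaks reliably present over the top ~6
  dilutions, fading beyond, so the ≥3-dilution gate binds realistically).
* **Constant-TIC matrix background**: every spot carries 60 fixed
  chemical-background peaks that absorb the remainder of a constant total
  ion current — an idealization of matrix suppression (more analyte,
  less matrix signal).  It makes TIC normalization exactly invertible,
  so noise-free series are exactly linear through the origin and
  parameter-recovery error is attributable to the noise model rather
  than to normalization coupling.  Real spectra have fluctuating TICs;
  passing recovery tests here does not certify behavior under strong
  TIC drift.
* **Pools**: pooled concentration = per-peptide mean (zeros included)
  of the member individuals' amplitudes; the normal pool draws unseen
  healthy donors from the control distribution.  Each pool replicate is
  an independent full dilution-series analysis.
* Generation is bit-reproducible for a fixed seed, and a seed is
  mandatory.

## Problem sizes and numerical choices in the test suite

The acceptance checks run the full spot-level pipeline on ten cohorts of
46 samples × 48 spots (~2200 spots each), a size at which the complete
ten-seed evaluation finishes in about a minute while every stage
(normalization, merging, regression, binning, filtering, selection,
LOOCV) is exercised end to end.  Parameter-recovery uses a 6-sample
cohort (~700 peptide series) with saturation at 1200 counts, which clips
the top one-to-two dilution points of about half the series.  Exhaustive
oracles (subset search for pruning, permutation enumeration for the
Wilcoxon null) are run at ≤ 6 points and ≤ 8 per group respectively,
where enumeration is exact and fast.

## Known limitations

* The published cohort's raw spectra are not available, so cohort-level
  counts (features passing filters, candidate numbers) are emulated, not
  reproduced; classifier performance on synthetic cohorts exceeds the
  published validation AUC because markers are independent, pools are
  noiseless averages of their members, and selection precedes LOOCV.
* The published per-marker p-values are mutually inconsistent with the
  published per-marker AUCs and amplitude moments at the printed group
  sizes; the generator follows the moments and frequencies, whose
  implied per-marker power at n = 17+17 is modest (~25–30% at α = 0.05).
  Selection specificity against null features is correspondingly limited
  by candidate-pool purity, not by the selection algorithm.
* Raw-spectrum processing (smoothing, baseline, monoisotopic picking),
  CE-MS migration modeling and MS/MS sequencing are out of scope; the
  pipeline starts from exported peak lists.
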