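# Methods

## Coordinates and promoter windows

All intervals are 0-based, half-open (BED convention); refFlat `txStart`
is taken as 0-based per the UCSC convention. The pTSS window of a
transcript is `[TSS − flank, TSS + flank)` with `flank = 1000` bp.
TSS = `tx_start` on the plus strand and `tx_end` (the half-open end) on
the minus strand, i.e. the first transcribed base of a minus-strand
transcript is `tx_end − 1`; because the window is symmetric this one-base
ambiguity is immaterial. Windows are built per transcript; overlapping
windows from different transcripts are kept and counted independently.
Windows are clipped at chromosome bounds, so `effective_length` can be
below `2·flank` near edges; clipped windows are excluded from metagene
averaging (with a warning) but kept, at their true length, in RPKM.

## Counting and normalization

A fragment increments a window's count when it overlaps the window by at
least 1 bp — not a midpoint or 5′-end rule — matching the behaviour of
standard interval-coverage tools and using all fragments that touch the
window. Window counts (not per-base depth sums) feed
RPKM = count × 10⁹ / (window length × total mapped fragments), where the
denominator is the sample's genome-wide deduplicated fragment count
("per million mapped reads" refers to library size, not to the windows).
Per-base depth is used only for metagene profiles.

Metagene profiles average per-base depth across the gene set's windows and
samples, reverse minus-strand windows so positive offsets point downstream
of transcription, bin (default 20 bp), and divide by the mean over the
outermost 10% of offsets on each side. That baseline has to be pinned for
the profile to be testable; note that with the default depletion width the
window edge lies only ~2σ from the TSS, so the baseline itself retains
roughly 13% of the dip and the normalized central value of a fully active
promoter is ≈ 0.46 rather than the naive 1 − depletion = 0.40. Tests
therefore compare against the plug-in prediction of the thinning model,
not a round number.

## Differential coverage

Per promoter: two-sided Wilcoxon rank-sum p-value comparing case and
control RPKM. The exact rank-sum null is enumerated when
n₁ + n₂ ≤ 20 and the pooled values are tie-free; otherwise the normal
approximation with tie correction and continuity correction is used (for
tie-free samples at n ≤ 20 the two agree within 0.02). P-values are
adjusted by the Benjamini–Hochberg step-up procedure; selection requires
FDR ≤ 0.1 and |log2FC| ≥ 1. Fold changes are ratios of arithmetic group
means with a 0.01-RPKM pseudocount on both means — the pseudocount keeps
sign and ordering stable when a group mean is zero. Testing is two-sided
(both coverage directions are biologically meaningful) and FDR is
computed within one case/control comparison at a time, never pooled
across disease comparisons. Z-score matrices standardize each window to
mean 0, sd 1 (sample sd, ddof = 1); zero-variance windows are emitted as
zeros with a warning.

## Classifier construction

Discretization: for each promoter, candidate cutoffs are the midpoints
between consecutive sorted unique training values plus one candidate below
the minimum and one above the maximum. Each candidate is scored by
balanced accuracy BA = (sensitivity + specificity)/2 with positive = case
and indicator `1{value > cutoff}`; the score is max(BA, 1 − BA) so that a
promoter informative in either direction scores equally — the logistic
coefficient sign absorbs the orientation. Ties go to the smallest
candidate. Binarization is strict: a value exactly at the cutoff maps
to 0.

Feature selection is bidirectional stepwise search minimizing AIC,
starting from the intercept-only model; at each step the single add or
drop with the largest AIC decrease is taken (ties broken by candidate
order), stopping when no move improves AIC or `max_features` (default 15,
matching the 10–13-gene scale of the published models) is reached. Under
AIC a pure-noise feature is admitted when its likelihood-ratio statistic
exceeds 2 (probability ≈ 0.157 for χ²₁), so stepwise over ~20 noise
candidates typically keeps 3–7 — parsimonious, not empty; the LOOCV
evaluation is what exposes such models as uninformative.

Logistic coefficients are maximum-likelihood via Newton/IRLS (convergence
when the largest score component < 1e-8, ≤ 100 iterations). Constant
features are dropped with a warning. Complete separation is diagnosed
when coefficients diverge past |β| = 15; iteration then stops at first
detection so the remaining coefficients keep their last finite, decisive
values, and the offending coefficients are capped at ±15 with a warning.

When several transcripts of one gene survive discovery, the transcript
with the smallest discovery p-value represents the gene (published
equations are gene-symbol-keyed, so a deterministic transcript → gene
reduction is required).

## LOOCV, ROC, and validation

Default ("fixed") LOOCV refits only the logistic coefficients in each
fold; the feature subset and discretization cutoffs stay fixed from the
full training cohort. This mirrors the published training description but
is optimistically biased, since the withheld sample influenced feature
selection. The "strict" mode re-runs the entire selection path per fold —
differential selection on the n−1 training samples, cutoff learning,
stepwise, fit — and is the mode used to certify null calibration. A fold
whose training part lacks a class, or whose selection returns no
features, predicts the overall prevalence (a constant carries no rank
information and scores AUC 0.5 with ties counted ½).

AUC is the Mann–Whitney U-statistic identity with ties counted ½; its
95% CI uses the DeLong placement-value variance estimator, and paired AUC
comparison the two-sided DeLong test for correlated AUCs (implemented
here; validated against a brute-force all-pairs count). The operating
threshold maximizes (sensitivity + specificity)/2 over the same candidate
grid as discretization, smallest maximizer on ties; calls are
`probability > threshold` (strict). Published decision thresholds being
unavailable, trained models store the threshold chosen on their LOOCV
probabilities.

Validation applies a frozen model — features, cutoffs, coefficients,
threshold unchanged — to cohorts checked to be sample-disjoint from
training. BMI (pre-pregnancy, kg/m²) can be appended as a raw continuous
covariate to a trained model's binary design; coefficients are refit, the
LOOCV is re-evaluated, and the paired DeLong p-value against the
promoter-only model is reported. BMI is not discretized: no published
cutoff exists for it, and a monotone continuous risk factor loses
information under binarization.

## Synthetic cohort generator

The generator emulates the features of cfDNA promoter profiling that the
pipeline's statistics rely on:

* **Annotation** — `n_genes` transcripts on `n_chromosomes`, TSSs ≥ 10 kb
  apart (windows never overlap), both strands, 50 kb edge margins.
* **Expression** — log-normal (long-tailed) with a shared cross-tissue
  component plus tissue noise, giving realistically correlated placenta
  and whole-blood profiles; ~5% of genes each are placenta-specific,
  blood-specific (zero in the other tissue), and unexpressed (zero in
  both). Promoter activity in [0, 1] is the fractional expression rank
  within the tissue; unexpressed genes have activity 0.
* **Fragments** — each sample draws exactly `fragments_per_sample`
  fragments. A fragment's tissue is placental with probability
  `placental_fraction` (default 0.10, the canonical pregnancy value).
  Midpoints are proposed uniformly and thinned with probability
  `activity × depletion_depth × exp(−d²/2σ²)` where d is the distance to
  the nearest TSS in the fragment's tissue of origin — an inverted
  Gaussian dip (smooth, parameter-sparse) with σ = depletion_width/2
  (default width 1000 bp) and default depth 0.6. Evaluating the kernel at
  the midpoint keeps the coverage dip centred on the TSS. Fragment
  lengths are Normal(167, 20) truncated to [50, 400] bp, the
  mononucleosome cfDNA mode.
* **Planted effects** — case samples add an extra uniform proposal
  component of mass (2^effect_lfc − 1) per bp over each planted pTSS
  window (widened by half a fragment length so overlap counting sees the
  full boost), making the expected case/control window-count ratio exactly
  2^effect_lfc. Planting is implemented as this multiplicative intensity
  boost rather than an activity shift because the bounded depletion dip
  (≤ depletion_depth × mixture activity) cannot produce |log2FC| ≥ ~0.7,
  let alone the 1.5 used in the recovery experiments. `effect_lfc = 0`
  yields a null cohort with cases and controls identical in law.
* **Covariates** — BMI is Normal(21.3, 2.2) for controls with a +1.5 kg/m²
  case shift by default (the clinical direction); gestational age is
  matched between groups. One master seed; per-sample seeds are fixed
  integer offsets from it, so cohorts are reproducible sample-by-sample.

What the generator does **not** model: sequencing error, GC and
mappability bias, platform batch effects, copy-number changes,
fragment-size differences between tissues, and biological overdispersion
beyond sampling noise. Consequently planted signals are much cleaner than
patient data — a planted log2FC of 1.5 at ~15 fragments per window is
recovered essentially completely, and trained classifiers reach LOOCV
AUCs near 1.0 where published patient-data classifiers sit near 0.72–0.81.
Passing tests certify the pipeline's correctness and calibration, not
clinical performance.

## Problem sizes used by the test suite

The simulation suites run at deliberately desk-sized conditions: the
planted-signal study uses 40 + 40 samples × 2000 promoters (≈ 25 Mb toy
genome) at 150 000 fragments per sample (≈ 15 fragments per window,
comparable to promoter counts from ~0.5–1× low-pass WGS); the mechanism
cohort 10 + 10 × 1000 promoters at 75 000 fragments; null calibration ten
seeds of 20 + 20 × 1000 promoters. The 20 + 20 null size is chosen so the
rank-sum p-value lattice is fine enough for a Kolmogorov–Smirnov
uniformity test to be meaningful: at 10 v 10 the exact two-sided p-value
places ≈ 9% of its null mass exactly at 1.0, which any KS test flags
regardless of implementation correctness.

## Known limitations

* Fixed-mode LOOCV inherits the published design's selection bias; use
  strict mode for unbiased generalization estimates.
* The exact Wilcoxon path is limited to n ≤ 20 tie-free samples; beyond
  that the tie-corrected normal approximation is used.
* DeLong CIs are truncated to [0, 1] and degenerate (zero-width) at
  AUC = 1, where the placement variance vanishes.
* Gene-level reduction keeps one transcript per gene; alternative
  promoters of the same gene are not modelled separately downstream.
* No batch correction is applied across sequencing platforms; a platform
  column in the metadata is carried through and logged only.
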