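# Methods

This note documents the models, parameter choices and numerical decisions
behind `mstates`, in the order the pipeline runs them.

## Synthetic cohorts

No public raw EEG accompanies the clinical resting-state design this
package targets, so validation rests on a generator whose defaults encode
that design: two groups of 18 subjects, eyes-closed resting EEG at 250 Hz,
~4 minutes per subject (`duration_s=240`), four quasi-stable topographies
with dwell means inside the canonical 60–120 ms range (defaults 70, 80, 90,
80 ms), and a planted group effect — group B's map-C dwell mean multiplied
by 1.3 — emulating the kind of single-map duration difference such studies
report. The channel count defaults to 64 rather than a high-density 204+
cap: template recovery and parameter estimation behave the same while
desk-scale runs stay fast; it is a config knob.

**State dynamics.** Dwell times are geometric per sample (mean =
`dwell_mean_ms`), successors drawn from a row-stochastic transition matrix
with structurally zero diagonal — the simplest semi-Markov model consistent
with a first-order Markov transition analysis. The empirical dwell
distribution of real microstate sequences is not firmly established;
geometric dwell is a modeling assumption of the generator, not a claim
about the data, and recovery tests only rely on its mean.

**Signal model.** The active template is scaled by a strictly positive
alpha-modulated envelope |sin(2π·10 t)| + 0.1, giving GFP maxima at 20/s —
a realistic peak rate for peak-based clustering — and an eyes-closed
alpha-dominant spectrum. The template's polarity is piecewise constant
between envelope troughs and flips there with probability 0.8. Mostly
alternating signs reproduce a genuine ~10 Hz oscillation and put the
spectral peak inside 8–14 Hz; independent signs (flip probability 0.5)
would concentrate the pulse-train spectrum at 0 Hz instead. The residual
randomness still exercises the polarity-invariance contract of the
clustering and back-fitting stages.

**Noise.** Spatially correlated Gaussian noise (channel-white noise
smoothed across neighboring electrodes with a Gaussian kernel of scale 0.5
on the unit-sphere montage, mixed 70/30 with white sensor noise), scaled so
the state-signal-to-noise RMS ratio equals `snr` exactly (default 4). Pure
white noise would make the clustering unrealistically easy.

**Templates.** Each template is the field of a random point dipole inside
the head sphere — smooth and dipolar like canonical microstate maps —
average-referenced, unit-norm, with candidates rejected until all pairwise
|r| < 0.8 so the group-level merge rule is not triggered by construction.
There is no biophysical forward model (no lead fields, no artifacts);
consequently, passing recovery tests demonstrates correctness of the
estimators under this signal model, not robustness to real artifacts,
volume-conduction structure, or non-stationarity.

Inter-subject variability is lognormal jitter (sd 0.1 on the log scale) of
the per-map dwell means. All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning; outputs are bitwise reproducible.

## Preprocessing

Second-order Butterworth band-pass 1–40 Hz plus an IIR notch at 50 Hz
(quality factor 30 — only the notch frequency is conventionally reported,
the bandwidth is our choice), both applied forward-backward. Zero-phase
filtering is chosen because segmentation boundaries are timing-sensitive.
Common average reference; polyphase resampling to 250 Hz (duration
preserved within one sample). GFP uses the population (1/C) normalization —
only relative values matter downstream. GFP peaks are strict local maxima;
plateaus resolve to their leftmost sample and endpoints are never peaks
(deterministic tie-breaking).

## Clustering

`ModifiedKMeans` alternates (a) assignment by maximal squared spatial
correlation and (b) template update as the first principal component of the
assigned maps' outer-product sum — the standard polarity-invariant update.
Both steps are coordinate ascent on GEV, so the per-restart iteration
converges monotonically; convergence is declared when the GEV improvement
falls below 1e-6 (at most 200 iterations), and the best of `n_init` random
restarts (default 300; restart templates are peaks sampled without
replacement) is kept. An empty cluster is re-seeded from the worst-fit
peak, iterating because a re-seed can steal a singleton cluster's only
member. `cluster_across_k` additionally warm-starts each k from the
previous solution plus the worst-fit peak, which makes best-of-restarts GEV
non-decreasing in k.

**Meta-criterion.** The reference implementation's exact metric set is
unpublished, so the number of maps is chosen by a documented median vote of
five internal validity criteria: silhouette on the polarity-invariant
distance 1−|r| (on a deterministic subsample of ≤ 400 peaks),
Calinski–Harabasz and Davies–Bouldin on polarity-aligned peak maps,
Krzanowski–Lai on the GFP-weighted dispersion curve, and a
cross-validation-style criterion (residual variance × ((C−1)/(C−1−k))²).
Ties take the smaller k; degenerate single-pattern input returns the
smallest candidate k. All criterion values are reported for audit.

**Two-level procedure.** Subject-level clustering (per-subject
meta-criterion, overridable to a fixed k for speed) produces subject
templates that are pooled, equally weighted, into group-level clustering;
group maps with |r| ≥ 0.80 are merged into their count-weighted dominant
pattern. The group GEV is reported over the pooled subject templates, not
the raw samples — data-level explained variance per map comes from
back-fitting.

Temporal smoothing parameters are listed among clustering parameters in
common reporting practice, but clustering operates on discontiguous GFP
peaks where a temporal window is undefined; smoothing is therefore applied
only at the back-fitting stage.

## Back-fitting and parameters

Assignment: per sample, argmax of |spatial correlation| over templates;
samples below the 0.5 threshold (or with zero spatial variance) are
UNASSIGNED; exact ties go to the lower map index. Smoothing is a penalized
windowed relabeling run to a fixed point (≤ 50 left-to-right sweeps): each
assigned sample's score for map m is the GFP²-weighted squared-correlation
support summed over ±3 samples plus `strength`/(2w+1) × mean(GFP²) per
window neighbor currently labeled m. With window 0 and strength 0 the
segmentation is unchanged; single-sample intrusions inside long runs are
removed at the defaults. The reference smoothing implementation is
described without equations in the literature, so equivalence with it is
not claimed; the algorithm and parameters here are documented and
exposed. UNASSIGNED samples are never relabeled, and smoothing may keep a
sample on a map whose instantaneous correlation is below the assignment
threshold — temporal context is the point of the pass.

Parameters per map: GEV_m = Σ_{label=m} (GFP_t·r_t)² / Σ_t GFP_t² × 100
(denominator over all samples); mean duration = mean run length in ms, runs
truncated at the record edges counted (deterministic; excluding them is not
implemented); coverage = percent of total samples, so coverages sum below
100 when UNASSIGNED samples exist; occurrence = runs per second. On fully
assigned segmentations coverage = occurrence × duration / 10 holds to
floating-point accuracy and is enforced by tests.

## Transitions

Transitions are counted between consecutive distinct-label *runs*;
transitions into or out of UNASSIGNED stretches are dropped. The expected
model draws successors in proportion to per-map run counts with the source
map excluded from the normalizing pool — including it would bias expected
probabilities downward given the structurally zero diagonal. Run counts
(not sample coverage) parameterize the expectation because transitions are
run-level events; the choice is configurable at the call site by passing a
different frequency vector.

## Group statistics

- Pooled-variance t (df = n₁+n₂−2) rather than Welch: the reporting
  convention df = 34 for 18 + 18 fixes the pooled form. Cohen's d uses the
  pooled SD.
- Mann–Whitney U is oriented to the first argument; p exact when
  n₁·n₂ ≤ 400 and tie-free, otherwise a continuity- and tie-corrected
  normal approximation. Cliff's δ = 2U/(n₁n₂) − 1.
- Li–Ji M_eff = Σ f(|λ_i|), f(x) = I(x ≥ 1) + (x − ⌊x⌋), over the
  eigenvalues of the variables' correlation matrix; per-test α =
  1 − (1−α)^(1/M_eff). The pipeline recomputes M_eff from its own data for
  the parameter family and the transition family separately rather than
  hard-coding any published threshold.
- TANOVA: subject maps are average-referenced and scaled to unit GFP; the
  statistic is the root-mean-square difference of the re-normalized
  group-mean maps; group labels are permuted (default 5000), and the
  observed statistic is included in numerator and denominator, so p ≥
  1/(n_perm+1). Subject maps are assumed polarity-aligned (the pipeline
  aligns each subject's class-mean map to the group template before
  testing).
- Benjamini–Hochberg FDR via statsmodels; bootstrap CIs are percentile
  intervals over paired resamples (default 5000), deterministic under a
  fixed seed; degenerate resamples are skipped.

The "rejected for p greater than α" phrasing that sometimes appears in
reports is treated as the conventional "less than".

## Spectra

One Hanning-tapered FFT over the whole record, zero-padded to the next fast
length with grid spacing ≤ 0.034 Hz; scaling preserves Parseval's identity
exactly (band-summed power equals the tapered mean square). Canonical bands:
delta 0.5–4, theta 4–8, alpha 8–14, low beta 14–26, high beta 26–40 Hz.
(The delta band's lower edge lies below a 1 Hz high-pass; the band edges
are configuration, and the package does not resolve that reporting
inconsistency.) The beta split can be re-derived by k-means on standardized
(frequency, log-power) pairs in a 14–40 Hz window — log power first,
because raw 1/f power dominates the distance otherwise — with boundaries at
midpoints between adjacent clusters' frequency extents (best of 20 seeded
restarts).

## Problem sizes in the test suite

The suite validates the estimators at desk scale: recovery and
planted-effect tests use 36-subject cohorts at 64 channels and 60 s per
subject, cluster ranges 1–8, and tens (not hundreds) of restarts; the
TANOVA calibration uses 1000 simulations × 200 permutations and the
bootstrap-coverage check 200 simulations × 400 resamples. These sizes are
the package's own choice of test conditions; all parameters scale up
through configuration, and the pipeline defaults (cluster range 1–12, 300
restarts, 5000 permutations/resamples, 240 s records) match the full
analysis the package implements.

## Known limitations

- The generator has no forward model, no artifacts (blinks, ECG, muscle),
  and stationary dynamics; tests certify estimator correctness under the
  stated signal model only.
- Manual/ICA artifact pipelines, bad-channel interpolation, source imaging
  and per-band microstate analysis are out of scope.
- Geometric dwell and the smoothing algorithm are documented choices, not
  reverse-engineered equivalents of any proprietary implementation.
- EDF files can be read (via mne) but not written; the native interchange
  format is delimited text with a JSON sidecar.
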