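# Methods

This note records the models, conventions and numerical choices behind
`neuromse`, in the order the pipeline applies them.

## Synthetic cohort model

Each subject's region time series is

```
x(t) = snr · osc(t) / rms(osc) + pink(t),
```

where `pink` is unit-SD 1/f^β noise (β = 1 by default; spectrum-shaped
Gaussian noise, DC removed) and `osc` is a narrow-band oscillation

```
osc(t) = a(t) · cos(2π f₀ t + φ(t)),    f₀ = 10 Hz.
```

**Envelope (amplitude complexity).** `a(t)` mixes a deterministic raised
cosine at 0.2 Hz (depth 0.5) with the absolute value of 0.5–4 Hz
band-limited Gaussian noise, both normalized to unit mean:
`a = (1−w)·slow + w·stoch` with mixing weight `w = amp_complexity ∈
[0, 1]`. The weight monotonically controls the short-scale entropy of the
Hilbert envelope, which is what the amplitude-MSE stage measures.

**Phase (phase complexity).** `φ(t)` is a mean-reverting (AR(1) /
discretized Ornstein–Uhlenbeck) random walk with per-sample innovation
SD `phase_diffusion` (rad) and relaxation time 2 s. Mean reversion keeps
`f₀` the spectral peak; a pure Brownian phase would destroy the
narrow-band structure the alpha IMF requires.

**Group effects.** A latent severity `s ∈ [0, 1]` (controls uniform on
[0, 0.2], patients on [0.6, 1.0]) interpolates the HC → AD parameter
pairs, and the interpolated values apply only in the designated temporal
regions; every other region uses HC parameters for all subjects, so
effects are confined by construction. Defaults encode the clinical
directions — patients have *lower* amplitude complexity (0.9 → 0.2) and
*higher* phase diffusion (0.02 → 0.05 rad/sample) — at `snr = 3.0`.
These three numbers were fixed once from a pilot sweep: at lower snr the
in-band 1/f background dominates the envelope and the amplitude contrast
becomes undetectable at realistic cohort sizes, while these values give
moderate effects (per-scale-factor |t| ≈ 2–4 at 8–20 subjects/group),
comparable to what small clinical M/EEG studies report.

**Manifest.** MMSE = clip(29 − 4·s + N(0, 3)) to [0, 30], which yields a
rank correlation of ≈ −0.4 between phase diffusion and MMSE across a
default cohort — enough structure to exercise the entropy–cognition
correlation path without claiming clinical realism. Ages and sex are
drawn to match typical HC/AD cohort demographics (68.1 ± 7.3 vs
71.7 ± 6.5 years; ~60% male); medication (donepezil) is assigned to
patients at rate 10/17. WMS-R subscores are group-conditional Gaussians
used only as manifest dressing. None of these induce signal effects.

**What the generator does not emulate:** volume conduction and source
leakage, artifacts (blinks, cardiac), non-stationary background, spatial
correlation between regions, multi-band oscillations, and any claim
about real MEG physiology. Passing tests therefore demonstrate that the
*pipeline* recovers what was injected, not that real AD data would
behave this way.

## Decomposition

Plain EMD sifts each candidate mode with natural cubic-spline envelopes
through the strict local extrema, mirror-extending two extrema per side
to suppress end swings. The inner loop runs a **fixed 10 sifts per IMF**
— the convention recommended for ensemble decompositions — because it
reproduces the canonical dyadic filter bank: on 1/f broadband input at
400 Hz (150 Hz low-pass) the five IMFs peak near >100, 40, 20, 10 and
4 Hz. A Cauchy-criterion early stop
(`Σ(h_prev − h)² / Σh_prev² < threshold`) is available via
`sift_stop_threshold` but is not the default: it halts after ~2 sifts
and shifts every mode roughly an octave low, while the classic pointwise
criterion fails to converge and over-sifts. Exactly `max_imfs = 5` IMFs
are extracted (remainder to residual), so ensemble members are
averaged index-aligned; members that run out of extrema contribute zero
IMFs at the missing indices.

EEMD adds fresh Gaussian white noise at `0.2 × SD` per ensemble member
(200 members at full scale; the member seeds derive deterministically
from the top-level seed). Completeness is exact for EMD (reconstruction
to machine precision) and bounded for EEMD by the averaged noise,
RMS ≤ noise_amp·SD/√n_ensembles (tested at 3× margin).

Consequence of the fixed-sift convention: the first mode can retain a
handful of riding waves, so the IMF property |#extrema − #zero
crossings| ≤ 1 holds only up to ~1% of the extrema count on broadband
noise; tests assert that tolerance.

The band-pass comparison path uses zero-phase 4th-order Butterworth
filters (gamma 33–55, beta 16–27, alpha 8–14, theta 4–7 Hz). IMF peak
frequencies are the argmax of a Welch PSD (segments of 1024 samples, DC
bin excluded).

## Hilbert spectral analysis

The analytic signal zeroes negative frequencies (`scipy.signal.hilbert`);
amplitude is its modulus, phase complexity uses `cos(arg)`. No edge
trimming is applied — trimming would change segment lengths downstream —
but edge-sensitive tests exclude 0.25 s per side. Zero-valued IMFs yield
a flagged-degenerate component with zero amplitude rather than masked
samples.

## Multiscale entropy

`SampEn(m=2, r=0.2)` uses ordered template pairs i ≠ j over the shared
index range i = 1…N−m for both template lengths, strict Chebyshev
inequality `< r_abs`, and returns an undefined marker (NaN) when either
count is zero. The tolerance is `r × SD` of the *un-coarse-grained*
component series of each segment (the canonical multiscale convention);
coarse-graining takes non-overlapping window means, dropping the
remainder. Per cell (component × scale factor), SampEn is computed per
segment and averaged over segments with defined values; cells with no
defined segment stay undefined (never zero), and cells whose
coarse-grained series are shorter than 25 samples are flagged
low-confidence but still computed. The implementation is exact —
verified against a brute-force pair-enumeration oracle — and for long
i.i.d. Gaussian input converges to −ln(2Φ(r/√2) − 1) ≈ 2.185 at r = 0.2.

Entropy profiles of narrow-band components ripple slightly across scale
factors where the coarse-graining window is commensurate with the
oscillation period; `count_peaks` therefore counts profile maxima after
adjacent-pair smoothing with a prominence of ≥ 10% of the profile range.
Adaptive (EEMD) alpha profiles are single-peaked under this definition
while band-pass-filtered profiles are not, reproducing the motivating
contrast for the adaptive decomposition.

## Group statistics

The screening model is a univariate split-plot ANCOVA per region group
and band: between-subject main effects (group, medication, sex; dummy
coded) plus centred age as covariate on the subject means; the group ×
scale-factor interaction tested on orthonormal contrast scores with the
error stratum being the contrast-level residual. Greenhouse–Geisser ε is
estimated from the residual covariance of the contrast scores and
clipped to [1/(k−1), 1]; both the GG-adjusted and sphericity-assumed
interaction p-values are reported, and region-level p-values are
Bonferroni-multiplied (default factor 7). Single-level factors are
dropped with a warning; subjects with any undefined profile cell are
excluded listwise. Against an independent mixed-ANOVA implementation
(single between factor, no covariate) the F statistics and uncorrected
p-values agree to machine precision; ε differs by < 0.02 because the
reference pools the covariance differently.

Two properties worth stating because they are easy to misread as bugs:
the GG ε *estimator* is biased low in small samples (≈ 0.64 at k = 20,
n = 40 under true sphericity — the bias that motivated Huynh–Feldt), and
consequently the GG-adjusted test is conservative there; calibration
tests therefore check the sphericity-assumed F at the nominal level and
the GG test for non-anticonservatism. Second, Benjamini–Hochberg at
q = 0.1 controls FDR, not family-wise error: with several strong
rejections in a family the step-up threshold rises and occasional null
flags are expected; tests assert the FDR property, not zero false flags.

Post-hoc per-scale-factor tests are pooled-variance t-tests (HC − AD
orientation) with BH across the 20 scale factors; undefined or
zero-variance cells leave the FDR family. Demographic helpers follow the
printed-table conventions: pooled t accepting (mean, SD, n) summary
tuples, and Pearson χ² without continuity correction (the only
convention consistent with the printed gender statistic).

## Classifier

Sparse autoencoders: one hidden layer (70 units at full scale), sigmoid
activations, linear decoder, loss = mean-squared reconstruction +
`l1_coeff` × mean |activation| (activation-level L1), trained by
full-batch Adam (default 200 epochs, learning rate 0.01), deterministic
per seed. The bank (300 members at full scale) differs only by seed; all
members train on every (subject, region) sample of the *training folds
only*, as do feature standardization, imputation (training-fold cell
means) and Fisher scoring. Features are (region, feature) pairs
restricted to the temporal regions; top-k by Fisher score
((μ₀−μ₁)²/(s₀²+s₁²); a zero-variance perfect separator ranks +inf, a
constant feature 0), ties toward the lower index. The subject-level
classifier is a linear soft-margin SVM (scikit-learn LinearSVC).

Double CV: per repeat, subjects are stratified into five folds
(round-robin per class after a seeded shuffle); each fold serves once as
test with the next fold as validation (3:1:1). Hyperparameters — k
uniform-integer in [100, 10000] and C log-uniform in [10⁻³, 1] — are
chosen by validation AUC over a fixed random-search budget (default 30
trials; a Bayesian searcher would satisfy the same contract), and the
train-fold-fitted model with the chosen hyperparameters is scored on the
test fold without refitting. AUC is the Mann–Whitney probability with
ties at ½; sensitivity takes AD as the positive class. Compared
architectures (plain SVM, FS+SVM, SAE+FS+SVM) share fold assignments.
Full-scale defaults are 300 repeats; scaled runs (tests, demo) use fewer
repeats and smaller SAE banks, which changes variance, not the
protocol.

## Pipeline

Stages (`simulate → decompose → hsa → entropy → stats → classify`) write
delimited-text outputs plus a `provenance.json` sidecar (stage
parameters, SHA-256 input digests, package version); a stage whose
provenance matches is skipped unless forced, and a corrupted digest
forces re-execution. The global seed feeds every stochastic stage
deterministically, so identical configurations produce byte-identical
outputs. Region-to-lobe grouping is configuration data
(`stats.region_groups`), with the Bonferroni factor equal to the number
of groups; the demo configuration ships a scaled-down analog of the
seven-lobe scheme. The ANCOVA screens the spectral MSE; post-hoc tests
cover all three components.

## Problem sizes used in the automated checks

Chosen for a single-CPU run: the dyadic filter-bank check uses 20
realizations at the full 200-ensemble setting; the single-peak contrast
8 subjects × 8 segments at 15 ensembles; effect recovery 20 replicates
of 20 subjects/group × 3 segments at 6 ensembles (plus 5 null
replicates); classifier integrity 20 repeats with a 10 × 10 SAE bank;
entropy oracles 100 short series plus one 20 000-sample Gaussian; GG
calibration 200 null ANCOVAs at n = 40 and one n = 1500 sphericity
check. The full-scale analysis parameters (200 ensembles, 12 segments,
300 SAEs, 300 repeats) remain the library defaults.

## Known limitations

- The generator's alpha band is narrower than real MEG alpha; the
  commensurability ripple in its MSE profiles is stronger than in real
  data (hence the prominence-based peak definition).
- The split-plot ANCOVA is the classical least-squares formulation; no
  mixed-effects likelihood machinery, no between-factor interactions.
- SAE training is full-batch on small sample counts; at 148 regions ×
  hundreds of subjects a mini-batch implementation would be preferable.
- EMD boundary handling (mirror extension) can still leak end effects
  into the lowest-frequency IMF on short segments.
- Classification metrics at demo scale (≤ 6 subjects) are mechanical
  smoke output only.
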