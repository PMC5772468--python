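# Methods

This note documents the generative model, the analysis conventions, the
calibration of the defaults, and what the synthetic study can and cannot
show about real data.

## Protocols and timebase

All times are hours elapsed since habitual wake (default wake time 07:12).
Both arms span 40 h with scan sessions at 5, 13, 21, 29 and 37 h. The nap
protocol (NP) alternates 160 min of scheduled wakefulness with 80-min nap
windows, ten cycles; naps therefore start at 2:40, 6:40, … 38:40 elapsed.
The biological night is the 16–24 h window; the first-day evening nap
(window 14:40–16:00, the wake maintenance zone) is identified as the nap
whose midpoint is closest to 15 h elapsed.

## Two-process sleepiness

Homeostatic pressure follows the classic saturating-exponential form,
`S_wake(t) = 1 − (1 − S0)·e^(−Δt/τr)` during wake and
`S_sleep(t) = S0·e^(−Δt/τd)` during naps, with defaults S0 = 0.38,
τr = 18.2 h, τd = 4.2 h. The circadian drive is
`C(t) = a·sin(2π(t − φ)/24)` with amplitude a = 1 and phase φ = 15 h, so
the sleepiness-promoting crest falls at 21 h elapsed (~04:00 clock time).
Latent sleepiness on the KSS scale is

    latent(t) = k0 + kS·S + kC·C + kSC·S·C .

The interaction coefficient is essential: with kSC = 0 the circadian
modulation of sleepiness would be the same whether rested or sleep
deprived, whereas the phenomenon being modelled is precisely that the
night-time surge is much larger under high sleep pressure. Defaults
kC = 0.3, kSC = 1.5 give an effective circadian amplitude `kC + kSC·S`
that roughly triples between the rested and deprived state; this choice
also makes the z(SD) − z(NP) weight profile monotone in time awake, the
behaviour expected of a "circadian influence removed" course. k0 = 3.3084
and kS = 3.4378 were calibrated once, by simulation, so that the default
31-subject cohort reproduces grand-mean KSS of 5.7 (SD arm) and 4.3 (NP
arm), then frozen. Ratings add Gaussian noise (sd 0.45 KSS) to the latent,
round to the nearest integer and clip to [1, 9]; a session's sleepiness
value is the mean of the pre- and post-scan rating, and in the NP arm each
nap also gets a pre/post rating pair around the latent at the nap
midpoint. The rating noise default was set during generator calibration:
because the NP profile is nearly flat (range ≈ 1 KSS), session-mean rating
noise propagates strongly into its z-scored weights, and 0.45 keeps that
weight noise commensurate with a plausible intra-individual rating scatter
while remaining below the between-subject trait spread (sd 0.45 KSS on
k0).

## PVT simulation

A 10-min session is a trial stream: 25% null events; a clock trial is an
ISI uniform on 2–10 s followed by a 1.5-s response-plus-feedback slot; a
null event displays its own 2–10 s counter in place of the fixation
period. This yields ≈ 63 responded trials per session. Trial timing is
drawn before response draws, so sessions with the same seed share a
schedule regardless of sleepiness.

Responses: a lapse (RT > 500 ms, exponential tail) occurs with logistic
probability `p(L) = 1/(1 + e^{−(L − x0)/s})` in latent sleepiness L;
otherwise RT is a shifted lognormal (shift 150 ms, median 90 + 12·L ms
above the shift, σ_log 0.22) truncated below 500 ms. Both the lapse
probability and the RT location are non-decreasing in L, and the lapse
indicator uses common uniforms, so a sleepier session lapses on a superset
of trials at a fixed seed. x0 = 7.708 and s = 1.632 were calibrated once
against the emulated study design's behavioural anchors — mean
session-4 lapses (13.3) and session-3 fast events (8.3) in the SD arm —
and frozen.

*Known limitation.* The emulated design's per-session counts include slightly more
lapses at 29 h than at 21 h awake, although subjective sleepiness peaks at
21 h; a lapse model monotone in a single sleepiness latent cannot
reproduce both, and this generator overshoots night-session lapses while
matching the two calibrated anchors. Real lapse dynamics carry a
time-on-task/homeostatic component not fully captured by momentary
subjective sleepiness.

## Toy brain and BOLD forward model

The toy brain is 20×24×20 voxels at 3-mm isotropic resolution with a
centred affine (so hemispheres split at x = 0 mm), carrying disjoint
axis-aligned block regions: thalamus, putamen, postcentral, parietal,
lingual, frontal. The atlas is defined by fractional extents and can be
instantiated at any grid size; analyses in the test-suite run at 12×14×12
to keep runtimes desk-scale.

A session's voxel series is `baseline·(1 + Σ_e amp_e/100·x_e(t)) + drift +
motion-coupled nuisance + AR(1) noise` with baseline 100 (so betas are in
percent signal change), where x_e is the unit-peak double-gamma-HRF
convolution of event class e's onsets, built by the same code that builds
the analysis design matrix. Drift is a random combination of the
analysis's own DCT basis and motion enters through the simulated
realignment series included in the design, so noise-free forward
simulations are recovered by OLS exactly (to 1e−6); this forward/inverse
consistency is asserted in the tests. AR(1) noise has marginal sd 2.5% of
baseline and lag-1 correlation 0.3.

### Planted effects

Ground-truth regional session-amplitude profiles are proportional to
±u, where u is the z-scored SD sleepiness profile orthogonalised against
the z-scored NP profile — the component of the sleepiness course unique to
extended wakefulness. Planting ±u (rather than the raw SD profile, which
correlates ~0.7 with the NP profile) encodes the scientific ground truth
that these regions track the homeostatic-by-circadian interaction and not
the circadian course alone, so the purely circadian contrasts are genuinely
null on synthetic data. Defaults (base amplitude A = 0.11% signal change):
thalamus +1.8A·u and putamen +1.5A·u (fast events, SD arm); postcentral
−1.4A·u, parietal −1.15A·u, lingual −0.8A·u, frontal −0.8A·u; slow-range
effects only in lingual (−0.6A) and frontal (−0.5A), leaving the thalamic
effect fast-specific. Compact subcortical blocks get larger nominal
amplitudes so their spatially smoothed effective amplitude matches the
cortical slabs. Per subject, the frontal amplitude scales as
(1 + 2.0·z(delta rebound)) and the thalamic amplitude as
(1 + 0.3·z(circadian strength)), planting the marker covariations; the
strong frontal gain makes the between-subject slope FWE-detectable at
n ≈ 26, as in the covariate analyses being emulated.

The amplitude/noise working point was chosen deliberately: anchored
contrast weights are estimated from the cohort's *observed* noisy KSS
profile, so weight-estimation error leaks a small multiple of the planted
amplitude into the nominally-null circadian contrast, with a group-t that
does not shrink with cohort size. A = 0.11% with noise sd 2.5% keeps that
leak below the detection threshold (null-contrast detections stay near
the nominal 5% FWER) while the true contrasts are detected essentially
always. This mirrors a real property of the design: with a nearly flat
circadian reference profile, the "pure circadian" contrast is intrinsically
the noisiest instrument in the set.

## Hypnograms

Naps are scored in 30-s epochs (160 per nap), drawn in 2-min blocks from
time-varying propensities: wakefulness peaks in the wake maintenance zone
(von-Mises-shaped 24-h bump centred at 14 h elapsed) scaled by the
subject's circadian promotion strength, is suppressed by homeostatic
pressure, and declines slowly over the protocol (so the first-day evening
nap carries the most wakefulness); REM propensity within sleep follows a
circadian bump centred at 25 h elapsed (late night/early morning) scaled
by the same latent, plus a sleepiness-coupled term and nap-level noise
calibrated so the (subject, nap)-level Spearman correlation between REM
minutes and the surrounding KSS rating is ≈ 0.4. NREM substages are a
fixed N1/N2/N3/N4 mixture. Epoch-level independence within 2-min blocks is
a simplification: synthetic hypnograms have realistic stage *fractions*
but not realistic bout-length distributions, so nothing downstream should
(or does) depend on stage-transition structure.

The circadian sleep-wake-promotion composite is the maximum over naps of
REM epochs as a percentage of sleep epochs, plus wake epochs in the
first-day evening nap as a percentage of nap epochs — both terms expressed
as percentages so they are commensurate ("amount of wakefulness" is not
given units in the source design; the percentage reading is an
interpretation, fixed here).

## Sleep EEG and the homeostatic marker

Baseline and recovery nights (8 h, 960 epochs of 30 s, fs = 32 Hz) are
generated as time series per epoch — white background activity (sd 20 μV)
plus a delta-band tone at a random exact FFT bin in 0.8–3.5 Hz — and
immediately reduced to one-sided Hanning periodograms (density scaling,
1/30 Hz resolution). With this convention a tone of amplitude a at a bin
centre contributes exactly a²/2 to the band-integrated power, giving a
closed-form check. Tone amplitudes are set so the expected artifact-free
NREM delta power (0.7–4 Hz, inclusive bin-centre membership) equals the
subject's planted night mean: baseline ≈ 400 μV², recovery = baseline +
planted rebound (population 80 ± 30 μV²), declining exponentially across
the night (τ = 2.5 h) with the night mean preserved. Two percent of epochs
are amplitude-scaled ×8 to mimic movement artifacts; rejection discards
epochs whose RMS exceeds 5× the median epoch RMS (the specific rule is an
implementation choice; any threshold separating ×8 artifacts works). The
rebound estimator is the recovery-minus-baseline difference of mean
artifact-free NREM delta power; subjects more than two interquartile
ranges below the 25th percentile of the group rebounds are excluded
(linear-interpolation percentiles). The default cohort plants one gross
negative rebound (−150 μV²) in the first of the 26 EEG subjects, which the
rule flags.

## Analysis conventions

* **RT partition**: lapses (RT > 500 ms) first; 25th/75th percentiles of
  the remaining RTs by linear interpolation between order statistics;
  fast/slow are strict exceedances. Lapses are excluded from the
  percentile computation (the overlap rule is not specified in the source
  design; exclusion is this package's fixed convention).
* **First-level GLM**: event classes fast/intermediate/slow/lapse, onsets
  convolved with the canonical double-gamma HRF (peak 6 s, undershoot
  16 s, ratio 1/6, 32 s support, unit peak); per-class time-modulation
  regressor (mean-centred trial index, omitted when a class has fewer than
  two events); six motion regressors; DCT high-pass at 128 s; intercept.
  Estimation is OLS — with AR(1) ρ = 0.3 noise OLS is unbiased though
  mildly inefficient, acceptable because group inference is
  permutation-based; prewhitening is deliberately not implemented.
  Null events and feedback are not modelled as regressors.
* **Smoothing**: isotropic Gaussian, FWHM 8 mm, applied to the session
  contrast volumes. Because the GLM is voxelwise-linear, smoothing betas
  equals fitting smoothed data, and applying it post-fit keeps the exact
  forward/inverse tests meaningful.
* **Anchored contrasts**: CxS_SD = z(SD means) on SD sessions; C_on_SD =
  z(NP means) on SD sessions; C_on_NP = z(NP means) on NP sessions;
  S_minus_C_SD = z(SD) − z(NP) on SD sessions (already zero-sum;
  re-centred defensively). The subtraction direction is chosen so the
  weights rise with time awake (a homeostatic slope); a sign switch is
  exposed for the opposite reading, since the two plausible directions
  differ only by T+/T− relabelling. Subjects with one missing session are
  included when their gapped profile correlates significantly (one-sided
  Pearson, α = 0.05, ≥ 3 shared sessions) with the group profile; weights
  are then re-standardised over the available sessions rather than
  imputing maps.
* **Group inference**: voxelwise one-sample t (df n−1) or covariate slope
  t (df n−2, mean-centred covariate), with FWE p-values from the
  permutation maxT distribution — sign flipping for one-sample tests,
  covariate permutation for slopes; p = (1 + #{maxT ≥ t})/(n_perm + 1),
  or the exhaustive count when fewer than n_perm distinct sign patterns
  exist (then p-values are multiples of 1/2ⁿ and the test is exact).
  Group maps are tested two-sided (maxT of |t|), with peak signs
  distinguishing activation increases from decreases. ROI small-volume
  correction recomputes the maxT null within the mask. Exclusive masking
  removes from a primary map all voxels with two-sided uncorrected
  p < 0.05 in the other speed range's map (the threshold is read as
  uncorrected); surviving FWE peaks are speed-specific. Peak tables list
  local maxima of |t| with FWE p ≤ 0.05, atlas label, hemisphere by the
  sign of x in mm (x = 0 → bilateral), Z-equivalent
  (standard-normal quantile of the t tail probability), and mm
  coordinates, sorted by p then |t|.
* **Behavioural inference**: condition/session effects are summarised
  descriptively with paired sign-flip permutation p-values (exhaustive for
  n ≤ 16); mixed-model ANOVA machinery is out of scope by design.

## Problem sizes used in the validation suite

Generator calibration checks run on the default 31-subject cohort. FWER
calibration uses 1000 null cohorts of n = 8 Gaussian subject maps on a
12³ grid with exhaustive (256-pattern) sign flipping. Pattern-recovery
frequencies use 40 seeded 31-subject cohorts on a 12×14×12 grid with 500
permutations; marker recovery uses a 26-subject cohort, matching the
number of subjects with usable sleep EEG in the emulated design. These
sizes keep each stage's statistics stable while the whole suite stays
desk-scale.

## What passing tests do and do not show

The generator shares its regressor construction with the analysis, so
forward/inverse exactness validates the estimation algebra, not the
hemodynamic model; real BOLD has nonlinear hemodynamics, spatially
structured noise, motion-by-susceptibility interactions and registration
error, none of which are simulated (motion enters only as a nuisance
series; data are born aligned). Null-contrast calibration shows the
permutation machinery is exact under exchangeability — real group maps can
violate symmetry assumptions. The behavioural calibration matches group
means by construction; it does not validate individual-level dynamics.
The planted-effect recovery frequencies characterise this pipeline's
sensitivity at the chosen SNR, not the detectability of any real effect.
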