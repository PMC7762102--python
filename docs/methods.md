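# Methods

`nvcomplexity` implements a complexity-based analysis of concurrent
EEG-fNIRS recordings acquired during working-memory testing, together with
a synthetic multimodal cohort generator that provides the statistical
structure the analysis assumes.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish.

## The analysis pipeline

### EEG chain

Raw EEG (250 Hz) is band-pass filtered 1–80 Hz with a 50 Hz notch
(zero-lag 2nd-order Butterworth, forward–backward).  The filtered signal is
decomposed into five bands — θ 3.5–8.2 Hz, α 7.4–13 Hz, β 13–30 Hz,
δ 1–4 Hz, γ 26–40 Hz — with zero-lag 4th-order Butterworth band-passes
(the broadband stage is 2nd order; the narrower band filters use 4th order
for adequate stop-bands, since the printed θ and α bands overlap by
design).  The power temporal envelope of each band is the modulus of the
Hilbert analytic signal, computed per channel; one second is dropped at
each epoch edge to discard the analytic-signal transient.  The global field
power (GFP) is the instantaneous across-channel population standard
deviation of the envelopes — envelopes first, then GFP.

### fNIRS chain

Two-wavelength (690/830 nm) intensities are converted to optical densities
`OD(t) = −ln(I(t)/I_avg)`, despiked with a wavelet procedure
(Daubechies-5, 4 levels; detail coefficients outside the central 90% of a
per-level Gaussian fit are zeroed; boundary coefficients are exempt because
they reflect the signal extension, not motion), band-passed 0.01–0.4 Hz
(zero-lag 4th-order Butterworth), and converted to ΔO₂Hb/ΔHHb (µM) with
the modified Beer–Lambert law:

    (ΔO₂Hb, ΔHHb)ᵀ = (1/d) · M⁻¹ · (ΔOD(λ₁), ΔOD(λ₂))ᵀ,
    M[i][j] = ε_j(λ_i) · DPF(λ_i, age)

with `d` the geometric source–detector distance in mm (35 mm long, 15 mm
short channels).  Extinction coefficients (mm⁻¹µM⁻¹, Gratzer/Prahl
compilation) and the general age/wavelength DPF polynomial ship as a
versioned JSON data file and can be overridden.  Because the OD
normalisation fixes an arbitrary per-trace constant, concentration changes
are defined up to an additive constant; all downstream statistics are
either mean-invariant or applied to band-passed (zero-mean) series.

The global scalp-hemodynamic component is estimated as the first principal
component across the short (15 mm) channels, per chromophore; each long
channel's scalar loading on that component is estimated by least squares
and the fitted contribution subtracted.  Scalp regression is applied after
MBLL, on hemoglobin series (the underlying reference method operates on
hemoglobin signals; the source text permits either order).  The corrected
long channels are averaged into one ΔO₂Hb and one ΔHHb trace.

### Complexity metrics

**Sample entropy.**  SampEn(m, r, N) = −ln(A/B), where B counts ordered
template pairs (i ≠ j) of length m within Chebyshev distance r and A the
same count at length m+1, both over the same starting-index range
(Richman–Moorman convention).  The printed normalisation in the source
formula uses different denominators at the two template levels, which is
internally inconsistent; the implementation and its brute-force oracle both
use the standard convention, which the toolbox the formula cites follows.
Defaults: m = 2, r = 0.2·SD (population SD), τ = 1 (τ appears in the
formula but is never set in the source; 1 is the universal default).
Undefined cases (zero variance with a relative tolerance, or no m+1
matches) raise rather than returning a sentinel.

**Conditional entropy.**  H(Y|X) = −Σ p(x,y) ln p(y|x) in nats, with each
series discretized by its own quantile (equal-mass) bins, 8 by default.
Quantile binning makes the estimate invariant under strictly monotone
amplitude transforms of either series.  The direction is fixed as
H(hemoglobin | EEG): the residual entropy of the hemodynamic signal once
the electrical signal is known, i.e. a neurovascular-coupling (NC) index
that *decreases* as coupling strengthens.

**Timescale matching.**  For the NC features, each band's GFP envelope is
convolved with the canonical HRF (see below), anti-alias low-passed at
0.4 × the fNIRS rate, and evaluated on the fNIRS-rate time grid (after the
low-pass there is no content near the new Nyquist, so grid interpolation
is exact to numerical precision).  The first `kernel_length` seconds of
the convolved series — the convolution start-up transient — are discarded,
and the hemoglobin trace is trimmed to the same window so the pair stays
aligned in time.  The convolution is applied per band (the source is
ambiguous between one broadband convolution and per-band; per-band matches
the 10 band × chromophore NC features).

**Canonical HRF.**  Difference of two gamma densities parameterised by
their modes: peak at 6 s, undershoot at 16 s, dispersions 1 s,
peak:undershoot ratio 6, kernel length 32 s, peak-normalised to 1.  The
mode parameterisation puts the kernel maximum exactly at `peak_delay`.

**Stationarity gate.**  Before any entropy is computed, each measured
series (band GFP envelope, decimated for SampEn; each averaged hemoglobin
trace) passes a Phillips–Perron Z_τ unit-root test at α = 0.05
(constant-only regression, Bartlett-kernel long-run variance, MacKinnon
asymptotic p-values).  If the unit root is not rejected the series is
linearly detrended and retested; series still non-stationary are flagged
and their features marked invalid — never silently zeroed.  Two choices
here deserve comment:

* *Truncation lag.*  The long Newey–West lag `12·(n/100)^{1/4}` is the
  default.  Band-limited physiological signals are heavily oversampled
  relative to their bandwidth (hemoglobin content ≤ 0.4 Hz sampled at
  10.42 Hz), and with the short lag the serial-correlation correction is
  badly undersized: perfectly stationary hemodynamic series get flagged as
  unit roots, preferentially in subjects with strong coupling.  With the
  long lag the test keeps its nominal behaviour on white noise (≥95%
  pass), trends (detrended, then pass) and random walks (flagged in the
  large majority of runs).
* *What is gated.*  The gate is applied to the measured series.  The
  HRF-convolved regressor inherits the verdict of the envelope it derives
  from: the convolution is a deterministic linear transform, and a
  unit-root test applied to so heavily smoothed a series has essentially
  no power at any realistic epoch length.

**Epoch equalisation.**  Paired series entering CondEn are truncated to
the shorter length (initial samples kept); in a cohort the per-phase
epochs are cut to the shortest subject's duration (the analysis assumes
roughly 4-minute epochs).

**SampEn cost control.**  Band GFP envelopes are decimated (anti-aliased)
to 25 Hz before SampEn; the O(N²) template count at 250 Hz would dominate
the run time without adding information above the envelope bandwidth.  The
decimation rate is a config knob (0 disables).

### The 17 features

Per subject × phase: 5 EEG SampEn (band GFP envelopes), 2 fNIRS SampEn
(averaged ΔO₂Hb, ΔHHb), 10 NC CondEn (each chromophore × each band).
Names and order are fixed and documented
(`sampen_eeg_{theta,alpha,beta,delta,gamma}`, `sampen_{o2hb,hhb}`,
`conden_{o2hb,hhb}_{theta,alpha,beta,delta,gamma}`) so classifier weights
are attributable.  A validity flag accompanies every feature.

### Group inference

* **CI filter.**  Per phase × feature × group, a bootstrap 95% CI of the
  value distribution (1000 resamples; each contributes the moments-based
  interval `mean_b ± 1.96·SD_b`, bounds averaged); values outside are
  excluded *individually* (degrees of freedom then vary per metric, as in
  the source's test table).  The moments-based form is deliberate: the
  source's printed CIs extend below zero for non-negative entropy metrics,
  which within-sample percentile bounds cannot do, and percentile bounds
  would trim the two most extreme values of nearly every group — a
  trimming that empirically inflates the downstream t statistics and
  destroys type-I control (measured: without any filter 20/20 null cohorts
  show no FDR-significant metric; with percentile trimming only 12/20;
  with the moments-based interval 16/20, and typical groups lose at most
  one value).  The filter feeds the descriptive statistics only: the
  classifiers use all gate-valid features, independently of the
  descriptive results, as the source states explicitly.
* **t-tests.**  Unpaired Student (pooled variance; the printed degrees of
  freedom are consistent with pooling), Cohen's d with pooled SD,
  Benjamini–Hochberg FDR across the metrics of one phase at α = 0.05.
* **Classifier.**  Per feature family (EEG: 5, fNIRS: 2, NC: 10 — never
  all 17 together, which would approach the size of the smaller class), an
  ordinary-least-squares linear model of the label (AD = 1, HC = 0) on the
  family's features plus intercept, scored by leave-one-out
  cross-validation; a full-sample fit reports the β weights.  Subjects
  with an invalid feature in the family are dropped for that family.
  Rank-deficient designs fall back to the pseudo-inverse with a warning.
* **ROC.**  Threshold sweep over the unique out-of-sample scores; the
  reported AUC uses the Mann–Whitney rank formulation with midranks, which
  equals the trapezoidal area of the sweep (asserted to 1e-12 in tests).
  Operating thresholds are inputs chosen for the desired
  sensitivity/specificity compromise; a Youden-optimal helper exists but
  is not the default.
* **AUC comparison.**  DeLong's paired test for correlated ROC curves
  (the source reports z statistics without naming a test; DeLong is the
  standard choice and the implementation matches R's `pROC::roc.test` to
  printed precision on fixtures).

## The synthetic cohort generator

The generator is first-class, tested code.  It emulates the features of
real data the analysis relies on; its defaults are the study conditions
(17 AD + 18 HC; 250 Hz EEG; 10.42 Hz two-wavelength optics; 16 long
35 mm + 4 short 15 mm channels; three phases of 240 s — the source
analysed epochs of roughly 4 minutes).  Ages are drawn from the reported
group moments (AD 67.6 ± 9.3, HC 69.2 ± 9.1 years), truncated to
[50, 90]; age feeds the DPF.

* **EEG.**  Per band: one shared "cortical source" (narrowband Gaussian
  noise) amplitude-modulated by a slow (≤0.2 Hz) positive modulator,
  projected to channels with heterogeneous topographic gains
  (U(0.2, 1.4)), mixed with channel-local narrowband noise, plus 1/f
  background.  The heterogeneous projection matters: with identical
  projections the across-channel SD (GFP) *anti-correlates* with source
  activity and no coupling information would survive the GFP step.
* **Neural drive.**  The Hilbert envelope of the summed band sources,
  low-passed at 0.5 Hz — i.e. exactly the quantity class the NC analysis
  estimates from EEG.
* **Hemodynamics.**  The drive is convolved with the canonical HRF,
  standardised, scaled by the group coupling gain × 0.5 µM, and injected
  into long channels only as ΔO₂Hb, with ΔHHb = −0.3·ΔO₂Hb
  (functional-hyperemia polarity, keeping both chromophore features
  informative).
* **Scalp.**  Mayer (~0.1 Hz), respiratory (~0.3 Hz) and cardiac (~1 Hz)
  oscillations with slow amplitude jitter form one global waveform,
  injected into *all* channels up to a per-channel gain — exactly the
  rank-one structure the short-channel regression assumes.
* **Optics.**  Channel hemoglobin maps to two-wavelength OD through the
  same extinction/DPF forward matrix the inversion uses, plus optional
  Gaussian OD noise (default SD 0.01, typical continuous-wave fNIRS
  noise) and Poisson motion spikes (1/min, ~3-sample exponential decay);
  intensities are `I₀·exp(−OD)` with per-trace `I₀`.  With noise, spikes
  and scalp off, the forward model composed with the OD conversion and
  MBLL is the identity on concentrations to ~1e-14 (mean-centred; the OD
  normalisation fixes the constant).

**Coupling-gain defaults.**  HC 1.0, AD 0.1 — severe neurovascular
dysregulation in the patient group.  The choice is deliberate: CondEn with
quantile binning is amplitude-invariant, so once the coupled signal sits
far above the residual noise floor at *both* gains the metric saturates
and carries no group information.  The group contrast lives in the ratio
of coupled signal to residual (noise + imperfect scalp removal), so the AD
gain must place the coupled signal near that floor.  With these defaults
the AD group shows *higher* NC CondEn (more residual hemodynamic entropy,
i.e. weaker coupling), mean per-feature |d| ≈ 1.4 at the default noise.

**What the generator does not emulate:** ocular/muscular/cardiac EEG
artifacts (the analysis of real data would interpose ICA cleaning, which
is out of scope here), realistic head-geometry photon transport,
channel-specific scalp physiology (scalp is exactly rank-one),
frequency-domain NIRS phase data, and any EEG spectral fingerprints of
disease (the synthetic group difference is confined to the coupling gain).
Consequently, passing end-to-end tests shows the *pipeline* recovers a
coupling-gain group difference at realistic n and noise — not that these
features separate real AD patients from controls, and not that EEG or
fNIRS SampEn families should classify above chance here (by construction
they should not).

## Validation problem sizes

Single-recording contracts (filter responses, round trips, feature schema)
run at 60–240 s.  The Monte-Carlo cohort experiments (classifier recovery,
null calibration, FDR control) use 20 cohorts × (17+18) subjects per
condition with one 180-second phase and 8 EEG channels: 180 s is the
shortest epoch at which the 0.01–0.4 Hz hemodynamic band contains enough
cycles for the stationarity gate to hold its nominal size (at 90 s,
gate failures concentrate in strong-coupling subjects and bias the
retained sample).  Under the strong-contrast defaults the NC-family LOOCV
AUC averages ≈ 0.95 over 20 seeds; under equal gains it averages ≈ 0.45
— leave-one-out scoring with 10 regressors at n = 35 is slightly
pessimistic relative to 0.5, a known property of LOOCV, and individual
null cohorts range roughly 0.28–0.61.

## Known limitations

* The package analyses synthetic or user-supplied recordings; no claim is
  made about reproducing the clinical study's printed statistics, which
  derive from undeposited patient data.
* The θ/α band overlap is implemented exactly as printed; features from
  the two bands are therefore correlated by construction.
* The PP gate's behaviour on short epochs (< 3 min) of 0.01–0.4 Hz
  signals is intrinsically poor; epoch durations below ~180 s will
  produce many gate-invalid hemoglobin features.
* EDF output quantises to 16 bits over each channel's range (relative
  error ≤ 1/65535 of the range); SNIRF output is lossless float64.
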