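# Methods

This note documents the models and procedures implemented in `tremormark`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Signal model and conditioning

A resting-tremor sEMG trace is treated as band-limited interference-pattern
noise whose amplitude is modulated by bursts of grouped motor-unit
discharges at the tremor frequency (~3–8 Hz, typically near 5 Hz).
Conditioning follows standard surface-EMG practice:

* **Band-pass 20–200 Hz.** Butterworth, designed automatically as the
  minimum order meeting explicit specifications (stop-band edges 10/230 Hz,
  ≤3 dB pass-band ripple, ≥40 dB stop-band attenuation; at 512 Hz this
  yields a 7-section second-order cascade). Applied forward–backward
  (zero phase) so envelope timing, zero crossings and slope reversals are
  not phase-distorted. The specs double under the two passes; the test
  suite checks the single-pass response against the design targets.
* **Segmentation.** Non-overlapping 1-s epochs; a trailing remainder
  shorter than 1 s is dropped. Time-domain features are computed per epoch
  and averaged.
* **Artifact rejection.** Manual expert screening is replaced by a
  reproducible amplitude-clip rule: an epoch is rejected when its peak
  absolute amplitude exceeds `k = 5` times the median per-epoch peak. The
  rejected count is logged and carried in the feature metadata.
* **Envelope.** Full-wave rectification followed by a centred 50-ms
  sliding-window RMS; at the edges the window shrinks rather than padding,
  so burst onsets are not diluted with fabricated samples. 50 ms is short
  against the ~200 ms tremor period (envelope tracks bursts) and long
  against the EMG carrier (~5–50 ms periods), which it averages out.

## The twelve features

Amplitudes are microvolts throughout; there is no unit column in any file.

| feature | definition | notes |
|---|---|---|
| wRMS | mean over epochs of per-epoch RMS | the "weighting" is the per-epoch averaging; a per-epoch weight hook is configurable |
| MMAV1/MMAV2 | weighted mean of \|x\| per epoch | weight 1 on the central half of 1-based indices; 0.5 (MMAV1) or linear ramps 4i/N, 4(N−i)/N (MMAV2) on the outer quarters |
| WL | Σ\|x_{i+1}−x_i\| per epoch | waveform length |
| ZC | sign changes with step ≥ `eps_zc` | `eps_zc = 50 µV` fixed amplitude threshold (Hudgins convention); a zero sample adopts the previous nonzero sign |
| SSC | interior points with (x_i−x_{i−1})(x_i−x_{i+1}) ≥ `eps_ssc` | `eps_ssc = 1250 µV²` |
| SampEn | −ln(A/B), m = 2, r = 0.2·SD, Chebyshev distance, self-matches excluded | computed on the concatenated retained signal decimated to ≤ 8192 points; capped at 10 (flagged) when no m+1 match exists |
| Peak(f), Peak(f)PSD | argmax of the envelope Welch PSD in 2–12 Hz; power as 10·log10(PSD) | ties break to the lower frequency; see detection rule below |
| MDP, MNP | median / mean PSD value over 20–200 Hz of the filtered signal | |
| FR | Σ PSD(20–60 Hz) / Σ PSD(60–200 Hz) | the low/high frequency-ratio feature; the split is configurable |

**Why fixed ZC/SSC thresholds.** With a near-zero threshold these counts
are scale-invariant functionals of the spectral shape and cannot respond to
amplitude suppression at all; published per-second counts of order 10 for a
signal that crosses zero hundreds of times per second imply thresholded
counting. The defaults are set against the package's µV amplitude
convention (typical off-state burst gain ~40 µV) so that crossings are
counted essentially during tremor bursts. Setting `eps = 0` restores the
raw scale-invariant counts (used by the scale-equivariance tests).

**Spectral routing.** The tremor rhythm (~5 Hz) lies below the 20 Hz filter
edge, so it is observable only as amplitude modulation: Peak(f) and
Peak(f)PSD are computed from the rectified-envelope spectrum. MDP, MNP and
FR summarise the EMG band itself and use the filtered (unrectified) signal.
Welch settings: 2-s Hann windows, 50% overlap, zero-padded to a ≤0.125 Hz
grid.

**Tremor-peak detection.** A peak is declared only when the in-band maximum
exceeds 2.5× the in-band median PSD; otherwise Peak(f)/Peak(f)PSD are
missing (not zero). The threshold separates the measured no-tremor regime
(noise envelopes reach ratios ≈ 2.1) from genuine bursts (ratios ≥ 4.5).
Strongly suppressed DBS-on recordings legitimately flag as "no tremor".

**Sample entropy at scale.** Pair counting uses a KD-tree under the
Chebyshev metric — exact, and verified against an O(N²) double-loop oracle
— so 60-s recordings cost ~0.2 s. Uniform decimation to ≤8192 points bounds
the cost; with r defined relative to the SD of the decimated signal, the
value is scale-free.

**Multi-channel reduction.** Per patient, the channel with the highest
DBS-off tremor-band envelope power is used for both conditions (the muscle
where tremor is best expressed); averaging across channels is available by
configuration.

## Cohort statistics

Improvement rates are fractions, positive for improvement:
`(pre − post)/pre` for clinical scores, `(off − on)/off` for features.
Sample entropy therefore takes negative IRs (stimulation raises entropy).
Feature IRs are missing when the off value is not positive.

Paired DBS-off/on comparisons use two-sided paired t-tests per feature with
no multiple-comparison correction (a Benjamini–Hochberg column is available
behind a flag). Zero-variance differences report p = 1 with a degenerate
flag. The co-correlation map Spearman-correlates the per-patient IRs of the
features that changed significantly, and zeroes entries with p ≥ α.

Feature selection Spearman-correlates each feature's IR against the
clinical tremor-scale IR and keeps features with p < α (default 0.05),
sorted by |R|. A feature observed in fewer than 80% of patients (e.g. the
tremor peak, undetectable in many DBS-on recordings) is not selectable:
the prediction model is complete-case, and selecting a mostly-missing
feature would silently shrink the cohort.

## Prediction model

`ImprovementGPR` regresses the clinical IR on the selected feature IRs
(at most the top 3 by |R|, matching the arity a ~39-patient cohort
supports) with a Gaussian process: constant mean, ARD squared-exponential
kernel with learned signal variance, per-feature length scales and white
noise, targets normalised internally, inputs standardised with
training-fold statistics only. Length scales are bounded below at 0.3 (on
standardised inputs) and the noise variance at 1e-2 (on normalised
targets): small noisy cohorts otherwise let marginal-likelihood
optimisation interpolate noise, which both degrades LOOCV predictions and
inflates the permutation null.

Two LOOCV routes:

* `per_fold` (default): hyperparameters re-optimised for each held-out
  patient — fully leak-free, n fits per evaluation.
* `shared`: hyperparameters optimised once per data set, then the exact
  closed-form Gaussian-process leave-one-out means
  (`loo_i = y_i − [K⁻¹y]_i/[K⁻¹]_ii`). One fit per evaluation; inputs are
  standardised on the full sample in this mode. The two routes agree
  closely (correlation > 0.95 in tests); the fast route powers the
  simulation studies.

The permutation test shuffles the clinical IRs, re-runs the full LOOCV fit
(hyperparameters re-optimised per permutation) and recomputes r. Feature
selection is performed once on the real labels and held fixed — mirroring a
select-then-permute order of operations; under a global null this is
optimistic, which the uncoupled-cohort simulations quantify (false-positive
rate remains near the nominal 5%). The primary p-value is
`count(r_perm ≥ r_true)/P`; because it can return 0, the positively biased
`(count+1)/(P+1)` estimator is co-reported.

## Synthetic cohort generator

One patient is generated as follows (defaults are the study conditions):

* latent clinical improvement `u ~ Beta(α, β)` with mean 0.76, SD 0.15
  (α, β from method of moments); EMG-level improvement `u_emg` shares that
  marginal through a Gaussian copula with correlation ρ (default 0.7).
  A copula rather than clipped additive noise: clipping piles probability
  mass at 1 and destroys the intended rank coupling.
* tremor frequency `f ~ N(4.93, 0.98²)` truncated to 3–8 Hz, identical in
  both conditions (stimulation suppresses bursts without shifting their
  frequency);
* DBS-off signal `x(t) = floor·n_bg(t) + gain·m(t)·n_burst(t)` at 512 Hz,
  where `m(t)` is a half-wave-rectified sinusoid at `f`, squared and
  normalised to peak 1; `n_bg` is unit-SD noise in 20–200 Hz and `n_burst`
  unit-SD noise in 20–100 Hz (grouped motor-unit discharges during bursts
  concentrate power at lower EMG frequencies — this is what lets the
  frequency-ratio and crossing-count features respond to stimulation);
  burst gain is log-normal (median 40 µV), modulation depth
  `gain/(gain+floor)` uniform on 0.6–0.95;
* DBS-on: burst gain × (1 − u_emg), tonic floor × (1 − 0.8·u_emg). The
  partial floor suppression reflects reduced tonic pathological activation
  under stimulation; a 20% baseline tone is never suppressed, so a full
  responder retains floor noise only. With a fully fixed floor, amplitude
  IRs are dominated by the depth draw instead of u_emg and the intended
  EMG–clinical coupling does not survive to the feature level;
* scores: UPDRS-t pre `~ N(15.60, 5.13²)` truncated to 4–28 and rounded;
  post `= round(pre·(1−u) + ε)`, ε ~ N(0, 0.8), clipped at 0. UPDRS-III
  analogous (pre ~ N(63.42, 17.85²), improvement mean 0.52).

What the generator does **not** emulate: motor-unit action-potential
shapes, recruitment and firing statistics, electrode/skin effects, mains
hum, non-stationary tremor (waxing/waning, re-emergence), movement
artifacts beyond amplitude clips, and any DBS washout dynamics. Passing
tests therefore demonstrate that the pipeline recovers the statistical
structure it assumes — suppression magnitudes coupled to outcomes, a stable
burst frequency — not that it is robust to every property of clinical
recordings.

## Numerical choices and problem sizes

* Welch grid 0.125 Hz (4096-point FFT at 512 Hz); tremor-peak ties break
  to the lower frequency.
* SampEn decimation target 8192 points; cap 10 when no length-m+1 match
  exists (flagged).
* Degenerate inputs: constant signals give SampEn 0; all-rejected
  recordings raise a quality error naming patient and channel; zero
  in-band envelope power flags "no tremor".
* All randomness flows from a single seed through `numpy` seed sequences;
  reports embed the configuration hash and seed, and regenerate
  byte-identically.
* Simulation-study sizes chosen for the package's test suite: full-loop
  power uses 39-patient cohorts of 30-s recordings with 100 permutations
  over 20 cohorts per coupling value; permutation-test calibration uses
  100 null cohorts at 200 permutations in feature-IR space; the
  rank-uniformity invariant runs 120 replicates at n = 16 with 40
  permutations. The tremor-frequency recovery check accepts the exact
  Monte-Carlo band for a 100-patient cohort mean (truncation offset plus
  two standard errors, ≈0.24 Hz) and separately requires the detector to
  track the generator's true cohort mean within 0.05 Hz.

## Known limitations

* Absolute MDP/MNP/Peak(f)PSD magnitudes depend on the amplitude and PSD
  unit conventions; only their DBS-off/on directions and associations are
  meaningful across data sets.
* The ZC/SSC thresholds are fixed voltages and should be re-examined for
  acquisition systems with different gain or noise floors.
* The shared-hyperparameter LOOCV route standardises inputs on the full
  sample; use the per-fold route when strict leakage-freedom matters more
  than runtime.
* EDF support is read-only and requires the optional `mne` dependency.
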