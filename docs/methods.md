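# Methods

This note documents the models, defaults and design choices behind
`attentrain`, and what its synthetic data can and cannot establish.

## Signal model of the synthetic EEG

A recording is the sum, per channel, of

* three **narrowband oscillations** — theta 4–8 Hz, alpha 8–12 Hz, beta
  13–30 Hz — realised as 4th-order Butterworth band-pass filtered white
  noise (zero-phase `sosfiltfilt`), each rescaled to its profile's RMS
  amplitude in µV. Filtered noise rather than sinusoids keeps the
  band-power features from depending on a single FFT bin;
* **pink (1/f) background noise**, shaped in the frequency domain and
  rescaled to its broadband RMS;
* **blink transients**: 300 ms half-sine pulses at Poisson-distributed
  onsets, *identical on both channels*. Frontal ocular artifacts are
  predominantly common-mode at Fp1/Fp2, which is precisely what the
  Fp1 − Fp2 virtual channel exploits; the common-mode construction makes
  that cancellation testable.

Oscillations and pink noise are drawn independently per channel, so the
two channels are uncorrelated except for blinks. Default sampling rate
is 128 Hz, chosen so one 2-s analysis block is exactly the 256-sample
FFT length; the deployed headset's rate and ADC range are not public,
so the rail default (±512 µV) is likewise an explicit assumption.

The default state profiles encode the resting-EEG contrast reported for
ADHD — elevated theta and reduced beta when inattentive: attentive
theta/beta amplitude ratio 0.5 (2 µV / 4 µV), inattentive 4 (16 µV /
4 µV), both over 10 µV pink noise with 8 blinks/min at 150 µV.

What the generator does **not** emulate: volume conduction and channel
correlation of real scalp EEG, non-stationary drifts, muscle (EMG)
artifacts, line noise, partially-correlated (non-identical) ocular
signals, and real inter-subject variability. Passing tests therefore
show the pipeline is correct and discriminates *when the assumed
spectral contrast exists*; they do not certify clinical performance.

## Artifact screening

Two defect classes are screened: **saturation** (|x| ≥ rail on either
channel) and **disconnection**, operationalised as a flatline — any 1-s
window with per-channel sample SD below 0.1 µV. The exclusion rule is
"the abnormality and everything within two seconds of it"; direction
being unstated, the symmetric ±2 s guard is used as the conservative
reading. Intervals are half-open [a, b) in 0-based seconds, merged when
overlapping; block tiling is anchored at the recording start, any block
intersecting an exclusion is dropped, and a trailing partial block is
dropped. A fully masked recording yields zero blocks, which feature
extraction rejects explicitly rather than returning NaNs.

## Spectral features

Per 256-sample block the one-sided power spectrum is P_k = |X_k|²/N²
with doubling for interior bins, so that Σ P_k equals the block mean
square exactly (Parseval; verified to 1e−6 relative in tests). Band
membership is half-open (low ≤ f < high) so contiguous bands never
double-count a bin. The default bank is 8 equal 3.25 Hz bands over
4–30 Hz; a "classical" preset with traditional rhythm edges is provided,
and arbitrary contiguous banks are accepted. The deployed device's exact
edges and window are unpublished; the rectangular window is the default
(Hann optional) since only the FFT length is documented. Blocks at other
sampling rates are linearly resampled to 256 samples, keeping the FFT
length invariant. Features are ordered channel-major (Fp1 0–7, Fp2 8–15,
diff 16–23) and log₁₀(x + 1e−12)-transformed by default for variance
stabilisation; the raw mode is retained for the conservation and
linearity tests.

## Attention model

Mutual information uses equal-frequency (quantile) binning with 8 bins
and the plug-in estimator minus the Miller–Madow bias term
(r−1)(c−1)/(2N ln 2), floored at 0. Equal-frequency binning makes the
estimate invariant under strictly monotone transforms; the correction
removes most of the positive small-sample bias (~0.13 bits at n = 40
with 8 bins), though the corrected estimate still fluctuates at the
±0.05-bit scale there — which is why the null behaviour is assessed
against permutation quantiles rather than an absolute threshold.

Selection keeps the top-k features (default k = 6) by MI, ties broken
by ascending index. The regression is ridge (default penalty 1.0) of
the ±1 label coding on standardised selected features — a deliberately
simple, deterministic choice that is stable at the ~40-epoch scale of a
calibration run; the deployed system's regression form, feature count
and MI estimator are unpublished, so all three are surfaced in the API.

The raw score is unbounded (a published week-0 summary of 60.9 with SD
81.0 implies values far outside 0–100); only the display transform is
bounded. The logistic display map is anchored to the class means: centre
c halfway between the mean attentive and mean relaxed raw scores, scale
s = (r_att − r_rel)/(2 ln 3), putting those anchors at 75 and 25. The
scale is floored at a tiny positive value so the display is always a
non-decreasing function of raw, even in the degenerate equal-means case.
Models serialise to JSON (schema-versioned); round-trip scores agree to
1e−12.

## Session engine

Speed is strictly proportional: v = v_max · display/100 (v_max default
2 units/s — the true game constant is unpublished). The display score is
smoothed by a trailing 3-block (6 s) moving average for playable
dynamics; the deployed smoothing is undocumented. Distance is the exact
discrete integral of speed over retained blocks. Fruit collection
(levels 2–3) is one Bernoulli opportunity per retained block with
success probability smoothed-score/100, a seeded stand-in for the jump
mechanics that preserves logbook-count semantics. The schedule builder
places 3 intensive sessions on days 0/2/4 of each of 8 weeks and 3
boosters at 28-day intervals after the intensive phase.

## Trial simulator and statistics

Baselines: IA and HI are drawn from truncated normals on [0, 27]
(defaults 17.7 ± 5.0 and 15.6 ± 3.9) and rounded; COM is defined as
IA + HI at every visit, preserving the table invariant. Follow-up
visits obey

    score_w = baseline + f_w · (a + β · baseline) + ε,  ε ~ N(0, σ²),

with the full effect (f_w = 1) from week 8 on, half of it (f_w = 0.5) at
the interim week-4 visit (no interim model is documented; half the
asymptotic effect is this package's choice), and clamping to the legal
range after rounding. The change model carries an intercept a as well as
the slope β = −0.7: the observed mean week-8 IA change of −4.6 points at
a 17.7-point mean baseline is arithmetically incompatible with a
through-the-origin slope of −0.7 (which would give −12.4), so the
defaults set a = 0.7·17.7 − 4.6 (IA) and 0.7·15.6 − 4.7 (HI), placing
the simulated mean changes at the observed values while leaving
slope-recovery semantics untouched. Default residual σ = 3 points.
Dropout is a per-week Bernoulli hazard (defaults 1/20 at week 4, 2/19 at
week 8, matching the modelled disposition); a subject lost at week w has
no visits from w on.

ΔBASM (week 0→20) is generated as mean 32.5 + SD 60.8 times
(c·z + √(1−c²)·ε) where z is the standardised ΔCOM and c the coupling
(default −0.6), giving a Spearman correlation near c; week-0 BASM is
N(60.9, 81.0). Clamping and rounding attenuate/perturb recovered slopes
by ≲0.05 at these settings — within the ±0.1 recovery tolerance used in
testing at n = 200.

Statistics follow the standard single-arm playbook: LOCF fills missing
visits from strictly earlier weeks only, drops subjects without baseline
(warning) and, by default, subjects with no follow-up at all; paired
t-tests are two-sided with a flagged degenerate result (p = 1 at zero
mean, rather than an exception) when the difference SD is 0; the
baseline→change regression is OLS with conventional SEs; Spearman uses
average ranks. No multiplicity correction is applied, mirroring the
analysis being reproduced. The week-24-vs-baseline analysis set is
ambiguous in the source material (LOCF n = 19 vs completers n = 17);
`mean_change` takes the table and week pair as arguments so either
convention can be computed, and neither is baked in. Multiple imputation
via MCMC is exposed only as a stub (`impute_mcmc`), being a named
off-the-shelf robustness check rather than part of the method.

## Problem sizes and numerics

Tests and the acceptance script use: 40-epoch calibrations of 10 s
epochs at 128 Hz; 200-subject trials for slope recovery and 100 seeds ×
100 subjects for the coupling-sign rate; 50 random blocks for Parseval;
60–120 s recordings for suppression and masking checks. These sizes give
comfortable statistical margins for every asserted property while
keeping the whole suite in the tens of seconds. Numerical tie-breaks and
guards: MI ties resolve to the lower feature index; standardiser SDs and
the display scale are floored at 1e−12; the logistic uses the
overflow-safe `expit`; band-edge membership uses a 1e−9 Hz tolerance so
exact-edge bins are assigned deterministically.

## Known limitations

* Synthetic EEG only; no claim of clinical validity transfers from these
  tests (see the generator's non-goals above).
* The disconnection detector is a flatline criterion; real dropouts can
  also present as high-impedance noise bursts, which are not modelled.
* The MI estimator is univariate; redundant (correlated) features are
  selected together rather than complementarily, as in the original
  device's description.
* EDF support writes 16-bit files with 1-s records (integer sampling
  rates only) and reads via `mne` when installed.
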