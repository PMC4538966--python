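# Methods

This note documents the models and procedures behind `dyadphys`: what the
synthetic-data generator emulates and how it is calibrated, how each index
is computed, the numerical choices involved, and what the package's
passing tests do and do not demonstrate about real recordings.

## Study design being emulated

A two-condition between-subjects experiment (personal vs. impersonal
pre-decision communication; 14 subjects per condition) with three phases
per session: a 5-min resting baseline, a 3-min conversation, and a
decision phase in a one-shot investment game. Physiology (BVP, GSR,
corrugator EMG, respiration, EEG FP1/FP2, photodiode) is exported at
256 Hz on one clock; gaze/pupil at 60 Hz on an independent clock shifted
by an unknown constant offset. The photodiode converts screen-luminance
changes into a physiology-unit channel, so stimulus transitions are
timestamped on the physiology clock; phase events in the timeline file are
on the stimulus/eye-tracker clock.

## Synthetic cohorts

### Index targets

Each subject is characterized by ten baseline-normalized index targets.
Targets are drawn per condition from the reference normal distributions
in `dyadphys.reference.INDEX_STATS` (per-condition mean and SD of each
index). Two deliberate design choices shape the joint distribution:

* **Latent activation coupling.** A standard-normal per-subject factor
  loads on every index with loading 0.7, in the direction the index loads
  on arousal/negative affect (positive for heart rate, skin conductance,
  EMG, alpha asymmetry, slow alpha, beta, LF/HF and pupil dilation;
  negative for NN50 and RMSSD). The arousal/valence model's own premise
  is that one affective state drives all channels; independent draws
  would contradict it, and the published marginals do not constrain the
  copula. Marginal means and SDs are unaffected.

* **Sample-moment matching (default).** With 14 subjects per group and
  the reference effect sizes (Cohen's d ≈ 0.6–0.9), an iid cohort has
  only ≈ 86% probability of reproducing the sign of all ten group
  differences at the *target* level — group-level sign recovery would
  test binomial luck, not the pipeline. By default the standardized
  draws of each index are therefore affinely rescaled so the group's
  sample mean and SD (ddof = 1) equal the reference values exactly, the
  same convention `MASS::mvrnorm(empirical = TRUE)` uses for emulating a
  printed descriptive table. `SynthesisConfig(match_moments=False)`
  restores iid sampling.

Drawn targets are clipped to physiological bounds (e.g. heart-rate ratio
0.55–2.05, RMSSD ratio ≥ 0.12): the reference RMSSD/NN50 marginals place
mass on negative or jointly impossible values in the tails — for any
point process, NN50 per minute cannot exceed bpm·RMSSD²/50² (Chebyshev).
Where clipping binds, sample moments deviate slightly from the reference
values.

### Waveforms

Morphology is deliberately schematic; only index-level statistics are
modelled.

* **Cardiac.** A beat train with interval
  `IBI(t) = T + A_LF sin(2π·0.1·t) + A_HF sin(2π·f_resp·t) + ε + bursts`,
  where ε is white jitter (3 ms, truncated at ±3σ) and "vagal bursts"
  displace single beats by ±55 ms at a sparse rate — they carry the NN50
  count, since smooth modulation at realistic amplitudes cannot produce
  the required suprathreshold successive differences at low RMSSD. The
  communication/decision base interval is `T_baseline / hr_target`
  (baseline 850 ms). The BVP waveform places a Gaussian systolic template
  (σ = 40 ms, peak exactly at the beat time) plus a 25% dicrotic wave at
  +280 ms, with 10% beat-amplitude variation and additive noise.
* **EEG.** 1/f background (2 µV RMS) plus narrowband noise components in
  7–10 Hz (alpha) and 13–30 Hz (beta) with per-phase power; blink
  artifacts are 120 µV Gaussian deflections (σ = 60 ms) shared between
  both frontal channels. Baseline mean alpha power 25 µV² with
  ln(FP1/FP2) = 0.5; the communication phase scales mean power by the
  slow-alpha target and the log-asymmetry by the asymmetry target.
  The baseline log-asymmetry of 0.5 keeps the asymmetry *ratio* well
  conditioned (band-power estimation noise of a few percent would swamp
  a near-zero denominator).
* **Electrodermal.** Tonic level (5 µS baseline, scaled by the SC target
  during communication, 2-s boundary ramps), a slow drift (0.02 µS/min),
  Poisson phasic responses (4/min, 0.15 µS, 0.75 s rise / 3 s decay) and
  measurement noise.
* **EMG.** Band-limited (20–120 Hz) Gaussian noise scaled to the target
  RMS (baseline 2 µV).
* **Respiration.** A phase-continuous sinusoid at 0.25 Hz (baseline) /
  0.30 Hz (communication) — inside the HF band, so respiratory sinus
  arrhythmia stays out of the LF band; the HF cardiac modulation uses the
  same frequency (RSA coupling).
* **Pupil/gaze.** Diameter 3 mm + additive communication-phase shift
  (the pupil target, in mm) + slow noise (0.05 mm, ~2 s correlation),
  sampled at 60 Hz on the gaze clock (timestamps = physio time + true
  offset, drawn U[−2, 2] s). Blinks (15/min, ≥ 0.6 s apart) open
  150–400 ms validity gaps with missing diameters; the same blink times
  drive the EEG artifacts, giving the sync module a common event train.
* **Photodiode.** 0.1 → 0.9 luminance square wave spanning exactly the
  communication phase, plus noise.

### Closed-loop calibration

Open-loop analytic parameter choices left condition-dependent biases in
the extracted NN50 and LF/HF (the realized burst periodogram and the
Welch band estimator on 2–4 segments are not captured well by analytic
budgets). Each phase's beat train is therefore calibrated in closed loop:
the train is regenerated from a fixed sub-seed (same noise realization)
for up to six iterations while (i) the burst rate is steered until the
measured NN50 rate hits the phase target and (ii) the LF amplitude share
is steered until the measured Welch LF/HF hits the target, both measured
with the package's own estimators. The communication phase targets
`ratio × measured-baseline` for both quantities, so the extracted
communication/baseline index lands on the subject's drawn target. The
burst rate stays capped by the RMSSD budget (bursts may consume at most
85% of the squared-RMSSD); NN50 targets infeasible at the subject's RMSSD
saturate at this cap — a monotone compression that preserves (indeed
amplifies) the between-condition ordering but shrinks the absolute NN50
ratio for low-RMSSD subjects. RMSSD itself is allocated analytically
across bursts, jitter and the two sinusoids and is recovered within a few
percent without iteration.

### Recovery accuracy (communication/baseline indices, default settings)

Measured on held-out subjects with ground-truth phase slicing: heart
rate, EMG, SC within ~1–2%; pupil shift within ±0.01 mm; alpha/beta
powers within ~5%; LF/HF ratio bias < 0.05 with SD ≈ 0.12; RMSSD ratio
SD ≈ 0.03; NN50 ratio unbiased for feasible subjects, compressed at the
feasibility frontier as described above.

## Stream synchronization

Blink events are detected as 75–500 ms validity gaps (gaze; event at the
gap midpoint) and as 75–500 ms excursions of the < 5 Hz-filtered averaged
frontal EEG beyond 6 MADs (event at the run midpoint). The offset
maximizes the cross-correlation of the two Gaussian-smoothed (σ = 25 ms)
event trains, evaluated as a sum of Gaussian kernels (σ√2) over event-time
differences: a coarse sweep at σ/2 over the ±3 s window finds the global
peak and checks for ambiguity (a secondary peak outside the main lobe
within 5% of the maximum is an error), then a 1 ms grid with parabolic
interpolation refines it. Sub-sample refinement is essential: the 60 Hz
gaze raster alone (16.7 ms) could not meet a 10 ms bound. On 180-s dyads
at 15 blinks/min the recovered offset is accurate to ~1 ms (95th
percentile), because ~45 events average down the per-event quantization
of the gaze raster. Photodiode transitions (signal binarized at the
midpoint of its 5th/95th percentiles after 10 ms smoothing, 50 ms
debounce, linear sub-sample crossing interpolation) provide the
communication boundaries directly on the physiology clock; the
timeline-through-offset route is the fallback when no photodiode channel
is usable, and the package can cross-check the two. Clock *drift* is not
modelled or corrected — the offset is assumed constant per session.

## Index extraction

* Systolic peaks: adaptive threshold (windowed median + half the
  median-to-95th range, 10 s windows), 250 ms refractory, sub-sample
  refinement by a least-squares parabola over the ±30 ms peak crown
  (a 3-point parabola amplifies additive noise ~10-fold).
* Artifact correction: intervals deviating > 25% from an 11-beat running
  median are flagged and replaced by cubic interpolation over beat index;
  > 20% flagged is a quality failure (the subject is excluded, mirroring
  real cohort attrition).
* Spectral HRV: tachogram cubic-splined to 4 Hz, Welch with 120-s Hann
  segments at 50% overlap (linear detrend); records shorter than one
  segment fall back to a single-segment periodogram with a warning; a
  flat tachogram yields NaN LF/HF with a warning. Band powers integrate
  the PSD by the trapezoid rule over VLF < 0.04, LF 0.04–0.15,
  HF 0.15–0.5 Hz.
* Respiration check: dominant Welch peak in 0.05–0.6 Hz of the decimated
  respiration channel; a rate below 0.15 Hz flags LF contamination, a
  peak under 2× the in-band median is indeterminate.
* SC: mean and SD of the 32 Hz polyphase-decimated slice. EMG: RMS of
  the mean-centered slice. EEG band power: Welch (2-s Hann segments, 50%
  overlap) averaged over blink-free segments (±200 ms around each blink
  excised), trapezoid band integral; slow alpha 7–10 Hz, beta 13–30 Hz
  (the beta range is the standard convention and configurable in
  `features.EEG_BANDS`).
* Alpha asymmetry: ln(FP1) − ln(FP2). Under activation-is-low-alpha,
  a *lower* value means greater left activation, i.e. more positive
  valence — consistent with the direction table used by the affect
  mapping.
* Pupil: binocular mean of valid eyes, gaps ≤ 500 ms linearly bridged,
  longer dropouts excluded, < 50% usable samples is a quality failure;
  the index is the phase mean minus the baseline mean (mm).
* Normalization: every index is communication/baseline, except pupil
  dilation (difference). NN50 enters as a per-minute rate so phases of
  unequal length compare; whether the original analysis length-normalized
  NN50 is unknowable from the published statistics, and the ratio form
  is invariant to the choice whenever both phases are scored identically.

## Affect mapping

Within-cohort z-scores (excluded subjects dropped) are averaged with
equal weights per dimension: arousal = mean(z_HR, z_SC, z_beta);
valence = −mean(z_EMG, z_AA); intensity = z_pupil;
attention = −z_slowalpha; negative affect = mean(z_LFHF, −z_NN50,
−z_RMSSD). Equal weights are a design choice: the direction table
specifies signs only. Cohort z-scaling (rather than any absolute scale)
makes the scores invariant to affine rescaling of any raw index and keeps
subjects comparable; it also means scores are only defined relative to a
cohort of ≥ 2 subjects with non-degenerate variance. Quadrants follow
the signs of (valence, arousal) with a 1e−9 neutrality band. Emotional
intensity is reported as a separate score and never modulates the
quadrant label.

## Inference

Levene's test (mean-centered, via one-way ANOVA on absolute deviations)
at α = 0.05 gates POOLED (df = n₁+n₂−2) versus WELCH
(Satterthwaite df) two-sample t-tests per physiological measure; trust
(Euros sent) and reciprocity (fraction of the tripled amount returned)
are tested POOLED. Reciprocity is analyzed as the fraction because the
absolute amount depends on the amount received. `t_from_summary` applies
the identical formulas to sufficient statistics, so a printed
descriptives table can be turned into its corrected t-tests exactly.
Stuart's tau-c is computed from concordant/discordant pair counts,
τ_c = 2m(C−D)/(n²(m−1)), with the standard null ASE for the
normal-approximation p-value. Achieved power uses the noncentral t with
noncentrality d·√(n₁n₂/(n₁+n₂)); opposite-tail terms that underflow to
NaN in scipy are treated as zero.

## Problem sizes used in validation

The validation suite uses 50 seeded 180-s dyads for the synchronization
bound, 20 seeded 14+14 cohorts at the reference population parameters for
sign/quadrant recovery, 1000 random interval series for the HRV
time-domain oracle, and brute-force pair enumeration on small random
tables for tau-c — sizes chosen so the full suite completes in minutes
while keeping the Monte-Carlo margins far from the pass thresholds.

## Limitations

* Waveforms are schematic: no motion artifacts beyond blinks, no
  ectopy-like arrhythmia beyond the NN50 bursts, sinusoidal rather than
  point-process cardiac modulation, stationary EEG background, and
  higher effective SNR than real frontal EEG. Passing recovery tests
  therefore demonstrates correctness of the estimators and the
  synchronization machinery on signals with known structure — not
  robustness to real-world artifact regimes.
* The reference NN50/RMSSD marginals are jointly infeasible in their
  tails; the generator resolves this with clipping and budget
  saturation, so extreme subjects' NN50 is compressed.
* LF/HF estimates on 3-min windows carry large inherent estimator
  variance (2 Welch segments); the closed-loop calibration compensates
  within the generator but real 3-min LF/HF values would be similarly
  noisy.
* No clock-drift model; the inter-stream offset is constant per session.
* The affect mapping is a fixed linear rule, not a trained classifier,
  and its equal weights are a convention.
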