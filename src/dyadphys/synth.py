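"""Synthetic dyadic sessions with known ground truth.

The generator emulates the acquisition layout of a two-condition (personal
vs impersonal communication) trust-game experiment: seven physiology
channels exported at 256 Hz on one clock, a 60 Hz gaze/pupil stream on an
independent clock shifted by an unknown constant offset, photodiode
luminance steps at the communication-phase boundaries, and blinks that
appear simultaneously as gaze validity gaps and frontal EEG artifacts.

Per-subject index targets are drawn from condition-specific normal
distributions (defaults: the reference study's per-condition means/SDs
after baseline normalization) and coupled through a latent within-subject
activation factor — the premise of the arousal/valence model is precisely
that one affective state drives all channels. Signal parameters are then
calibrated so that the extraction pipeline recovers each subject's targets:
communication-phase physiology is the subject's fixed baseline physiology
scaled by the drawn target ratios (pupil dilation excepted: an additive mm
shift).

Waveform morphology is deliberately schematic (sinusoidal cardiac
modulation, band-limited noise for EEG/EMG); only index-level statistics
are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from . import reference
from .errors import ParameterError
from .features import IBISeries
from .io import (ChannelName, ChannelRecording, Condition, DecisionRecord,
                 EventTimeline, GazeRecording, Role, SessionRecord)

#: Direction in which each index loads on the latent activation factor
#: (impersonal communication is the high-activation condition).
LATENT_SIGNS = {name: 1.0 for name in reference.INDEX_NAMES}
LATENT_SIGNS["nn50"] = -1.0
LATENT_SIGNS["rmssd"] = -1.0

#: Hard physiological clips applied to drawn index targets.
TARGET_BOUNDS = {
    "heart_rate": (0.55, 2.05),
    "emg_corrugator": (0.15, 4.0),
    "skin_conductance": (0.2, 4.0),
    "alpha_asymmetry": (0.2, 3.5),
    "slow_alpha": (0.15, 4.0),
    "beta": (0.15, 4.0),
    "lf_hf": (0.2, 4.0),
    "pupil_dilation": (-0.5, 1.5),
    "nn50": (0.08, 3.0),
    "rmssd": (0.12, 3.0),
}


@dataclass
class SynthesisConfig:
    """Study-condition parameters of the synthetic cohort.

    Phase durations follow the emulated protocol (5 min resting baseline,
    3 min communication, decision phase) and the cohort size is 14 subjects
    per condition. ``index_stats`` holds the per-condition (mean, sd) of
    each baseline-normalized index the cohort should reproduce.
    """

    seed: int = 0
    n_per_condition: int = 14
    baseline_s: float = 300.0
    comm_s: float = 180.0
    decision_s: float = 120.0
    physio_rate_hz: float = 256.0
    gaze_rate_hz: float = 60.0
    true_offset_s: Optional[float] = None        # None: draw U(offset_range)
    offset_range_s: tuple = (-2.0, 2.0)
    blink_rate_per_min: float = 15.0
    latent_loading: float = 0.7
    match_moments: bool = True
    index_stats: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in reference.INDEX_STATS.items()})
    # fixed baseline physiology shared by all subjects
    baseline_ibi_ms: float = 850.0
    baseline_rmssd_ms: float = 40.0
    baseline_lf_hf: float = 1.0
    lf_freq_hz: float = 0.1
    resp_rate_baseline_hz: float = 0.25
    resp_rate_comm_hz: float = 0.30
    ibi_jitter_ms: float = 3.0
    nn50_spike_ms: float = 55.0
    baseline_sc_uS: float = 5.0
    sc_drift_uS_per_min: float = 0.02
    scr_rate_per_min: float = 4.0
    scr_amp_uS: float = 0.15
    baseline_emg_rms_uV: float = 2.0
    baseline_alpha_power_uV2: float = 25.0
    baseline_log_asymmetry: float = 0.5
    baseline_beta_power_uV2: float = 9.0
    eeg_background_rms_uV: float = 2.0
    blink_artifact_uV: float = 120.0
    pupil_baseline_mm: float = 3.0
    pupil_noise_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.n_per_condition < 2:
            raise ParameterError("need n_per_condition >= 2")
        if self.blink_rate_per_min <= 0:
            raise ParameterError("blink rate must be positive")
        for rate in (self.resp_rate_baseline_hz, self.resp_rate_comm_hz):
            if not 0.15 <= rate <= 0.5:
                raise ParameterError("respiration rate must sit in the HF "
                                     "band (0.15-0.5 Hz)")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.comm_s + self.decision_s

    @property
    def phase_bounds(self) -> dict:
        b, c = self.baseline_s, self.comm_s
        return {"BASELINE": (0.0, b), "COMM": (b, b + c),
                "DECISION": (b + c, self.total_s)}


@dataclass
class GroundTruth:
    """Exactly what was generated for one subject."""

    subject_id: str
    condition: str
    role: str
    indices: dict
    true_offset_s: float
    phase_bounds: dict
    blink_times: np.ndarray = field(repr=False, default=None)


def draw_index_targets(config: SynthesisConfig, condition,
                       rng: np.random.Generator) -> dict:
    """Draw one subject's ten index targets from the condition population.

    Marginals are the configured normals; a latent activation factor with
    loading ``latent_loading`` couples the draws in the direction each index
    loads on arousal/negative affect.
    """
    cond = Condition(condition).value
    rho = config.latent_loading
    z0 = rng.standard_normal()
    targets = {}
    for name in reference.INDEX_NAMES:
        mean, sd = config.index_stats[name][cond]
        z = (LATENT_SIGNS[name] * rho * z0
             + math.sqrt(1.0 - rho ** 2) * rng.standard_normal())
        targets[name] = float(np.clip(mean + sd * z, *TARGET_BOUNDS[name]))
    return targets


def draw_cohort_targets(config: SynthesisConfig, condition, n: int,
                        rng: np.random.Generator) -> list:
    """Draw index targets for a whole condition group.

    With ``match_moments`` (the default) the latent-coupled z-draws are
    affinely standardized per index so the group's *sample* mean and SD
    equal the configured population values exactly — the convention for
    emulating a printed descriptive-statistics table (cf. mvrnorm's
    ``empirical=TRUE``); physiological clipping is applied afterwards.
    Without it, subjects are drawn iid from the configured normals.
    """
    cond = Condition(condition).value
    if not config.match_moments:
        return [draw_index_targets(config, cond, rng) for _ in range(n)]
    if n < 2:
        raise ParameterError("moment matching needs n >= 2")
    rho = config.latent_loading
    z0 = rng.standard_normal(n)
    out = [dict() for _ in range(n)]
    for name in reference.INDEX_NAMES:
        mean, sd = config.index_stats[name][cond]
        z = (LATENT_SIGNS[name] * rho * z0
             + math.sqrt(1.0 - rho ** 2) * rng.standard_normal(n))
        z = (z - z.mean()) / z.std(ddof=1)
        vals = np.clip(mean + sd * z, *TARGET_BOUNDS[name])
        for subject, v in zip(out, vals):
            subject[name] = float(v)
    return out


# ---------------------------------------------------------------------------
# Interbeat-interval train
# ---------------------------------------------------------------------------

def _ibi_phase_params(config: SynthesisConfig, base_ibi_ms: float,
                      rmssd_ms: float, nn50_per_min: float, lf_hf: float,
                      hf_freq: float,
                      lam_override: Optional[float] = None) -> dict:
    """Calibrate one phase's IBI parameters from its target indices.

    Short-term variability is budgeted across four components: sparse
    vagal-burst beat displacements of fixed size (they carry the NN50
    count), white jitter, and LF/HF sinusoids whose amplitude split fixes
    the spectral balance (the broadband contribution of jitter and bursts
    to each band is accounted for analytically).
    """
    T = base_ibi_ms / 1000.0
    bpm = 60.0 / T
    delta = config.nn50_spike_ms
    lam = max(nn50_per_min, 0.0) / 1.8  # 2 large diffs per burst, ~0.9 detected
    if lam_override is not None:
        lam = lam_override
    lam_max = 0.85 * rmssd_ms ** 2 * bpm / (2 * delta ** 2)
    lam = min(lam, lam_max)
    r2 = rmssd_ms ** 2 - (2 * lam / bpm) * delta ** 2
    s = min(config.ibi_jitter_ms, math.sqrt(max(r2, 0.0) / 6.0))
    r2_sin = max(r2 - 2 * s ** 2, 0.0)
    c_lf = 2 * abs(math.sin(math.pi * config.lf_freq_hz * T))
    c_hf = 2 * abs(math.sin(math.pi * hf_freq * T))
    # broadband (white) PSD level over the beat-rate Nyquist band
    var_white = s ** 2 + (lam / bpm) * delta ** 2
    level = var_white / (bpm / 120.0)
    w_lf, w_hf = level * 0.11, level * 0.35
    c = 2 * (lf_hf * w_hf - w_lf)
    y = (2 * r2_sin - c_lf ** 2 * c) / (c_lf ** 2 * lf_hf + c_hf ** 2)
    if y < 0:
        y, x = 0.0, max(2 * r2_sin, 0.0) / c_lf ** 2
    else:
        x = lf_hf * y + c
        if x < 0:
            x, y = 0.0, 2 * r2_sin / c_hf ** 2
    return {"base_ibi_ms": base_ibi_ms, "lf_amp_ms": math.sqrt(x),
            "hf_amp_ms": math.sqrt(y), "jitter_ms": s,
            "spike_rate_per_min": lam, "spike_delta_ms": delta,
            "hf_freq_hz": hf_freq, "lf_freq_hz": config.lf_freq_hz}


def synthesize_ibi_train(duration_s: float, base_ibi_ms: float,
                         lf_amp_ms: float = 0.0, hf_amp_ms: float = 0.0,
                         jitter_ms: float = 0.0, lf_freq_hz: float = 0.1,
                         hf_freq_hz: float = 0.25,
                         spike_rate_per_min: float = 0.0,
                         spike_delta_ms: float = 60.0,
                         rng: Optional[np.random.Generator] = None,
                         start_s: float = 0.0) -> IBISeries:
    """Beat train: base interval + LF/HF sinusoids + jitter + sparse bursts.

    Mean interval equals ``base_ibi_ms`` up to jitter, so mean heart rate
    matches 60000/base to within ~2 bpm on windows of two minutes or more.
    """
    if duration_s <= 0:
        raise ParameterError("IBI synthesis needs a positive duration")
    if base_ibi_ms - lf_amp_ms - hf_amp_ms <= 0:
        raise ParameterError("modulation amplitudes exceed the base interval")
    rng = rng if rng is not None else np.random.default_rng(0)
    p_spike = spike_rate_per_min * base_ibi_ms / 60000.0
    t = start_s
    beats = [t]
    intervals = []
    while t - start_s < duration_s:
        tau = t - start_s
        ibi = (base_ibi_ms
               + lf_amp_ms * math.sin(2 * math.pi * lf_freq_hz * tau)
               + hf_amp_ms * math.sin(2 * math.pi * hf_freq_hz * tau))
        if jitter_ms > 0:
            ibi += float(np.clip(rng.normal(0.0, jitter_ms),
                                 -3 * jitter_ms, 3 * jitter_ms))
        if p_spike > 0 and rng.random() < p_spike:
            ibi += spike_delta_ms * (1.0 if rng.random() < 0.5 else -1.0)
        if ibi <= 0:
            raise ParameterError("non-positive interbeat interval generated")
        intervals.append(ibi)
        t += ibi / 1000.0
        beats.append(t)
    return IBISeries(intervals_ms=np.asarray(intervals),
                     beat_times_s=np.asarray(beats))


def _calibrated_phase_train(config: SynthesisConfig, t_start: float,
                            duration_s: float, base_ibi_ms: float,
                            rmssd_ms: float, nn50_per_min: float,
                            lf_hf_target: float, hf_freq: float, seed: int,
                            n_iter: int = 6, rtol_lf: float = 0.02,
                            rtol_nn: float = 0.05) -> tuple:
    """Phase train whose *measured* LF/HF and NN50 rate hit their targets.

    The same noise realization (fixed sub-seed) is regenerated while the
    vagal-burst rate and the LF amplitude are steered toward the values the
    actual extraction estimators report — the analytic budget alone cannot
    anticipate the realized burst count or broadband periodogram. The burst
    rate stays capped by the short-term-variability budget, so NN50 targets
    that are infeasible at the subject's RMSSD saturate at the cap (a
    monotone compression rather than random scatter). Returns the train and
    its measured LF/HF (NaN when not measurable).
    """
    from .features import hrv_spectral, hrv_time_domain

    lam = None          # None: analytic initial guess inside the budget
    lf_scale = 1.0
    train, measured_lf = None, np.nan
    calibratable = duration_s >= 120 and np.isfinite(lf_hf_target)
    nn_seed = nn50_per_min if np.isfinite(nn50_per_min) else 0.0
    nominal_lf = lf_hf_target if np.isfinite(lf_hf_target) else 1.0
    for _ in range(n_iter):
        # the correction factor scales the *requested* spectral balance so
        # the analytic budget (and hence RMSSD) stays exact
        p = _ibi_phase_params(config, base_ibi_ms, rmssd_ms, nn_seed,
                              nominal_lf * lf_scale ** 2, hf_freq,
                              lam_override=lam)
        train = synthesize_ibi_train(
            duration_s, p["base_ibi_ms"], p["lf_amp_ms"], p["hf_amp_ms"],
            p["jitter_ms"], p["lf_freq_hz"], p["hf_freq_hz"],
            p["spike_rate_per_min"], p["spike_delta_ms"],
            rng=np.random.default_rng(seed), start_s=t_start)
        if not calibratable:
            break
        td = hrv_time_domain(train)
        nn_rate = td.nn50_count / (train.duration_s / 60.0)
        measured_lf = hrv_spectral(train).lf_hf_ratio
        if not np.isfinite(measured_lf) or measured_lf <= 0:
            break
        at_cap = (lam is not None
                  and p["spike_rate_per_min"] < lam * (1.0 - 1e-9))
        at_floor = lam is not None and lam <= 0.02 and nn_rate > nn50_per_min
        ok_nn = (not np.isfinite(nn50_per_min) or nn50_per_min <= 0
                 or at_cap or at_floor
                 or abs(nn_rate / nn50_per_min - 1.0) < rtol_nn)
        ok_lf = abs(measured_lf / lf_hf_target - 1.0) < rtol_lf
        if ok_nn and ok_lf:
            break
        cur = p["spike_rate_per_min"]
        if not ok_nn:
            lam = float(np.clip(cur * np.clip(nn50_per_min / max(nn_rate, 0.3),
                                              0.5, 2.0), 0.02, 60.0))
        else:
            lam = cur
        if not ok_lf:
            lf_scale *= float(np.clip(math.sqrt(lf_hf_target / measured_lf),
                                      0.7, 1.4))
    nn_final = (train.duration_s and
                hrv_time_domain(train).nn50_count / (train.duration_s / 60.0))
    return train, measured_lf, float(nn_final)


def _session_ibi_train(config: SynthesisConfig, phase_targets: dict,
                       lf_hf_ratio_target: float,
                       rng: np.random.Generator) -> IBISeries:
    """Beat train over the whole session, calibrated per phase.

    ``phase_targets`` maps phase -> (base_ibi_ms, rmssd_ms, nn50_per_min,
    hf_freq). The communication phase is calibrated against the baseline's
    *measured* LF/HF so the extracted communication/baseline ratio lands on
    the subject's target rather than on the nominal baseline value.
    """
    beats = [np.asarray([0.0])]
    intervals = []
    base_lf, base_nn = np.nan, np.nan
    for phase in ("BASELINE", "COMM", "DECISION"):
        lo, hi = config.phase_bounds[phase]
        seed = int(rng.integers(2 ** 31))
        base_ibi, rmssd, nn_ratio, hf_freq = phase_targets[phase]
        if phase == "BASELINE":
            lf_target, nn_target = config.baseline_lf_hf, np.nan
        elif phase == "COMM" and np.isfinite(base_lf):
            lf_target = lf_hf_ratio_target * base_lf
            nn_target = nn_ratio * base_nn
        else:
            lf_target, nn_target = np.nan, np.nan
        seg, lf_meas, nn_meas = _calibrated_phase_train(
            config, lo, hi - lo, base_ibi, rmssd, nn_target, lf_target,
            hf_freq, seed)
        if phase == "BASELINE":
            base_lf, base_nn = lf_meas, nn_meas
        # trim any beat spilling past the phase end so times stay monotone
        keep = seg.beat_times_s[1:] <= hi
        intervals.append(seg.intervals_ms[keep])
        beats.append(seg.beat_times_s[1:][keep])
    return IBISeries(intervals_ms=np.concatenate(intervals),
                     beat_times_s=np.concatenate(beats))


def synthesize_bvp(ibi: IBISeries, rate: float = 256.0,
                   duration_s: Optional[float] = None,
                   rng: Optional[np.random.Generator] = None) -> ChannelRecording:
    """Pulse waveform with a systolic template at every beat time.

    The template's maximum sits exactly on the beat time (a Gaussian
    systolic wave plus a smaller dicrotic wave 280 ms later), so a peak
    detector recovers the interbeat intervals to within one sample.
    """
    if rate < 64:
        raise ParameterError("BVP must be sampled at >= 64 Hz to resolve peaks")
    rng = rng if rng is not None else np.random.default_rng(0)
    if duration_s is None:
        duration_s = float(ibi.beat_times_s[-1] + 0.5)
    n = int(round(duration_s * rate))
    x = np.zeros(n)
    t0 = ibi.beat_times_s[0]
    for tb in ibi.beat_times_s:
        amp = 1.0 + 0.1 * rng.standard_normal()
        for center, a, width in ((tb, amp, 0.040), (tb + 0.28, 0.25 * amp, 0.055)):
            lo = max(0, int((center - 4 * width) * rate))
            hi = min(n, int((center + 4 * width) * rate) + 1)
            if lo >= hi:
                continue
            tt = np.arange(lo, hi) / rate
            x[lo:hi] += a * np.exp(-0.5 * ((tt - center) / width) ** 2)
    x += 0.01 * rng.standard_normal(n)
    return ChannelRecording(ChannelName.BVP, rate, x, start_offset=0.0,
                            units="a.u.")


# ---------------------------------------------------------------------------
# EEG / EMG / GSR / respiration / photodiode
# ---------------------------------------------------------------------------

def _band_noise(rng: np.random.Generator, n: int, rate: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="band", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / max(np.std(y), 1e-12)


def _pink_noise(rng: np.random.Generator, n: int, rate: float,
                rms: float) -> np.ndarray:
    """1/f background, unit-normalized then scaled to the requested RMS."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / rate)
    spec /= np.sqrt(np.maximum(f, 0.5))
    y = np.fft.irfft(spec, n)
    return rms * y / max(np.std(y), 1e-12)


def _phase_envelope(config: SynthesisConfig, rate: float, n: int,
                    values: dict, smooth_s: float = 1.0) -> np.ndarray:
    """Per-phase values with linear ramps (width ``smooth_s``) at boundaries."""
    t = np.arange(n) / rate
    xp, fp = [0.0], [values["BASELINE"]]
    for a, b in (("BASELINE", "COMM"), ("COMM", "DECISION")):
        edge = config.phase_bounds[a][1]
        xp += [edge - smooth_s / 2, edge + smooth_s / 2]
        fp += [values[a], values[b]]
    xp.append(config.total_s)
    fp.append(values["DECISION"])
    return np.interp(t, xp, fp)


def synthesize_eeg(config: SynthesisConfig, duration_s: float, rate: float,
                   alpha_power: dict, beta_power: dict,
                   blink_times: np.ndarray,
                   rng: np.random.Generator) -> ChannelRecording:
    """One frontal EEG channel: 1/f background + narrowband alpha (7-10 Hz)
    and beta (13-30 Hz) components with per-phase power + blink deflections.

    ``alpha_power``/``beta_power`` map phase name -> band power (uV^2).
    """
    n = int(round(duration_s * rate))
    x = _pink_noise(rng, n, rate, config.eeg_background_rms_uV)
    for band, powers in (((7.0, 10.0), alpha_power), ((13.0, 30.0), beta_power)):
        env = np.sqrt(_phase_envelope(config, rate, n, powers))
        x += env * _band_noise(rng, n, rate, *band)
    t = np.arange(n) / rate
    for tb in np.asarray(blink_times):
        amp = config.blink_artifact_uV * rng.uniform(0.8, 1.2)
        lo = max(0, int((tb - 0.3) * rate))
        hi = min(n, int((tb + 0.3) * rate) + 1)
        if lo < hi:
            x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - tb) / 0.06) ** 2)
    return ChannelRecording(ChannelName.EEG_FP1, rate, x, units="uV")


def synthesize_gaze_pupil(config: SynthesisConfig, duration_s: float,
                          pupil_shift_mm: float, blink_times: np.ndarray,
                          true_offset_s: float,
                          rng: np.random.Generator) -> GazeRecording:
    """Pupil stream on the gaze clock with blink gaps.

    Diameter = baseline + an additive shift during communication/decision
    + slow noise; samples inside 150-400 ms blink windows are invalid with
    missing diameters. Timestamps are physio time plus the true offset.
    """
    rate = config.gaze_rate_hz
    n = int(round(duration_s * rate))
    t_phys = np.arange(n) / rate
    shift_env = _phase_envelope(config, rate, n,
                                {"BASELINE": 0.0, "COMM": pupil_shift_mm,
                                 "DECISION": pupil_shift_mm}, smooth_s=1.0)
    slow = gaussian_filter1d(rng.standard_normal(n), 2.0 * rate, mode="nearest")
    slow *= config.pupil_noise_mm / max(np.std(slow), 1e-12)
    base = config.pupil_baseline_mm + shift_env + slow
    left = base + 0.02 * rng.standard_normal(n)
    right = base + 0.02 * rng.standard_normal(n)
    validity = np.ones(n, dtype=bool)
    for tb in np.asarray(blink_times):
        dur = rng.uniform(0.15, 0.40)
        validity &= ~((t_phys >= tb - dur / 2) & (t_phys < tb + dur / 2))
    left[~validity] = np.nan
    right[~validity] = np.nan
    return GazeRecording(sampling_rate=rate,
                         timestamps=t_phys + true_offset_s,
                         pupil_left_mm=left, pupil_right_mm=right,
                         validity=validity)


def _draw_blink_times(config: SynthesisConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Quasi-Poisson blink train with a 600 ms minimum separation."""
    mean_gap = 60.0 / config.blink_rate_per_min
    times, t = [], 1.0
    while True:
        t += max(0.6, rng.exponential(mean_gap))
        if t >= config.total_s - 1.0:
            break
        times.append(t)
    return np.asarray(times)


def _alpha_sides(mean_power: float, log_asym: float) -> tuple:
    """Split a mean alpha power into FP1/FP2 with a given ln(L/R)."""
    p_right = 2.0 * mean_power / (1.0 + math.exp(log_asym))
    return math.exp(log_asym) * p_right, p_right


# ---------------------------------------------------------------------------
# Whole sessions and cohorts
# ---------------------------------------------------------------------------

def synthesize_session(config: SynthesisConfig, condition, role,
                       rng: np.random.Generator, subject_id: str = "S00",
                       targets: Optional[dict] = None,
                       decision: Optional[DecisionRecord] = None) -> tuple:
    """Generate one subject's full session plus its ground truth.

    Communication- and decision-phase physiology equals the fixed baseline
    physiology scaled by the subject's target index ratios (the decision
    phase inherits the communication state, as affect persists into the
    choice); pupil diameter gets the additive target shift.
    """
    condition = Condition(condition)
    role = Role(role)
    if targets is None:
        targets = draw_index_targets(config, condition, rng)
    offset = (config.true_offset_s if config.true_offset_s is not None
              else float(rng.uniform(*config.offset_range_s)))
    rate = config.physio_rate_hz
    total = config.total_s
    n = int(round(total * rate))
    bounds = config.phase_bounds
    blink_times = _draw_blink_times(config, rng)

    # --- cardiac chain ----------------------------------------------------
    base_targets = (config.baseline_ibi_ms, config.baseline_rmssd_ms,
                    np.nan, config.resp_rate_baseline_hz)
    comm_targets = (config.baseline_ibi_ms / targets["heart_rate"],
                    config.baseline_rmssd_ms * targets["rmssd"],
                    targets["nn50"], config.resp_rate_comm_hz)
    ibi = _session_ibi_train(
        config, {"BASELINE": base_targets, "COMM": comm_targets,
                 "DECISION": comm_targets}, targets["lf_hf"], rng)
    bvp = synthesize_bvp(ibi, rate, duration_s=total, rng=rng)

    # --- EEG --------------------------------------------------------------
    base_l, base_r = _alpha_sides(config.baseline_alpha_power_uV2,
                                  config.baseline_log_asymmetry)
    comm_l, comm_r = _alpha_sides(
        config.baseline_alpha_power_uV2 * targets["slow_alpha"],
        config.baseline_log_asymmetry * targets["alpha_asymmetry"])
    beta_base = config.baseline_beta_power_uV2
    beta_comm = beta_base * targets["beta"]
    eeg = {}
    for name, alphas in ((ChannelName.EEG_FP1, (base_l, comm_l)),
                         (ChannelName.EEG_FP2, (base_r, comm_r))):
        rec = synthesize_eeg(
            config, total, rate,
            alpha_power={"BASELINE": alphas[0], "COMM": alphas[1],
                         "DECISION": alphas[1]},
            beta_power={"BASELINE": beta_base, "COMM": beta_comm,
                        "DECISION": beta_comm},
            blink_times=blink_times, rng=rng)
        rec.channel_name = name
        eeg[name] = rec

    # --- GSR / EMG / respiration / photodiode -----------------------------
    t = np.arange(n) / rate
    tonic = _phase_envelope(
        config, rate, n,
        {"BASELINE": config.baseline_sc_uS,
         "COMM": config.baseline_sc_uS * targets["skin_conductance"],
         "DECISION": config.baseline_sc_uS * targets["skin_conductance"]},
        smooth_s=2.0)
    gsr = tonic + config.sc_drift_uS_per_min * t / 60.0
    n_scr = rng.poisson(config.scr_rate_per_min * total / 60.0)
    for ts in np.sort(rng.uniform(0, total, n_scr)):
        lo = int(ts * rate)
        hi = min(n, lo + int(20 * rate))
        tau = (np.arange(lo, hi) / rate) - ts
        gsr[lo:hi] += config.scr_amp_uS * (
            np.exp(-tau / 3.0) - np.exp(-tau / 0.75)) / 0.472
    gsr += 0.01 * rng.standard_normal(n)
    gsr_rec = ChannelRecording(ChannelName.GSR, rate, gsr, units="uS")

    emg_env = np.sqrt(_phase_envelope(
        config, rate, n,
        {"BASELINE": config.baseline_emg_rms_uV ** 2,
         "COMM": (config.baseline_emg_rms_uV * targets["emg_corrugator"]) ** 2,
         "DECISION": (config.baseline_emg_rms_uV
                      * targets["emg_corrugator"]) ** 2}))
    emg = emg_env * _band_noise(rng, n, rate, 20.0, 120.0)
    emg_rec = ChannelRecording(ChannelName.EMG_CS, rate, emg, units="uV")

    resp_freq = _phase_envelope(
        config, rate, n,
        {"BASELINE": config.resp_rate_baseline_hz,
         "COMM": config.resp_rate_comm_hz,
         "DECISION": config.resp_rate_comm_hz})
    rsp = np.sin(2 * math.pi * np.cumsum(resp_freq) / rate)
    rsp += 0.05 * rng.standard_normal(n)
    rsp_rec = ChannelRecording(ChannelName.RSP, rate, rsp, units="a.u.")

    comm_mask = (t >= bounds["COMM"][0]) & (t < bounds["COMM"][1])
    photo = 0.1 + 0.8 * comm_mask + 0.02 * rng.standard_normal(n)
    photo_rec = ChannelRecording(ChannelName.PHOTODIODE, rate, photo,
                                 units="a.u.")

    gaze = synthesize_gaze_pupil(config, total, targets["pupil_dilation"],
                                 blink_times, offset, rng)

    timeline = EventTimeline([
        ("BASELINE_START", bounds["BASELINE"][0] + offset),
        ("BASELINE_END", bounds["BASELINE"][1] + offset),
        ("COMM_START", bounds["COMM"][0] + offset),
        ("COMM_END", bounds["COMM"][1] + offset),
        ("DECISION_START", bounds["DECISION"][0] + offset),
        ("DECISION_END", bounds["DECISION"][1] + offset),
    ])
    if decision is None:
        decision = sample_decision(condition, role, rng)
    session = SessionRecord(
        subject_id=subject_id, condition=condition, role=role,
        channels={ChannelName.BVP: bvp, ChannelName.GSR: gsr_rec,
                  ChannelName.EMG_CS: emg_rec, ChannelName.RSP: rsp_rec,
                  ChannelName.EEG_FP1: eeg[ChannelName.EEG_FP1],
                  ChannelName.EEG_FP2: eeg[ChannelName.EEG_FP2],
                  ChannelName.PHOTODIODE: photo_rec},
        gaze=gaze, timeline=timeline, decision=decision)
    truth = GroundTruth(subject_id=subject_id, condition=condition.value,
                        role=role.value, indices=dict(targets),
                        true_offset_s=offset, phase_bounds=dict(bounds),
                        blink_times=blink_times)
    return session, truth


def sample_decision(condition, role, rng: np.random.Generator) -> DecisionRecord:
    """Sample a trust-game outcome from the reference empirical frequencies."""
    cond = Condition(condition).value
    if Role(role) is Role.PROPOSER:
        table = reference.TRUST_FREQUENCIES[cond]
        amounts = list(table)
        p = np.asarray([table[a] for a in amounts], dtype=float)
        amount = int(rng.choice(amounts, p=p / p.sum()))
        q1 = "Big" if amount >= 1000 else "Small"
        return DecisionRecord(amount_sent=amount, proposer_q1=q1,
                              proposer_q2=int(rng.integers(1, 5)))
    table = reference.RECIPROCITY_FREQUENCIES[cond]
    fracs = list(table)
    p = np.asarray([table[f] for f in fracs], dtype=float)
    frac = float(rng.choice(fracs, p=p / p.sum()))
    q1 = {0.25: "Unfair", 0.5: "PartiallyFair", 0.75: "Fair"}.get(frac, "Fair")
    return DecisionRecord(fraction_returned=frac, responder_q1=q1,
                          responder_q2=int(rng.integers(1, 6)))


def generate_cohort(config: SynthesisConfig) -> list:
    """Generate the full two-condition cohort (n_per_condition each).

    Subjects alternate proposer/responder within each condition, emulating
    randomly coupled dyads. Returns [(SessionRecord, GroundTruth), ...],
    deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    out = []
    for condition in (Condition.PC, Condition.IC):
        targets = draw_cohort_targets(config, condition,
                                      config.n_per_condition, rng)
        for i in range(config.n_per_condition):
            role = Role.PROPOSER if i % 2 == 0 else Role.RESPONDER
            subject_id = f"{condition.value}{i + 1:02d}"
            out.append(synthesize_session(config, condition, role, rng,
                                          subject_id=subject_id,
                                          targets=targets[i]))
    return out


def cohort_to_dataframes(cohort) -> tuple:
    """Ground-truth and decision tables for a generated cohort."""
    import pandas as pd

    gt_rows, dec_rows = [], []
    for session, truth in cohort:
        row = {"subject_id": truth.subject_id, "condition": truth.condition,
               "role": truth.role, "true_offset_s": truth.true_offset_s}
        row.update({k: v for k, v in truth.indices.items()})
        gt_rows.append(row)
        d = session.decision
        dec_rows.append({"subject_id": truth.subject_id,
                         "condition": truth.condition, "role": truth.role,
                         "amount_sent": d.amount_sent,
                         "fraction_returned": d.fraction_returned,
                         "proposer_q1": d.proposer_q1,
                         "proposer_q2": d.proposer_q2,
                         "responder_q1": d.responder_q1,
                         "responder_q2": d.responder_q2})
    return pd.DataFrame(gt_rows), pd.DataFrame(dec_rows)
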