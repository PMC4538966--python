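"""Per-subject physiological index extraction.

Each subject contributes ten indices: cardiovascular (heart rate, NN50,
RMSSD, LF/HF sympathovagal balance), electrodermal (mean skin conductance),
myographic (corrugator EMG RMS), cortical (slow-alpha power, beta power,
frontal alpha asymmetry) and pupillary (baseline-corrected dilation). All
but pupil dilation are expressed as the communication-phase value divided
by the same subject's resting-baseline value; pupil dilation is the mean
diameter difference in mm.

HRV follows the standard task-force conventions: NN50 counts successive
interbeat-interval pairs differing by strictly more than 50 ms, RMSSD is
the root mean square of successive differences, and spectral powers are
integrated over VLF (< 0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.5 Hz)
bands of the evenly resampled tachogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import interpolate, ndimage, signal

from .errors import (DegenerateError, InsufficientDataError, ParameterError,
                     QualityError)
from .io import (ChannelName, ChannelRecording, EventTimeline, GazeRecording,
                 Phase, SessionRecord, slice_gaze, slice_phase)

#: EEG bands (Hz). Beta's range is the standard convention; the slow-alpha
#: sub-band is deliberately narrow because it indexes sustained attention.
EEG_BANDS = {"slow_alpha": (7.0, 10.0), "beta": (13.0, 30.0)}

#: HRV spectral bands (Hz).
HRV_BANDS = {"vlf": (0.003, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.5)}


@dataclass
class IBISeries:
    """Interbeat intervals (ms) with beat times and per-interval artifact flags."""

    intervals_ms: np.ndarray
    beat_times_s: np.ndarray
    artifact_flags: np.ndarray = None

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.intervals_ms.size, dtype=bool)
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if self.beat_times_s.size != self.intervals_ms.size + 1:
            raise ValueError("need len(beat_times) == len(intervals) + 1")
        if self.artifact_flags.size != self.intervals_ms.size:
            raise ValueError("one artifact flag per interval")
        if np.any(self.intervals_ms <= 0):
            raise ValueError("intervals must be positive")

    @property
    def duration_s(self) -> float:
        return float(self.intervals_ms.sum()) / 1000.0


@dataclass
class SpectralHRV:
    """Band powers (ms^2) of the interpolated tachogram, grid kept for audit."""

    vlf_power: float
    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    frequency_grid: np.ndarray = field(repr=False, default=None)
    psd: np.ndarray = field(repr=False, default=None)


class TimeDomainHRV(NamedTuple):
    heart_rate_bpm: float
    nn50_count: int
    rmssd_ms: float


class RespirationReport(NamedTuple):
    rate_hz: float
    lf_contamination: bool
    indeterminate: bool


@dataclass
class FeatureVector:
    """The ten per-subject indices, baseline-normalized."""

    subject_id: str
    condition: str
    role: str
    heart_rate: float = np.nan
    emg_corrugator: float = np.nan
    skin_conductance: float = np.nan
    alpha_asymmetry: float = np.nan
    slow_alpha: float = np.nan
    beta: float = np.nan
    lf_hf: float = np.nan
    pupil_dilation: float = np.nan
    nn50: float = np.nan
    rmssd: float = np.nan
    excluded: bool = False
    exclusion_reason: str = ""

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition": str(getattr(self.condition, "value", self.condition)),
            "role": str(getattr(self.role, "value", self.role)),
            "heart_rate": self.heart_rate,
            "emg_corrugator": self.emg_corrugator,
            "skin_conductance": self.skin_conductance,
            "alpha_asymmetry": self.alpha_asymmetry,
            "slow_alpha": self.slow_alpha,
            "beta": self.beta,
            "lf_hf": self.lf_hf,
            "pupil_dilation": self.pupil_dilation,
            "nn50": self.nn50,
            "rmssd": self.rmssd,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
        }


# ---------------------------------------------------------------------------
# Cardiovascular chain
# ---------------------------------------------------------------------------

def detect_bvp_peaks(bvp: ChannelRecording, refractory_s: float = 0.25,
                     window_s: float = 10.0) -> IBISeries:
    """Systolic peak detection on a blood-volume-pulse waveform.

    Local maxima above an adaptive threshold (windowed median plus half the
    windowed 95th-to-median range) with a 250 ms refractory period; peak
    times are refined by parabolic interpolation, so interbeat intervals are
    accurate to well under one sample period on clean signals.
    """
    rate = bvp.sampling_rate
    if rate < 64:
        raise ParameterError("BVP peak detection needs >= 64 Hz sampling")
    if bvp.duration < 10:
        raise InsufficientDataError("need >= 10 s of BVP signal")
    x = bvp.samples
    n_win = max(1, int(round(window_s * rate)))
    edges = np.arange(0, x.size, n_win)
    centers, thresholds = [], []
    for lo in edges:
        seg = x[lo:lo + n_win]
        med, p95 = np.percentile(seg, [50, 95])
        centers.append(lo + seg.size / 2.0)
        thresholds.append(med + 0.5 * (p95 - med))
    threshold = np.interp(np.arange(x.size), centers, thresholds)
    peaks, _ = signal.find_peaks(x, height=threshold,
                                 distance=max(1, int(round(refractory_s * rate))))
    if peaks.size < 2:
        raise InsufficientDataError("fewer than 2 systolic peaks found")
    # sub-sample refinement: least-squares parabola over the peak's crown
    # (wider than 3 points so additive noise barely moves the vertex)
    half = max(1, int(round(0.03 * rate)))
    rel = np.arange(-half, half + 1, dtype=float)
    t_peaks = peaks.astype(float)
    for k, i in enumerate(peaks):
        if i - half < 0 or i + half >= x.size:
            continue
        y = x[i - half:i + half + 1]
        c2, c1, _ = np.polyfit(rel, y, 2)
        if c2 < 0:
            t_peaks[k] = i + np.clip(-c1 / (2 * c2), -half, half)
    beat_times = bvp.start_offset + t_peaks / rate
    intervals = np.diff(beat_times) * 1000.0
    return IBISeries(intervals_ms=intervals, beat_times_s=beat_times)


def correct_ibi_artifacts(ibi: IBISeries, deviation: float = 0.25,
                          window: int = 11, max_flagged: float = 0.20) -> IBISeries:
    """Flag and interpolate ectopic/missed-beat intervals.

    Intervals deviating more than 25% from an 11-beat running median are
    flagged and replaced by cubic interpolation over beat index; more than
    20% flagged intervals is a quality failure.
    """
    x = ibi.intervals_ms
    if x.size < 5:
        raise InsufficientDataError("need >= 5 intervals for artifact correction")
    med = ndimage.median_filter(x, size=min(window, x.size), mode="nearest")
    flags = np.abs(x - med) > deviation * med
    if flags.mean() > max_flagged:
        raise QualityError(
            f"{100 * flags.mean():.0f}% of intervals flagged as artifacts "
            f"(limit {100 * max_flagged:.0f}%)")
    corrected = x.copy()
    if flags.any():
        idx = np.arange(x.size)
        good = idx[~flags]
        kind = "cubic" if good.size >= 4 else "linear"
        f = interpolate.interp1d(good, x[~flags], kind=kind,
                                 fill_value="extrapolate")
        corrected[flags] = f(idx[flags])
    beat_times = np.concatenate(
        [[ibi.beat_times_s[0]],
         ibi.beat_times_s[0] + np.cumsum(corrected) / 1000.0])
    return IBISeries(intervals_ms=corrected, beat_times_s=beat_times,
                     artifact_flags=flags)


def hrv_time_domain(ibi: IBISeries) -> TimeDomainHRV:
    """Heart rate (bpm), NN50 count (strict > 50 ms) and RMSSD (ms)."""
    x = ibi.intervals_ms
    if x.size < 2:
        raise InsufficientDataError("need >= 2 intervals")
    diffs = np.diff(x)
    return TimeDomainHRV(
        heart_rate_bpm=60000.0 / float(np.mean(x)),
        nn50_count=int(np.sum(np.abs(diffs) > 50.0)),
        rmssd_ms=float(np.sqrt(np.mean(diffs ** 2))),
    )


def hrv_spectral(ibi: IBISeries, resample_hz: float = 4.0,
                 segment_s: float = 120.0) -> SpectralHRV:
    """Fourier HRV: cubic tachogram interpolation to an even grid, linear
    detrend, Welch PSD (120 s Hann segments, 50% overlap), band integration.

    Records shorter than one Welch segment fall back to a single-segment
    periodogram with a warning; under 30 s is an error. A flat tachogram
    yields an undefined (NaN) LF/HF ratio with a warning.
    """
    if ibi.duration_s < 30:
        raise InsufficientDataError("need >= 30 s of intervals for spectra")
    t = ibi.beat_times_s[1:]
    x = ibi.intervals_ms
    spline = interpolate.CubicSpline(t, x)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tach = spline(grid)
    nperseg = int(segment_s * resample_hz)
    if grid.size < nperseg:
        warnings.warn("record shorter than one Welch segment; "
                      "using a single-segment periodogram", stacklevel=2)
        nperseg = grid.size
    freqs, psd = signal.welch(tach, fs=resample_hz, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2,
                              detrend="linear")
    powers = {name: _band_power(freqs, psd, lo, hi)
              for name, (lo, hi) in HRV_BANDS.items()}
    if powers["hf"] <= 0 or (powers["lf"] + powers["hf"]) < 1e-6:
        warnings.warn("degenerate tachogram: LF/HF undefined", stacklevel=2)
        ratio = np.nan
    else:
        ratio = powers["lf"] / powers["hf"]
    return SpectralHRV(vlf_power=powers["vlf"], lf_power=powers["lf"],
                       hf_power=powers["hf"], lf_hf_ratio=ratio,
                       frequency_grid=freqs, psd=psd)


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal band integral of a one-sided PSD."""
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def respiration_check(rsp: ChannelRecording,
                      spectral: Optional[SpectralHRV] = None,
                      band: tuple = (0.05, 0.6)) -> RespirationReport:
    """Dominant respiration frequency and LF-contamination screen.

    Respiration slower than 0.15 Hz would leak respiratory sinus arrhythmia
    into the LF band, invalidating LF/HF as a sympathovagal index; such
    records are flagged. A spectrum without a dominant peak (peak < 2x the
    in-band median) is reported as indeterminate.
    """
    # respiration lives well below 2 Hz; decimate before the PSD
    x = rsp.samples - np.mean(rsp.samples)
    fs = rsp.sampling_rate
    if fs > 4:
        dec = int(fs // 4)
        x = signal.resample_poly(x, 1, dec)
        fs = fs / dec
    nperseg = min(x.size, int(60 * fs))
    freqs, psd = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        return RespirationReport(np.nan, False, True)
    in_band = psd[mask]
    peak_idx = int(np.argmax(in_band))
    rate = float(freqs[mask][peak_idx])
    indeterminate = in_band[peak_idx] < 2.0 * np.median(in_band)
    contamination = (not indeterminate) and rate < 0.15
    return RespirationReport(rate, contamination, indeterminate)


# ---------------------------------------------------------------------------
# Electrodermal, myographic, cortical, pupillary indices
# ---------------------------------------------------------------------------

def sc_statistics(gsr: ChannelRecording, target_hz: float = 32.0) -> tuple:
    """Mean and SD (microsiemens) of the skin-conductance slice at 32 Hz.

    Skin conductance is a slow process; 32 Hz preserves it without
    distortion, so higher-rate exports are polyphase-decimated first.
    """
    x = gsr.samples
    if gsr.sampling_rate > target_hz:
        from fractions import Fraction
        frac = Fraction(target_hz / gsr.sampling_rate).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator)
    return float(np.mean(x)), float(np.std(x))


def emg_rms_envelope(emg: ChannelRecording) -> float:
    """Phase-level RMS amplitude (microvolts) of the mean-centered EMG."""
    x = emg.samples - np.mean(emg.samples)
    return float(np.sqrt(np.mean(x ** 2)))


def eeg_band_power(eeg: ChannelRecording, band,
                   blink_times: Optional[Sequence[float]] = None,
                   blink_pad_s: float = 0.2, segment_s: float = 2.0) -> float:
    """Welch band power (uV^2) after excising blink-contaminated intervals.

    ``band`` is a (low, high) pair in Hz or a key of :data:`EEG_BANDS`.
    Windows of +/-200 ms around each blink are removed; the PSD is the
    duration-weighted average over the remaining contiguous segments.
    """
    if isinstance(band, str):
        band = EEG_BANDS[band]
    lo, hi = band
    rate = eeg.sampling_rate
    x = eeg.samples
    usable = np.ones(x.size, dtype=bool)
    if blink_times is not None:
        t = eeg.times
        for bt in blink_times:
            usable &= ~((t >= bt - blink_pad_s) & (t <= bt + blink_pad_s))
    nperseg = int(segment_s * rate)
    segments = _contiguous_runs(usable, min_len=nperseg)
    total = sum(hi_ - lo_ for lo_, hi_ in segments)
    if total < 2 * nperseg:
        raise InsufficientDataError(
            f"only {total / rate:.1f} s of blink-free EEG (need >= "
            f"{2 * segment_s:.0f} s)")
    acc, weight = 0.0, 0
    freqs = None
    for lo_, hi_ in segments:
        seg = x[lo_:hi_]
        freqs, psd = signal.welch(seg, fs=rate, window="hann", nperseg=nperseg,
                                  noverlap=nperseg // 2, detrend="constant")
        acc += psd * seg.size
        weight += seg.size
    return _band_power(freqs, acc / weight, lo, hi)


def _contiguous_runs(mask: np.ndarray, min_len: int = 1) -> list:
    """[start, stop) index pairs of True runs of at least ``min_len``."""
    padded = np.concatenate([[False], mask, [False]])
    changes = np.flatnonzero(np.diff(padded.astype(int)))
    runs = list(zip(changes[::2], changes[1::2]))
    return [(a, b) for a, b in runs if b - a >= min_len]


def alpha_asymmetry(power_fp1: float, power_fp2: float) -> float:
    """Left-minus-right log alpha power, ln(FP1) - ln(FP2).

    Under the activation-is-low-alpha convention a *lower* value means
    greater left-frontal activation, i.e. more positive emotional valence.
    """
    if power_fp1 <= 0 or power_fp2 <= 0:
        raise DegenerateError("alpha powers must be positive")
    return float(np.log(power_fp1) - np.log(power_fp2))


def _clean_pupil(gaze: GazeRecording, max_gap_s: float = 0.5,
                 min_valid_fraction: float = 0.5) -> np.ndarray:
    """Binocular pupil trace with short blink gaps linearly bridged.

    Gaps no longer than 500 ms (blinks) are interpolated; longer dropouts
    stay excluded. Fewer than 50% usable samples is a quality failure.
    """
    left, right = gaze.pupil_left_mm, gaze.pupil_right_mm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        both = np.nanmean(np.column_stack([left, right]), axis=1)
    valid = gaze.validity & ~np.isnan(both)
    if not valid.any():
        raise QualityError("no valid pupil samples")
    t = gaze.timestamps
    usable = valid.copy()
    for lo, hi in _contiguous_runs(~valid):
        gap = t[min(hi, t.size - 1)] - t[lo]
        if gap <= max_gap_s:
            usable[lo:hi] = True  # will be bridged
    if usable.mean() < min_valid_fraction:
        raise QualityError(
            f"only {100 * usable.mean():.0f}% usable pupil samples")
    filled = both.copy()
    filled[~valid] = np.interp(t[~valid], t[valid], both[valid])
    return filled[usable]


def pupil_dilation(gaze_phase: GazeRecording,
                   gaze_baseline: GazeRecording) -> float:
    """Mean binocular diameter in the phase minus the baseline mean (mm)."""
    return float(np.mean(_clean_pupil(gaze_phase))
                 - np.mean(_clean_pupil(gaze_baseline)))


# ---------------------------------------------------------------------------
# Full per-subject battery
# ---------------------------------------------------------------------------

def _phase_indices(session: SessionRecord, start_s: float, end_s: float,
                   offset_s: float, eeg_blinks) -> dict:
    """All raw (un-normalized) indices on one physio-clock window."""
    bounds = EventTimeline([("COMM_START", start_s), ("COMM_END", end_s)])
    out = {}

    def phase_slice(name):
        if ChannelName(name) not in session.channels:
            raise QualityError(f"missing channel {name}")
        return slice_phase(session.channel(name), bounds, Phase.COMM)

    bvp = phase_slice(ChannelName.BVP)
    ibi = correct_ibi_artifacts(detect_bvp_peaks(bvp))
    td = hrv_time_domain(ibi)
    sp = hrv_spectral(ibi)
    out["heart_rate"] = td.heart_rate_bpm
    out["nn50_per_min"] = td.nn50_count / (ibi.duration_s / 60.0)
    out["rmssd"] = td.rmssd_ms
    out["lf_hf"] = sp.lf_hf_ratio
    out["skin_conductance"] = sc_statistics(phase_slice(ChannelName.GSR))[0]
    out["emg_corrugator"] = emg_rms_envelope(phase_slice(ChannelName.EMG_CS))
    blinks = [b for b in eeg_blinks if start_s <= b <= end_s]
    p1 = eeg_band_power(phase_slice(ChannelName.EEG_FP1), "slow_alpha", blinks)
    p2 = eeg_band_power(phase_slice(ChannelName.EEG_FP2), "slow_alpha", blinks)
    b1 = eeg_band_power(phase_slice(ChannelName.EEG_FP1), "beta", blinks)
    b2 = eeg_band_power(phase_slice(ChannelName.EEG_FP2), "beta", blinks)
    out["slow_alpha"] = 0.5 * (p1 + p2)
    out["beta"] = 0.5 * (b1 + b2)
    out["alpha_asymmetry"] = alpha_asymmetry(p1, p2)
    gaze = slice_gaze(session.gaze, start_s + offset_s, end_s + offset_s)
    out["pupil_mm"] = float(np.mean(_clean_pupil(gaze)))
    out["respiration"] = respiration_check(phase_slice(ChannelName.RSP), sp)
    return out


def extract_features(session: SessionRecord, alignment=None,
                     comm_bounds: Optional[tuple] = None) -> FeatureVector:
    """Compute the ten baseline-normalized indices for one session.

    The communication window is located on the physiology clock (photodiode
    if available, otherwise the timeline mapped through the alignment); every
    ratio index is communication / baseline, pupil dilation is the mm
    difference, and NN50 enters as a per-minute rate so phases of unequal
    length stay comparable.

    Raises :class:`QualityError` on any per-channel quality failure; cohort
    drivers turn that into an exclusion (as real cohorts lose subjects to
    signal quality).
    """
    from .sync import detect_blinks_eeg, locate_communication_period

    offset = float(alignment.offset_s) if alignment is not None else 0.0
    if comm_bounds is None:
        comm_bounds = locate_communication_period(session, alignment)
    base_start, base_end = session.timeline.phase_bounds(Phase.BASELINE)
    base_bounds = (base_start - offset, base_end - offset)
    try:
        eeg_blinks = detect_blinks_eeg(session.channel(ChannelName.EEG_FP1),
                                       session.channel(ChannelName.EEG_FP2)).event_times
    except KeyError as exc:
        raise QualityError(f"missing channel {exc}") from exc
    comm = _phase_indices(session, *comm_bounds, offset, eeg_blinks)
    base = _phase_indices(session, *base_bounds, offset, eeg_blinks)
    fv = FeatureVector(subject_id=session.subject_id,
                       condition=session.condition.value,
                       role=session.role.value)
    for name, key in [("heart_rate", "heart_rate"),
                      ("emg_corrugator", "emg_corrugator"),
                      ("skin_conductance", "skin_conductance"),
                      ("alpha_asymmetry", "alpha_asymmetry"),
                      ("slow_alpha", "slow_alpha"),
                      ("beta", "beta"),
                      ("lf_hf", "lf_hf"),
                      ("nn50", "nn50_per_min"),
                      ("rmssd", "rmssd")]:
        denom = base[key]
        if denom == 0 or not np.isfinite(denom) or not np.isfinite(comm[key]):
            raise QualityError(f"degenerate baseline for {name}")
        setattr(fv, name, comm[key] / denom)
    fv.pupil_dilation = comm["pupil_mm"] - base["pupil_mm"]
    return fv


def extract_cohort_features(sessions, alignments=None) -> "pandas.DataFrame":
    """Run :func:`extract_features` over a cohort, recording exclusions.

    ``alignments`` may be None (estimate blink-train alignment per session),
    or a list matching ``sessions``.
    """
    import pandas as pd

    from .sync import align_session

    rows = []
    for i, session in enumerate(sessions):
        alignment = alignments[i] if alignments is not None else None
        try:
            if alignment is None:
                alignment = align_session(session)
            fv = extract_features(session, alignment)
        except Exception as exc:  # exclusion mirrors real cohort attrition
            fv = FeatureVector(subject_id=session.subject_id,
                               condition=session.condition.value,
                               role=session.role.value,
                               excluded=True, exclusion_reason=str(exc))
        rows.append(fv.as_dict())
    return pd.DataFrame(rows)
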