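"""Cross-device clock alignment for dyadic sessions.

The eye tracker and the physiology unit run on independent clocks. Two
event families exist on both: eye blinks (validity gaps in the gaze stream;
large slow frontal deflections in the EEG) and phase transitions (timeline
entries on the stimulus clock; photodiode luminance steps on the physiology
unit). A constant offset is recovered by cross-correlating Gaussian-smoothed
event trains on a 1 ms lag grid with parabolic sub-sample refinement —
the 60 Hz gaze raster alone could not resolve a 10 ms alignment bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy import signal

from .errors import (AmbiguityError, DegenerateError, InsufficientDataError,
                     LocalizationError, ParameterError)
from .io import (ChannelName, ChannelRecording, GazeRecording, Phase,
                 SessionRecord)


class EventSource(str, Enum):
    GAZE_BLINK = "GAZE_BLINK"
    EEG_BLINK = "EEG_BLINK"
    PHOTODIODE = "PHOTODIODE"


@dataclass
class EventTrain:
    """Strictly increasing event times (s) on one device clock."""

    event_times: np.ndarray
    source: EventSource

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.source = EventSource(self.source)
        if self.event_times.size > 1 and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.event_times.size)


@dataclass
class AlignmentResult:
    """Estimated clock offset (gaze minus physio) with an error bound."""

    offset_s: float
    alignment_error_bound_s: float
    n_events_matched: int

    def __post_init__(self) -> None:
        if self.alignment_error_bound_s < 0:
            raise ValueError("error bound must be >= 0")


#: Oculometric blink-duration convention (s).
BLINK_DURATION_BOUNDS = (0.075, 0.5)


def detect_blinks_gaze(gaze: GazeRecording) -> EventTrain:
    """Blink events from validity gaps of 75-500 ms; time = gap midpoint."""
    invalid = ~gaze.validity
    t = gaze.timestamps
    period = 1.0 / gaze.sampling_rate
    times = []
    for lo, hi in _runs(invalid):
        dur = t[hi - 1] - t[lo] + period
        if BLINK_DURATION_BOUNDS[0] <= dur <= BLINK_DURATION_BOUNDS[1]:
            times.append(0.5 * (t[lo] + t[hi - 1]))
    return EventTrain(np.asarray(times), EventSource.GAZE_BLINK)


def detect_blinks_eeg(eeg_fp1: ChannelRecording, eeg_fp2: ChannelRecording,
                      k: float = 6.0, lowpass_hz: float = 5.0) -> EventTrain:
    """Blink artifacts on the averaged frontal EEG.

    The averaged FP1/FP2 signal is zero-phase low-passed below 5 Hz; runs
    where its magnitude exceeds k times the median absolute deviation for
    75-500 ms become events at the run midpoint.
    """
    if k <= 1:
        raise ParameterError("threshold multiplier k must exceed 1")
    rate = eeg_fp1.sampling_rate
    x = 0.5 * (eeg_fp1.samples + eeg_fp2.samples)
    sos = signal.butter(4, lowpass_hz, btype="low", fs=rate, output="sos")
    low = signal.sosfiltfilt(sos, x - np.median(x))
    mad = np.median(np.abs(low - np.median(low)))
    if mad == 0:
        raise DegenerateError("flat EEG signal: MAD is zero")
    above = np.abs(low) > k * mad
    times = []
    for lo, hi in _runs(above):
        dur = (hi - lo) / rate
        if BLINK_DURATION_BOUNDS[0] <= dur <= BLINK_DURATION_BOUNDS[1]:
            times.append(eeg_fp1.start_offset + 0.5 * (lo + hi - 1) / rate)
    return EventTrain(np.asarray(times), EventSource.EEG_BLINK)


def detect_photodiode_events(photodiode: ChannelRecording,
                             debounce_s: float = 0.05) -> EventTrain:
    """Luminance transitions of the screen-mounted photodiode.

    The signal is lightly smoothed and binarized at the midpoint of its
    5th/95th percentiles; level runs shorter than the debounce window are
    ignored and each surviving transition time is refined by linear
    interpolation of the threshold crossing.
    """
    x = photodiode.samples
    rate = photodiode.sampling_rate
    p5, p95 = np.percentile(x, [5, 95])
    if p95 - p5 < 1e-12 or p95 - p5 < 0.1 * max(np.abs(p95), 1e-12):
        warnings.warn("photodiode signal is constant: no events detected",
                      stacklevel=2)
        return EventTrain(np.asarray([]), EventSource.PHOTODIODE)
    threshold = 0.5 * (p5 + p95)
    n_smooth = max(1, int(round(0.01 * rate)))
    smooth = np.convolve(x, np.ones(n_smooth) / n_smooth, mode="same")
    state = smooth > threshold
    # debounce: drop level runs shorter than the window
    min_run = max(1, int(round(debounce_s * rate)))
    runs = _runs(state) + _runs(~state)
    for lo, hi in runs:
        if hi - lo < min_run:
            state[lo:hi] = not state[lo]
    times = []
    for i in np.flatnonzero(np.diff(state.astype(int)) != 0):
        y0, y1 = smooth[i], smooth[i + 1]
        frac = 0.0 if y1 == y0 else np.clip((threshold - y0) / (y1 - y0), 0, 1)
        times.append(photodiode.start_offset + (i + frac) / rate)
    return EventTrain(np.asarray(times), EventSource.PHOTODIODE)


def estimate_offset(train_a: EventTrain, train_b: EventTrain,
                    search_window_s: float = 3.0, sigma_s: float = 0.025,
                    grid_s: float = 0.001,
                    ambiguity_ratio: float = 0.95) -> AlignmentResult:
    """Clock offset (a minus b) maximizing smoothed event-train correlation.

    Both trains are convolved with a Gaussian (sigma 25 ms); their
    cross-correlation is evaluated on a 1 ms lag grid inside the search
    window and the peak is refined by parabolic interpolation. A secondary
    peak within 5% of the maximum (outside the main lobe) is an ambiguity
    error, as is any pair of trains with fewer than three events.
    """
    a, b = train_a.event_times, train_b.event_times
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("need >= 3 events in each train")
    # correlating two sigma-smoothed trains == Gaussian kernel of sqrt(2)*sigma
    sigma_c = np.sqrt(2.0) * sigma_s
    diffs = (a[:, None] - b[None, :]).ravel()
    diffs = diffs[(diffs > -search_window_s - 5 * sigma_c)
                  & (diffs < search_window_s + 5 * sigma_c)]
    if diffs.size == 0:
        raise InsufficientDataError("no event pairs inside the search window")

    def correlate(lags):
        return np.exp(-((diffs[None, :] - lags[:, None]) ** 2)
                      / (2 * sigma_c ** 2)).sum(axis=1)

    # coarse sweep for the peak and the ambiguity check, fine grid to refine
    coarse_step = sigma_s / 2
    coarse = np.arange(-search_window_s, search_window_s + coarse_step / 2,
                       coarse_step)
    corr_c = correlate(coarse)
    i_c = int(np.argmax(corr_c))
    lobe = np.abs(coarse - coarse[i_c]) < 4 * sigma_c
    rival = corr_c[~lobe]
    if rival.size and rival.max() >= ambiguity_ratio * corr_c[i_c]:
        raise AmbiguityError("correlation peak is ambiguous (secondary peak "
                             f"within {100 * (1 - ambiguity_ratio):.0f}% of max)")
    lags = np.arange(coarse[i_c] - 2 * coarse_step,
                     coarse[i_c] + 2 * coarse_step + grid_s / 2, grid_s)
    corr = correlate(lags)
    i_max = int(np.argmax(corr))
    offset = lags[i_max]
    if 0 < i_max < lags.size - 1:
        y0, y1, y2 = corr[i_max - 1:i_max + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            offset = offset + 0.5 * grid_s * (y0 - y2) / denom
    matched = int(np.sum(np.min(np.abs(a[:, None] - offset - b[None, :]),
                                axis=1) <= 2 * sigma_s))
    # conservative bound: kernel width over effective sqrt(n) of matches
    bound = sigma_c / np.sqrt(max(matched, 1))
    return AlignmentResult(offset_s=float(offset),
                           alignment_error_bound_s=float(bound),
                           n_events_matched=matched)


def align_session(session: SessionRecord,
                  search_window_s: float = 3.0) -> AlignmentResult:
    """Blink-train alignment of a session's gaze clock to its physio clock."""
    gaze_train = detect_blinks_gaze(session.gaze)
    eeg_train = detect_blinks_eeg(session.channel(ChannelName.EEG_FP1),
                                  session.channel(ChannelName.EEG_FP2))
    return estimate_offset(gaze_train, eeg_train, search_window_s)


def locate_communication_period(session: SessionRecord,
                                alignment: Optional[AlignmentResult] = None,
                                use_photodiode: bool = True,
                                tolerance_s: float = 1.0) -> tuple:
    """Communication-phase (start, end) on the physiology clock.

    Photodiode luminance steps are the primary source: the transition pair
    nearest the timeline boundaries (mapped through the clock offset) is
    selected. Without a usable photodiode channel the mapped timeline alone
    is used, which requires an alignment. The recovered duration must agree
    with the timeline's within 0.5 s.
    """
    offset = float(alignment.offset_s) if alignment is not None else 0.0
    t_start, t_end = session.timeline.phase_bounds(Phase.COMM)
    expected = (t_start - offset, t_end - offset)
    nominal = t_end - t_start
    if use_photodiode:
        if ChannelName.PHOTODIODE not in session.channels:
            raise LocalizationError("photodiode channel absent")
        events = detect_photodiode_events(
            session.channel(ChannelName.PHOTODIODE)).event_times
        bounds = []
        for exp in expected:
            near = events[np.abs(events - exp) <= tolerance_s] if events.size \
                else np.asarray([])
            if near.size == 0:
                raise LocalizationError(
                    f"no photodiode transition within {tolerance_s} s of "
                    f"expected boundary {exp:.2f} s")
            bounds.append(float(near[np.argmin(np.abs(near - exp))]))
        start, end = bounds
    else:
        if alignment is None:
            raise LocalizationError("timeline localization requires an "
                                    "alignment estimate")
        start, end = expected
    if not (nominal - 0.5 <= end - start <= nominal + 0.5):
        raise LocalizationError(
            f"recovered duration {end - start:.2f} s deviates from the "
            f"timeline's {nominal:.2f} s by more than 0.5 s")
    return start, end


def _runs(mask: np.ndarray) -> list:
    """[start, stop) pairs of True runs."""
    padded = np.concatenate([[False], np.asarray(mask, dtype=bool), [False]])
    changes = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(changes[::2], changes[1::2]))
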