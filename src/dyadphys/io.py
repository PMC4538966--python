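"""Data model and delimited-file I/O for dyadic physiological sessions.

A session couples seven physiology channels (BVP, GSR, corrugator EMG,
respiration, frontal EEG at FP1/FP2, and a photodiode wired into the
physiology unit), a gaze/pupil stream on an independent eye-tracker clock,
a phase-event timeline, and the subject's trust-game decision record.

File dialects are deliberately simple: one channel per comma-delimited file
with ``#``-prefixed header lines carrying channel name, sampling rate and
units; gaze streams are tab-delimited with per-sample validity. Round-trip
``read(write(x)) == x`` holds bit-exactly for all formats.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import BoundsError, ConsistencyError, FormatError


class ChannelName(str, Enum):
    BVP = "BVP"
    GSR = "GSR"
    EMG_CS = "EMG_CS"
    RSP = "RSP"
    EEG_FP1 = "EEG_FP1"
    EEG_FP2 = "EEG_FP2"
    PHOTODIODE = "PHOTODIODE"


class Condition(str, Enum):
    PC = "PC"  # personal communication
    IC = "IC"  # impersonal communication


class Role(str, Enum):
    PROPOSER = "proposer"
    RESPONDER = "responder"


class Phase(str, Enum):
    BASELINE = "BASELINE"
    COMM = "COMM"
    DECISION = "DECISION"


#: Timeline event labels, in canonical session order.
EVENT_LABELS = (
    "BASELINE_START",
    "BASELINE_END",
    "COMM_START",
    "COMM_END",
    "DECISION_START",
    "DECISION_END",
)

#: Menu of amounts (Euros) a proposer may send.
TRUST_MENU = (100, 500, 1000, 1500, 2000)
#: Menu of fractions of the tripled amount a responder may return.
RECIPROCITY_MENU = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class ChannelRecording:
    """One uniformly sampled physiological channel.

    ``start_offset`` is the time of the first sample on the session clock of
    the acquiring device; cross-device alignment is the sync module's job.
    """

    channel_name: ChannelName
    sampling_rate: float
    samples: np.ndarray
    start_offset: float = 0.0
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.channel_name = ChannelName(self.channel_name)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("ChannelRecording requires non-empty samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times on the device clock."""
        return self.start_offset + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class GazeRecording:
    """Pupillometry stream on the eye tracker's own clock.

    Missing pupil samples are NaN and must coincide with ``validity=False``.
    """

    sampling_rate: float
    timestamps: np.ndarray
    pupil_left_mm: np.ndarray
    pupil_right_mm: np.ndarray
    validity: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.pupil_left_mm = np.asarray(self.pupil_left_mm, dtype=float)
        self.pupil_right_mm = np.asarray(self.pupil_right_mm, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if not (self.timestamps.size == self.pupil_left_mm.size
                == self.pupil_right_mm.size == self.validity.size):
            raise ValueError("gaze arrays must have equal length")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("gaze timestamps must be strictly increasing")
        missing = np.isnan(self.pupil_left_mm) & np.isnan(self.pupil_right_mm)
        if np.any(missing & self.validity):
            raise ValueError("missing pupil samples must be flagged invalid")

    @property
    def start_offset(self) -> float:
        return float(self.timestamps[0])


@dataclass
class EventTimeline:
    """Phase-boundary events (label, time) with non-decreasing times.

    Times are on the stimulus-delivery clock (the PC that also hosts the eye
    tracker); mapping them onto the physiology clock requires an offset
    estimate from the sync module.
    """

    events: list

    def __post_init__(self) -> None:
        times = [t for _, t in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("timeline times must be non-decreasing")
        labels = [lbl for lbl, _ in self.events]
        order = [EVENT_LABELS.index(lbl) for lbl in labels if lbl in EVENT_LABELS]
        if order != sorted(order):
            raise ValueError("phases must run baseline -> communication -> decision")

    def time_of(self, label: str) -> float:
        for lbl, t in self.events:
            if lbl == label:
                return float(t)
        raise KeyError(label)

    def phase_bounds(self, phase: Phase) -> tuple[float, float]:
        phase = Phase(phase)
        return (self.time_of(f"{phase.value}_START"), self.time_of(f"{phase.value}_END"))


@dataclass
class DecisionRecord:
    """Trust-game outcome and post-decision questionnaire codes."""

    amount_sent: Optional[int] = None        # proposer only, Euros
    fraction_returned: Optional[float] = None  # responder only
    proposer_q1: Optional[str] = None        # "Big" | "Small"
    proposer_q2: Optional[int] = None        # 4-level motivation code
    responder_q1: Optional[str] = None       # "Fair" | "PartiallyFair" | "Unfair"
    responder_q2: Optional[int] = None       # 5-level motivation code

    def __post_init__(self) -> None:
        if self.amount_sent is not None and self.amount_sent not in TRUST_MENU:
            raise ValueError(f"amount_sent must be one of {TRUST_MENU}")
        if (self.fraction_returned is not None
                and not any(math.isclose(self.fraction_returned, f)
                            for f in RECIPROCITY_MENU)):
            raise ValueError(f"fraction_returned must be one of {RECIPROCITY_MENU}")


@dataclass
class SessionRecord:
    """Everything recorded for one subject in one game round."""

    subject_id: str
    condition: Condition
    role: Role
    channels: dict
    gaze: GazeRecording
    timeline: EventTimeline
    decision: DecisionRecord

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.role = Role(self.role)
        self.channels = {ChannelName(k): v for k, v in self.channels.items()}
        for name, rec in self.channels.items():
            if rec.channel_name != name:
                raise ValueError(f"channel key {name} does not match recording "
                                 f"{rec.channel_name}")

    def channel(self, name: ChannelName) -> ChannelRecording:
        return self.channels[ChannelName(name)]


# ---------------------------------------------------------------------------
# Channel files: CSV with "# key=value" header lines, then time_s,value rows.
# ---------------------------------------------------------------------------

def write_channel_file(recording: ChannelRecording, path) -> None:
    """Write a channel as a two-column CSV with a metadata header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# channel={recording.channel_name.value}, "
                 f"rate_hz={float(recording.sampling_rate)!r}, "
                 f"units={recording.units}, "
                 f"start_offset_s={float(recording.start_offset)!r}\n")
        fh.write("time_s,value\n")
        times = recording.times
        for t, v in zip(times, recording.samples):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def _parse_header(line: str) -> dict:
    if not line.startswith("#"):
        raise FormatError("channel file must start with a '# key=value' header")
    fields = {}
    for part in line.lstrip("#").split(","):
        if "=" in part:
            k, v = part.split("=", 1)
            fields[k.strip()] = v.strip()
    return fields


def read_channel_file(path, channel_name: Optional[ChannelName] = None) -> ChannelRecording:
    """Read a channel file, validating the header rate against timestamp spacing.

    The declared rate must agree with the median timestamp spacing to within
    0.1%; non-monotonic timestamps are a format error.
    """
    path = Path(path)
    with path.open() as fh:
        header = _parse_header(fh.readline())
        colnames = fh.readline().strip().split(",")
        if colnames[:2] != ["time_s", "value"]:
            raise FormatError(f"unexpected columns {colnames} in {path}")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.shape[0] == 0:
        raise FormatError(f"no samples in {path}")
    times, values = data[:, 0], data[:, 1]
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise FormatError(f"non-monotonic timestamps in {path}")
    try:
        rate = float(header["rate_hz"])
    except KeyError as exc:
        raise FormatError(f"missing rate_hz in header of {path}") from exc
    if times.size > 1:
        spacing = float(np.median(np.diff(times)))
        if abs(spacing - 1.0 / rate) > max(1e-6, 0.001 / rate):
            raise ConsistencyError(
                f"header rate {rate} Hz disagrees with median spacing "
                f"{spacing:.6g} s in {path}")
    name = ChannelName(channel_name) if channel_name else ChannelName(header["channel"])
    if channel_name and "channel" in header and header["channel"] != name.value:
        raise ConsistencyError(f"requested {name.value} but file holds "
                               f"{header['channel']}")
    return ChannelRecording(
        channel_name=name,
        sampling_rate=rate,
        samples=values,
        start_offset=float(header.get("start_offset_s", times[0])),
        units=header.get("units", "a.u."),
    )


# ---------------------------------------------------------------------------
# Gaze files: TSV with validity column; NaN encodes missing pupil samples.
# ---------------------------------------------------------------------------

def write_gaze_file(gaze: GazeRecording, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# rate_hz={float(gaze.sampling_rate)!r}\n")
        fh.write("time_s\tpupil_left_mm\tpupil_right_mm\tvalidity\n")
        for t, l, r, v in zip(gaze.timestamps, gaze.pupil_left_mm,
                              gaze.pupil_right_mm, gaze.validity):
            fh.write(f"{float(t)!r}\t{float(l)!r}\t{float(r)!r}\t{int(v)}\n")


def read_gaze_file(path) -> GazeRecording:
    path = Path(path)
    with path.open() as fh:
        header = _parse_header(fh.readline())
        fh.readline()  # column names
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return GazeRecording(
        sampling_rate=float(header["rate_hz"]),
        timestamps=data[:, 0],
        pupil_left_mm=data[:, 1],
        pupil_right_mm=data[:, 2],
        validity=data[:, 3].astype(bool),
    )


def write_timeline_file(timeline: EventTimeline, path) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write("label,time_s\n")
        for lbl, t in timeline.events:
            fh.write(f"{lbl},{float(t)!r}\n")


def read_timeline_file(path) -> EventTimeline:
    events = []
    with Path(path).open() as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            events.append((row["label"], float(row["time_s"])))
    return EventTimeline(events)


_DECISION_COLS = ["subject_id", "condition", "role", "amount_sent",
                  "fraction_returned", "proposer_q1", "proposer_q2",
                  "responder_q1", "responder_q2"]


def write_decisions_file(rows: Sequence[dict], path) -> None:
    """Write one decision row per subject; empty string encodes None."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_DECISION_COLS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: ("" if row.get(k) is None else row[k])
                             for k in _DECISION_COLS})


def read_decisions_file(path) -> list:
    rows = []
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            parsed = dict(row)
            for k in ("amount_sent", "proposer_q2", "responder_q2"):
                parsed[k] = int(float(row[k])) if row[k] else None
            parsed["fraction_returned"] = (float(row["fraction_returned"])
                                           if row["fraction_returned"] else None)
            for k in ("proposer_q1", "responder_q1"):
                parsed[k] = row[k] or None
            rows.append(parsed)
    return rows


def slice_phase(recording: ChannelRecording, timeline: EventTimeline,
                phase: Phase, offset_s: float = 0.0) -> ChannelRecording:
    """Cut the sub-recording spanning a timeline phase.

    ``offset_s`` maps timeline times onto the recording's clock
    (physio time = timeline time − offset). The slice length is
    floor(phase duration × rate) samples.
    """
    start, end = timeline.phase_bounds(phase)
    start -= offset_s
    end -= offset_s
    rate = recording.sampling_rate
    i0 = int(round((start - recording.start_offset) * rate))
    n = int(math.floor((end - start) * rate))
    if i0 < 0 or i0 + n > recording.samples.size:
        raise BoundsError(
            f"phase {Phase(phase).value} [{start:.3f}, {end:.3f}] s outside "
            f"recording span [{recording.start_offset:.3f}, "
            f"{recording.start_offset + recording.duration:.3f}] s")
    return replace(recording, samples=recording.samples[i0:i0 + n],
                   start_offset=recording.start_offset + i0 / rate)


def slice_gaze(gaze: GazeRecording, start_s: float, end_s: float) -> GazeRecording:
    """Cut the gaze samples with timestamps in [start_s, end_s)."""
    mask = (gaze.timestamps >= start_s) & (gaze.timestamps < end_s)
    if not np.any(mask):
        raise BoundsError(f"no gaze samples in [{start_s}, {end_s}) s")
    return GazeRecording(
        sampling_rate=gaze.sampling_rate,
        timestamps=gaze.timestamps[mask],
        pupil_left_mm=gaze.pupil_left_mm[mask],
        pupil_right_mm=gaze.pupil_right_mm[mask],
        validity=gaze.validity[mask],
    )
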