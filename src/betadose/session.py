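"""Session containers and I/O for the streamed-sensing JSON dialect.

A *session* is one hemisphere's monopolar-review recording: bipolar LFP
channel(s) sampled at 250 Hz, a per-sample stimulation-amplitude trace in mA
and event annotations marking rest periods, finger-tapping blocks,
stimulation steps and the final ramp-down.  Vendor exports from sensing
implants are proprietary and undocumented, so the package defines its own
versioned JSON dialect (see ``schema/session.schema.json``) that carries the
same information; a mapping guide for converting real exports lives in the
docs.

Time convention: seconds from recording start, 0-based; annotations are
half-open intervals ``[onset, onset + duration)``.  Samples are stored as
microvolt floats without integer quantization.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
from scipy import signal as sp_signal

from .errors import AlignmentError, CorruptFileError, FormatError, InvalidArgumentError

SCHEMA_VERSION = "1.0"

ANNOTATION_LABELS = ("rest", "tap_block", "ramp_down")  # plus "stim_step:<mA>"


def _valid_label(label: str) -> bool:
    if label in ANNOTATION_LABELS:
        return True
    if label.startswith("stim_step:"):
        try:
            float(label.split(":", 1)[1])
            return True
        except ValueError:
            return False
    return False


@dataclass(frozen=True)
class Annotation:
    """A labelled half-open interval ``[onset_s, onset_s + duration_s)``."""

    onset_s: float
    duration_s: float
    label: str

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise InvalidArgumentError(f"annotation duration must be >= 0, got {self.duration_s}")
        if not _valid_label(self.label):
            raise InvalidArgumentError(f"unknown annotation label {self.label!r}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SessionRecording:
    """One hemisphere's LFP session with stimulation trace and annotations.

    Parameters
    ----------
    subject_id : str
        Pseudonymous subject identifier.
    hemisphere : {"left", "right"}
    channels : list of (label, samples)
        LFP channels in microvolts; all the same length.
    sampling_rate_hz : float
        250 Hz for the sensing implant emulated here.
    stim_trace_mA : ndarray
        Per-sample stimulation amplitude in mA, same length as the channels.
    events : list of Annotation
    metadata : dict
        Free-form provenance (seed, device, contacts, ground truth ...).
    """

    subject_id: str
    hemisphere: str
    channels: list[tuple[str, np.ndarray]]
    sampling_rate_hz: float
    stim_trace_mA: np.ndarray
    events: list[Annotation] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise InvalidArgumentError(f"hemisphere must be left|right, got {self.hemisphere!r}")
        if self.sampling_rate_hz <= 0:
            raise InvalidArgumentError("sampling_rate_hz must be > 0")
        self.stim_trace_mA = np.asarray(self.stim_trace_mA, dtype=float)
        self.channels = [(lbl, np.asarray(s, dtype=float)) for lbl, s in self.channels]
        n = len(self.stim_trace_mA)
        for lbl, s in self.channels:
            if len(s) != n:
                raise CorruptFileError(
                    f"channel {lbl!r} length {len(s)} != stim trace length {n}"
                )
        dur = self.duration_s
        for ev in self.events:
            if ev.onset_s < 0 or ev.end_s > dur + 1e-9:
                raise InvalidArgumentError(
                    f"event {ev.label!r} [{ev.onset_s}, {ev.end_s}) outside [0, {dur:.3f}]"
                )

    @property
    def n_samples(self) -> int:
        return len(self.stim_trace_mA)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, label: str) -> np.ndarray:
        for lbl, s in self.channels:
            if lbl == label:
                return s
        raise KeyError(label)

    @property
    def lfp(self) -> np.ndarray:
        """The first LFP channel (the analysis channel)."""
        return self.channels[0][1]

    def events_labelled(self, label: str) -> list[Annotation]:
        return [ev for ev in self.events if ev.label == label]

    def sample_slice(self, ann: Annotation) -> slice:
        fs = self.sampling_rate_hz
        return slice(int(round(ann.onset_s * fs)), int(round(ann.end_s * fs)))


@dataclass
class AccelTrace:
    """3-axis accelerometer trace, possibly on a different clock than the LFP.

    ``start_offset_s`` is the offset of the accelerometer clock relative to
    the LFP clock: accel sample 0 occurs at LFP time ``start_offset_s``.
    """

    sampling_rate_hz: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise InvalidArgumentError("sampling_rate_hz must be > 0")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise InvalidArgumentError("accelerometer axes must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.z)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


# ---------------------------------------------------------------------------
# JSON dialect I/O
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = (
    "schema_version",
    "subject_id",
    "hemisphere",
    "sampling_rate_hz",
    "channels",
    "stim_trace_mA",
    "events",
    "metadata",
)


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError(f"{name} contains non-finite samples (NaN/Inf refused)")


def write_session(recording: SessionRecording, path: str | Path) -> None:
    """Write a session to the JSON dialect with deterministic key order.

    Non-finite samples are refused: the dialect has no NaN representation.
    Two writes of the same recording produce byte-identical files.
    """
    _check_finite("stim_trace_mA", recording.stim_trace_mA)
    for lbl, s in recording.channels:
        _check_finite(f"channel {lbl!r}", s)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": recording.subject_id,
        "hemisphere": recording.hemisphere,
        "sampling_rate_hz": recording.sampling_rate_hz,
        "channels": [
            {"label": lbl, "samples": [float(v) for v in s]} for lbl, s in recording.channels
        ],
        "stim_trace_mA": [float(v) for v in recording.stim_trace_mA],
        "events": [
            {"onset_s": ev.onset_s, "duration_s": ev.duration_s, "label": ev.label}
            for ev in recording.events
        ],
        "metadata": recording.metadata,
    }
    try:
        text = json.dumps(doc, sort_keys=True, separators=(",", ":"))
        Path(path).write_text(text)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise IOError(f"cannot write session to {path}: {exc}") from exc


def read_session(path: str | Path) -> SessionRecording:
    """Read and validate a session file; lossless inverse of :func:`write_session`."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise CorruptFileError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError("document root must be an object")
    for fld in _REQUIRED_FIELDS:
        if fld not in doc:
            raise FormatError(fld)
    if doc["hemisphere"] not in ("left", "right"):
        raise FormatError("hemisphere")
    if not isinstance(doc["channels"], list) or not doc["channels"]:
        raise FormatError("channels")
    channels = []
    for ch in doc["channels"]:
        if not isinstance(ch, dict) or "label" not in ch or "samples" not in ch:
            raise FormatError("channels[].label/samples")
        channels.append((ch["label"], np.asarray(ch["samples"], dtype=float)))
    stim = np.asarray(doc["stim_trace_mA"], dtype=float)
    events = []
    for ev in doc["events"]:
        if not isinstance(ev, dict) or not {"onset_s", "duration_s", "label"} <= set(ev):
            raise FormatError("events[].onset_s/duration_s/label")
        try:
            events.append(Annotation(ev["onset_s"], ev["duration_s"], ev["label"]))
        except InvalidArgumentError as exc:
            raise FormatError(f"events: {exc}") from exc
    n = len(stim)
    for lbl, s in channels:
        if len(s) != n:
            raise CorruptFileError(
                f"channel {lbl!r} length {len(s)} != stim trace length {n}"
            )
    return SessionRecording(
        subject_id=doc["subject_id"],
        hemisphere=doc["hemisphere"],
        channels=channels,
        sampling_rate_hz=float(doc["sampling_rate_hz"]),
        stim_trace_mA=stim,
        events=events,
        metadata=doc["metadata"],
    )


def write_accel_csv(accel: AccelTrace, path: str | Path) -> None:
    """Write an accelerometer trace to CSV (header ``time_s,x,y,z``)."""
    t = accel.start_offset_s + np.arange(accel.n_samples) / accel.sampling_rate_hz
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "x", "y", "z"])
        for i in range(accel.n_samples):
            w.writerow([repr(float(t[i])), repr(float(accel.x[i])),
                        repr(float(accel.y[i])), repr(float(accel.z[i]))])


def read_accel_csv(path: str | Path) -> AccelTrace:
    """Read an accelerometer CSV written by :func:`write_accel_csv`.

    The sampling rate is inferred from the median time step; the first
    timestamp becomes ``start_offset_s``.
    """
    data = np.genfromtxt(path, delimiter=",", names=True)
    if data.dtype.names is None or set(data.dtype.names) != {"time_s", "x", "y", "z"}:
        raise FormatError("accelerometer CSV must have header time_s,x,y,z")
    t = np.atleast_1d(data["time_s"])
    if len(t) < 2:
        raise CorruptFileError("accelerometer CSV has fewer than 2 samples")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise CorruptFileError("non-increasing time column")
    return AccelTrace(
        sampling_rate_hz=1.0 / dt,
        x=np.atleast_1d(data["x"]),
        y=np.atleast_1d(data["y"]),
        z=np.atleast_1d(data["z"]),
        start_offset_s=float(t[0]),
    )


def merge_accelerometer(recording: SessionRecording, accel: AccelTrace) -> SessionRecording:
    """Resample the accel z-axis to the LFP rate and append it as ``accel_z``.

    The accelerometer must cover the whole LFP time span after applying its
    clock offset; an anti-alias lowpass is part of the polyphase resampling.
    Event annotations are untouched.
    """
    fs = recording.sampling_rate_hz
    t0, t1 = accel.start_offset_s, accel.start_offset_s + accel.duration_s
    if t0 > 1e-9 or t1 < recording.duration_s - 1e-9:
        raise AlignmentError(
            f"accelerometer covers [{t0:.3f}, {t1:.3f}) s but LFP spans "
            f"[0, {recording.duration_s:.3f}) s"
        )
    if abs(accel.sampling_rate_hz - fs) < 1e-9:
        z = accel.z
    else:
        from fractions import Fraction

        ratio = Fraction(fs / accel.sampling_rate_hz).limit_denominator(1000)
        z = sp_signal.resample_poly(accel.z, ratio.numerator, ratio.denominator)
    # shift onto the LFP clock, then cut to the LFP duration
    offset_samples = int(round(-t0 * fs))
    z = z[offset_samples : offset_samples + recording.n_samples]
    if len(z) < recording.n_samples:
        raise AlignmentError("resampled accelerometer shorter than LFP after alignment")
    merged = replace(
        recording,
        channels=recording.channels + [("accel_z", z)],
        events=list(recording.events),
        metadata=dict(recording.metadata),
    )
    return merged
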