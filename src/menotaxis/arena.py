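"""Data model and file I/O for rotating-tether flight experiments.

Heading traces are per-frame body angles of one tethered fly in the
arena (real-world) frame, recorded at the camera frame rate together
with a flying/stopped flag. Stimulus schedules describe timed epochs,
each presenting zero or more wavelength-tagged LED azimuths; an epoch
with no stimuli is a dark (or out-of-arena rest) period and is never
analyzed for heading.

File dialects
-------------
* trace CSV: header ``frame,time_s,heading_deg,flying``; one row per
  frame; ``flying`` in {0, 1}.
* schedule YAML/JSON: ``paradigm``, ``rotation_dir`` and
  ``epochs: [{t_start_s, t_end_s, label, stimuli: [{azimuth_deg, channel}]}]``.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .circkit import CircularSample, wrap_deg

__all__ = [
    "HeadingTrace",
    "Stimulus",
    "StimulusEpoch",
    "StimulusSchedule",
    "FlightSegment",
    "read_trace",
    "write_trace",
    "read_schedule",
    "write_schedule",
    "segment_trace",
    "to_reference_frame",
    "count_stop_episodes",
]

DEFAULT_FRAME_RATE_HZ = 25.0
CHANNELS = ("green", "uv")

#: labels (by prefix) of epochs that carry a stimulus but are not flight
#: analysis periods (e.g. the intertrial interval of varied-stimuli trials)
NON_ANALYSIS_PREFIXES = ("intertrial", "rest", "dark")


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class HeadingTrace:
    """Frame-rate heading time series for one fly (arena frame)."""

    fly_id: str
    time_s: np.ndarray
    heading_deg: np.ndarray
    flying: np.ndarray
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.heading_deg = wrap_deg(np.asarray(self.heading_deg, dtype=float))
        self.flying = np.asarray(self.flying, dtype=bool)
        if not (len(self.time_s) == len(self.heading_deg) == len(self.flying)):
            raise ValueError("time_s, heading_deg and flying must be equal length")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        dt = np.diff(self.time_s)
        if np.any(dt < 0):
            row = int(np.argmax(dt < 0)) + 2  # 1-based row of the later frame
            raise ValueError(f"time_s not monotone at row {row}")
        # frames are either consecutive (~1/rate) or separated by a
        # recording gap (fly out of the arena); never faster than the camera
        step = 1.0 / self.frame_rate_hz
        if np.any(dt < 0.5 * step - 1e-9):
            row = int(np.argmax(dt < 0.5 * step - 1e-9)) + 2
            raise ValueError(f"time step shorter than the frame period at row {row}")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class Stimulus:
    """One LED at a fixed arena azimuth for the duration of an epoch."""

    azimuth_deg: float
    channel: str

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        object.__setattr__(self, "azimuth_deg", wrap_deg(self.azimuth_deg))


@dataclass(frozen=True)
class StimulusEpoch:
    """Half-open time interval [t_start_s, t_end_s) with 0+ stimuli."""

    t_start_s: float
    t_end_s: float
    label: str
    stimuli: tuple = ()

    def __post_init__(self):
        if not self.t_end_s > self.t_start_s:
            raise ValueError(f"epoch {self.label!r}: t_end_s must exceed t_start_s")
        object.__setattr__(self, "stimuli", tuple(
            s if isinstance(s, Stimulus) else Stimulus(**s) for s in self.stimuli
        ))

    @property
    def is_dark(self) -> bool:
        return len(self.stimuli) == 0

    @property
    def is_analysis(self) -> bool:
        """True for flight periods whose headings enter the statistics."""
        if self.is_dark:
            return False
        lab = self.label.lower()
        return not any(lab.startswith(p) for p in NON_ANALYSIS_PREFIXES)

    def azimuth(self, channel: str) -> float:
        for s in self.stimuli:
            if s.channel == channel:
                return s.azimuth_deg
        raise KeyError(f"epoch {self.label!r} has no {channel} stimulus")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered, non-overlapping epochs covering the experiment."""

    epochs: tuple
    paradigm: str = "custom"
    rotation_dir: str = "none"

    def __post_init__(self):
        eps = tuple(self.epochs)
        if not eps:
            raise ValueError("schedule needs at least one epoch")
        for prev, nxt in zip(eps, eps[1:]):
            if nxt.t_start_s < prev.t_end_s - 1e-9:
                raise ValueError(
                    f"epochs {prev.label!r} and {nxt.label!r} overlap"
                )
        if self.rotation_dir not in ("cw", "ccw", "none"):
            raise ValueError(f"unknown rotation_dir {self.rotation_dir!r}")
        object.__setattr__(self, "epochs", eps)

    @property
    def t_end_s(self) -> float:
        return self.epochs[-1].t_end_s

    def analysis_epochs(self) -> List[StimulusEpoch]:
        return [e for e in self.epochs if e.is_analysis]

    def epoch_at(self, t: float) -> Optional[StimulusEpoch]:
        for e in self.epochs:
            if e.t_start_s <= t < e.t_end_s:
                return e
        return None


@dataclass
class FlightSegment:
    """One analysis slice of a trace: the frames of one flight period
    (or one sub-bin of it), with stopped frames flagged."""

    fly_id: str
    label: str
    time_s: np.ndarray
    heading_deg: np.ndarray
    flying: np.ndarray
    stimuli: tuple = ()
    stop_count: int = 0

    @property
    def angles_flying(self) -> np.ndarray:
        """Arena-frame headings of the flying frames only."""
        return self.heading_deg[self.flying]

    def reference_azimuth(self, channel: str) -> float:
        for s in self.stimuli:
            if s.channel == channel:
                return s.azimuth_deg
        raise KeyError(f"segment {self.label!r} has no {channel} stimulus")


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------

TRACE_COLUMNS = ("frame", "time_s", "heading_deg", "flying")


def read_trace(path_or_buf, fly_id: Optional[str] = None,
               frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> HeadingTrace:
    """Read a per-frame heading CSV into a :class:`HeadingTrace`.

    Headings are wrapped to (-180, 180]; time must be monotone
    non-decreasing (validation errors name the offending row).
    """
    df = pd.read_csv(path_or_buf)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing column(s): {', '.join(missing)}")
    for col in ("time_s", "heading_deg"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax((bad | df[col].isna()).to_numpy())) + 1
            raise ValueError(f"unparseable {col} at data row {row}")
    if fly_id is None:
        fly_id = Path(path_or_buf).stem if isinstance(
            path_or_buf, (str, Path)) else "fly"
    return HeadingTrace(
        fly_id=fly_id,
        time_s=df["time_s"].to_numpy(float),
        heading_deg=df["heading_deg"].to_numpy(float),
        flying=df["flying"].to_numpy(int).astype(bool),
        frame_rate_hz=frame_rate_hz,
    )


def write_trace(trace: HeadingTrace, path_or_buf) -> None:
    """Write a trace in the canonical CSV dialect (round-trips read_trace)."""
    df = pd.DataFrame({
        "frame": np.arange(len(trace), dtype=int),
        "time_s": trace.time_s,
        "heading_deg": trace.heading_deg,
        "flying": trace.flying.astype(int),
    })
    df.to_csv(path_or_buf, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# schedule I/O
# ---------------------------------------------------------------------------

def _schedule_to_dict(schedule: StimulusSchedule) -> dict:
    return {
        "paradigm": schedule.paradigm,
        "rotation_dir": schedule.rotation_dir,
        "epochs": [
            {
                "t_start_s": e.t_start_s,
                "t_end_s": e.t_end_s,
                "label": e.label,
                "stimuli": [
                    {"azimuth_deg": s.azimuth_deg, "channel": s.channel}
                    for s in e.stimuli
                ],
            }
            for e in schedule.epochs
        ],
    }


def _schedule_from_dict(d: dict) -> StimulusSchedule:
    epochs = tuple(
        StimulusEpoch(
            t_start_s=float(e["t_start_s"]),
            t_end_s=float(e["t_end_s"]),
            label=str(e.get("label", f"epoch{i}")),
            stimuli=tuple(
                Stimulus(azimuth_deg=float(s["azimuth_deg"]),
                         channel=str(s["channel"]))
                for s in e.get("stimuli", [])
            ),
        )
        for i, e in enumerate(d["epochs"])
    )
    return StimulusSchedule(
        epochs=epochs,
        paradigm=str(d.get("paradigm", "custom")),
        rotation_dir=str(d.get("rotation_dir", "none")),
    )


def read_schedule(path_or_buf) -> StimulusSchedule:
    """Read a stimulus schedule from YAML or JSON (by extension/content)."""
    if isinstance(path_or_buf, (str, Path)):
        text = Path(path_or_buf).read_text()
    else:
        text = path_or_buf.read()
    d = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(d, dict) or "epochs" not in d:
        raise ValueError("schedule must be a mapping with an 'epochs' list")
    return _schedule_from_dict(d)


def write_schedule(schedule: StimulusSchedule, path_or_buf) -> None:
    d = _schedule_to_dict(schedule)
    if isinstance(path_or_buf, (str, Path)):
        p = Path(path_or_buf)
        if p.suffix.lower() == ".json":
            p.write_text(json.dumps(d, indent=1))
        else:
            p.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        yaml.safe_dump(d, path_or_buf, sort_keys=False)


# ---------------------------------------------------------------------------
# segmentation and reference frames
# ---------------------------------------------------------------------------

def count_stop_episodes(flags) -> int:
    """Number of maximal runs of stopped frames in a flying/stopped flag
    vector (or trace/segment). An episode spanning a segment boundary
    counts once in every segment it touches."""
    if isinstance(flags, (HeadingTrace, FlightSegment)):
        flags = flags.flying
    f = np.asarray(flags, dtype=bool)
    if f.size == 0:
        return 0
    stopped = ~f
    starts = stopped & ~np.concatenate([[False], stopped[:-1]])
    return int(starts.sum())


def segment_trace(trace: HeadingTrace, schedule: StimulusSchedule,
                  bin_s: Optional[float] = None) -> List[FlightSegment]:
    """Slice a trace into flight segments, one per analysis epoch (or per
    ``bin_s`` sub-bin of it). Dark and intertrial/rest epochs yield no
    segment. Time intervals are half-open at frame resolution, so every
    frame lands in at most one segment. Stopped frames stay in the
    segment (for episode counting) but are flagged.
    """
    epochs = schedule.analysis_epochs()
    if not epochs:
        raise ValueError("schedule has no analysis epochs")
    if trace.time_s[-1] < epochs[0].t_start_s:
        raise ValueError("trace does not overlap the schedule's flight epochs")
    segments: List[FlightSegment] = []
    for e in epochs:
        bounds = []
        if bin_s is None:
            bounds = [(e.t_start_s, e.t_end_s, e.label)]
        else:
            nbin = max(1, int(round(e.duration_s / bin_s)))
            for b in range(nbin):
                lo = e.t_start_s + b * bin_s
                hi = min(e.t_start_s + (b + 1) * bin_s, e.t_end_s)
                bounds.append((lo, hi, f"{e.label}_bin{b + 1}"))
        for lo, hi, label in bounds:
            mask = (trace.time_s >= lo - 1e-9) & (trace.time_s < hi - 1e-9)
            if not mask.any():
                continue
            flying = trace.flying[mask]
            segments.append(FlightSegment(
                fly_id=trace.fly_id,
                label=label,
                time_s=trace.time_s[mask],
                heading_deg=trace.heading_deg[mask],
                flying=flying,
                stimuli=e.stimuli,
                stop_count=count_stop_episodes(flying),
            ))
    if not segments:
        raise ValueError("no frames fall inside any analysis epoch")
    return segments


def to_reference_frame(segment: FlightSegment, reference: str = "arena",
                       channel: str = "green",
                       include_stopped: bool = False) -> CircularSample:
    """Express a segment's headings in the arena or a stimulus frame.

    ``reference='arena'`` returns the headings unchanged;
    ``reference='stimulus'`` subtracts the azimuth of the requested
    channel's LED (so a fly aimed straight at that LED reads 0 deg).
    Stopped frames are excluded by default: a stopped tethered fly's
    body angle is not an orientation choice.
    """
    angles = segment.heading_deg if include_stopped else segment.angles_flying
    if angles.size == 0:
        raise ValueError(f"segment {segment.label!r} has no usable frames")
    if reference == "arena":
        return CircularSample(angles, frame="arena")
    if reference == "stimulus":
        az = segment.reference_azimuth(channel)
        return CircularSample(angles - az, frame="stimulus_relative")
    raise ValueError(f"unknown reference {reference!r}")
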