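"""Session I/O: accelerometer CSV streams, interval label tracks, and annotation.

A recording session consists of a tri-axial acceleration stream (units of g,
x pointing toward the ground so gravity reads +1 g at rest, z pointing away
from the rider) and an interval label track listing which of 11 fine riding
activities the horse performed in each time span.  Labels are aligned to
samples with a half-open ``[start, end)`` convention so every boundary sample
belongs to exactly one interval.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FINE_ACTIVITIES",
    "LOCATIONS",
    "UNLABELLED",
    "AccelStream",
    "LabelTrack",
    "SessionRecord",
    "read_accel_csv",
    "write_accel_csv",
    "read_labels",
    "write_labels",
    "annotate",
    "read_manifest",
    "write_manifest",
]

#: The 11 fine activity labels: halt plus collected/medium/normal variants of
#: the three moving gaits.
FINE_ACTIVITIES: frozenset[str] = frozenset(
    {"halt"}
    | {
        f"{variant} {gait}"
        for variant in ("collected", "medium", "normal")
        for gait in ("walk", "trot", "canter")
    }
)

#: Rider body sites where a sensor can be worn.
LOCATIONS: tuple[str, ...] = ("knee", "backbone", "chest", "arm")

UNLABELLED = "unlabelled"

_STANDARD_GRAVITY = 9.80665  # m/s^2 per g


@dataclass
class AccelStream:
    """Tri-axial acceleration samples for one session.

    Parameters
    ----------
    t : ndarray of shape (n,)
        Seconds since session start, strictly increasing.
    a : ndarray of shape (n, 3)
        Acceleration in g; axis order x (toward ground), y, z (away from rider).
    rate_hz : float
        Nominal sampling rate.  The median sample spacing must agree with
        ``1 / rate_hz`` to within 1%.
    """

    t: np.ndarray
    a: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.t.ndim != 1:
            raise ValueError("t must be one-dimensional")
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise ValueError("a must have shape (n, 3): exactly 3 channels")
        if len(self.t) != len(self.a):
            raise ValueError("t and a must have equal length")
        if len(self.t) < 2:
            raise ValueError("a stream needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        nominal = 1.0 / self.rate_hz
        if abs(np.median(dt) - nominal) > 0.01 * nominal:
            raise ValueError(
                f"median sample spacing {np.median(dt):.6f}s inconsistent with "
                f"nominal rate {self.rate_hz} Hz"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.rate_hz


@dataclass
class LabelTrack:
    """Sorted, non-overlapping activity intervals ``(start_s, end_s, activity)``."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(s), float(e), str(lab)) for s, e, lab in self.intervals]
        ivs.sort(key=lambda iv: iv[0])
        for s, e, lab in ivs:
            if e <= s:
                raise ValueError(f"interval ({s}, {e}) has end <= start")
            if lab not in FINE_ACTIVITIES and lab != UNLABELLED:
                raise ValueError(f"unknown activity label: {lab!r}")
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping intervals at t={s1}")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_duration_s(self) -> float:
        return sum(e - s for s, e, _ in self.intervals)


@dataclass
class SessionRecord:
    """One (horse, rider, sensor location) recording: stream plus labels."""

    horse_id: str
    rider_id: str
    location: str
    stream: AccelStream
    labels: LabelTrack
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(
                f"location must be one of {LOCATIONS}, got {self.location!r}"
            )
        if not self.session_id:
            self.session_id = f"{self.horse_id}_{self.location}"


def read_accel_csv(path, units: str = "g") -> AccelStream:
    """Read an accelerometer CSV with header ``timestamp,x,y,z``.

    Timestamps may be ISO-8601 strings or float seconds; they are converted to
    seconds since the first sample.  The nominal rate is inferred from the
    median sample spacing.  Set ``units="ms2"`` if the file stores m/s² to
    convert to g on read.
    """
    df = pd.read_csv(path)
    missing = {"timestamp", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"accelerometer CSV missing columns: {sorted(missing)}")
    if len(df) < 2:
        raise ValueError("accelerometer CSV needs at least 2 rows")
    ts = df["timestamp"]
    if ts.dtype == object:
        t = pd.to_datetime(ts, format="ISO8601").astype("int64").to_numpy() / 1e9
    else:
        t = ts.to_numpy(dtype=float)
    t = t - t[0]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    a = df[["x", "y", "z"]].to_numpy(dtype=float)
    if units == "ms2":
        a = a / _STANDARD_GRAVITY
    elif units != "g":
        raise ValueError(f"units must be 'g' or 'ms2', got {units!r}")
    rate_hz = 1.0 / float(np.median(dt))
    # snap to an integral rate when within the 1% tolerance (e.g. 49.9 -> 50)
    if abs(rate_hz - round(rate_hz)) / rate_hz < 0.01:
        rate_hz = float(round(rate_hz))
    return AccelStream(t=t, a=a, rate_hz=rate_hz)


def write_accel_csv(stream: AccelStream, path) -> None:
    """Write a stream as ``timestamp,x,y,z`` with float-second timestamps.

    Values are written with enough digits that a write→read round trip
    reproduces them to 1e-6 g.
    """
    df = pd.DataFrame(
        {
            "timestamp": stream.t,
            "x": stream.a[:, 0],
            "y": stream.a[:, 1],
            "z": stream.a[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.8f")


def read_labels(path) -> LabelTrack:
    """Read an interval label file with rows ``start_s, end_s, activity``.

    Accepts tab- or comma-separated values, with or without a header row.
    Unknown activity names and overlapping intervals are rejected.
    """
    text = Path(path).read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(_stdio.StringIO(text), sep=sep, header=None, skipinitialspace=True)
    if df.shape[1] < 3:
        raise ValueError("label file needs 3 columns: start_s, end_s, activity")
    # tolerate a header row
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if len(df) == 0:
        return LabelTrack([])
    intervals = [
        (float(r[0]), float(r[1]), str(r[2]).strip())
        for r in df.itertuples(index=False)
    ]
    return LabelTrack(intervals)


def write_labels(labels: LabelTrack, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for s, e, lab in labels:
            fh.write(f"{s:.6f}{sep}{e:.6f}{sep}{lab}\n")


def annotate(stream: AccelStream, labels: LabelTrack) -> np.ndarray:
    """Assign each sample the activity of the interval containing it.

    Intervals are half-open ``[start, end)``; samples outside every interval
    get :data:`UNLABELLED`.  Returns an array of label strings, one per sample.
    """
    out = np.full(len(stream), UNLABELLED, dtype=object)
    if len(labels) == 0:
        return out
    starts = np.array([s for s, _, _ in labels])
    ends = np.array([e for _, e, _ in labels])
    names = np.array([lab for _, _, lab in labels], dtype=object)
    idx = np.searchsorted(starts, stream.t, side="right") - 1
    valid = (idx >= 0) & (stream.t >= starts[np.clip(idx, 0, None)])
    valid &= stream.t < ends[np.clip(idx, 0, None)]
    out[valid] = names[idx[valid]]
    return out


def read_manifest(path) -> list[dict]:
    """Read a cohort manifest (YAML list of session entries)."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError("manifest must be a YAML list of session entries")
    required = {"horse_id", "rider_id", "location", "accel_csv", "labels"}
    for e in entries:
        missing = required - set(e)
        if missing:
            raise ValueError(f"manifest entry missing keys: {sorted(missing)}")
    return entries


def write_manifest(entries: list[dict], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
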