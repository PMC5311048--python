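"""Reading and writing accelerometer streams, annotations and sessions.

All on-disk formats are plain comma-separated UTF-8 text with one header
line and '.' decimals, so read/write round-trips are stable.

Stream CSV schema:      ``t,x,y,z``          (seconds from session start, g, g, g)
Annotation CSV schema:  ``start_s,end_s,label``  with label in
:data:`LABELS`; any time not covered by a labeled interval is implicitly
``unknown`` (non-stereotyped movement).

Acceleration is kept in g-units throughout; recurrence thresholds are
relative to whatever unit the trajectory uses, so no conversion to m/s^2
is performed anywhere in the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Body positions of the three wearable sensors.
SENSOR_POSITIONS = ("left_wrist", "right_wrist", "torso")

#: The three stereotypical motor movement (SMM) classes.
SMM_LABELS = ("rock", "flap", "flaprock")

#: Label for non-stereotyped (background) movement.
UNKNOWN = "unknown"

#: All annotation labels, SMM classes first.
LABELS = SMM_LABELS + (UNKNOWN,)

STREAM_COLUMNS = ["t", "x", "y", "z"]
ANNOTATION_COLUMNS = ["start_s", "end_s", "label"]

_META_FILENAME = "meta.json"
_ANNOTATION_FILENAME = "annotations.csv"


class FormatError(ValueError):
    """A file does not follow the expected schema."""


class ValidationError(ValueError):
    """Data violates a structural invariant."""


@dataclass
class AccelerometerStream:
    """A uniformly sampled 3-axis acceleration recording from one sensor.

    Parameters
    ----------
    sensor_position:
        One of :data:`SENSOR_POSITIONS`.
    sampling_rate_hz:
        Nominal sampling rate; timestamps must be uniform within 1 % of
        ``1/sampling_rate_hz``.
    t:
        Strictly increasing timestamps in seconds from session start, shape (N,).
    xyz:
        Acceleration in g-units, shape (N, 3).
    """

    sensor_position: str
    sampling_rate_hz: float
    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        if self.sensor_position not in SENSOR_POSITIONS:
            raise ValidationError(
                f"unknown sensor position {self.sensor_position!r}; "
                f"expected one of {SENSOR_POSITIONS}"
            )
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise ValidationError(
                f"expected t of shape (N,) and xyz of shape (N, 3); "
                f"got {self.t.shape} and {self.xyz.shape}"
            )
        if not (np.isfinite(self.t).all() and np.isfinite(self.xyz).all()):
            raise ValidationError("stream contains non-finite values")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            bad = dt <= 0
            if bad.any():
                row = int(np.argmax(bad)) + 1
                raise ValidationError(
                    f"timestamps not strictly increasing at row {row}"
                )
            nominal = 1.0 / self.sampling_rate_hz
            off = np.abs(dt - nominal) > 0.01 * nominal
            if off.any():
                row = int(np.argmax(off)) + 1
                raise ValidationError(
                    f"sample spacing deviates more than 1% from "
                    f"1/{self.sampling_rate_hz:g} s at row {row}"
                )

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def start_s(self) -> float:
        return float(self.t[0])

    @property
    def end_s(self) -> float:
        return float(self.t[-1])

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AnnotationTrack:
    """Labeled intervals for one session; uncovered time is ``unknown``.

    ``intervals`` is a sequence of ``(start_s, end_s, label)`` tuples kept
    sorted by start time.  Labeled (non-unknown) intervals must be pairwise
    non-overlapping.
    """

    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        norm = []
        for iv in self.intervals:
            start, end, label = iv
            start, end = float(start), float(end)
            if not end > start:
                raise ValidationError(
                    f"interval ({start}, {end}, {label!r}) has end <= start"
                )
            if label not in LABELS:
                raise FormatError(
                    f"unknown label {label!r}; allowed labels are {LABELS}"
                )
            norm.append((start, end, label))
        norm.sort()
        labeled = [iv for iv in norm if iv[2] != UNKNOWN]
        for prev, cur in zip(labeled, labeled[1:]):
            if cur[0] < prev[1] - 1e-12:
                raise ValidationError(
                    f"labeled intervals overlap: {prev} and {cur}"
                )
        self.intervals = norm

    @property
    def labeled_intervals(self) -> list:
        return [iv for iv in self.intervals if iv[2] != UNKNOWN]

    def coverage(self, start_s: float, end_s: float) -> dict:
        """Seconds of [start_s, end_s) covered by each SMM label."""
        cov: dict = {}
        for s, e, label in self.labeled_intervals:
            overlap = min(e, end_s) - max(s, start_s)
            if overlap > 0:
                cov[label] = cov.get(label, 0.0) + overlap
        return cov

    def label_at(self, time_s: float) -> str:
        """Label of the interval containing ``time_s`` (half-open), else unknown."""
        for s, e, label in self.labeled_intervals:
            if s <= time_s < e:
                return label
        return UNKNOWN


@dataclass
class Session:
    """Aligned multi-sensor streams plus the annotation track of one recording."""

    participant_id: str
    session_id: str
    streams: dict
    annotations: AnnotationTrack

    def __post_init__(self) -> None:
        if not self.streams:
            raise ValidationError("session has no streams")
        for pos, stream in self.streams.items():
            if stream.sensor_position != pos:
                raise ValidationError(
                    f"stream keyed {pos!r} reports position "
                    f"{stream.sensor_position!r}"
                )
        if self.end_s <= self.start_s:
            raise ValidationError("streams share no common time span")
        tol = 1e-6
        for s, e, label in self.annotations.labeled_intervals:
            if s < self.start_s - tol or e > self.end_s + tol:
                raise ValidationError(
                    f"annotation ({s}, {e}, {label!r}) lies outside the "
                    f"common stream span [{self.start_s}, {self.end_s}]"
                )

    @property
    def start_s(self) -> float:
        return max(s.start_s for s in self.streams.values())

    @property
    def end_s(self) -> float:
        return min(s.end_s for s in self.streams.values())

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# CSV readers / writers


def _read_csv_checked(path, expected_columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path)
    if list(df.columns) != expected_columns:
        raise FormatError(
            f"{path}: expected columns {expected_columns}, "
            f"found {list(df.columns)}"
        )
    return df


def read_stream_csv(path, sensor_position: str,
                    sampling_rate_hz: float) -> AccelerometerStream:
    """Read one ``t,x,y,z`` CSV into a validated stream, rows in file order."""
    df = _read_csv_checked(path, STREAM_COLUMNS)
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric value in body ({exc})") from exc
    return AccelerometerStream(
        sensor_position=sensor_position,
        sampling_rate_hz=sampling_rate_hz,
        t=values["t"].to_numpy(),
        xyz=values[["x", "y", "z"]].to_numpy(),
    )


def write_stream_csv(stream: AccelerometerStream, path) -> None:
    df = pd.DataFrame(
        {"t": stream.t, "x": stream.xyz[:, 0],
         "y": stream.xyz[:, 1], "z": stream.xyz[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_annotations_csv(path) -> AnnotationTrack:
    """Read a ``start_s,end_s,label`` CSV; an empty body means all-unknown."""
    df = _read_csv_checked(path, ANNOTATION_COLUMNS)
    intervals = [
        (float(r.start_s), float(r.end_s), str(r.label))
        for r in df.itertuples(index=False)
    ]
    return AnnotationTrack(intervals)


def write_annotations_csv(track: AnnotationTrack, path) -> None:
    df = pd.DataFrame(track.intervals, columns=ANNOTATION_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Session directories


def write_session(session: Session, directory) -> None:
    """Write one session as ``<sensor>.csv`` files + annotations + metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "participant_id": session.participant_id,
        "session_id": session.session_id,
        "sensors": {
            pos: {"sampling_rate_hz": s.sampling_rate_hz}
            for pos, s in session.streams.items()
        },
    }
    (directory / _META_FILENAME).write_text(json.dumps(meta, indent=2,
                                                       sort_keys=True))
    for pos, stream in session.streams.items():
        write_stream_csv(stream, directory / f"{pos}.csv")
    write_annotations_csv(session.annotations,
                          directory / _ANNOTATION_FILENAME)


def read_session(directory) -> Session:
    directory = Path(directory)
    meta_path = directory / _META_FILENAME
    if not meta_path.exists():
        raise FileNotFoundError(f"no session metadata at {meta_path}")
    meta = json.loads(meta_path.read_text())
    streams = {}
    for pos, info in meta["sensors"].items():
        streams[pos] = read_stream_csv(
            directory / f"{pos}.csv", pos, float(info["sampling_rate_hz"])
        )
    annotations = read_annotations_csv(directory / _ANNOTATION_FILENAME)
    return Session(meta["participant_id"], meta["session_id"],
                   streams, annotations)


def write_cohort(sessions, root) -> None:
    """Write sessions under ``root/<participant>/<session>/``."""
    root = Path(root)
    for session in sessions:
        write_session(session,
                      root / session.participant_id / session.session_id)


def load_sessions(root) -> list:
    """Load every session directory (one containing meta.json) under root."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"no session directory at {root}")
    sessions = []
    for meta_path in sorted(root.glob("**/" + _META_FILENAME)):
        sessions.append(read_session(meta_path.parent))
    if not sessions:
        raise FileNotFoundError(f"no sessions found under {root}")
    return sessions


def load_public_dataset(root) -> list:
    """Adapter for a local export of the public SMM accelerometer corpus.

    Expected layout (one directory per recording)::

        root/
          study1/participant1/session1/{left_wrist,right_wrist,torso}.csv
          study1/participant1/session1/annotations.csv
          study2/...

    Study 1 recordings are read at 60 Hz, Study 2 at 90 Hz (the two sensor
    generations used in the corpus).  The released archive does not ship in
    this exact layout; convert it once with any tool of your choice.  This
    loader is optional: nothing in the pipeline or test suite requires it.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset not found at {root}")
    rates = {"study1": 60.0, "study2": 90.0}
    sessions = []
    for study_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        rate = rates.get(study_dir.name.lower())
        if rate is None:
            continue
        for part_dir in sorted(p for p in study_dir.iterdir() if p.is_dir()):
            for sess_dir in sorted(p for p in part_dir.iterdir()
                                   if p.is_dir()):
                streams = {}
                for pos in SENSOR_POSITIONS:
                    csv = sess_dir / f"{pos}.csv"
                    if not csv.exists():
                        raise FileNotFoundError(
                            f"missing stream file {csv} "
                            f"(expected one CSV per sensor position)"
                        )
                    streams[pos] = read_stream_csv(csv, pos, rate)
                ann_path = sess_dir / _ANNOTATION_FILENAME
                if not ann_path.exists():
                    raise FileNotFoundError(
                        f"missing annotation file {ann_path}"
                    )
                annotations = read_annotations_csv(ann_path)
                sessions.append(Session(
                    participant_id=part_dir.name,
                    session_id=f"{study_dir.name}_{sess_dir.name}",
                    streams=streams,
                    annotations=annotations,
                ))
    if not sessions:
        raise FileNotFoundError(
            f"dataset not found: no study*/participant*/session* "
            f"directories under {root}"
        )
    return sessions


# ---------------------------------------------------------------------------
# Feature tables and results


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def save_json(obj, path) -> None:
    """Write results as deterministic (sorted-key) JSON."""
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default)
        + "\n"
    )
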