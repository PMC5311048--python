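"""Sliding-window segmentation and per-window feature assembly.

Streams are cut into fixed-length overlapping windows (default 1 s with
87 % overlap), each window is assigned a ground-truth label from the
annotation track, and the nine RQA measures are computed per sensor,
giving d = 9 features per sensor (27 for the three-sensor array).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_streams import UNKNOWN, Session, ValidationError
from .recurrence import MEASURES, RQAConfig, window_features

#: Identity columns preceding the feature columns in every feature table.
ID_COLUMNS = ("participant", "session", "window", "start_s", "label")


@dataclass(frozen=True)
class SegmentationConfig:
    """Window length, overlap and labeling rule for segmentation.

    ``overlap_fraction`` is converted to a whole-sample step,
    ``step = round((1 - overlap) * N)`` with ``N = round(T * rate)``;
    at 60 Hz and 87 % this gives an 8-sample step (86.7 % actual
    overlap).
    """

    window_length_s: float = 1.0
    overlap_fraction: float = 0.87
    label_rule: str = "majority"

    def __post_init__(self) -> None:
        if not self.window_length_s > 0:
            raise ValidationError("window_length_s must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValidationError("overlap_fraction must be in [0, 1)")
        if self.label_rule not in ("majority", "center"):
            raise ValidationError("label_rule must be 'majority' or 'center'")

    def window_samples(self, sampling_rate_hz: float) -> int:
        n = int(round(self.window_length_s * sampling_rate_hz))
        if n < 2:
            raise ValidationError(
                f"window of {self.window_length_s} s at "
                f"{sampling_rate_hz} Hz has fewer than 2 samples"
            )
        return n

    def step_samples(self, sampling_rate_hz: float) -> int:
        step = int(round((1.0 - self.overlap_fraction)
                         * self.window_samples(sampling_rate_hz)))
        if step < 1:
            raise ValidationError(
                "overlap too large: step would be below one sample"
            )
        return step


@dataclass
class Window:
    """One fixed-length multi-sensor excerpt with its ground-truth label."""

    participant_id: str
    session_id: str
    window_index: int
    start_s: float
    duration_s: float
    trajectories: dict
    label: str


def label_interval(start_s: float, end_s: float, annotations,
                   rule: str = "majority") -> str:
    """Label covering [start_s, end_s) under the given rule.

    majority: the label (including implicit unknown time) covering the
    largest fraction of the window wins; any tie goes to unknown.
    center: the label of the interval containing the window midpoint.
    """
    if rule == "center":
        return annotations.label_at((start_s + end_s) / 2.0)
    cov = annotations.coverage(start_s, end_s)
    cov[UNKNOWN] = cov.get(UNKNOWN, 0.0) + (end_s - start_s) - sum(cov.values())
    best = max(cov.values())
    winners = [lab for lab, c in cov.items() if c >= best - 1e-12]
    return winners[0] if len(winners) == 1 else UNKNOWN


def label_window(window: Window, annotations,
                 rule: str = "majority") -> str:
    return label_interval(window.start_s, window.start_s + window.duration_s,
                          annotations, rule)


def segment_session(session: Session, config: SegmentationConfig,
                    sensors=None) -> list:
    """Cut one session into labeled overlapping windows.

    Windows start at multiples of the step and must lie fully inside all
    requested streams; the common clock of the first requested sensor
    defines the step in seconds.  A stream shorter than one window yields
    an empty list with a warning.
    """
    sensors = tuple(sensors) if sensors is not None else tuple(session.streams)
    for sensor in sensors:
        if sensor not in session.streams:
            raise ValueError(
                f"session {session.participant_id}/{session.session_id} "
                f"has no stream for sensor {sensor!r}"
            )
    streams = {s: session.streams[s] for s in sensors}
    ref = streams[sensors[0]]
    step_s = config.step_samples(ref.sampling_rate_hz) / ref.sampling_rate_hz
    t0 = max(s.start_s for s in streams.values())
    n_per_sensor = {s: config.window_samples(st.sampling_rate_hz)
                    for s, st in streams.items()}

    windows = []
    k = 0
    while True:
        start_s = t0 + k * step_s
        trajectories = {}
        for sensor, stream in streams.items():
            i0 = int(round((start_s - stream.start_s)
                           * stream.sampling_rate_hz))
            n = n_per_sensor[sensor]
            if i0 < 0 or i0 + n > stream.n_samples:
                trajectories = None
                break
            trajectories[sensor] = stream.xyz[i0:i0 + n]
        if trajectories is None:
            break
        window = Window(
            participant_id=session.participant_id,
            session_id=session.session_id,
            window_index=k,
            start_s=start_s,
            duration_s=config.window_length_s,
            trajectories=trajectories,
            label=UNKNOWN,
        )
        window.label = label_window(window, session.annotations,
                                    config.label_rule)
        windows.append(window)
        k += 1

    if not windows:
        warnings.warn(
            f"session {session.participant_id}/{session.session_id} is "
            f"shorter than one window; no windows produced",
            stacklevel=2,
        )
    return windows


def feature_names(sensors) -> list:
    """Sensor-major feature column names, nine RQA measures per sensor."""
    return [f"{sensor}.{measure}" for sensor in sensors
            for measure in MEASURES]


def feature_columns(table: pd.DataFrame) -> list:
    """The feature columns of a table (everything beyond identity/flags)."""
    skip = set(ID_COLUMNS)
    return [c for c in table.columns
            if c not in skip and not c.startswith("_")]


def feature_table_from_windows(windows, sensors,
                               rqa_config: RQAConfig) -> pd.DataFrame:
    """One feature row per window; columns are sensor-major RQA measures."""
    sensors = tuple(sensors)
    cols = feature_names(sensors)
    values = np.empty((len(windows), len(cols)))
    ids = []
    for i, window in enumerate(windows):
        feats = window_features(window, rqa_config)
        values[i] = np.concatenate([feats[s].as_array() for s in sensors])
        ids.append((window.participant_id, window.session_id,
                    window.window_index, window.start_s, window.label))
    table = pd.DataFrame(ids, columns=list(ID_COLUMNS))
    table[cols] = values
    return table


def build_feature_table(sessions, sensors, seg_config: SegmentationConfig,
                        rqa_config: RQAConfig) -> pd.DataFrame:
    """Segment sessions and assemble the full windows-by-features table.

    Rows follow session order; d = 9 x len(sensors) feature columns.
    Deterministic given its inputs.
    """
    sensors = tuple(sensors)
    frames = []
    for session in sessions:
        windows = segment_session(session, seg_config, sensors)
        if windows:
            frames.append(feature_table_from_windows(windows, sensors,
                                                     rqa_config))
    if not frames:
        return pd.DataFrame(columns=list(ID_COLUMNS) + feature_names(sensors))
    return pd.concat(frames, ignore_index=True)
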