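"""Velocity/acceleration-threshold parsing of gaze samples into saccades and
fixations.

Gaze is sampled nominally at 1000 Hz.  Angular speed is computed from
central differences of the pixel positions, converting each axis's
displacement to degrees with its own calibration before combining them as a
Euclidean angular speed; acceleration is the (central-difference)
derivative of speed.  No smoothing is applied.

A sample is saccadic when its speed exceeds the velocity threshold (default
30 deg/s) or |acceleration| exceeds the acceleration threshold (default
8000 deg/s^2); a saccade runs from the first suprathreshold sample to the
first subsequent sample at which both measures are back below threshold.
Fixations are the maximal inter-saccadic intervals, including the leading
and trailing intervals.  Runs of invalid samples (blinks / track loss)
split events and belong to neither class.  Event spans are contiguous:
each event ends where the next begins, so fixation + saccade + invalid
durations sum exactly to the trace duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import DisplayConfig, px_to_deg

GAZE_COLUMNS = ("t_ms", "x_px", "y_px", "valid")


@dataclass(frozen=True)
class GazeSample:
    t_ms: int
    x_px: float
    y_px: float
    valid: bool = True


@dataclass(frozen=True)
class EventParams:
    """Detection thresholds.  ``motion_thresh_deg`` vetoes saccades whose
    amplitude is below it (0.0 disables the veto); ``min_fixation_ms``
    merges shorter fixations into the preceding saccade (0 disables)."""

    velocity_thresh_deg_s: float = 30.0
    accel_thresh_deg_s2: float = 8000.0
    motion_thresh_deg: float = 0.0
    min_fixation_ms: int = 0

    def __post_init__(self) -> None:
        if (
            self.velocity_thresh_deg_s < 0
            or self.accel_thresh_deg_s2 < 0
            or self.motion_thresh_deg < 0
            or self.min_fixation_ms < 0
        ):
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class FixationEvent:
    onset_ms: float
    offset_ms: float
    centroid_xy: tuple[float, float]

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    amplitude_deg: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def as_gaze_frame(samples) -> pd.DataFrame:
    """Normalize a list of :class:`GazeSample` or a DataFrame to the canonical
    gaze-frame layout; enforces strictly increasing timestamps."""
    if isinstance(samples, pd.DataFrame):
        df = samples.loc[:, list(GAZE_COLUMNS)].reset_index(drop=True)
    else:
        df = pd.DataFrame(
            [(s.t_ms, s.x_px, s.y_px, s.valid) for s in samples],
            columns=list(GAZE_COLUMNS),
        )
    t = df["t_ms"].to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("gaze samples must be strictly increasing in t_ms")
    return df


def compute_kinematics(
    samples, cfg: DisplayConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample angular speed (deg/s) and acceleration (deg/s^2).

    Central differences over +/-1 sample; one-sided differences at the
    endpoints.  Requires at least 3 samples.
    """
    df = as_gaze_frame(samples)
    if len(df) < 3:
        raise ValueError("kinematics require at least 3 samples")
    t_s = df["t_ms"].to_numpy(float) / 1000.0
    vx = _signed_deg_rate(df["x_px"].to_numpy(float), t_s, "horizontal", cfg)
    vy = _signed_deg_rate(df["y_px"].to_numpy(float), t_s, "vertical", cfg)
    speed = np.hypot(vx, vy)
    accel = np.gradient(speed, t_s)
    return speed, accel


def _signed_deg_rate(pos: np.ndarray, t_s: np.ndarray, axis: str, cfg) -> np.ndarray:
    # per-sample central-difference displacement (px) and time step (s); the
    # displacement is converted to degrees at this small scale, where the
    # tangent calibration is effectively linear
    dpos = np.gradient(pos)
    dt = np.gradient(t_s)
    return np.sign(dpos) * px_to_deg(np.abs(dpos), axis, cfg) / dt


def detect_events(
    samples,
    params: EventParams | None = None,
    cfg: DisplayConfig | None = None,
) -> tuple[list[SaccadeEvent], list[FixationEvent]]:
    """Parse a gaze trace into (saccades, fixations).

    Invalid-sample runs split events; an all-invalid trace yields empty
    lists and a warning.  Valid runs too short for kinematics (< 3 samples)
    are classed as fixation.
    """
    params = params or EventParams()
    cfg = cfg or DisplayConfig.default()
    df = as_gaze_frame(samples)
    n = len(df)
    if n == 0:
        raise ValueError("empty gaze trace")
    valid = df["valid"].to_numpy(bool)
    if not valid.any():
        warnings.warn("all samples invalid; no events detected", stacklevel=2)
        return [], []

    # label per sample: 0 fixation, 1 saccade, 2 invalid
    labels = np.full(n, 2, dtype=int)
    for start, stop in _runs(valid):
        seg = df.iloc[start:stop]
        if stop - start < 3:
            labels[start:stop] = 0
            continue
        speed, accel = compute_kinematics(seg, cfg)
        sacc = (speed > params.velocity_thresh_deg_s) | (
            np.abs(accel) > params.accel_thresh_deg_s2
        )
        labels[start:stop] = np.where(sacc, 1, 0)

    t = df["t_ms"].to_numpy(float)
    x = df["x_px"].to_numpy(float)
    y = df["y_px"].to_numpy(float)

    segments = []  # (label, i0, i1, onset, offset) with offset = next onset
    for i0, i1 in _runs_of_labels(labels):
        onset = t[i0]
        offset = t[i1] if i1 < n else t[n - 1]
        if offset > onset or (i0 == 0 and i1 >= n and n == 1):
            segments.append((labels[i0], i0, i1, onset, offset))

    segments = _apply_vetoes(segments, params, x, y, cfg)

    saccades: list[SaccadeEvent] = []
    fixations: list[FixationEvent] = []
    for label, i0, i1, onset, offset in segments:
        if offset <= onset:
            continue
        if label == 0:
            sl = slice(i0, min(i1, n))
            fixations.append(
                FixationEvent(
                    onset_ms=onset,
                    offset_ms=offset,
                    centroid_xy=(float(np.mean(x[sl])), float(np.mean(y[sl]))),
                )
            )
        elif label == 1:
            j = min(i1, n) - 1
            saccades.append(
                SaccadeEvent(
                    onset_ms=onset,
                    offset_ms=offset,
                    start_xy=(float(x[i0]), float(y[i0])),
                    end_xy=(float(x[j]), float(y[j])),
                    amplitude_deg=_amplitude_deg(x[i0], y[i0], x[j], y[j], cfg),
                )
            )
    return saccades, fixations


def _amplitude_deg(x0, y0, x1, y1, cfg) -> float:
    return float(
        np.hypot(
            px_to_deg(abs(x1 - x0), "horizontal", cfg),
            px_to_deg(abs(y1 - y0), "vertical", cfg),
        )
    )


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _runs_of_labels(labels: np.ndarray):
    """(start, stop) pairs of maximal constant-label runs, in order."""
    n = len(labels)
    bounds = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], bounds))
    stops = np.concatenate((bounds, [n]))
    return list(zip(starts, stops))


def _apply_vetoes(segments, params: EventParams, x, y, cfg):
    """Optional post-passes: amplitude veto (motion threshold) relabels
    sub-threshold saccades as fixation; minimum fixation duration merges
    short fixations into the preceding saccade."""
    out = list(segments)
    if params.motion_thresh_deg > 0:
        relabeled = []
        for label, i0, i1, onset, offset in out:
            if label == 1:
                j = min(i1, len(x)) - 1
                if _amplitude_deg(x[i0], y[i0], x[j], y[j], cfg) < params.motion_thresh_deg:
                    label = 0
            relabeled.append((label, i0, i1, onset, offset))
        out = _merge_adjacent(relabeled)
    if params.min_fixation_ms > 0:
        merged = []
        for seg in out:
            label, i0, i1, onset, offset = seg
            if (
                label == 0
                and offset - onset < params.min_fixation_ms
                and merged
                and merged[-1][0] == 1
            ):
                pl, pi0, pi1, ponset, _ = merged[-1]
                merged[-1] = (pl, pi0, i1, ponset, offset)
            else:
                merged.append(seg)
        out = merged
    return out


def _merge_adjacent(segments):
    merged = []
    for seg in segments:
        if merged and merged[-1][0] == seg[0] and merged[-1][3 + 1] == seg[3]:
            label, i0, _, onset, _ = merged[-1]
            merged[-1] = (label, i0, seg[2], onset, seg[4])
        else:
            merged.append(seg)
    return merged


def events_to_frame(saccades, fixations) -> pd.DataFrame:
    """One row per event: type, onset, offset, duration, centroid/amplitude."""
    rows = []
    for f in fixations:
        rows.append(
            dict(
                type="fixation",
                onset_ms=f.onset_ms,
                offset_ms=f.offset_ms,
                duration_ms=f.duration_ms,
                x=f.centroid_xy[0],
                y=f.centroid_xy[1],
                amplitude_deg=np.nan,
            )
        )
    for s in saccades:
        rows.append(
            dict(
                type="saccade",
                onset_ms=s.onset_ms,
                offset_ms=s.offset_ms,
                duration_ms=s.duration_ms,
                x=s.end_xy[0],
                y=s.end_xy[1],
                amplitude_deg=s.amplitude_deg,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["type", "onset_ms", "offset_ms", "duration_ms", "x", "y", "amplitude_deg"],
    )
    return df.sort_values("onset_ms", kind="stable").reset_index(drop=True)
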