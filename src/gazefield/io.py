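"""Readers and writers for the pipeline's interchange formats.

CSV is the canonical interchange: gaze samples (t_ms, x_px, y_px, valid,
optionally trial), detected events, trial logs and statistical tables all
travel as plain CSV with a one-line ``# gazefield-schema: <name> v1``
header comment.  ROI maps are JSON; stimuli are 8-bit grayscale PNG; the
run configuration is YAML with keys named exactly after the dataclass
fields.  A minimal EyeLink-ASC-style text dialect is supported read-only:
sample lines ``<t> <x> <y> <pupil>`` (``.`` marks track loss) and message
lines ``MSG <t> <text>``, where a message whose text starts with
``TRIALID`` opens a new trial; all other lines are ignored.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .events import EventParams, GAZE_COLUMNS, as_gaze_frame
from .geometry import APERTURE_DIAMETER_PX, DisplayConfig, StimulusImage, calibrate_pitch
from .roi import ROIMap

SCHEMA_PREFIX = "# gazefield-schema:"


def _write_csv(df: pd.DataFrame, path, schema: str) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"{SCHEMA_PREFIX} {schema} v1\n")
        df.to_csv(fh, index=False)


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        skip = 1 if first.startswith("#") else 0
    return pd.read_csv(path, skiprows=skip)


def write_gaze(path, samples, trial: int | None = None) -> None:
    """Write one trial's gaze samples (or a frame with a ``trial`` column)."""
    df = samples if isinstance(samples, pd.DataFrame) else as_gaze_frame(samples)
    df = df.copy()
    if trial is not None and "trial" not in df.columns:
        df.insert(0, "trial", trial)
    _write_csv(df, path, "gaze")


def read_gaze(path, dialect: str = "csv") -> dict[int, pd.DataFrame]:
    """Read gaze samples grouped by trial.

    Returns an ordered mapping trial id -> gaze frame.  A CSV without a
    ``trial`` column is a single trial 0.  Duplicate or non-increasing
    timestamps raise with the offending line; invalid samples are flagged
    (``valid=False``), never dropped.
    """
    if dialect == "csv":
        df = _read_csv(path)
        missing = {"t_ms", "x_px", "y_px"} - set(df.columns)
        if missing:
            raise ValueError(f"gaze CSV missing columns {sorted(missing)}")
        if "valid" not in df.columns:
            df["valid"] = True
        trials = (
            {int(k): g.drop(columns="trial") for k, g in df.groupby("trial", sort=False)}
            if "trial" in df.columns
            else {0: df}
        )
        out = {}
        for k, g in trials.items():
            t = g["t_ms"].to_numpy()
            bad = np.flatnonzero(np.diff(t) <= 0)
            if bad.size:
                raise ValueError(
                    f"non-increasing timestamp in trial {k} at row {int(bad[0]) + 1}"
                )
            out[k] = g.loc[:, list(GAZE_COLUMNS)].reset_index(drop=True)
        return out
    if dialect == "asc_min":
        return _read_asc(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_asc(path) -> dict[int, pd.DataFrame]:
    trials: dict[int, list] = {}
    current: int | None = None
    n_anon = 0
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "MSG":
                if len(parts) >= 3 and parts[2].startswith("TRIALID"):
                    token = parts[3] if len(parts) > 3 else parts[2][7:] or str(n_anon)
                    try:
                        current = int(token)
                    except ValueError:
                        current = n_anon
                    n_anon += 1
                    trials.setdefault(current, [])
                continue
            try:
                t = int(float(parts[0]))
            except ValueError:
                continue  # non-sample line, ignored
            if current is None:
                current = n_anon
                n_anon += 1
                trials.setdefault(current, [])
            try:
                x, y = float(parts[1]), float(parts[2])
                valid = True
            except (ValueError, IndexError):
                x, y, valid = np.nan, np.nan, False
            if trials[current] and t <= trials[current][-1][0]:
                raise ValueError(f"non-increasing timestamp at line {lineno}")
            trials[current].append((t, x, y, valid))
    return {
        k: pd.DataFrame(v, columns=list(GAZE_COLUMNS)) for k, v in trials.items()
    }


def write_events(path, events_frame: pd.DataFrame) -> None:
    _write_csv(events_frame, path, "events")


def write_trial_log(path, trials: pd.DataFrame) -> None:
    _write_csv(trials, path, "trials")


def read_trial_log(path) -> pd.DataFrame:
    return _read_csv(path)


def write_roi_map(path, m: ROIMap) -> None:
    Path(path).write_text(json.dumps(m.to_dict(), indent=1))


def read_roi_map(path) -> ROIMap:
    return ROIMap.from_dict(json.loads(Path(path).read_text()))


def write_stimulus_png(path, img: StimulusImage) -> None:
    from PIL import Image

    Image.fromarray(np.asarray(img.pixels, dtype=np.uint8), mode="L").save(path)


def read_stimulus_png(path, frame_origin_xy=(0, 0)) -> StimulusImage:
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return StimulusImage(pixels=arr, frame_origin_xy=tuple(frame_origin_xy))


@dataclass
class RunConfig:
    """Run configuration; the defaults are the experiment's constants."""

    screen_width_px: int = 1024
    screen_height_px: int = 768
    viewing_distance_cm: float = 82.0
    refresh_hz: float = 85.0
    background_gray: int = 128
    aperture_diameter_px: float = APERTURE_DIAMETER_PX
    aperture_angle_h_deg: float = 5.81
    aperture_angle_v_deg: float = 5.17
    velocity_thresh_deg_s: float = 30.0
    accel_thresh_deg_s2: float = 8000.0
    motion_thresh_deg: float = 0.0
    min_fixation_ms: int = 0
    study_duration_ms: int = 3000
    drift_check_max_deg: float = 2.0  # recalibration rule, recorded only
    rt_trim_sd: float = 3.0
    n_bins: int = 5
    window_ms: int = 100
    n_windows: int = 30
    seed: int = 0
    n_experts: int = 15
    n_novices: int = 15

    def display(self) -> DisplayConfig:
        ph, pv = calibrate_pitch(
            self.aperture_angle_h_deg,
            self.aperture_angle_v_deg,
            self.aperture_diameter_px,
            self.viewing_distance_cm,
        )
        return DisplayConfig(
            screen_width_px=self.screen_width_px,
            screen_height_px=self.screen_height_px,
            viewing_distance_cm=self.viewing_distance_cm,
            pixel_pitch_h_cm=ph,
            pixel_pitch_v_cm=pv,
            refresh_hz=self.refresh_hz,
            background_gray=self.background_gray,
        )

    def event_params(self) -> EventParams:
        return EventParams(
            velocity_thresh_deg_s=self.velocity_thresh_deg_s,
            accel_thresh_deg_s2=self.accel_thresh_deg_s2,
            motion_thresh_deg=self.motion_thresh_deg,
            min_fixation_ms=self.min_fixation_ms,
        )

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def overrides(self) -> dict:
        """Fields differing from the defaults (echoed to the log)."""
        ref = RunConfig()
        return {
            k: v for k, v in asdict(self).items() if getattr(ref, k) != v
        }


@dataclass
class RunManifest:
    """Provenance record written next to every stage's outputs."""

    config_hash: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage: str = ""
    version: str = "0.1.0"
    timestamp: float = field(default_factory=time.time)

    @classmethod
    def create(cls, config: RunConfig, stage: str, inputs: Mapping[str, Path] = ()) -> "RunManifest":
        cfg_hash = hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest()
        sums = {
            str(name): hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in dict(inputs).items()
        }
        return cls(config_hash=cfg_hash, input_checksums=sums, stage=stage)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))
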