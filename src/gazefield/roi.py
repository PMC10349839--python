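"""Region-of-interest attribution of fixations and proportion looking time.

Each stimulus carries five hand-drawn (here: programmatically drawn)
polygonal regions -- head, wings, body, tail, feet.  A fixation is
attributed to the region containing its centroid (boundary points count as
inside); fixations landing outside every region are off-bird and excluded
from both numerator and denominator of the looking-time proportions.
Where hand-drawn polygons overlap, attribution follows the fixed priority
head > wings > body > tail > feet.

Proportions are reported overall (per-ROI fixated time over total on-bird
time) and as a time course in 100-ms windows relative to stimulus onset
(30 windows over the 3000-ms study display); fixation time spanning a
window boundary is split proportionally, so the windowed analysis conserves
the overall summary exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .events import FixationEvent

ROI_LABELS = ("head", "wings", "body", "tail", "feet")
OFF_BIRD = "off_bird"
UNDEFINED = float("nan")  # marker for windows with no on-bird time
DEFAULT_WINDOW_MS = 100
DEFAULT_N_WINDOWS = 30


@dataclass
class ROIMap:
    """Five labeled polygons for one stimulus, in image-frame pixel
    coordinates (0-based, origin at the frame's top-left corner).

    ``frame_origin_xy`` locates the image frame on the screen so that
    fixation centroids in screen coordinates can be transformed in.
    """

    image_id: str
    polygons: dict[str, Sequence[tuple[float, float]]]
    frame_origin_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        missing = set(ROI_LABELS) - set(self.polygons)
        extra = set(self.polygons) - set(ROI_LABELS)
        if missing or extra:
            raise ValueError(
                f"ROI map must have exactly the labels {ROI_LABELS}; "
                f"missing={sorted(missing)}, extra={sorted(extra)}"
            )
        self._shapes = {}
        for label in ROI_LABELS:
            poly = Polygon(self.polygons[label])
            if not poly.is_valid or poly.area <= 0:
                raise ValueError(f"polygon for {label!r} is not simple/non-degenerate")
            self._shapes[label] = poly

    def shape(self, label: str) -> Polygon:
        return self._shapes[label]

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "frame_origin_xy": list(self.frame_origin_xy),
            "rois": {k: [list(map(float, v)) for v in self.polygons[k]] for k in ROI_LABELS},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ROIMap":
        return cls(
            image_id=d["image_id"],
            polygons={k: [tuple(p) for p in v] for k, v in d["rois"].items()},
            frame_origin_xy=tuple(d.get("frame_origin_xy", (0.0, 0.0))),
        )


def assign_fixation(fixation: FixationEvent | tuple[float, float], m: ROIMap) -> str:
    """Label of the ROI containing the fixation centroid, else ``OFF_BIRD``.

    The centroid is taken in screen coordinates and shifted by the map's
    frame origin.  Boundary points count as inside; overlaps resolve by the
    priority order of ``ROI_LABELS``.
    """
    if m is None:
        raise ValueError("missing ROI map")
    if isinstance(fixation, FixationEvent):
        sx, sy = fixation.centroid_xy
    else:
        sx, sy = fixation
    ox, oy = m.frame_origin_xy
    pt = Point(sx - ox, sy - oy)
    for label in ROI_LABELS:
        if m.shape(label).covers(pt):  # covers() includes the boundary
            return label
    return OFF_BIRD


@dataclass(frozen=True)
class LookingSummary:
    proportions: dict[str, float]
    total_on_bird_ms: float


def proportion_looking(
    fixations: Iterable[FixationEvent], m: ROIMap
) -> LookingSummary:
    """Per-ROI fixated time divided by total on-bird fixated time.

    Zero on-bird time yields NaN proportions (undefined, not zero).
    """
    dur = {label: 0.0 for label in ROI_LABELS}
    for f in fixations:
        label = assign_fixation(f, m)
        if label != OFF_BIRD:
            dur[label] += f.duration_ms
    total = sum(dur.values())
    if total <= 0:
        return LookingSummary({k: UNDEFINED for k in ROI_LABELS}, 0.0)
    return LookingSummary({k: dur[k] / total for k in ROI_LABELS}, total)


@dataclass(frozen=True)
class TimeCourse:
    """Per-window ROI proportions: ``values[w, i]`` is window ``w``'s
    proportion for ``ROI_LABELS[i]`` (NaN rows mark windows with no on-bird
    time).  ``on_bird_ms[w]`` is the on-bird fixated time in window ``w``."""

    window_ms: int
    values: np.ndarray  # (n_windows, len(ROI_LABELS))
    on_bird_ms: np.ndarray  # (n_windows,)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def series(self, label: str) -> np.ndarray:
        return self.values[:, ROI_LABELS.index(label)]


def time_course(
    fixations: Iterable[FixationEvent],
    m: ROIMap,
    window_ms: int = DEFAULT_WINDOW_MS,
    n_windows: int = DEFAULT_N_WINDOWS,
) -> TimeCourse:
    """ROI proportions in consecutive windows relative to stimulus onset.

    Fixation onsets/offsets must already be expressed relative to stimulus
    onset (ms).  Duration spanning a window boundary is split
    proportionally between the windows.
    """
    acc = np.zeros((n_windows, len(ROI_LABELS)))
    for f in fixations:
        label = assign_fixation(f, m)
        if label == OFF_BIRD:
            continue
        li = ROI_LABELS.index(label)
        lo, hi = f.onset_ms, f.offset_ms
        w0 = max(int(math.floor(lo / window_ms)), 0)
        w1 = min(int(math.ceil(hi / window_ms)), n_windows)
        for w in range(w0, w1):
            overlap = min(hi, (w + 1) * window_ms) - max(lo, w * window_ms)
            if overlap > 0:
                acc[w, li] += overlap
    on_bird = acc.sum(axis=1)
    values = np.full_like(acc, UNDEFINED)
    defined = on_bird > 0
    values[defined] = acc[defined] / on_bird[defined, None]
    return TimeCourse(window_ms=window_ms, values=values, on_bird_ms=on_bird)


def timecourse_correlation(a: TimeCourse, b: TimeCourse, label: str) -> float:
    """Pearson correlation of two time courses for one ROI, over the windows
    defined in both.  Requires matching window grids and >= 3 common
    defined windows."""
    from scipy.stats import pearsonr

    if a.window_ms != b.window_ms or a.n_windows != b.n_windows:
        raise ValueError("time courses must share the same window grid")
    xa, xb = a.series(label), b.series(label)
    ok = ~np.isnan(xa) & ~np.isnan(xb)
    if ok.sum() < 3:
        raise ValueError("need at least 3 windows defined in both time courses")
    return float(pearsonr(xa[ok], xb[ok])[0])
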