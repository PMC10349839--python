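"""Pixel/degree calibration and gaze-contingent masking operators.

The display model is a flat screen viewed from a fixed distance.  A pixel
extent ``n`` along one axis subtends the visual angle

    theta(n) = 2 * atan(n * pitch / (2 * distance))

where ``pitch`` is the physical pixel pitch (cm/px) along that axis.  The
pitch is calibrated from a known angle/extent pair rather than from monitor
dimensions, so the horizontal and vertical pitches may differ (the same
aperture diameter subtends different angles on the two axes).

Screen coordinates are 0-based pixels, origin at the top-left, x rightward,
y downward.  Apertures are hard-edged circles in pixel space; a pixel is
inside the aperture when the distance from its center to the gaze position
is at most the radius (ties count as inside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

Axis = Literal["horizontal", "vertical"]

#: Calibration constants: the aperture of 190 px subtends 5.81 deg
#: horizontally and 5.17 deg vertically at 82 cm.
APERTURE_DIAMETER_PX = 190.0
APERTURE_ANGLE_H_DEG = 5.81
APERTURE_ANGLE_V_DEG = 5.17
VIEWING_DISTANCE_CM = 82.0


def calibrate_pitch(
    angle_h_deg: float,
    angle_v_deg: float,
    extent_px: float,
    distance_cm: float,
) -> tuple[float, float]:
    """Derive (horizontal, vertical) pixel pitch in cm/px from an angle/extent pair.

    Solves ``2*atan(extent*pitch/(2*distance)) == angle`` for ``pitch`` on
    each axis, so that :func:`px_to_deg` of ``extent_px`` reproduces the
    given angles exactly.
    """
    for name, v in (
        ("angle_h_deg", angle_h_deg),
        ("angle_v_deg", angle_v_deg),
        ("extent_px", extent_px),
        ("distance_cm", distance_cm),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v!r}")
    if angle_h_deg >= 90 or angle_v_deg >= 90:
        raise ValueError("calibration angles must be < 90 degrees")

    def pitch(angle: float) -> float:
        return 2.0 * distance_cm * math.tan(math.radians(angle) / 2.0) / extent_px

    return pitch(angle_h_deg), pitch(angle_v_deg)


@dataclass(frozen=True)
class DisplayConfig:
    """Screen geometry and calibration.

    ``pixel_pitch_h_cm``/``pixel_pitch_v_cm`` are physical pixel sizes; they
    may differ.  ``background_gray`` is the luminance (0-255) used for the
    masked region and the blank background.
    """

    screen_width_px: int = 1024
    screen_height_px: int = 768
    viewing_distance_cm: float = VIEWING_DISTANCE_CM
    pixel_pitch_h_cm: float = 0.0
    pixel_pitch_v_cm: float = 0.0
    refresh_hz: float = 85.0
    background_gray: int = 128

    def __post_init__(self) -> None:
        if self.pixel_pitch_h_cm <= 0 or self.pixel_pitch_v_cm <= 0:
            raise ValueError("pixel pitches must be strictly positive")
        if not 0 <= self.background_gray <= 255:
            raise ValueError("background_gray must be in 0..255")

    @classmethod
    def default(cls, **overrides) -> "DisplayConfig":
        """Standard 1024x768 display at 82 cm, pitch calibrated from the
        190-px aperture's 5.81 deg (H) / 5.17 deg (V) subtense."""
        ph, pv = calibrate_pitch(
            APERTURE_ANGLE_H_DEG,
            APERTURE_ANGLE_V_DEG,
            APERTURE_DIAMETER_PX,
            VIEWING_DISTANCE_CM,
        )
        kwargs = dict(pixel_pitch_h_cm=ph, pixel_pitch_v_cm=pv)
        kwargs.update(overrides)
        return cls(**kwargs)

    def _pitch(self, axis: Axis) -> float:
        if axis == "horizontal":
            return self.pixel_pitch_h_cm
        if axis == "vertical":
            return self.pixel_pitch_v_cm
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def px_to_deg(extent_px, axis: Axis, cfg: DisplayConfig):
    """Visual angle (degrees) subtended by a pixel extent along one axis.

    Accepts scalars or arrays; strictly increasing and concave in the extent.
    """
    pitch = cfg._pitch(axis)
    extent = np.asarray(extent_px, dtype=float)
    if np.any(extent < 0):
        raise ValueError("extent_px must be non-negative")
    deg = np.degrees(2.0 * np.arctan(extent * pitch / (2.0 * cfg.viewing_distance_cm)))
    return float(deg) if np.isscalar(extent_px) else deg


def deg_to_px(angle_deg, axis: Axis, cfg: DisplayConfig):
    """Inverse of :func:`px_to_deg` (round-trips to < 1e-9 px)."""
    pitch = cfg._pitch(axis)
    angle = np.asarray(angle_deg, dtype=float)
    if np.any(angle < 0) or np.any(angle >= 180):
        raise ValueError("angle_deg must be in [0, 180)")
    px = 2.0 * cfg.viewing_distance_cm * np.tan(np.radians(angle) / 2.0) / pitch
    return float(px) if np.isscalar(angle_deg) else px


@dataclass(frozen=True)
class Aperture:
    """Hard-edged circular window/mask, in screen pixels."""

    center_xy: tuple[float, float] = (0.0, 0.0)
    diameter_px: float = APERTURE_DIAMETER_PX

    def __post_init__(self) -> None:
        if not self.diameter_px > 0:
            raise ValueError("diameter_px must be positive")

    @property
    def radius_px(self) -> float:
        return self.diameter_px / 2.0

    def contains(self, x, y, center_xy: tuple[float, float] | None = None):
        """Membership test: distance(point, center) <= radius."""
        cx, cy = center_xy if center_xy is not None else self.center_xy
        return (np.asarray(x, float) - cx) ** 2 + (
            np.asarray(y, float) - cy
        ) ** 2 <= self.radius_px**2


STIMULUS_FRAME_PX = 450  # stimulus images are scaled into a 450x450 frame


@dataclass
class StimulusImage:
    """8-bit grayscale stimulus raster plus its top-left position on screen."""

    pixels: np.ndarray
    frame_origin_xy: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D luminance grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def centered(cls, pixels: np.ndarray, cfg: DisplayConfig) -> "StimulusImage":
        """Place the raster at the center of the screen."""
        h, w = np.asarray(pixels).shape
        ox = (cfg.screen_width_px - w) // 2
        oy = (cfg.screen_height_px - h) // 2
        return cls(pixels=pixels, frame_origin_xy=(ox, oy))


VIEWING_CONDITIONS = ("full", "central", "peripheral")


def aperture_mask(
    img: StimulusImage, gaze_xy: tuple[float, float], aperture: Aperture
) -> np.ndarray:
    """Boolean array: True where the pixel center lies inside the gaze-centered
    aperture.  Pixel (row i, col j) has its center at screen point
    (origin_x + j, origin_y + i)."""
    h, w = img.shape
    ox, oy = img.frame_origin_xy
    gx, gy = gaze_xy
    ys = np.arange(h, dtype=float)[:, None] + oy - gy
    xs = np.arange(w, dtype=float)[None, :] + ox - gx
    return xs**2 + ys**2 <= aperture.radius_px**2


def apply_viewing_condition(
    img: StimulusImage,
    gaze_xy: tuple[float, float],
    condition: str,
    aperture: Aperture,
    cfg: DisplayConfig,
) -> StimulusImage:
    """Render one viewing condition at a gaze position.

    ``full`` returns the image unchanged; ``central`` shows only the pixels
    inside the gaze-centered aperture (periphery replaced by background
    gray); ``peripheral`` shows only the pixels outside it.  For any pixel
    and gaze, exactly one of the central/peripheral renderings shows the
    original luminance.
    """
    gx, gy = gaze_xy
    if not (math.isfinite(gx) and math.isfinite(gy)):
        raise ValueError("gaze_xy must be finite")
    if condition not in VIEWING_CONDITIONS:
        raise ValueError(
            f"condition must be one of {VIEWING_CONDITIONS}, got {condition!r}"
        )
    if condition == "full":
        return StimulusImage(img.pixels.copy(), img.frame_origin_xy)
    inside = aperture_mask(img, gaze_xy, aperture)
    bg = np.array(cfg.background_gray, dtype=img.pixels.dtype)
    if condition == "central":
        out = np.where(inside, img.pixels, bg)
    else:  # peripheral
        out = np.where(inside, bg, img.pixels)
    return StimulusImage(out, img.frame_origin_xy)


def render_replay(
    img: StimulusImage,
    samples: Sequence,
    condition: str,
    aperture: Aperture,
    cfg: DisplayConfig,
) -> list[StimulusImage]:
    """Offline reconstruction of what the participant saw: one frame per gaze
    sample, each frame being :func:`apply_viewing_condition` at that sample's
    gaze position.  Display latency is treated as zero."""
    samples = list(samples)
    if not samples:
        raise ValueError("render_replay requires at least one gaze sample")
    times = [s.t_ms for s in samples]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("samples must be strictly increasing in t_ms")
    return [
        apply_viewing_condition(img, (s.x_px, s.y_px), condition, aperture, cfg)
        for s in samples
    ]
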