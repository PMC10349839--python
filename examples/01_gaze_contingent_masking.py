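"""Gaze-contingent masking: the central-view window and peripheral-view mask.

Builds a synthetic 450x450 grayscale stimulus centered on a 1024x768
display, then renders the three viewing conditions at a gaze position and
reports how much of the image survives each mask.
"""

import numpy as np

from gazefield import (
    Aperture,
    DisplayConfig,
    StimulusImage,
    apply_viewing_condition,
    px_to_deg,
)

cfg = DisplayConfig.default()
print(f"aperture: 190 px = {px_to_deg(190, 'horizontal', cfg):.2f} deg horizontally, "
      f"{px_to_deg(190, 'vertical', cfg):.2f} deg vertically at "
      f"{cfg.viewing_distance_cm:.0f} cm")

# a luminance gradient so every pixel is distinguishable from the background
stim = np.tile(np.linspace(0, 255, 450, dtype=np.uint8), (450, 1))
stim[stim == cfg.background_gray] = 0
img = StimulusImage.centered(stim, cfg)
gaze = (cfg.screen_width_px / 2, cfg.screen_height_px / 2)  # fixating the center

for condition in ("full", "central", "peripheral"):
    out = apply_viewing_condition(img, gaze, condition, Aperture(), cfg)
    visible = int((out.pixels == stim).sum())
    print(f"{condition:>10}-view: {visible:6d} of {stim.size} pixels visible "
          f"({visible / stim.size:.1%})")

# The central and peripheral counts sum to the full count: the window and
# mask are exact complements of each other around the gaze position.
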