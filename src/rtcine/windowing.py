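"""Histogram-based auto-windowing for real-time image display.

Real-time and segmented cine images differ in their intensity
distribution, so a fixed display window gives unfair visual contrast.
The auto-window here adapts the window to each image's histogram:

* ``threshold_count = max(1, floor(total_pixels / 2500))``
* threshold signal intensity = the largest intensity value whose
  histogram count is at least ``threshold_count`` (sparse bright
  outliers are thereby excluded from the display range)
* ``window_width  = threshold_intensity - min_intensity``
* ``window_center = window_width / 2 + min_intensity``

Histogram granularity is one intensity unit on the stored integer
pixels.  If no intensity reaches the threshold count the image maximum
is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WindowSettings", "auto_window_type2", "apply_window"]


@dataclass
class WindowSettings:
    width: float
    center: float

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("window width must be >= 0")


def auto_window_type2(image: np.ndarray) -> WindowSettings:
    """Window width/center from the pixel-intensity histogram (see module doc)."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if not np.issubdtype(image.dtype, np.integer):
        raise ValueError("auto-windowing operates on integer intensity images")
    flat = image.ravel()
    lo = int(flat.min())
    threshold_count = max(1, flat.size // 2500)
    counts = np.bincount(flat - lo)  # bin per intensity unit, offset by lo
    qualifying = np.nonzero(counts >= threshold_count)[0]
    if qualifying.size:
        threshold_intensity = lo + int(qualifying[-1])
    else:
        threshold_intensity = int(flat.max())
    width = float(threshold_intensity - lo)
    return WindowSettings(width=width, center=width / 2.0 + lo)


def apply_window(image: np.ndarray, settings: WindowSettings) -> np.ndarray:
    """Map the window interval linearly onto 8-bit display values.

    ``[center - width/2, center + width/2]`` maps to [0, 255], values
    outside are clipped; a zero-width window gives uniform mid-gray.
    """
    image = np.asarray(image, dtype=float)
    if settings.width == 0:
        return np.full(image.shape, 128, dtype=np.uint8)
    lo = settings.center - settings.width / 2.0
    scaled = (image - lo) / settings.width
    return np.round(np.clip(scaled, 0.0, 1.0) * 255.0).astype(np.uint8)
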