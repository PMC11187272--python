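"""Color indicators: per-view channel means over the plant mask and the
blue/green, blue/red, green/red ratios.

Side-view values for a plant are the averages of the six side images; the
ratios are computed from the averaged means (not averaged per-view ratios).
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np

from .segmentation import PlantImage, PlantMask

COLOR_KEYS = ("R_mean", "G_mean", "B_mean", "ratio_BG", "ratio_BR", "ratio_GR")


def color_means(image: PlantImage, mask: PlantMask) -> Tuple[float, float, float]:
    """Mean R, G, B digital numbers over the foreground pixels."""
    if mask.empty or mask.foreground_count == 0:
        raise ValueError("color_means requires a non-empty mask")
    if mask.pixels.shape != image.pixels.shape[:2]:
        raise ValueError("mask shape does not match image")
    px = image.pixels[mask.pixels].astype(np.float64)
    r, g, b = px[:, 0].mean(), px[:, 1].mean(), px[:, 2].mean()
    return float(r), float(g), float(b)


def color_ratios(means: Sequence[float]) -> Tuple[float, float, float]:
    """Ratios B/G, B/R, G/R from (R, G, B) means."""
    r, g, b = means
    if r <= 0 or g <= 0:
        raise ValueError("color_ratios requires positive R and G means")
    return float(b / g), float(b / r), float(g / r)


def color_features(image: PlantImage, mask: PlantMask) -> Dict[str, float]:
    """The six per-view color indicators, keyed by :data:`COLOR_KEYS`."""
    r, g, b = color_means(image, mask)
    bg, br, gr = color_ratios((r, g, b))
    return {
        "R_mean": r,
        "G_mean": g,
        "B_mean": b,
        "ratio_BG": bg,
        "ratio_BR": br,
        "ratio_GR": gr,
    }


def average_side_views(per_view_means: Sequence[Sequence[float]]) -> Dict[str, float]:
    """Plant-level side color features from six per-view (R, G, B) means.

    The R, G, B means are averaged arithmetically across the six views and
    the three ratios are then computed from the averaged means.
    """
    if len(per_view_means) != 6:
        raise ValueError(f"expected exactly 6 side views, got {len(per_view_means)}")
    arr = np.asarray(per_view_means, dtype=np.float64)
    if arr.shape != (6, 3):
        raise ValueError("each side view must provide (R, G, B) means")
    r, g, b = arr.mean(axis=0)
    bg, br, gr = color_ratios((r, g, b))
    return {
        "R_mean": float(r),
        "G_mean": float(g),
        "B_mean": float(b),
        "ratio_BG": bg,
        "ratio_BR": br,
        "ratio_GR": gr,
    }
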