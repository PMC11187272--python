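"""Plant foreground segmentation.

The built-in method is an excess-green index (2G − R − B) threshold with an
Otsu split, followed by largest-connected-component selection and hole
filling.  It is a deliberately simple stand-in for a learned segmenter: the
stage contract (RGB view in, aligned binary mask out) is what downstream
feature extraction depends on, and an externally produced mask — e.g. from a
trained encoder–decoder network — can be passed through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

ViewTag = Literal["side_1", "side_2", "side_3", "side_4", "side_5", "side_6", "top"]

SIDE_VIEWS = ("side_1", "side_2", "side_3", "side_4", "side_5", "side_6")
ALL_VIEWS = SIDE_VIEWS + ("top",)


@dataclass
class PlantImage:
    """One RGB view of a single plant (H×W×3, uint8 DN in [0, 255])."""

    pixels: np.ndarray
    view: str = "side_1"
    sample_id: str = ""
    year: Optional[int] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("PlantImage requires an H×W×3 array")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError("PlantImage requires H, W >= 32")
        self.pixels = px


@dataclass
class PlantMask:
    """Binary foreground mask aligned with its source view.

    ``empty`` flags a segmentation that found no foreground; downstream
    stages must reject empty masks rather than divide by zero.
    """

    pixels: np.ndarray
    empty: bool = field(default=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("PlantMask requires a 2-D array")
        self.empty = bool(self.empty or self.pixels.sum() == 0)

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


def excess_green(pixels: np.ndarray) -> np.ndarray:
    """Excess-green index 2G − R − B, signed integer valued.

    Invariant to adding a constant DN to all three channels.
    """
    px = np.asarray(pixels).astype(np.int32)
    return 2 * px[..., 1] - px[..., 0] - px[..., 2]


def _largest_component(fg: np.ndarray) -> np.ndarray:
    # 4-connectivity: stable areas for downstream morphology
    lab = label(fg, connectivity=1)
    if lab.max() == 0:
        return np.zeros_like(fg, dtype=bool)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def segment_plant(
    image: PlantImage,
    method: str = "threshold",
    mask: Optional[np.ndarray] = None,
) -> PlantMask:
    """Segment the plant foreground from one RGB view.

    Parameters
    ----------
    image:
        The view to segment.
    method:
        ``"threshold"`` (excess-green + Otsu + largest component + hole
        fill) or ``"provided"`` (pass an external ``mask`` through).
    mask:
        Required for ``method="provided"``; returned unchanged.
    """
    if method == "provided":
        if mask is None:
            raise ValueError("method='provided' requires a mask")
        if mask.shape != image.pixels.shape[:2]:
            raise ValueError("provided mask shape does not match image")
        return PlantMask(np.asarray(mask) > 0)
    if method != "threshold":
        raise ValueError(f"unknown segmentation method: {method!r}")

    exg = excess_green(image.pixels)
    if exg.min() == exg.max():
        # uniform image: no contrast to split on
        return PlantMask(np.zeros(exg.shape, dtype=bool), empty=True)
    thresh = threshold_otsu(exg.astype(np.float64))
    fg = exg > thresh
    fg = _largest_component(fg)
    if not fg.any():
        return PlantMask(fg, empty=True)
    fg = ndimage.binary_fill_holes(fg)
    return PlantMask(fg)
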