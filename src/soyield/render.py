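"""Schematic single-plant view renderer.

The renderer composites overlapping elliptical "leaf" blobs around a stem on
a contrasting soil-like background, together with a white disk standing in
for the 30 cm reference board.  It is deliberately *not* photorealistic: its
job is to produce images whose true masks, projected areas and view
geometry are known exactly, so that segmentation and feature extraction can
be tested against ground truth.  Six side views are rendered as independent
±10% trait perturbations of one latent plant (so six-view averaging
demonstrably reduces variance) plus one top view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import disk, ellipse

from .morphology import ScaleRef
from .segmentation import SIDE_VIEWS, PlantImage, PlantMask

BACKGROUND_RGB = (120, 105, 95)
BOARD_RGB = (250, 250, 250)


@dataclass
class PlantLatent:
    """Latent traits of one rendered plant.

    area_px:      target projected foreground area per view (pixels)
    height_frac:  plant height as a fraction of the canvas height
    width_frac:   canopy width as a fraction of the canvas width
    greenness:    0..1, scales the green channel of the foliage
    granularity:  0..1, per-pixel texture noise amplitude
    """

    area_px: float
    height_frac: float = 0.7
    width_frac: float = 0.5
    greenness: float = 0.6
    granularity: float = 0.3

    def jittered(self, rng: np.random.Generator, amount: float = 0.1) -> "PlantLatent":
        j = lambda v: float(v * (1 + rng.uniform(-amount, amount)))
        return PlantLatent(
            area_px=j(self.area_px),
            height_frac=min(j(self.height_frac), 0.9),
            width_frac=min(j(self.width_frac), 0.9),
            greenness=float(np.clip(j(self.greenness), 0.05, 1.0)),
            granularity=float(np.clip(self.granularity, 0.0, 1.0)),
        )


@dataclass
class RenderedView:
    image: PlantImage
    true_mask: PlantMask
    target_area_px: float = 0.0


@dataclass
class RenderedPlant:
    views: Dict[str, RenderedView] = field(default_factory=dict)
    scale: ScaleRef | None = None


def _board_geometry(canvas: int) -> Tuple[int, int, int]:
    """Board disk (row, col, radius) in the top-left corner."""
    r = max(4, canvas // 10)
    return r + 2, r + 2, r


def _grow_blob_mask(
    canvas: int,
    target_area: float,
    rng: np.random.Generator,
    seed_region: np.ndarray,
    forbidden: np.ndarray,
    max_iter: int = 600,
) -> np.ndarray:
    """Grow a connected blob mask to within ±5% of the target area.

    Elliptical leaves are attached at random foreground pixels; the leaf
    size shrinks as the remaining deficit shrinks, so the loop converges
    inside the tolerance instead of overshooting.
    """
    m = seed_region & ~forbidden
    base = max(2.0, np.sqrt(target_area) / 6.0)
    for _ in range(max_iter):
        area = m.sum()
        deficit = target_area - area
        if deficit <= 0.02 * target_area:
            break
        anchors = np.argwhere(m)
        if len(anchors) == 0:
            break
        ar, ac = anchors[rng.integers(len(anchors))]
        semi = min(base, max(1.5, 0.9 * np.sqrt(deficit / np.pi)))
        rr_ax = semi * rng.uniform(0.6, 1.4)
        cc_ax = semi * rng.uniform(0.6, 1.4)
        ang = rng.uniform(0, np.pi)
        rr, cc = ellipse(ar, ac, rr_ax, cc_ax, shape=(canvas, canvas), rotation=ang)
        m[rr, cc] = True
        m &= ~forbidden
    return ndimage.binary_fill_holes(m)


def _colorize(
    mask: np.ndarray,
    board: Tuple[int, int, int],
    latent: PlantLatent,
    rng: np.random.Generator,
) -> np.ndarray:
    canvas = mask.shape[0]
    img = np.empty((canvas, canvas, 3), dtype=np.float64)
    img[...] = BACKGROUND_RGB
    img += rng.normal(0, 4, size=img.shape)

    br, bc, brad = board
    rr, cc = disk((br, bc), brad, shape=(canvas, canvas))
    img[rr, cc] = BOARD_RGB
    img[rr, cc] += rng.normal(0, 2, size=(len(rr), 3))

    g = 70 + 130 * latent.greenness
    foliage = np.array([60.0, g, 55.0])
    n_fg = int(mask.sum())
    tex = rng.normal(0, 6 + 25 * latent.granularity, size=(n_fg, 3))
    img[mask] = foliage + tex
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _render_single(
    latent: PlantLatent,
    rng: np.random.Generator,
    canvas: int,
    view: str,
    sample_id: str,
    year: int | None,
) -> RenderedView:
    board = _board_geometry(canvas)
    br, bc, brad = board
    forbidden = np.zeros((canvas, canvas), dtype=bool)
    rr, cc = disk((br, bc), brad + 3, shape=(canvas, canvas))
    forbidden[rr, cc] = True

    seed_region = np.zeros((canvas, canvas), dtype=bool)
    if view == "top":
        # radial canopy seeded from a small central core
        c0 = canvas // 2
        half = max(2, int(canvas * latent.width_frac / 8))
        seed_region[c0 - half : c0 + half, c0 - half : c0 + half] = True
    else:
        # stem rising from the bottom centre
        h = int(canvas * latent.height_frac)
        c0 = canvas // 2
        sw = max(1, canvas // 80)
        seed_region[canvas - h : canvas - 2, c0 - sw : c0 + sw + 1] = True

    mask = _grow_blob_mask(canvas, latent.area_px, rng, seed_region, forbidden)
    img = _colorize(mask, board, latent, rng)
    pi = PlantImage(img, view=view, sample_id=sample_id, year=year)
    return RenderedView(image=pi, true_mask=PlantMask(mask), target_area_px=latent.area_px)


def render_plant_views(
    latent: PlantLatent,
    seed: int,
    canvas: int = 160,
    sample_id: str = "",
    year: int | None = None,
) -> RenderedPlant:
    """Render six side views and one top view of one latent plant.

    Returns the seven RGB views with their true masks and the cm/px scale
    record implied by the rendered board.  Bit-identical for a fixed seed.
    """
    if latent.area_px <= 0:
        raise ValueError("latent area must be positive")
    if latent.area_px > 0.5 * canvas * canvas:
        raise ValueError("latent area exceeds renderer bounds for this canvas")
    rng = np.random.default_rng(seed)
    plant = RenderedPlant()
    for v in SIDE_VIEWS:
        sub = np.random.default_rng(rng.integers(2**31))
        jl = latent.jittered(sub)
        plant.views[v] = _render_single(jl, sub, canvas, v, sample_id, year)
    sub = np.random.default_rng(rng.integers(2**31))
    plant.views["top"] = _render_single(latent, sub, canvas, "top", sample_id, year)
    _, _, brad = _board_geometry(canvas)
    plant.scale = ScaleRef(board_span_px=2 * brad)
    return plant
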