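"""Mask morphology: fixed banks of 30 side-view and 16 top-view shape
descriptors, calibrated from pixels to centimetres via the 30 cm white
reference board imaged alongside each plant.

The bank covers the descriptor families used in single-plant phenotyping:
projected and convex areas, plant height and the width profile at
fractional heights (1/5 … 4/5 measured from the top of the bounding box),
solidity, rectangularity (extent), circularity/compactness, perimeter-based
convexity, ellipse fits, and Feret (caliper) diameters.  Lengths are
reported in cm and areas in cm²; dimensionless descriptors are unchanged by
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import regionprops

from .segmentation import PlantMask

SIDE_MORPH_KEYS = (
    "height",
    "max_width",
    "min_width",
    "width_1_5",
    "width_2_5",
    "width_3_5",
    "width_4_5",
    "mean_width",
    "width_std",
    "area",
    "convex_area",
    "solidity",
    "perimeter",
    "convex_perimeter",
    "convexity",
    "circularity",
    "extent",
    "aspect_ratio",
    "equivalent_diameter",
    "major_axis",
    "minor_axis",
    "eccentricity",
    "orientation",
    "centroid_height_frac",
    "bbox_area",
    "hull_bbox_ratio",
    "area_height_ratio",
    "upper_area_frac",
    "perimeter_area_ratio",
    "max_feret",
)

TOP_MORPH_KEYS = (
    "area",
    "convex_area",
    "solidity",
    "perimeter",
    "convex_perimeter",
    "circularity",
    "bbox_width",
    "bbox_height",
    "extent",
    "aspect_ratio",
    "equivalent_diameter",
    "major_axis",
    "minor_axis",
    "eccentricity",
    "max_feret",
    "min_feret",
)

# classification of descriptors by physical dimension, for calibration
_LENGTH_KEYS = {
    "height",
    "max_width",
    "min_width",
    "width_1_5",
    "width_2_5",
    "width_3_5",
    "width_4_5",
    "mean_width",
    "width_std",
    "perimeter",
    "convex_perimeter",
    "equivalent_diameter",
    "major_axis",
    "minor_axis",
    "max_feret",
    "min_feret",
    "bbox_width",
    "bbox_height",
    "area_height_ratio",
}
_AREA_KEYS = {"area", "convex_area", "bbox_area"}
_INV_LENGTH_KEYS = {"perimeter_area_ratio"}


@dataclass
class ScaleRef:
    """Pixel→cm calibration from the 30 cm white reference board."""

    board_span_px: float
    board_diameter_cm: float = 30.0

    def __post_init__(self) -> None:
        if self.board_span_px <= 0:
            raise ValueError("board span must be positive")

    @property
    def cm_per_px(self) -> float:
        return self.board_diameter_cm / self.board_span_px


def _require_mask(mask: PlantMask) -> np.ndarray:
    if mask.empty or mask.foreground_count == 0:
        raise ValueError("morphology requires a non-empty mask")
    return mask.pixels


def width_profile(mask: PlantMask, fractions: Sequence[float]) -> list[float]:
    """Horizontal extent of the mask at fractional plant heights.

    For fraction f the row ``round(f · height)`` below the top of the plant
    bounding box is inspected; the width is rightmost − leftmost + 1
    foreground column on that row, or 0 for an empty row.
    """
    m = _require_mask(mask)
    rows = np.flatnonzero(m.any(axis=1))
    r0, r1 = rows[0], rows[-1]
    height = int(r1 - r0 + 1)
    widths = []
    for f in fractions:
        idx = r0 + int(round(f * height))
        idx = min(max(idx, r0), r1)
        cols = np.flatnonzero(m[idx])
        widths.append(float(cols[-1] - cols[0] + 1) if cols.size else 0.0)
    return widths


def _min_feret(m: np.ndarray) -> float:
    """Minimum caliper diameter over the convex hull of pixel squares."""
    coords = np.argwhere(m).astype(np.float64)
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    pts = (coords[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    best = np.inf
    for k in range(len(hp)):
        a, b = hp[k], hp[(k + 1) % len(hp)]
        edge = b - a
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        rel = hp - a
        d = np.abs(edge[0] * rel[:, 1] - edge[1] * rel[:, 0]) / norm
        best = min(best, d.max())
    return float(best)


def _calibrate(feats: Dict[str, float], scale: ScaleRef | None, units: str) -> Dict[str, float]:
    if units == "px" or scale is None:
        return feats
    if units != "cm":
        raise ValueError("units must be 'cm' or 'px'")
    s = scale.cm_per_px
    out = {}
    for k, v in feats.items():
        if k in _LENGTH_KEYS:
            out[k] = v * s
        elif k in _AREA_KEYS:
            out[k] = v * s * s
        elif k in _INV_LENGTH_KEYS:
            out[k] = v / s
        else:
            out[k] = v
    return out


def _shared_props(m: np.ndarray):
    props = regionprops(m.astype(np.uint8))[0]
    hull_props = regionprops(props.image_convex.astype(np.uint8))[0]
    return props, hull_props


def side_morphology(
    mask: PlantMask, scale: ScaleRef | None = None, units: str = "cm"
) -> Dict[str, float]:
    """The 30-descriptor side-view bank (calibrated unless units='px')."""
    m = _require_mask(mask)
    props, hull_props = _shared_props(m)
    r0, c0, r1, c1 = props.bbox
    height = float(r1 - r0)
    bbox_w = float(c1 - c0)

    row_any = m.any(axis=1)
    row_widths = []
    for r in np.flatnonzero(row_any):
        cols = np.flatnonzero(m[r])
        row_widths.append(cols[-1] - cols[0] + 1)
    row_widths = np.asarray(row_widths, dtype=np.float64)

    area = float(props.area)
    convex_area = float(props.area_convex)
    perim = float(props.perimeter)
    convex_perim = float(hull_props.perimeter)
    w15, w25, w35, w45 = width_profile(mask, (0.2, 0.4, 0.6, 0.8))
    mid_row = r0 + (r1 - r0) // 2
    upper = float(m[r0:mid_row, :].sum())

    feats = {
        "height": height,
        "max_width": float(row_widths.max()),
        "min_width": float(row_widths.min()),
        "width_1_5": w15,
        "width_2_5": w25,
        "width_3_5": w35,
        "width_4_5": w45,
        "mean_width": float(row_widths.mean()),
        "width_std": float(row_widths.std()),
        "area": area,
        "convex_area": convex_area,
        "solidity": area / convex_area,
        "perimeter": perim,
        "convex_perimeter": convex_perim,
        "convexity": convex_perim / perim if perim > 0 else 1.0,
        "circularity": 4 * np.pi * area / perim**2 if perim > 0 else 1.0,
        "extent": area / (height * bbox_w),
        "aspect_ratio": height / float(row_widths.max()),
        "equivalent_diameter": float(props.equivalent_diameter_area),
        "major_axis": float(props.axis_major_length),
        "minor_axis": float(props.axis_minor_length),
        "eccentricity": float(props.eccentricity),
        "orientation": float(props.orientation),
        "centroid_height_frac": (float(props.centroid[0]) - r0) / height,
        "bbox_area": height * bbox_w,
        "hull_bbox_ratio": convex_area / (height * bbox_w),
        "area_height_ratio": area / height,
        "upper_area_frac": upper / area,
        "perimeter_area_ratio": perim / area,
        "max_feret": float(props.feret_diameter_max),
    }
    assert set(feats) == set(SIDE_MORPH_KEYS)
    return _calibrate(feats, scale, units)


def top_morphology(
    mask: PlantMask, scale: ScaleRef | None = None, units: str = "cm"
) -> Dict[str, float]:
    """The 16-descriptor top-view bank (calibrated unless units='px')."""
    m = _require_mask(mask)
    props, hull_props = _shared_props(m)
    r0, c0, r1, c1 = props.bbox
    bbox_h = float(r1 - r0)
    bbox_w = float(c1 - c0)
    area = float(props.area)
    convex_area = float(props.area_convex)
    perim = float(props.perimeter)
    convex_perim = float(hull_props.perimeter)

    feats = {
        "area": area,
        "convex_area": convex_area,
        "solidity": area / convex_area,
        "perimeter": perim,
        "convex_perimeter": convex_perim,
        "circularity": 4 * np.pi * area / perim**2 if perim > 0 else 1.0,
        "bbox_width": bbox_w,
        "bbox_height": bbox_h,
        "extent": area / (bbox_h * bbox_w),
        "aspect_ratio": bbox_w / bbox_h,
        "equivalent_diameter": float(props.equivalent_diameter_area),
        "major_axis": float(props.axis_major_length),
        "minor_axis": float(props.axis_minor_length),
        "eccentricity": float(props.eccentricity),
        "max_feret": float(props.feret_diameter_max),
        "min_feret": _min_feret(m),
    }
    assert set(feats) == set(TOP_MORPH_KEYS)
    return _calibrate(feats, scale, units)


def average_side_morphology(per_view: Sequence[Dict[str, float]]) -> Dict[str, float]:
    """Element-wise mean of six per-view side morphology banks."""
    if len(per_view) != 6:
        raise ValueError(f"expected exactly 6 side views, got {len(per_view)}")
    return {k: float(np.mean([v[k] for v in per_view])) for k in SIDE_MORPH_KEYS}
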