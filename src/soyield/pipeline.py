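"""Per-plant feature extraction: seven views → one 92-column feature row.

Side features (53 = 6 color + 17 texture + 30 morphology) are six-view
averages: channel means and morphology/texture banks are averaged
element-wise across the side views and the color ratios recomputed from
the averaged means.  Top features (39 = 6 + 17 + 16) come from the single
overhead view.  Columns are named ``{side|top}_{family}_{key}``.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np

from .color import COLOR_KEYS, average_side_views, color_features, color_means
from .morphology import (
    SIDE_MORPH_KEYS,
    TOP_MORPH_KEYS,
    ScaleRef,
    average_side_morphology,
    side_morphology,
    top_morphology,
)
from .segmentation import SIDE_VIEWS, PlantImage, PlantMask, segment_plant
from .texture import TEXTURE_KEYS, side_texture, texture_features

SIDE_FEATURE_COUNT = len(COLOR_KEYS) + len(TEXTURE_KEYS) + len(SIDE_MORPH_KEYS)  # 53
TOP_FEATURE_COUNT = len(COLOR_KEYS) + len(TEXTURE_KEYS) + len(TOP_MORPH_KEYS)  # 39


def feature_columns() -> list[str]:
    """Canonical ordering of the 92 per-plant feature columns."""
    cols = []
    for fam, keys in (("color", COLOR_KEYS), ("texture", TEXTURE_KEYS), ("morph", SIDE_MORPH_KEYS)):
        cols += [f"side_{fam}_{k}" for k in keys]
    for fam, keys in (("color", COLOR_KEYS), ("texture", TEXTURE_KEYS), ("morph", TOP_MORPH_KEYS)):
        cols += [f"top_{fam}_{k}" for k in keys]
    return cols


def extract_plant_features(
    images: Mapping[str, PlantImage],
    scale: ScaleRef,
    masks: Optional[Mapping[str, PlantMask]] = None,
    segmentation_method: str = "threshold",
) -> Dict[str, float]:
    """Extract the full per-plant feature vector from its seven views.

    ``images`` must hold the keys side_1..side_6 and top.  If ``masks`` is
    given those masks are used; otherwise each view is segmented with the
    built-in method.  Raises if any view is missing or any mask is empty.
    """
    missing = [v for v in (*SIDE_VIEWS, "top") if v not in images]
    if missing:
        sid = next(iter(images.values())).sample_id if images else ""
        raise ValueError(f"plant {sid!r} is missing views: {missing}")

    view_masks: Dict[str, PlantMask] = {}
    for v, img in images.items():
        if masks is not None and v in masks:
            m = masks[v]
        else:
            m = segment_plant(img, method=segmentation_method)
        if m.empty:
            raise ValueError(f"empty mask for view {v} of plant {img.sample_id!r}")
        view_masks[v] = m

    side_means = [color_means(images[v], view_masks[v]) for v in SIDE_VIEWS]
    side_tex = [texture_features(images[v], view_masks[v]) for v in SIDE_VIEWS]
    side_morph = [side_morphology(view_masks[v], scale) for v in SIDE_VIEWS]

    out: Dict[str, float] = {}
    for k, v in average_side_views(side_means).items():
        out[f"side_color_{k}"] = v
    for k, v in side_texture(side_tex).items():
        out[f"side_texture_{k}"] = v
    for k, v in average_side_morphology(side_morph).items():
        out[f"side_morph_{k}"] = v

    for k, v in color_features(images["top"], view_masks["top"]).items():
        out[f"top_color_{k}"] = v
    for k, v in texture_features(images["top"], view_masks["top"]).items():
        out[f"top_texture_{k}"] = v
    for k, v in top_morphology(view_masks["top"], scale).items():
        out[f"top_morph_{k}"] = v

    assert len(out) == SIDE_FEATURE_COUNT + TOP_FEATURE_COUNT
    return out
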