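"""File formats and run configuration.

Interchange formats are deliberately plain: PNG/JPG views, 0/255
single-channel PNG masks, CSV tables (one row per plant: sample_id,
variety, year, treatment, replicate, yield_g, then feature columns), JSON
for nested results.  Every artifact written by the CLI embeds the seed and
a short config hash.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .segmentation import ALL_VIEWS, PlantImage, PlantMask

META_COLUMNS = ["sample_id", "variety", "year", "treatment", "replicate", "yield_g"]

_VIEW_SUFFIX = {f"s{i}": f"side_{i}" for i in range(1, 7)} | {"top": "top"}


@dataclass
class RunConfig:
    """Paths, seed and stage options for one CLI run."""

    images_dir: Optional[str] = None
    masks_dir: Optional[str] = None
    yield_csv: Optional[str] = None
    output_dir: str = "soyield_out"
    seed: int = 0
    threshold: float = 0.5
    models: list = field(default_factory=lambda: ["catboost", "lightgbm", "gbdt", "rf", "mlp"])
    scale_board_px: Optional[float] = None
    canvas: int = 64

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def read_image(path: str | Path, view: str = "", sample_id: str = "") -> PlantImage:
    img = Image.open(path)
    if img.mode == "RGBA":
        warnings.warn(f"{path}: alpha channel dropped")
        img = img.convert("RGB")
    elif img.mode != "RGB":
        img = img.convert("RGB")
    return PlantImage(np.asarray(img), view=view or "side_1", sample_id=sample_id)


def read_mask(path: str | Path) -> PlantMask:
    arr = np.asarray(Image.open(path).convert("L"))
    return PlantMask(arr > 127)


def write_mask(mask: PlantMask, path: str | Path) -> None:
    Image.fromarray((mask.pixels * np.uint8(255)).astype(np.uint8), mode="L").save(path)


def read_yield_csv(path: str | Path) -> pd.DataFrame:
    """Read the per-plant yield/metadata CSV, validating its invariants."""
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dupes = df.loc[df["sample_id"].duplicated(), "sample_id"]
    if len(dupes):
        lines = (dupes.index + 2).tolist()  # header is line 1
        raise ValueError(f"{path}: duplicate sample_id at lines {lines}")
    bad = df.index[df["yield_g"].isna()]
    if len(bad):
        raise ValueError(f"{path}: missing yield at lines {(bad + 2).tolist()}")
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in feature table")
    if df.columns.duplicated().any():
        raise ValueError("duplicate column names in feature table")
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return read_yield_csv(path)


def plant_image_paths(images_dir: str | Path) -> Dict[str, Dict[str, Path]]:
    """Group ``{sample_id}_{s1..s6|top}.png`` files by plant and view tag."""
    out: Dict[str, Dict[str, Path]] = {}
    for p in sorted(Path(images_dir).iterdir()):
        if p.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        stem, _, suffix = p.stem.rpartition("_")
        if suffix not in _VIEW_SUFFIX or not stem:
            continue
        out.setdefault(stem, {})[_VIEW_SUFFIX[suffix]] = p
    return out


def write_json(obj, path: str | Path, seed: Optional[int] = None, config_hash: str = "") -> None:
    payload = {"seed": seed, "config_hash": config_hash, "result": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
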