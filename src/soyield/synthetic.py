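"""Synthetic trial generator.

Emulates a two-year, multi-variety, replicated pot trial with two planting
treatments (sole cropping and maize strip intercropping):

* **table tier** — per-plant yields built from Gaussian variance
  components (genotype ``Vg``, genotype×location ``Vll``, genotype×year
  ``Vly``, residual ``Vr``) plus a fixed treatment offset, with named
  features planted at configurable Pearson correlations with yield and
  pure-noise features alongside;
* **image tier** — for each plant, six side views plus one top view
  rendered by :mod:`soyield.render`, with latent canopy area tied to yield
  so that image→feature extraction can recover the planted ordering.

Recording-error outliers (offsets of 5–60 residual SDs, a data-entry-error
scale) are injected per year so the outlier-removal stage has real work to
do; the default bookkeeping mirrors the study design this package is built
around: 240 varieties × 3 reps × 2 treatments in year one (1,440 plants)
and 202 varieties in year two (1,212 plants), 7 images per plant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .render import PlantLatent, render_plant_views

META_COLUMNS = ("sample_id", "variety", "year", "treatment", "replicate", "yield_g")

#: planted feature→r map used by default; names follow the field's
#: abbreviation style (side/top texture and morphology indicators)
DEFAULT_SIGNALS: Dict[str, float] = {
    "SME": 0.85,
    "SGD": 0.72,
    "SG": 0.70,
    "SDM": -0.66,
    "TSC": 0.64,
    "SRA": 0.62,
    "SSC": 0.60,
    "SE": -0.58,
    "SGE1": 0.56,
    "TRH": 0.55,
    "SGA": 0.54,
    "TG": 0.52,
    "SHE": 0.51,
    "TDM": -0.35,
    "SIG1": -0.30,
}


@dataclass
class TrialConfig:
    """Design and signal structure of one synthetic trial."""

    n_varieties: int = 240
    n_reps: int = 3
    years: Tuple[int, ...] = (2022, 2023)
    treatments: Tuple[str, ...] = ("sole", "intercrop")
    varieties_per_year: Optional[Mapping[int, int]] = None
    variance_components: Dict[str, float] = field(
        default_factory=lambda: {"Vg": 10.0, "Vll": 0.0, "Vly": 9.0, "Vr": 27.0}
    )
    planted_signals: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGNALS))
    n_noise_features: int = 10
    yield_mean: float = 25.0
    treatment_delta: float = 1.0
    n_outliers: Optional[Mapping[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be non-negative")
        for name, r in self.planted_signals.items():
            if abs(r) > 1:
                raise ValueError(f"planted r for {name!r} must satisfy |r| <= 1")
            if name in META_COLUMNS:
                raise ValueError(f"planted signal {name!r} collides with a metadata column")
        if self.varieties_per_year is None:
            # default mirrors the study bookkeeping: 240 then 202 varieties
            drop = 38 if self.n_varieties == 240 and len(self.years) == 2 else 0
            self.varieties_per_year = {
                y: self.n_varieties - (drop if k > 0 else 0)
                for k, y in enumerate(self.years)
            }
        if self.n_outliers is None:
            if self.varieties_per_year == {2022: 240, 2023: 202} and self.n_reps == 3 \
                    and len(self.treatments) == 2:
                self.n_outliers = {2022: 149, 2023: 121}
            else:
                self.n_outliers = {y: 0 for y in self.years}

    @property
    def n_samples(self) -> int:
        return sum(
            self.varieties_per_year[y] * self.n_reps * len(self.treatments)
            for y in self.years
        )


@dataclass
class TrialTruth:
    """Generator-side ground truth for recovery tests."""

    config: TrialConfig
    realized_r: Dict[str, float]
    variance_components: Dict[str, float]
    outlier_ids: List[str]
    latent_z: Optional[pd.Series] = None
    cm_per_px: Optional[float] = None
    mask_paths: Dict[str, str] = field(default_factory=dict)
    seeds: Dict[str, int] = field(default_factory=dict)


def _total_sd(cfg: TrialConfig) -> float:
    return float(np.sqrt(sum(cfg.variance_components.values())))


def generate_feature_table(config: TrialConfig) -> Tuple[pd.DataFrame, TrialTruth]:
    """Generate the per-plant feature/yield table and its ground truth.

    Yield per plant = mean + variety effect + variety×year effect +
    treatment offset + residual, all Gaussian with the configured variance
    components.  Each planted feature f with target correlation r is
    ``r·z + √(1−r²)·ε`` where z is the standardized *clean* yield (before
    outlier injection — a recording error does not change the plant), so
    the expected sample Pearson correlation equals r.  Noise features are
    independent standard normals.
    """
    rng = np.random.default_rng(config.seed)
    vc = config.variance_components
    all_varieties = [f"V{k+1:03d}" for k in range(config.n_varieties)]
    g = rng.normal(0, np.sqrt(vc["Vg"]), size=config.n_varieties)
    loc = rng.normal(0, np.sqrt(vc["Vll"]), size=config.n_varieties)
    gy = rng.normal(0, np.sqrt(vc["Vly"]), size=(config.n_varieties, len(config.years)))

    rows = []
    clean_yield = []
    n_treat = len(config.treatments)
    for yi, year in enumerate(config.years):
        nv = config.varieties_per_year[year]
        for vi in range(nv):
            for treatment in config.treatments:
                t_off = config.treatment_delta * (
                    0.5 if treatment == config.treatments[0] else -0.5
                ) * (1 if n_treat > 1 else 0)
                for rep in range(1, config.n_reps + 1):
                    resid = rng.normal(0, np.sqrt(vc["Vr"]))
                    y_val = config.yield_mean + g[vi] + loc[vi] + gy[vi, yi] + t_off + resid
                    rows.append(
                        {
                            "sample_id": f"{year}_{all_varieties[vi]}_{treatment}_r{rep}",
                            "variety": all_varieties[vi],
                            "year": year,
                            "treatment": treatment,
                            "replicate": rep,
                        }
                    )
                    clean_yield.append(y_val)

    df = pd.DataFrame(rows, columns=list(META_COLUMNS[:5]))
    clean = np.asarray(clean_yield, dtype=np.float64)
    sd = clean.std() if clean.size else 0.0
    z = (clean - clean.mean()) / sd if sd > 0 else np.zeros_like(clean)

    # outlier injection: positive offsets with a spread of magnitudes so
    # sequential studentized-residual deletion can peel them one by one.
    # Offsets are scaled by the full yield SD — the residual scale of the
    # intercept+treatment model the outlier test fits (variety effects are
    # not in that model, so they are part of its residual).
    observed = clean.copy()
    outlier_ids: List[str] = []
    resid_sd = sd if sd > 0 else 1.0
    for year, count in dict(config.n_outliers).items():
        if count <= 0:
            continue
        idx_year = np.flatnonzero(df["year"].to_numpy() == year)
        if count > len(idx_year):
            raise ValueError(f"cannot inject {count} outliers into {len(idx_year)} rows")
        chosen = rng.choice(idx_year, size=count, replace=False)
        offsets = rng.uniform(7.0, 60.0, size=count) * resid_sd
        observed[chosen] = observed[chosen] + offsets
        outlier_ids.extend(df.loc[chosen, "sample_id"])

    df["yield_g"] = observed

    realized: Dict[str, float] = {}
    for name, r in config.planted_signals.items():
        noise = rng.standard_normal(len(df))
        f = r * z + np.sqrt(max(0.0, 1 - r * r)) * noise
        df[name] = f
        denom = f.std() * z.std()
        realized[name] = float((f * z).mean() - f.mean() * z.mean()) / denom if denom > 0 else 0.0
    for k in range(config.n_noise_features):
        name = f"noise_{k+1:02d}"
        df[name] = rng.standard_normal(len(df))
        realized[name] = float(np.corrcoef(df[name], z)[0, 1]) if len(df) > 2 else 0.0

    truth = TrialTruth(
        config=config,
        realized_r=realized,
        variance_components=dict(vc),
        outlier_ids=outlier_ids,
        latent_z=pd.Series(z, index=df["sample_id"].to_numpy(), name="latent_z"),
        seeds={"table": config.seed},
    )
    return df, truth


def latents_for_yields(
    table: pd.DataFrame,
    truth: TrialTruth,
    canvas: int,
) -> Dict[str, PlantLatent]:
    """Map each plant's latent yield score to renderer traits.

    Canopy area scales linearly with the clean standardized yield (clipped
    at ±2.5 SD) around 12% of the canvas, so extracted projected area
    should track yield ordering.
    """
    base_area = 0.12 * canvas * canvas
    out = {}
    for sid in table["sample_id"]:
        zval = float(truth.latent_z.loc[sid])
        area = base_area * (1 + 0.25 * np.clip(zval, -2.5, 2.5))
        g = 0.6 + 0.08 * np.clip(zval, -2.5, 2.5)
        out[sid] = PlantLatent(area_px=area, greenness=float(np.clip(g, 0.1, 1.0)))
    return out


def generate_trial_images(
    config: TrialConfig,
    out_dir: str | Path,
    canvas: int = 64,
    write_masks: bool = True,
) -> Tuple[pd.DataFrame, TrialTruth]:
    """Write an image-tier dataset: 7 PNG views per plant + yield CSV + truth.

    Layout under ``out_dir``: ``images/{sample_id}_s{1..6}.png`` and
    ``images/{sample_id}_top.png``; parallel ``masks/`` with 0/255 PNGs;
    ``yield.csv`` with the metadata and feature columns; ``truth.json``.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    if write_masks:
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    table, truth = generate_feature_table(config)
    latents = latents_for_yields(table, truth, canvas)
    rng = np.random.default_rng(config.seed + 1)

    cm_per_px = None
    for sid in table["sample_id"]:
        plant_seed = int(rng.integers(2**31))
        plant = render_plant_views(latents[sid], seed=plant_seed, canvas=canvas, sample_id=sid)
        cm_per_px = plant.scale.cm_per_px
        for view, rv in plant.views.items():
            suffix = "top" if view == "top" else f"s{view.split('_')[1]}"
            Image.fromarray(rv.image.pixels).save(out_dir / "images" / f"{sid}_{suffix}.png")
            if write_masks:
                mask_img = (rv.true_mask.pixels * np.uint8(255)).astype(np.uint8)
                mpath = out_dir / "masks" / f"{sid}_{suffix}.png"
                Image.fromarray(mask_img, mode="L").save(mpath)
                truth.mask_paths[f"{sid}_{suffix}"] = str(mpath)

    truth.cm_per_px = cm_per_px
    truth.seeds["images"] = config.seed + 1
    table.to_csv(out_dir / "yield.csv", index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "cm_per_px": cm_per_px,
                "variance_components": truth.variance_components,
                "realized_r": truth.realized_r,
                "outlier_ids": truth.outlier_ids,
                "n_samples": int(len(table)),
            },
            fh,
            indent=1,
        )
    return table, truth
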