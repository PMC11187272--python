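"""Gray–gradient co-occurrence texture traits.

Unlike the displacement-based Haralick GLCM, the gray–gradient co-occurrence
matrix (GGCM, after Hong Jiguang's construction) tallies, at the *same*
pixel, the joint occurrence of the quantized intensity level and the
quantized gradient-magnitude level.  The intensity image is the HSI I
channel, I = (R + G + B) / 3; the gradient image is a 3×3 Sobel magnitude.
Both axes are min–max quantized to 16 levels over the plant foreground, and
the 16×16 count matrix H(i, j) is normalized to probabilities
p(i, j) = H(i, j) / ΣH.

Fifteen traits are computed from the GGCM and two more from the raw 256-bin
gray histogram, for 17 per view:

====== =================================== ==========================================
key    trait                               formula
====== =================================== ==========================================
T1     small-gradient dominance            [Σ_i Σ_j H(i,j)/j²] / ΣH
T2     large-gradient dominance            [Σ_i Σ_j j²·H(i,j)] / ΣH
T3     energy                              Σ p(i,j)²
T4     gradient-distribution inhomogeneity Σ_j [Σ_i H(i,j)]² / ΣH
mu2    gradient average                    Σ_j j·p_grad(j)
T5     gradient entropy                    −Σ_j p_grad(j)·ln p_grad(j)
T6     grayscale entropy                   −Σ_i p_gray(i)·ln p_gray(i)
T7     mixed entropy                       −Σ_i Σ_j p(i,j)·ln p(i,j)
T8     differential moment                 Σ_i Σ_j (i−j)²·p(i,j)
T9     inverse differential moment         Σ_i Σ_j p(i,j) / (1 + (i−j)²)
sigma2 gradient standard deviation         √(Σ_j (j−mu2)²·p_grad(j))
T10    gray–gradient correlation           Σ_i Σ_j (i−mu1)(j−mu2)·p(i,j) / (σ1σ2)
T11    grayscale-distribution inhomog.     Σ_i [Σ_j H(i,j)]² / ΣH
mu1    gray average                        Σ_i i·p_gray(i)
sigma1 grayscale standard deviation        √(Σ_i (i−mu1)²·p_gray(i))
S2     gray-histogram variance             Σ_k (P_k − P̄)² / 255  (256 bins)
Hhist  gray-histogram entropy              −Σ_k P_k·ln P_k
====== =================================== ==========================================

where p_gray(i) = Σ_j p(i,j) and p_grad(j) = Σ_i p(i,j).  Natural
logarithms; zero-probability terms contribute 0 to entropies.  S2 keeps the
255 divisor of the source formulation (a nonstandard variance normaliser)
and is computed on the normalized histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import ndimage

from .segmentation import PlantImage, PlantMask

N_LEVELS = 16

TEXTURE_KEYS = (
    "T1",
    "T2",
    "T3",
    "T4",
    "mu2",
    "T5",
    "T6",
    "T7",
    "T8",
    "T9",
    "sigma2",
    "T10",
    "T11",
    "mu1",
    "sigma1",
    "S2",
    "Hhist",
)


@dataclass
class GrayGradientPair:
    """Foreground gray and gradient images quantized to levels 1..16."""

    grayQ: np.ndarray
    gradQ: np.ndarray
    mask: PlantMask


@dataclass
class GGCM:
    """16×16 gray-level × gradient-level co-occurrence matrix."""

    H: np.ndarray
    p: np.ndarray
    n_pixels: int


def to_intensity(image: PlantImage, mask: PlantMask | None = None) -> np.ndarray:
    """HSI intensity channel I = (R + G + B) / 3, real valued."""
    if mask is not None and (mask.empty or mask.foreground_count == 0):
        raise ValueError("to_intensity requires a non-empty mask")
    return np.asarray(image.pixels, dtype=np.float64).mean(axis=2)


def gradient_magnitude(gray: np.ndarray) -> np.ndarray:
    """3×3 Sobel gradient magnitude √(gx² + gy²), replicate-padded borders.

    Unnormalised Sobel kernels: a vertical step edge of height h gives an
    interior edge-column magnitude of 4h.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("gradient_magnitude requires an image of at least 3×3")
    gx = ndimage.sobel(gray, axis=1, mode="nearest")
    gy = ndimage.sobel(gray, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def _quantize(values: np.ndarray, levels: int) -> np.ndarray:
    vmin = values.min()
    vmax = values.max()
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.int64)
    q = np.floor((values - vmin) / (vmax - vmin) * levels).astype(np.int64) + 1
    return np.clip(q, 1, levels)


def quantize_pair(
    gray: np.ndarray,
    gradient: np.ndarray,
    mask: PlantMask,
    levels: int = N_LEVELS,
) -> GrayGradientPair:
    """Min–max quantize foreground gray and gradient onto levels 1..16.

    Each axis is quantized independently over foreground pixels only; a
    constant channel maps every pixel to level 1.
    """
    if mask.empty or mask.foreground_count == 0:
        raise ValueError("quantize_pair requires a non-empty mask")
    m = mask.pixels
    grayQ = np.zeros(m.shape, dtype=np.int64)
    gradQ = np.zeros(m.shape, dtype=np.int64)
    grayQ[m] = _quantize(np.asarray(gray, dtype=np.float64)[m], levels)
    gradQ[m] = _quantize(np.asarray(gradient, dtype=np.float64)[m], levels)
    return GrayGradientPair(grayQ=grayQ, gradQ=gradQ, mask=mask)


def build_ggcm(pair: GrayGradientPair, levels: int = N_LEVELS) -> GGCM:
    """Co-located joint histogram of (gray level, gradient level) pairs."""
    m = pair.mask.pixels
    n = int(m.sum())
    if n == 0:
        raise ValueError("build_ggcm requires a non-empty foreground")
    gi = pair.grayQ[m] - 1
    gj = pair.gradQ[m] - 1
    H = np.zeros((levels, levels), dtype=np.int64)
    np.add.at(H, (gi, gj), 1)
    return GGCM(H=H, p=H / n, n_pixels=n)


def texture_traits(ggcm: GGCM, gray_foreground: np.ndarray) -> Dict[str, float]:
    """The 17 texture traits from a GGCM plus the raw foreground gray values.

    ``gray_foreground`` holds the unquantized I-channel values of the
    foreground pixels, used for the two 256-bin histogram traits.  When one
    of the marginal standard deviations is zero the correlation T10 is
    degenerate and reported as 0.
    """
    H = ggcm.H.astype(np.float64)
    p = ggcm.p
    n = H.sum()
    if n <= 0:
        raise ValueError("texture_traits requires at least one foreground pixel")
    levels = H.shape[0]
    i = np.arange(1, levels + 1, dtype=np.float64)[:, None]  # gray axis (rows)
    j = np.arange(1, levels + 1, dtype=np.float64)[None, :]  # gradient axis (cols)

    p_gray = p.sum(axis=1)  # marginal over gradient → gray distribution
    p_grad = p.sum(axis=0)  # marginal over gray → gradient distribution
    iv = i.ravel()
    jv = j.ravel()

    out: Dict[str, float] = {}
    out["T1"] = float((H / j**2).sum() / n)
    out["T2"] = float((j**2 * H).sum() / n)
    out["T3"] = float((p**2).sum())
    out["T4"] = float((H.sum(axis=0) ** 2).sum() / n)
    mu2 = float((jv * p_grad).sum())
    out["mu2"] = mu2
    out["T5"] = float(-np.sum(p_grad[p_grad > 0] * np.log(p_grad[p_grad > 0])))
    out["T6"] = float(-np.sum(p_gray[p_gray > 0] * np.log(p_gray[p_gray > 0])))
    out["T7"] = float(-np.sum(p[p > 0] * np.log(p[p > 0])))
    out["T8"] = float((p * (i - j) ** 2).sum())
    out["T9"] = float((p / (1.0 + (i - j) ** 2)).sum())
    sigma2 = float(np.sqrt(((jv - mu2) ** 2 * p_grad).sum()))
    out["sigma2"] = sigma2
    mu1 = float((iv * p_gray).sum())
    sigma1 = float(np.sqrt(((iv - mu1) ** 2 * p_gray).sum()))
    if sigma1 > 0 and sigma2 > 0:
        out["T10"] = float(((i - mu1) * (j - mu2) * p).sum() / (sigma1 * sigma2))
    else:
        out["T10"] = 0.0  # degenerate marginal
    out["T11"] = float((H.sum(axis=1) ** 2).sum() / n)
    out["mu1"] = mu1
    out["sigma1"] = sigma1

    vals = np.clip(np.round(np.asarray(gray_foreground, dtype=np.float64)), 0, 255)
    hist = np.bincount(vals.astype(np.int64), minlength=256).astype(np.float64)
    P = hist / hist.sum()
    out["S2"] = float(((P - P.mean()) ** 2).sum() / 255.0)
    nz = P[P > 0]
    out["Hhist"] = float(-np.sum(nz * np.log(nz)))
    return out


def texture_features(image: PlantImage, mask: PlantMask) -> Dict[str, float]:
    """All 17 per-view texture traits from an RGB view and its mask."""
    gray = to_intensity(image, mask)
    grad = gradient_magnitude(gray)
    pair = quantize_pair(gray, grad, mask)
    ggcm = build_ggcm(pair)
    return texture_traits(ggcm, gray[mask.pixels])


def side_texture(per_view: Sequence[Dict[str, float]]) -> Dict[str, float]:
    """Element-wise mean of six per-view trait dictionaries."""
    if len(per_view) != 6:
        raise ValueError(f"expected exactly 6 side views, got {len(per_view)}")
    return {k: float(np.mean([v[k] for v in per_view])) for k in TEXTURE_KEYS}
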