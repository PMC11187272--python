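"""Independent naive-summation oracles for the texture traits.

Everything here is written with explicit Python loops and no imports from
the package's texture internals, so it can serve as an independent check
of the vectorized implementation.
"""

import math

import numpy as np


def naive_quantize(values, levels=16):
    values = [float(v) for v in values]
    vmin, vmax = min(values), max(values)
    if vmax == vmin:
        return [1 for _ in values]
    out = []
    for v in values:
        q = int(math.floor((v - vmin) / (vmax - vmin) * levels)) + 1
        out.append(min(max(q, 1), levels))
    return out


def naive_ggcm(grayQ, gradQ, mask, levels=16):
    """Double-loop tally of co-located (gray level, gradient level) pairs."""
    H = [[0] * levels for _ in range(levels)]
    n = 0
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c]:
                H[grayQ[r, c] - 1][gradQ[r, c] - 1] += 1
                n += 1
    return H, n


def naive_traits(H, gray_vals, levels=16):
    """All 17 texture traits by naive summation over the 16×16 matrix."""
    n = sum(sum(row) for row in H)
    p = [[H[i][j] / n for j in range(levels)] for i in range(levels)]
    row_sum = [sum(H[i][j] for j in range(levels)) for i in range(levels)]  # per gray i
    col_sum = [sum(H[i][j] for i in range(levels)) for j in range(levels)]  # per grad j
    p_gray = [rs / n for rs in row_sum]
    p_grad = [cs / n for cs in col_sum]

    out = {}
    out["T1"] = sum(
        H[i][j] / (j + 1) ** 2 for i in range(levels) for j in range(levels)
    ) / n
    out["T2"] = sum(
        (j + 1) ** 2 * H[i][j] for i in range(levels) for j in range(levels)
    ) / n
    out["T3"] = sum(p[i][j] ** 2 for i in range(levels) for j in range(levels))
    out["T4"] = sum(cs**2 for cs in col_sum) / n
    mu2 = sum((j + 1) * p_grad[j] for j in range(levels))
    out["mu2"] = mu2
    out["T5"] = -sum(pg * math.log(pg) for pg in p_grad if pg > 0)
    out["T6"] = -sum(pg * math.log(pg) for pg in p_gray if pg > 0)
    out["T7"] = -sum(
        p[i][j] * math.log(p[i][j])
        for i in range(levels)
        for j in range(levels)
        if p[i][j] > 0
    )
    out["T8"] = sum(
        p[i][j] * ((i + 1) - (j + 1)) ** 2 for i in range(levels) for j in range(levels)
    )
    out["T9"] = sum(
        p[i][j] / (1 + ((i + 1) - (j + 1)) ** 2)
        for i in range(levels)
        for j in range(levels)
    )
    sigma2 = math.sqrt(sum(((j + 1) - mu2) ** 2 * p_grad[j] for j in range(levels)))
    out["sigma2"] = sigma2
    mu1 = sum((i + 1) * p_gray[i] for i in range(levels))
    sigma1 = math.sqrt(sum(((i + 1) - mu1) ** 2 * p_gray[i] for i in range(levels)))
    if sigma1 > 0 and sigma2 > 0:
        out["T10"] = (
            sum(
                ((i + 1) - mu1) * ((j + 1) - mu2) * p[i][j]
                for i in range(levels)
                for j in range(levels)
            )
            / (sigma1 * sigma2)
        )
    else:
        out["T10"] = 0.0
    out["T11"] = sum(rs**2 for rs in row_sum) / n
    out["mu1"] = mu1
    out["sigma1"] = sigma1

    hist = [0] * 256
    for v in gray_vals:
        k = int(round(float(v)))
        k = min(max(k, 0), 255)
        hist[k] += 1
    total = sum(hist)
    P = [h / total for h in hist]
    pbar = sum(P) / 256
    out["S2"] = sum((pk - pbar) ** 2 for pk in P) / 255
    out["Hhist"] = -sum(pk * math.log(pk) for pk in P if pk > 0)
    return out


def naive_texture_pipeline(image_rgb, mask):
    """Full naive path: intensity → Sobel → quantize → GGCM → traits."""
    h, w, _ = image_rgb.shape
    gray = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            gray[r, c] = (
                float(image_rgb[r, c, 0])
                + float(image_rgb[r, c, 1])
                + float(image_rgb[r, c, 2])
            ) / 3.0

    def at(r, c):
        return gray[min(max(r, 0), h - 1), min(max(c, 0), w - 1)]

    grad = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            gx = (
                (at(r - 1, c + 1) + 2 * at(r, c + 1) + at(r + 1, c + 1))
                - (at(r - 1, c - 1) + 2 * at(r, c - 1) + at(r + 1, c - 1))
            )
            gy = (
                (at(r + 1, c - 1) + 2 * at(r + 1, c) + at(r + 1, c + 1))
                - (at(r - 1, c - 1) + 2 * at(r - 1, c) + at(r - 1, c + 1))
            )
            grad[r, c] = math.hypot(gx, gy)

    fg = [(r, c) for r in range(h) for c in range(w) if mask[r, c]]
    gq_list = naive_quantize([gray[r, c] for r, c in fg])
    dq_list = naive_quantize([grad[r, c] for r, c in fg])
    grayQ = np.ones((h, w), dtype=int)
    gradQ = np.ones((h, w), dtype=int)
    for (r, c), gq, dq in zip(fg, gq_list, dq_list):
        grayQ[r, c] = gq
        gradQ[r, c] = dq
    H, _ = naive_ggcm(grayQ, gradQ, mask)
    return naive_traits(H, [gray[r, c] for r, c in fg])
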