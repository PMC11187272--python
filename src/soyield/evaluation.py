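"""Evaluation: regression metrics, outlier removal, and broad-sense
heritability from trial variance components.

Metrics are the standard RMSE = √(Σ(y−ŷ)²/m), MAE = Σ|y−ŷ|/m and
R² = 1 − Σ(ŷ−y)²/Σ(ȳ−y)².  Heritability uses the pot-trial form

    H² = Vg / (Vg + Vll/n + Vly/n + Vr/n²)

with n the replicate count; note the n² divisor on the residual component
(kept as the source formulation; ``conventional=True`` switches the Vr
divisor to n·years).  Variance components are estimated by balanced
method-of-moments ANOVA on the variety × year × replicate layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats


def _check_pair(y, yhat) -> Tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    if y.size < 1:
        raise ValueError("empty input")
    return y, yhat


def rmse(y, yhat) -> float:
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def r2(y, yhat) -> float:
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined for zero-variance y")
    return float(1.0 - np.sum((yhat - y) ** 2) / ss_tot)


def metrics(y, yhat) -> Dict[str, float]:
    return {"RMSE": rmse(y, yhat), "MAE": mae(y, yhat), "R2": r2(y, yhat)}


@dataclass
class HeritabilityInput:
    """Variance components (yield-variance units) and replicate count."""

    Vg: float
    Vll: float
    Vly: float
    Vr: float
    n: int

    def __post_init__(self) -> None:
        for name in ("Vg", "Vll", "Vly", "Vr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def heritability(inp: HeritabilityInput, conventional: bool = False, years: int = 2) -> float:
    """Broad-sense heritability H² from variance components."""
    vr_div = inp.n * years if conventional else inp.n**2
    denom = inp.Vg + inp.Vll / inp.n + inp.Vly / inp.n + inp.Vr / vr_div
    if denom <= 0:
        raise ValueError("heritability undefined: zero denominator")
    return float(inp.Vg / denom)


def estimate_components(
    table: pd.DataFrame,
    yield_col: str = "yield_g",
    n_override: Optional[int] = None,
) -> HeritabilityInput:
    """Method-of-moments ANOVA estimates of (Vg, Vly, Vr) from a trial table.

    The treatment fixed effect is removed by centring within treatment
    before the variety × year ANOVA; rows within a variety×year cell then
    count as replicates.  Vll is fixed at 0 (single-location trial).
    Negative component estimates are truncated at zero.  Varieties not
    observed in every year are dropped; mildly unbalanced replicate counts
    fall back to the harmonic-mean cell size with a warning.
    """
    df = table.copy()
    if df["variety"].nunique() < 2:
        raise ValueError("estimate_components requires >= 2 varieties")
    if df["year"].nunique() < 2:
        raise ValueError("estimate_components requires >= 2 years")

    if "treatment" in df.columns and df["treatment"].nunique() > 1:
        df[yield_col] = df[yield_col] - df.groupby("treatment")[yield_col].transform("mean") \
            + df[yield_col].mean()

    # keep varieties present in all years
    years = sorted(df["year"].unique())
    per_year = df.groupby("variety")["year"].nunique()
    keep = per_year[per_year == len(years)].index
    df = df[df["variety"].isin(keep)]
    if df["variety"].nunique() < 2:
        raise ValueError("fewer than 2 varieties observed in all years")

    cell_sizes = df.groupby(["variety", "year"]).size()
    if cell_sizes.min() < 2:
        raise ValueError("estimate_components requires >= 2 replicates per cell")
    if cell_sizes.nunique() > 1:
        warnings.warn("unbalanced replicate counts; using harmonic-mean cell size")
        m = float(stats.hmean(cell_sizes))
    else:
        m = float(cell_sizes.iloc[0])

    G = df["variety"].nunique()
    Y = len(years)
    y = df[yield_col].to_numpy()
    grand = y.mean()

    var_means = df.groupby("variety")[yield_col].mean()
    cell_means = df.groupby(["variety", "year"])[yield_col].mean()
    year_means = df.groupby("year")[yield_col].mean()

    ss_g = m * Y * float(((var_means - grand) ** 2).sum())
    ss_y = m * G * float(((year_means - grand) ** 2).sum())
    interact = (
        cell_means
        - var_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
        - year_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_gy = m * float((interact**2).sum())
    fitted = cell_means.reindex(list(zip(df["variety"], df["year"]))).to_numpy()
    ss_e = float(((y - fitted) ** 2).sum())

    ms_g = ss_g / (G - 1)
    ms_gy = ss_gy / ((G - 1) * (Y - 1))
    ms_e = ss_e / (G * Y * (m - 1))

    Vr = max(0.0, ms_e)
    Vly = max(0.0, (ms_gy - ms_e) / m)
    Vg = max(0.0, (ms_g - ms_gy) / (m * Y))
    n = int(n_override) if n_override is not None else int(round(m))
    return HeritabilityInput(Vg=Vg, Vll=0.0, Vly=Vly, Vr=Vr, n=n)


def remove_outliers(
    table: pd.DataFrame,
    yield_col: str = "yield_g",
    alpha: float = 0.05,
    max_iter: int = 500,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Iterative Bonferroni-adjusted studentized-residual outlier removal.

    Within each year, yields are modelled as intercept + treatment effect;
    externally studentized residuals are tested with Bonferroni-adjusted
    two-sided p-values and every row with adjusted p < ``alpha`` is removed,
    iterating until none qualify.  Returns the filtered table and a removal
    log (sample_id, year, residual, Bonferroni p, iteration).
    """
    df = table.copy()
    log_rows = []
    for year in sorted(df["year"].unique()):
        sub = df[df["year"] == year]
        if len(sub) < 10:
            raise ValueError(f"need >= 10 rows per year, year {year} has {len(sub)}")
        for it in range(1, max_iter + 1):
            sub = df[df["year"] == year]
            y = sub[yield_col].to_numpy(dtype=np.float64)
            n = len(y)
            # design: intercept + treatment dummies
            if "treatment" in sub.columns and sub["treatment"].nunique() > 1:
                X = pd.get_dummies(sub["treatment"], drop_first=True).to_numpy(dtype=np.float64)
                X = np.column_stack([np.ones(n), X])
            else:
                X = np.ones((n, 1))
            p_params = X.shape[1]
            if np.ptp(y) == 0:
                raise ValueError(f"degenerate constant yields in year {year}")
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            hat = np.einsum(
                "ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X
            )
            dof = n - p_params - 1
            if dof < 1:
                break
            s2 = resid @ resid / (n - p_params)
            # externally studentized residuals via the deletion identity
            r_int = resid / np.sqrt(s2 * (1 - hat))
            with np.errstate(invalid="ignore", divide="ignore"):
                t_ext = r_int * np.sqrt(dof / (n - p_params - r_int**2))
            # r_int² → n−p corresponds to an arbitrarily extreme point
            t_ext[~np.isfinite(t_ext)] = np.sign(r_int[~np.isfinite(t_ext)]) * np.inf
            p_raw = 2 * stats.t.sf(np.abs(t_ext), dof)
            p_bonf = np.minimum(1.0, p_raw * n)
            bad = np.flatnonzero(p_bonf < alpha)
            if bad.size == 0:
                break
            for b in bad:
                log_rows.append(
                    {
                        "sample_id": sub.iloc[b]["sample_id"],
                        "year": year,
                        "studentized_residual": float(t_ext[b]),
                        "bonferroni_p": float(p_bonf[b]),
                        "iteration": it,
                    }
                )
            df = df.drop(sub.index[bad])
    log = pd.DataFrame(
        log_rows,
        columns=["sample_id", "year", "studentized_residual", "bonferroni_p", "iteration"],
    )
    return df.reset_index(drop=True), log
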