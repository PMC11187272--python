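"""Feature selection: absolute-Pearson screening and importance-ranked
incremental minimization.

Screening keeps every feature whose |r| with yield reaches the threshold
(default 0.5, inclusive); negative correlates are kept on the same footing
as positive ones.  Screened features are grouped into the nine canonical
input combinations — side morphology (m1), side texture (m2), their union
(m3), the top-view counterparts (M1–M3), and the side+top unions
(S1 = m1+M1, S2 = m2+M2, S3 = m3+M3).  A fitted tree ensemble then ranks
features by normalized split-gain importance, and the incremental curve
refits the model on the top-k features for k = 1..K to locate the plateau —
the smallest bank whose accuracy matches the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import metrics
from .models import ModelSpec, fit_predict

COMBINATION_LABELS = ("m1", "m2", "m3", "M1", "M2", "M3", "S1", "S2", "S3")


@dataclass
class SelectionResult:
    correlations: pd.Series  # signed Pearson r per feature
    retained: List[str]
    threshold: float
    label: str = ""


def pearson_screen(
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    target_col: str = "yield_g",
    threshold: float = 0.5,
    label: str = "",
) -> SelectionResult:
    """Retain features with |Pearson r| ≥ threshold against yield.

    Constant features get r = 0.  Retained names are ordered by |r|
    descending, ties alphabetical, for deterministic downstream column
    order.
    """
    if len(table) < 3:
        raise ValueError("pearson_screen requires at least 3 samples")
    y = table[target_col].to_numpy(dtype=np.float64)
    if y.std() == 0:
        raise ValueError("zero-variance yield")
    corrs = {}
    for c in feature_cols:
        x = table[c].to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite values in feature {c!r}")
        corrs[c] = 0.0 if x.std() == 0 else float(np.corrcoef(x, y)[0, 1])
    s = pd.Series(corrs)
    kept = [c for c in feature_cols if abs(s[c]) >= threshold]
    kept.sort(key=lambda c: (-abs(s[c]), c))
    return SelectionResult(correlations=s, retained=kept, threshold=threshold, label=label)


def make_combinations(
    side_morph: SelectionResult,
    side_texture: SelectionResult,
    top_morph: SelectionResult,
    top_texture: SelectionResult,
) -> Dict[str, List[str]]:
    """Build the nine labeled input sets from per-view/per-family screens.

    Color features are screened but enter no combination (they fall below
    the threshold in the motivating analysis; the combinations are defined
    over morphology and texture only).
    """
    def _merge(parts: Sequence[SelectionResult | List[str]]) -> List[str]:
        seen, out = set(), []
        for part in parts:
            names = part.retained if isinstance(part, SelectionResult) else part
            for nme in names:
                if nme in seen:
                    raise ValueError(f"feature name collision across families: {nme!r}")
                seen.add(nme)
                out.append(nme)
        return out

    combos: Dict[str, List[str]] = {
        "m1": list(side_morph.retained),
        "m2": list(side_texture.retained),
        "M1": list(top_morph.retained),
        "M2": list(top_texture.retained),
    }
    combos["m3"] = _merge([side_morph, side_texture])
    combos["M3"] = _merge([top_morph, top_texture])
    combos["S1"] = _merge([combos["m1"], combos["M1"]])
    combos["S2"] = _merge([combos["m2"], combos["M2"]])
    combos["S3"] = _merge([combos["m3"], combos["M3"]])
    for lbl in ("m1", "m2", "m3", "M1", "M2", "M3"):
        if not combos[lbl]:
            raise ValueError(f"combination {lbl} retained no features")
    return combos


def importance_ranking(fit_result) -> pd.Series:
    """Normalized split-gain importances, sorted descending (ties alphabetical)."""
    imp = getattr(fit_result, "importances", None)
    if imp is None:
        raise ValueError(
            f"model {fit_result.spec.name!r} does not expose split-gain importances"
        )
    imp = imp / imp.sum()
    order = sorted(imp.index, key=lambda c: (-imp[c], c))
    return imp.reindex(order)


@dataclass
class ImportanceCurve:
    ranked: List[str]
    ks: List[int]
    rmse: List[float]
    mae: List[float]
    r2: List[float]
    plateau_index: int = field(default=-1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.ks, "RMSE": self.rmse, "MAE": self.mae, "R2": self.r2}
        )


def incremental_selection(
    ranked: Sequence[str],
    spec: ModelSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    target_col: str = "yield_g",
    eps: float = 0.01,
) -> ImportanceCurve:
    """Refit on top-k features for k = 1..K and locate the R² plateau.

    The plateau index is the smallest k from which R² no longer changes by
    ``eps`` or more: |R²(j) − R²(k)| < eps for every j ≥ k.
    """
    ranked = list(ranked)
    if len(ranked) < 2:
        raise ValueError("incremental_selection requires at least 2 ranked features")
    ks, rmses, maes, r2s = [], [], [], []
    for k in range(1, len(ranked) + 1):
        fr = fit_predict(spec, train, test, ranked[:k], target_col)
        ks.append(k)
        rmses.append(fr.test_metrics["RMSE"])
        maes.append(fr.test_metrics["MAE"])
        r2s.append(fr.test_metrics["R2"])
    plateau = len(ranked)
    for k in range(1, len(ranked) + 1):
        if all(abs(r2s[j] - r2s[k - 1]) < eps for j in range(k - 1, len(ranked))):
            plateau = k
            break
    return ImportanceCurve(
        ranked=ranked, ks=ks, rmse=rmses, mae=maes, r2=r2s, plateau_index=plateau
    )
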