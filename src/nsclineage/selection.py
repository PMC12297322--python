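"""Model comparison by small-sample-corrected AIC and Akaike weights.

For weighted least squares with cost E on n residuals and k fitted
parameters:

    AIC  = n * ln(E / n) + 2k
    AICc = AIC + 2k(k + 1) / (n - k - 1)

Akaike weights normalize exp(-Delta_i/2) over the compared scenarios and
read as the relative likelihood that each scenario is the best of the
set.  When all scenarios share the same k the AICc ranking reduces to the
cost ranking.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimation import FitResult

__all__ = ["aicc", "akaike_weights", "build_selection_table"]


def aicc(E: float, n: int, k: int) -> Tuple[float, float]:
    """AIC and AICc of a weighted-least-squares fit."""
    if E <= 0:
        raise ValueError("cost E must be strictly positive")
    if n <= k + 1:
        raise ValueError(
            f"small-sample correction undefined for n={n} <= k+1={k + 1}"
        )
    aic = n * math.log(E / n) + 2 * k
    return aic, aic + 2 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_scores: Sequence[float]) -> np.ndarray:
    """Akaike weights from a list of AICc scores (shift-invariant)."""
    scores = np.asarray(list(aicc_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one AICc score")
    if not np.all(np.isfinite(scores)):
        raise ValueError("AICc scores must be finite")
    delta = scores - scores.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def _table_for(fits: List[FitResult], setting_label: str) -> pd.DataFrame:
    rows = []
    for f in fits:
        a, ac = aicc(f.cost, f.n, f.k)
        rows.append({
            "setting": setting_label, "scenario": f.scenario,
            "E": f.cost, "n": f.n, "k": f.k, "AIC": a, "AICc": ac,
        })
    df = pd.DataFrame(rows)
    df["deltaAICc"] = df["AICc"] - df["AICc"].min()
    df["weight"] = akaike_weights(df["AICc"].to_numpy())
    return df.sort_values(["AICc", "scenario"], kind="stable").reset_index(drop=True)


def build_selection_table(
    fits: Iterable[FitResult], pooling: str = "per-setting"
) -> pd.DataFrame:
    """Rank scenario fits by AICc, per setting and optionally pooled.

    With ``pooling="overall"`` an additional block sums E and n across
    settings per scenario, counting each free-parameter symbol once; that
    pooled AICc is approximate (flagged in ``DataFrame.attrs``) because
    the per-setting fits were optimized independently.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    if pooling not in ("per-setting", "overall"):
        raise ValueError("pooling must be 'per-setting' or 'overall'")

    by_setting: dict = {}
    for f in fits:
        by_setting.setdefault(f.setting, []).append(f)
    for setting, group in by_setting.items():
        ns = {f.n for f in group}
        if len(ns) > 1:
            raise ValueError(
                f"fits within setting {setting!r} disagree on data size "
                f"{sorted(ns)}: mixed datasets"
            )

    blocks = [_table_for(group, setting) for setting, group in sorted(by_setting.items())]

    if pooling == "overall" and len(by_setting) > 1:
        pooled_rows = []
        scenarios = sorted({f.scenario for f in fits})
        for scen in scenarios:
            group = [f for f in fits if f.scenario == scen]
            if len(group) < len(by_setting):
                continue  # scenario missing in some setting: not comparable
            E = sum(f.cost for f in group)
            n = sum(f.n for f in group)
            symbols = sorted({name for f in group for name in f.free_names})
            a, ac = aicc(E, n, len(symbols))
            pooled_rows.append({
                "setting": "overall", "scenario": scen,
                "E": E, "n": n, "k": len(symbols), "AIC": a, "AICc": ac,
            })
        if pooled_rows:
            pdf = pd.DataFrame(pooled_rows)
            pdf["deltaAICc"] = pdf["AICc"] - pdf["AICc"].min()
            pdf["weight"] = akaike_weights(pdf["AICc"].to_numpy())
            blocks.append(pdf.sort_values(["AICc", "scenario"], kind="stable").reset_index(drop=True))

    table = pd.concat(blocks, ignore_index=True)
    table.attrs["pooling"] = pooling
    table.attrs["pooled_aicc_approximate"] = pooling == "overall"
    return table
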