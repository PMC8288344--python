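"""Decompose fitted neighbourhood effects by origin (the partial-residual view).

Each focal tree's fitted neighbourhood effect — every DI and HOI term times
its estimated coefficient — is split by where the effect comes from relative
to the focal's own group i:

* DI_ii   — direct effect of conspecific neighbours,
* DI_ij   — direct effect of heterospecific neighbours,
* HOI_ii,i — conspecific transmitter, conspecific initiator,
* HOI_ii,j — conspecific transmitter, heterospecific initiator,
* HOI_ij,i — heterospecific transmitter, conspecific initiator,
* HOI_ij,j — heterospecific transmitter, heterospecific initiator.

Components live on the linear-predictor scale (log-odds of survival, or log
growth), so they add exactly: di_total + hoi_total = total, and together
with the size terms they reconstruct each tree's fitted linear predictor.
A distribution entirely above zero is read as facilitative, entirely below
as competitive, and one crossing zero as mixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .census import CensusPlot
from .models import FitResult

COMPONENTS = ["di_intra", "di_inter", "hoi_ii_i", "hoi_ii_j",
              "hoi_ij_i", "hoi_ij_j"]


def decompose_effects(fit: FitResult, terms: pd.DataFrame,
                      focal_group: str) -> pd.DataFrame:
    """Per-focal effect components from a SIZE+DI+HOI fit and its term table."""
    if fit.model_class != "SIZE_DI_HOI":
        raise ValueError("decomposition requires a SIZE+DI+HOI fit, got "
                         f"{fit.model_class}")
    groups = list(fit.groups)
    t_groups = terms.attrs.get("groups")
    if t_groups is not None and list(t_groups) != groups:
        raise ValueError(f"grouping mismatch: fit {groups} vs terms "
                         f"{list(t_groups)}")
    for key in ("u", "v", "R"):
        tv, fv = terms.attrs.get(key), fit.kernel.get(key)
        if tv is not None and fv is not None and tv != fv:
            raise ValueError(f"terms computed at {key}={tv} but fit used "
                             f"{key}={fv}")
    if focal_group not in groups:
        raise ValueError(f"unknown focal group {focal_group!r}")

    out = pd.DataFrame({"focal_id": terms["focal_id"]})
    for c in COMPONENTS:
        out[c] = 0.0
    p = fit.params
    for j in groups:
        contrib = p[f"di_{j}"] * terms[f"di_{j}"].to_numpy(float)
        key = "di_intra" if j == focal_group else "di_inter"
        out[key] += contrib
    for j in groups:
        for k in groups:
            contrib = (p[f"hoi_{j}_{k}"]
                       * terms[f"hoi_{j}_{k}"].to_numpy(float))
            same_j = j == focal_group
            same_k = k == focal_group
            key = ("hoi_ii_i" if same_j and same_k else
                   "hoi_ii_j" if same_j else
                   "hoi_ij_i" if same_k else "hoi_ij_j")
            out[key] += contrib
    out["di_total"] = out["di_intra"] + out["di_inter"]
    out["hoi_total"] = (out["hoi_ii_i"] + out["hoi_ii_j"]
                        + out["hoi_ij_i"] + out["hoi_ij_j"])
    out["total"] = out["di_total"] + out["hoi_total"]
    return out


def summarize_effects(decomp: pd.DataFrame,
                      components: list | None = None) -> pd.DataFrame:
    """Boxplot-style summary per component: quartiles, whiskers, sign verdict.

    Whiskers follow the 1.5 x IQR convention (most extreme observation inside
    the fence).  Verdict: "facilitative" if every value is > 0,
    "competitive" if every value is < 0, otherwise "mixed" (which includes
    the all-zero, no-neighbour case).
    """
    if decomp.empty:
        raise ValueError("empty decomposition table")
    components = components or COMPONENTS + ["di_total", "hoi_total", "total"]
    rows = []
    for c in components:
        x = decomp[c].to_numpy(float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        verdict = ("facilitative" if np.all(x > 0)
                   else "competitive" if np.all(x < 0) else "mixed")
        rows.append({
            "component": c, "median": med, "q1": q1, "q3": q3,
            "whisker_lo": float(inside.min()) if len(inside) else np.nan,
            "whisker_hi": float(inside.max()) if len(inside) else np.nan,
            "frac_positive": float(np.mean(x > 0)),
            "verdict": verdict})
    return pd.DataFrame(rows).set_index("component")
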