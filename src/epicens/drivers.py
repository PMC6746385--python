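"""Drivers of ensemble disagreement.

Relates per-cell agreement metrics to fertilizer application rate, climate
region and the ensemble's cultivar-distribution class.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "build_driver_table",
    "regress_metric_vs_n",
    "bin_by_fertilizer",
    "classify_cultivar_agreement",
]


def build_driver_table(world, cv_field, r_field, configs, water_regime: str) -> pd.DataFrame:
    """One row per cell: metrics plus the candidate drivers."""
    cultivar_by_config = {
        cfg.label: np.array(
            [
                cfg.cult.cultivar_for_cell(
                    str(world.climate_region[i]), world.country_dev[int(world.country_id[i])]
                )
                for i in range(world.n_cells)
            ]
        )
        for cfg in configs
    }
    classes = [
        classify_cultivar_agreement(
            {lab: ids[i] for lab, ids in cultivar_by_config.items()}
        )
        for i in range(world.n_cells)
    ]
    return pd.DataFrame(
        {
            "cell": np.arange(world.n_cells),
            "cv_av": np.asarray(cv_field.values, dtype=float),
            "median_r": np.asarray(r_field.values, dtype=float),
            "n_rate": world.n_rate,
            "climate_region": world.climate_region,
            "water_regime": water_regime,
            "cultivar_class": classes,
        }
    )


def regress_metric_vs_n(
    table: pd.DataFrame,
    metric: str = "cv_av",
    region: str | None = None,
    water: str | None = None,
    cap: float = 200.0,
) -> dict | None:
    """OLS of a metric on N rate over cells with n_rate <= cap.

    Returns {slope, intercept, r2, p, n} or None (with a warning) for
    strata with fewer than 3 usable cells.
    """
    sub = table
    if region is not None:
        sub = sub[sub["climate_region"] == region]
    if water is not None:
        sub = sub[sub["water_regime"] == water]
    sub = sub[sub["n_rate"] <= cap]
    x = sub["n_rate"].values.astype(float)
    y = sub[metric].values.astype(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0:
        warnings.warn(
            f"degenerate stratum (region={region}, water={water}): {len(x)} cells"
        )
        return None
    fit = stats.linregress(x, y)
    rsq = float(fit.rvalue**2)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": rsq if np.isfinite(rsq) else 0.0,  # constant metric
        "p": float(fit.pvalue),
        "n": int(len(x)),
    }


def bin_by_fertilizer(table: pd.DataFrame, metric: str = "cv_av",
                      bin_width: float = 50.0) -> pd.DataFrame:
    """Metric distribution per half-open fertilizer bin [k*w, (k+1)*w)."""
    if bin_width <= 0:
        raise DataError("bin_width must be > 0")
    sub = table[np.isfinite(table[metric].values.astype(float))]
    k = np.floor(sub["n_rate"].values / bin_width).astype(int)
    rows = []
    for b in sorted(set(k)):
        vals = sub[metric].values[k == b].astype(float)
        q1, q3 = np.percentile(vals, [25, 75])
        rows.append(
            {
                "bin_lo": b * bin_width,
                "bin_hi": (b + 1) * bin_width,
                "n_cells": len(vals),
                "median": float(np.median(vals)),
                "q1": float(q1),
                "q3": float(q3),
            }
        )
    return pd.DataFrame(rows)


def classify_cultivar_agreement(cultivar_by_config: dict[str, int]) -> str:
    """Class of the cultivar choices one cell receives across the ensemble.

    ``all_high`` if every member plants cultivar 1 or 2; ``dominant_low``
    if at least n_configs - 1 members plant cultivar 4; ``mixed``
    otherwise.
    """
    ids = list(cultivar_by_config.values())
    if not ids:
        raise DataError("no cultivar assignments supplied")
    if all(i in (1, 2) for i in ids):
        return "all_high"
    if sum(1 for i in ids if i == 4) >= max(len(ids) - 1, 1):
        return "dominant_low"
    return "mixed"
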