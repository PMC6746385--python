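"""Ensemble agreement metrics and their spatial summaries.

Per grid cell: the coefficient of variation across members' long-term mean
yields (cv_av), the CV of a mean-normalized time series (cv_t, analytically
identical to cv and kept for protocol fidelity), the mean error, and the
median pairwise Pearson correlation of yield time series.  Spatial
summaries report quantiles and fractions of cells exceeding significance
thresholds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .errors import DataError

__all__ = [
    "cv",
    "cv_t",
    "cv_av",
    "mean_error",
    "pairwise_r",
    "median_r",
    "median_r_field",
    "critical_r",
    "fraction_significant",
    "quantile_table",
]


def cv(series) -> float:
    """Coefficient of variation [%]: sample SD / mean * 100.

    Missing (NaN) entries are dropped.  Undefined (NaN) for zero mean or
    fewer than two values.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return float("nan")
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(x.std(ddof=1) / m * 100.0)


def cv_t(series) -> float:
    """CV [%] of the mean-normalized series.

    Scaling the series mean to 1 leaves SD/mean unchanged, so this equals
    :func:`cv` exactly; the separate name mirrors the analysis protocol.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return float("nan")
    m = x.mean()
    if m == 0:
        return float("nan")
    return cv(x / m)


def _metric_field(values: np.ndarray, cells, metric: str, **attrs) -> xr.DataArray:
    return xr.DataArray(
        values, dims=("cell",), coords={"cell": cells}, name=metric, attrs=attrs
    )


def cv_av(cube: xr.DataArray, cells=None, configs=None, years=None) -> xr.DataArray:
    """Per-cell CV across the configs' long-term mean yields.

    ``cube`` must have dims (config, year, cell) after any selection; the
    caller selects scenario/water beforehand.  ``years`` restricts the
    averaging window.
    """
    sub = cube
    if configs is not None:
        sub = sub.sel(config=list(configs))
    if cells is not None:
        sub = sub.sel(cell=list(cells))
    if years is not None:
        sub = sub.sel(year=list(years))
    extra = [d for d in sub.dims if d not in ("config", "year", "cell")]
    if extra:
        raise DataError(f"select dimensions {extra} before computing cv_av")
    if sub.sizes["config"] < 2:
        raise DataError("cv_av needs at least two configs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = sub.mean(dim="year", skipna=True)  # (config, cell)
    vals = np.array([cv(means.values[:, i]) for i in range(means.sizes["cell"])])
    return _metric_field(vals, means["cell"].values, "cv_av", units="%")


def mean_error(estimate_series, reference_series, relative: bool = False) -> float:
    """Mean error: mean(estimate - reference) over aligned years.

    With ``relative=True`` the result is divided by the reference mean
    (fraction of relative change).
    """
    est = np.asarray(estimate_series, dtype=float)
    ref = np.asarray(reference_series, dtype=float)
    if est.shape != ref.shape:
        raise DataError("estimate and reference series must be aligned")
    ok = np.isfinite(est) & np.isfinite(ref)
    if not ok.any():
        return float("nan")
    me = float(np.mean(est[ok] - ref[ok]))
    if relative:
        rm = float(np.mean(ref[ok]))
        if rm == 0:
            return float("nan")
        return me / rm
    return me


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return float("nan")
    xd = x - x.mean()
    yd = y - y.mean()
    den = np.sqrt(np.sum(xd * xd) * np.sum(yd * yd))
    if den == 0:
        return float("nan")
    return float(np.sum(xd * yd) / den)


def pairwise_r(cube: xr.DataArray, cell, window=None) -> np.ndarray:
    """Symmetric matrix of pairwise Pearson r over configs for one cell.

    ``cube`` has dims (config, year, cell) after selection; ``window`` is an
    iterable of years.  Zero-variance pairs are NaN.
    """
    sub = cube.sel(cell=cell)
    if window is not None:
        window = list(window)
        if len(window) < 3:
            raise DataError("correlation window must span at least 3 years")
        sub = sub.sel(year=window)
    vals = sub.transpose("config", "year").values
    k = vals.shape[0]
    mat = np.full((k, k), np.nan)
    for i in range(k):
        mat[i, i] = 1.0
        for j in range(i + 1, k):
            r = _pearson(vals[i], vals[j])
            mat[i, j] = mat[j, i] = r
    return mat


def median_r(matrix: np.ndarray) -> float:
    """Median of the off-diagonal upper triangle, NaN pairs excluded."""
    m = np.asarray(matrix, dtype=float)
    iu = np.triu_indices_from(m, k=1)
    vals = m[iu]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return float("nan")
    return float(np.median(vals))


def median_r_field(cube: xr.DataArray, window=None) -> xr.DataArray:
    """Per-cell median pairwise correlation field."""
    cells = cube["cell"].values
    vals = np.array([median_r(pairwise_r(cube, c, window)) for c in cells])
    return _metric_field(vals, cells, "median_r")


def critical_r(n: int, alpha: float) -> float:
    """Two-sided critical Pearson r: t*/sqrt(t*^2 + n - 2), df = n - 2."""
    if n < 4:
        raise DataError("need n >= 4")
    if not 0.0 < alpha < 1.0:
        raise DataError("alpha must be in (0, 1)")
    tstar = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(tstar / np.sqrt(tstar**2 + n - 2))


def fraction_significant(metric_field: xr.DataArray, n: int,
                         alpha_levels=(0.1, 0.01)) -> pd.DataFrame:
    """Percent of cells whose median r exceeds the critical r per level."""
    vals = np.asarray(metric_field.values, dtype=float)
    vals = vals[np.isfinite(vals)]
    rows = []
    if len(vals) == 0:
        warnings.warn("empty metric field; no cells to evaluate")
        return pd.DataFrame(columns=["alpha", "critical_r", "fraction_pct"])
    for alpha in alpha_levels:
        rc = critical_r(n, alpha)
        rows.append(
            {
                "alpha": alpha,
                "critical_r": rc,
                "fraction_pct": float(np.mean(vals > rc) * 100.0),
            }
        )
    return pd.DataFrame(rows)


def quantile_table(metric_field: xr.DataArray,
                   probs=(0.0, 0.25, 0.5, 0.75, 0.9, 0.95, 1.0)) -> pd.DataFrame:
    """Empirical quantiles (linear interpolation, numpy default / type 7)."""
    vals = np.asarray(metric_field.values, dtype=float)
    vals = vals[np.isfinite(vals)]
    qs = np.quantile(vals, probs) if len(vals) else np.full(len(probs), np.nan)
    return pd.DataFrame({"prob": list(probs), "value": qs})
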