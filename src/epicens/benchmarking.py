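"""Benchmarking simulated national yields against reported series.

Reported yields are detrended by subtracting a centered 5-year moving mean
and recombining the anomalies with the mean over a reference window (the
simulated series are stationary by design and are not detrended).
Countries with FAO-estimated data or strongly fluctuating harvested areas
are excluded.  Each configuration is scored per country by the Pearson
correlation and the mean error; "best" is the configuration with the
highest r (ties broken by lower |ME|, then label order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .metrics import _pearson, critical_r, mean_error

__all__ = [
    "BenchmarkResult",
    "detrend_reported",
    "filter_countries",
    "benchmark",
    "multi_model_mean_benchmark",
    "top_producers",
]


@dataclass
class BenchmarkResult:
    country_id: int
    config: str
    r: float
    me: float
    significant: bool
    best_flag: bool


def detrend_reported(series, window: int = 5, ref_window=None,
                     mode: str = "additive") -> np.ndarray:
    """Remove the technology trend from a reported yield series.

    anomaly_t = y_t - movmean(y, window)_t with a centered window shrunk at
    the edges.  The anomalies are recombined with the mean over
    ``ref_window`` (index positions; defaults to the central 7 entries):
    additively by default, multiplicatively (anomaly ratio times reference
    mean) as an option.
    """
    y = np.asarray(series, dtype=float)
    if np.all(~np.isfinite(y)):
        raise DataError("all-missing series")
    if len(y) < window:
        raise DataError(f"series shorter than the {window}-year window")
    mov = (
        pd.Series(y).rolling(window=window, center=True, min_periods=1).mean().values
    )
    if ref_window is None:
        mid = len(y) // 2
        lo = max(mid - 3, 0)
        ref_window = range(lo, min(lo + 7, len(y)))
    ref_mean = float(np.nanmean(y[list(ref_window)]))
    if mode == "additive":
        return (y - mov) + ref_mean
    if mode == "multiplicative":
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(mov != 0, y / mov, np.nan)
        return ratio * ref_mean
    raise DataError(f"unknown detrending mode {mode!r}")


def filter_countries(reported: dict, max_fluctuation: float = 1.0):
    """Apply the benchmark country filters.

    Drops countries whose data carry the FAO-estimated flag (rule a) and
    countries whose harvested area fluctuates by more than
    ``max_fluctuation`` relative to its minimum (rule b; a zero minimum
    counts as infinite fluctuation).  Returns (retained ids, drop reasons).
    """
    retained = []
    dropped: dict[int, str] = {}
    for cid, series in sorted(reported.items()):
        if series.fao_estimated_flag:
            dropped[cid] = "fao_estimated"
            continue
        area = np.asarray(series.harvested_area, dtype=float)
        amin, amax = float(np.min(area)), float(np.max(area))
        if amin <= 0 or (amax - amin) / amin > max_fluctuation:
            dropped[cid] = "area_fluctuation"
            continue
        retained.append(cid)
    return retained, dropped


def _align(years_a, vals_a, years_b, vals_b):
    common, ia, ib = np.intersect1d(years_a, years_b, return_indices=True)
    return common, np.asarray(vals_a, dtype=float)[ia], np.asarray(vals_b, dtype=float)[ib]


def benchmark(
    national: pd.DataFrame,
    reported_detrended: dict[int, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.1,
):
    """Score each config against detrended reported national series.

    ``national`` is a tidy frame (country_id, config, year, yield) for one
    scenario; ``reported_detrended`` maps country id to (years, values).
    Returns (list of :class:`BenchmarkResult`, counts table per config with
    columns best / all_significant).
    """
    configs = sorted(national["config"].unique())
    if len(configs) < 1:
        raise DataError("need at least one config")
    results: list[BenchmarkResult] = []
    for cid, (rep_years, rep_vals) in sorted(reported_detrended.items()):
        scored = []
        for cfg in configs:
            sub = national[(national["country_id"] == cid) & (national["config"] == cfg)]
            if sub.empty:
                continue
            yrs, est, ref = _align(sub["year"].values, sub["yield"].values,
                                   rep_years, rep_vals)
            ok = np.isfinite(est) & np.isfinite(ref)
            if ok.sum() < 3:
                continue
            r = _pearson(est[ok], ref[ok])
            me = mean_error(est[ok], ref[ok])
            n = int(ok.sum())
            sig = bool(np.isfinite(r) and r > 0 and r > critical_r(max(n, 4), alpha))
            scored.append(BenchmarkResult(cid, cfg, r, me, sig, False))
        if not scored:
            continue
        # best: highest r, then lower |ME|, then label order
        ranked = sorted(
            scored,
            key=lambda b: (
                -(b.r if np.isfinite(b.r) else -np.inf),
                abs(b.me) if np.isfinite(b.me) else np.inf,
                b.config,
            ),
        )
        ranked[0].best_flag = True
        results.extend(scored)

    counts = pd.DataFrame(
        [
            {
                "config": cfg,
                "best": sum(1 for b in results if b.config == cfg and b.best_flag),
                "all_significant": sum(
                    1 for b in results if b.config == cfg and b.significant
                ),
            }
            for cfg in configs
        ]
    )
    return results, counts


def multi_model_mean_benchmark(
    national: pd.DataFrame,
    reported_detrended: dict[int, tuple[np.ndarray, np.ndarray]],
    subsets: dict[str, list[str]],
) -> pd.DataFrame:
    """Benchmark unweighted multi-model-mean series per config subset.

    Returns a tidy frame (subset, country_id, r, me).
    """
    rows = []
    for name, cfgs in subsets.items():
        if not cfgs:
            raise DataError(f"subset {name!r} is empty")
        sub = national[national["config"].isin(cfgs)]
        mmm = (
            sub.groupby(["country_id", "year"])["yield"].mean().reset_index()
        )
        for cid, (rep_years, rep_vals) in sorted(reported_detrended.items()):
            s = mmm[mmm["country_id"] == cid]
            if s.empty:
                continue
            yrs, est, ref = _align(s["year"].values, s["yield"].values,
                                   rep_years, rep_vals)
            ok = np.isfinite(est) & np.isfinite(ref)
            if ok.sum() < 3:
                continue
            rows.append(
                {
                    "subset": name,
                    "country_id": cid,
                    "r": _pearson(est[ok], ref[ok]),
                    "me": mean_error(est[ok], ref[ok]),
                }
            )
    return pd.DataFrame(rows)


def top_producers(reported: dict, k: int = 10) -> list[int]:
    """Top-k countries by mean production; ties broken by country id."""
    scored = sorted(
        reported.items(),
        key=lambda kv: (-float(np.mean(kv[1].production)), kv[0]),
    )
    return [cid for cid, _ in scored[:k]]
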