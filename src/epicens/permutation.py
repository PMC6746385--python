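"""Factorial permutation of the six setup domains between two presets.

Every combination of the six binary domain choices (2^6 = 64) is
materialized by splicing domain blocks from an "e" preset and a "g" preset.
Effects are attributed per domain from the 32 paired differences obtained
by toggling that domain while holding the other five fixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .config import DOMAINS, ConfigurationError, SetupConfig
from .errors import DataError
from .metrics import _pearson, cv_t, mean_error
from .simulator import run_ensemble

__all__ = [
    "selection_label",
    "enumerate_selections",
    "enumerate_configs",
    "run_permutation",
    "config_correlation_matrix",
    "attribute_domains",
    "DomainAttribution",
]


def selection_label(selection: dict[str, str]) -> str:
    """Canonical 6-letter label, domain order cult..manage (e.g. 'eggeeg')."""
    return "".join(selection[d] for d in DOMAINS)


def enumerate_selections() -> list[dict[str, str]]:
    """All 64 domain selections in canonical (binary counting) order.

    ``cult`` is the most significant bit; 'e' = 0, 'g' = 1.
    """
    out = []
    for bits in itertools.product("eg", repeat=len(DOMAINS)):
        out.append(dict(zip(DOMAINS, bits)))
    return out


def enumerate_configs(preset_e: SetupConfig, preset_g: SetupConfig) -> list[SetupConfig]:
    """Materialize the 64 spliced configurations.

    Each config's label is its 6-letter selection string.  Splicing is
    exact: a domain set to 'e' carries a deep copy of the e-preset block.
    """
    for preset in (preset_e, preset_g):
        for dom in DOMAINS:
            if getattr(preset, dom, None) is None:
                raise ConfigurationError(f"preset {preset.label!r} missing domain {dom}")
    configs = []
    for sel in enumerate_selections():
        cfg = preset_e
        label = selection_label(sel)
        new = SetupConfig(label=label)
        for dom in DOMAINS:
            source = preset_e if sel[dom] == "e" else preset_g
            new = new.replace_domain(dom, getattr(source, dom))
        configs.append(new)
    return configs


def run_permutation(
    world,
    configs: list[SetupConfig],
    scenario: str = "fullharm",
    water: str = "rainfed",
) -> tuple[xr.DataArray, pd.DataFrame]:
    """Run all spliced configs and summarize against the all-e baseline.

    Returns (yield cube over the 64 configs, summary frame with the global
    area-weighted mean yield, CV_t of the global series, and the mean error
    relative to the all-'e' baseline per config).
    """
    cube = run_ensemble(world, configs, scenarios=[scenario], water_regimes=[water])
    # global series over complete years only, weighted by total harvested
    # area (the evaluation focuses on a single water regime)
    valid_years = [int(y) for y in cube["year"].values if y >= 2]
    series = {}
    for cfg in configs:
        sub = cube.sel(config=cfg.label, scenario=scenario, water=water,
                       year=valid_years)
        w = world.area_rainfed + world.area_irrigated
        vals = sub.transpose("year", "cell").values
        valid = np.isfinite(vals)
        num = np.nansum(np.where(valid, vals, 0.0) * w[None, :], axis=1)
        den = np.sum(np.where(valid, w[None, :], 0.0), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            series[cfg.label] = np.where(den > 0, num / den, np.nan)
    baseline_label = "e" * len(DOMAINS)
    base = series.get(baseline_label)
    rows = []
    for cfg in configs:
        s = series[cfg.label]
        rows.append(
            {
                "config": cfg.label,
                "mean_yield": float(np.nanmean(s)),
                "cv_t": cv_t(s),
                "relative_me": (
                    mean_error(s, base, relative=True) if base is not None else np.nan
                ),
            }
        )
    summary = pd.DataFrame(rows)
    summary.attrs["global_series"] = series
    return cube, summary


def config_correlation_matrix(series_by_config: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson r among per-config global yield series."""
    labels = list(series_by_config)
    first = np.asarray(series_by_config[labels[0]], dtype=float)
    if np.sum(np.isfinite(first)) < 3:
        raise DataError("need at least 3 years for the correlation matrix")
    k = len(labels)
    mat = np.full((k, k), np.nan)
    for i in range(k):
        mat[i, i] = 1.0
        xi = np.asarray(series_by_config[labels[i]], dtype=float)
        for j in range(i + 1, k):
            r = _pearson(xi, np.asarray(series_by_config[labels[j]], dtype=float))
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=labels, columns=labels)


@dataclass
class DomainAttribution:
    """Paired effect distributions per setup domain.

    ``pairs`` maps each domain to its 32 differences metric(g-side) -
    metric(e-side) with the other five domains held fixed; ``summary`` has
    one row per domain (mean, median, IQR, sign counts).
    """

    pairs: dict[str, np.ndarray]
    summary: pd.DataFrame


def attribute_domains(metric_by_config: dict[str, float]) -> DomainAttribution:
    """Attribute a per-config scalar metric to the six setup domains.

    ``metric_by_config`` maps every 6-letter selection label to a metric
    value; all 64 labels must be present.
    """
    labels = set(metric_by_config)
    expected = {selection_label(s) for s in enumerate_selections()}
    if labels != expected:
        missing = sorted(expected - labels)[:3]
        raise DataError(f"attribution needs all 64 configs (missing e.g. {missing})")
    pairs: dict[str, np.ndarray] = {}
    rows = []
    for k, dom in enumerate(DOMAINS):
        diffs = []
        for sel in enumerate_selections():
            if sel[dom] != "e":
                continue
            lab_e = selection_label(sel)
            sel_g = dict(sel)
            sel_g[dom] = "g"
            lab_g = selection_label(sel_g)
            diffs.append(metric_by_config[lab_g] - metric_by_config[lab_e])
        arr = np.asarray(diffs, dtype=float)
        assert len(arr) == 32
        pairs[dom] = arr
        q1, q3 = np.nanpercentile(arr, [25, 75])
        rows.append(
            {
                "domain": dom,
                "mean": float(np.nanmean(arr)),
                "median": float(np.nanmedian(arr)),
                "iqr": float(q3 - q1),
                "n_positive": int(np.sum(arr > 0)),
                "n_negative": int(np.sum(arr < 0)),
            }
        )
    return DomainAttribution(pairs=pairs, summary=pd.DataFrame(rows))
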