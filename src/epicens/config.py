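"""Model setup configurations.

A :class:`SetupConfig` describes one ensemble member as six independent
blocks of parameters and method switches ("setup domains"): cultivar
distribution (``cult``), soil data (``soil_d``), soil handling (``soil_p``),
nutrient-cycling coefficients (``coeff_n``), hydrologic coefficients
(``coeff_w``) and crop management (``manage``).  Blocks can be spliced
between configurations, which is what the factorial permutation experiment
does.

Five presets are shipped (:data:`PRESETS`): ``boku``, ``iiasa``, ``tamu``,
``gepic`` and ``pepic``.  The pair used by the permutation experiment is
exposed as ``preset_e`` (= ``iiasa``) and ``preset_g`` (= ``gepic``).
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import yaml

from .errors import EpicensError

__all__ = [
    "CultivarParams",
    "CultBlock",
    "SoilDBlock",
    "SoilPBlock",
    "CoeffNBlock",
    "CoeffWBlock",
    "ManageBlock",
    "SetupConfig",
    "ConfigurationError",
    "scurve_coefficients",
    "scurve_from_anchors",
    "default_cultivars",
    "make_preset",
    "preset_labels",
    "PRESETS",
    "DOMAINS",
    "config_to_yaml",
    "config_from_yaml",
]

DOMAINS = ("cult", "soil_d", "soil_p", "coeff_n", "coeff_w", "manage")


class ConfigurationError(EpicensError, ValueError):
    """Raised for invalid or incomplete setup configurations."""


@dataclass(frozen=True)
class CultivarParams:
    """Yield-formation parameters of one cultivar.

    ``hi_min``/``hi_max`` bound the realized harvest index, ``t_base`` and
    ``t_opt`` define the growing-degree accumulation and the temperature
    stress ramp, ``rue`` is radiation-use efficiency in g biomass per MJ
    intercepted radiation.
    """

    cultivar_id: int
    hi_min: float
    hi_max: float
    t_base: float
    t_opt: float
    rue: float

    def __post_init__(self) -> None:
        if not (0.0 < self.hi_min <= self.hi_max < 1.0):
            raise ConfigurationError(
                f"cultivar {self.cultivar_id}: need 0 < hi_min <= hi_max < 1"
            )
        if not self.t_base < self.t_opt:
            raise ConfigurationError(
                f"cultivar {self.cultivar_id}: need t_base < t_opt"
            )


def default_cultivars() -> dict[int, CultivarParams]:
    """The four shipped maize cultivars.

    1 and 2 are high-yielding varieties, 3 an adapted cool-climate variety,
    4 a low-yielding drought-sensitive variety.  Values are configurable
    placeholders, not calibrated ground truth.
    """
    return {
        1: CultivarParams(1, hi_min=0.30, hi_max=0.55, t_base=8.0, t_opt=25.0, rue=4.0),
        2: CultivarParams(2, hi_min=0.30, hi_max=0.52, t_base=10.0, t_opt=28.0, rue=3.8),
        3: CultivarParams(3, hi_min=0.28, hi_max=0.50, t_base=6.0, t_opt=22.0, rue=3.4),
        4: CultivarParams(4, hi_min=0.14, hi_max=0.46, t_base=8.0, t_opt=26.0, rue=3.5),
    }


@dataclass
class CultBlock:
    """Cultivar choice and geographic distribution rule.

    rule:
      - ``all_high``       — cultivar 1 everywhere
      - ``by_region``      — one cultivar per climate region
                             (temperate→1, tropical→2, cold→3, arid→4)
      - ``by_development`` — cultivar 1 where the country development score
                             >= ``dev_threshold``, cultivar 4 elsewhere
    """

    rule: str = "all_high"
    dev_threshold: float = 0.8
    cultivars: dict[int, CultivarParams] = field(default_factory=default_cultivars)
    # fraction of the growing season after which water stress feeds the
    # harvest-index reduction
    hi_sensitive_fraction: float = 0.50

    def cultivar_for_cell(self, climate_region: str, country_dev: float) -> int:
        if self.rule == "all_high":
            return 1
        if self.rule == "by_region":
            return {"temperate": 1, "tropical": 2, "cold": 3, "arid": 4}[climate_region]
        if self.rule == "by_development":
            return 1 if country_dev >= self.dev_threshold else 4
        raise ConfigurationError(f"unknown cultivar rule {self.rule!r}")


@dataclass
class SoilDBlock:
    """Source of soil hydraulic parameters and vertical discretization.

    ``input_pedotransfer_A`` takes FC/WP/K_sat as provided in the input
    soil data (higher FC, lower WP); ``online_pedotransfer_B`` re-estimates
    them with a fixed alternative pedotransfer rule (lower FC, higher WP,
    higher conductivity).  ``n_layers`` merges adjacent input layers when
    smaller than the input layer count.
    """

    hydraulic_source: str = "input_pedotransfer_A"
    n_layers: int = 4

    def __post_init__(self) -> None:
        if self.hydraulic_source not in ("input_pedotransfer_A", "online_pedotransfer_B"):
            raise ConfigurationError(f"unknown hydraulic source {self.hydraulic_source!r}")
        if self.n_layers < 1:
            raise ConfigurationError("n_layers must be >= 1")


@dataclass
class SoilPBlock:
    """Soil profile handling and simulation continuity.

    ``static`` re-initializes texture/organic pools every year (water and
    mineral nutrients carry over); ``dynamic`` carries all state over and
    erodes the top layer at ``topsoil_loss_rate`` per year.  ``decadal``
    continuity resets the soil at each decade boundary and pre-runs
    ``spinup_years`` unscored years.
    """

    handling: str = "static"
    continuity: str = "transient"
    spinup_years: int = 0
    topsoil_loss_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.handling not in ("static", "dynamic"):
            raise ConfigurationError(f"unknown soil handling {self.handling!r}")
        if self.continuity not in ("transient", "decadal"):
            raise ConfigurationError(f"unknown continuity {self.continuity!r}")
        if not 0.0 <= self.topsoil_loss_rate <= 0.05:
            raise ConfigurationError("topsoil_loss_rate must be in [0, 0.05]")
        if self.spinup_years < 0:
            raise ConfigurationError("spinup_years must be >= 0")


@dataclass
class CoeffNBlock:
    """Organic matter and nutrient cycling coefficients."""

    microbial_decay: float = 1.0
    n_volatilization: float = 0.005
    denitrification_rate: float = 0.005
    oxygen_coeff: float = 0.90
    # sigmoid anchors: ((x1, y1), (x2, y2)); moisture x = relative wetness,
    # oxygen x = layer mid depth in mm.  y values are fractions.
    moisture_fn_anchors: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (0.2, 0.05),
        (0.8, 0.90),
    )
    oxygen_fn_anchors: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (200.0, 0.05),
        (500.0, 0.90),
    )


@dataclass
class CoeffWBlock:
    """Hydrologic coefficients: PET and runoff/evaporation parameters."""

    hargreaves_lin: float = 0.0023
    hargreaves_exp: float = 0.5
    soil_evap_coeff: float = 2.5
    cn_index_coeff: float = 1.0


@dataclass
class ManageBlock:
    """Crop management: irrigation/fertilization strategy and agronomy."""

    irrigation_trigger: float = 0.90
    max_single_irrigation: float = 500.0
    fert_trigger: float = 0.90
    fixed_timing: bool = False
    fert_dose: float = 30.0
    row_spacing_factor: float = 1.0
    residue_removal: float = 0.0
    # default-scenario assumptions of the modelling group
    default_n_scale: float = 1.0
    default_season_shift: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.irrigation_trigger <= 1.0:
            raise ConfigurationError("irrigation_trigger must be in (0, 1]")
        if not 0.0 < self.fert_trigger <= 1.0:
            raise ConfigurationError("fert_trigger must be in (0, 1]")
        if self.max_single_irrigation <= 0:
            raise ConfigurationError("max_single_irrigation must be > 0")


@dataclass
class SetupConfig:
    """One ensemble member: a label plus the six setup-domain blocks."""

    label: str
    cult: CultBlock = field(default_factory=CultBlock)
    soil_d: SoilDBlock = field(default_factory=SoilDBlock)
    soil_p: SoilPBlock = field(default_factory=SoilPBlock)
    coeff_n: CoeffNBlock = field(default_factory=CoeffNBlock)
    coeff_w: CoeffWBlock = field(default_factory=CoeffWBlock)
    manage: ManageBlock = field(default_factory=ManageBlock)

    def replace_domain(self, domain: str, block) -> "SetupConfig":
        """Return a copy of this config with one domain block swapped."""
        if domain not in DOMAINS:
            raise ConfigurationError(f"unknown setup domain {domain!r}")
        new = copy.deepcopy(self)
        setattr(new, domain, copy.deepcopy(block))
        return new


# ---------------------------------------------------------------------------
# two-anchor sigmoid (EPIC S-curve family)

def scurve_coefficients(anchor1, anchor2):
    """Solve f(x) = x / (x + exp(b1 - b2*x)) through two anchor points.

    Anchors are (x, y) pairs with x1 < x2, 0 < y1 < y2 < 1 and x > 0.
    Returns (b1, b2).
    """
    (x1, y1), (x2, y2) = anchor1, anchor2
    if not (x1 < x2) or not (0.0 < y1 < y2 < 1.0) or x1 <= 0:
        raise ConfigurationError(f"degenerate sigmoid anchors {anchor1}, {anchor2}")
    c1 = np.log(x1 * (1.0 - y1) / y1)
    c2 = np.log(x2 * (1.0 - y2) / y2)
    b2 = (c1 - c2) / (x2 - x1)
    b1 = c1 + b2 * x1
    return float(b1), float(b2)


def scurve_from_anchors(x, anchor1, anchor2):
    """Evaluate the two-anchor sigmoid at ``x`` (scalar or array).

    Monotone increasing, bounded in (0, 1), passes through both anchors.
    """
    b1, b2 = scurve_coefficients(anchor1, anchor2)
    x = np.asarray(x, dtype=float)
    xp = np.maximum(x, 1e-12)
    out = xp / (xp + np.exp(b1 - b2 * xp))
    out = np.where(x <= 0, 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# presets

def _boku() -> SetupConfig:
    return SetupConfig(
        label="boku",
        cult=CultBlock(rule="all_high"),
        soil_d=SoilDBlock(hydraulic_source="online_pedotransfer_B", n_layers=4),
        soil_p=SoilPBlock(handling="static", continuity="transient"),
        coeff_n=CoeffNBlock(
            microbial_decay=1.0, n_volatilization=0.005,
            denitrification_rate=0.0025, oxygen_coeff=0.90,
            oxygen_fn_anchors=((200.0, 0.05), (500.0, 0.90)),
        ),
        coeff_w=CoeffWBlock(hargreaves_lin=0.0023, hargreaves_exp=0.5,
                            soil_evap_coeff=2.5, cn_index_coeff=1.5),
        manage=ManageBlock(irrigation_trigger=0.90, max_single_irrigation=50.0,
                           fert_trigger=0.90, default_n_scale=1.5,
                           default_season_shift=-10),
    )


def _iiasa() -> SetupConfig:
    return SetupConfig(
        label="iiasa",
        cult=CultBlock(rule="by_region"),
        soil_d=SoilDBlock(hydraulic_source="input_pedotransfer_A", n_layers=4),
        soil_p=SoilPBlock(handling="static", continuity="transient"),
        coeff_n=CoeffNBlock(
            microbial_decay=0.8, n_volatilization=0.700,
            denitrification_rate=0.005, oxygen_coeff=0.99,
            oxygen_fn_anchors=((400.0, 0.05), (600.0, 0.90)),
        ),
        coeff_w=CoeffWBlock(hargreaves_lin=0.0023, hargreaves_exp=0.6,
                            soil_evap_coeff=1.5, cn_index_coeff=1.2),
        manage=ManageBlock(irrigation_trigger=0.80, max_single_irrigation=500.0,
                           fert_trigger=0.80, default_n_scale=1.0,
                           default_season_shift=0),
    )


def _tamu() -> SetupConfig:
    return SetupConfig(
        label="tamu",
        cult=CultBlock(rule="by_development", dev_threshold=0.35,
                       hi_sensitive_fraction=0.45),
        soil_d=SoilDBlock(hydraulic_source="online_pedotransfer_B", n_layers=4),
        soil_p=SoilPBlock(handling="dynamic", continuity="transient",
                          topsoil_loss_rate=0.002),
        coeff_n=CoeffNBlock(
            microbial_decay=1.0, n_volatilization=0.030,
            denitrification_rate=0.005, oxygen_coeff=0.80,
            oxygen_fn_anchors=((200.0, 0.05), (500.0, 0.90)),
        ),
        coeff_w=CoeffWBlock(hargreaves_lin=0.0023, hargreaves_exp=0.5,
                            soil_evap_coeff=2.5, cn_index_coeff=1.0),
        # default == fullharm for this preset (first set up in-project)
        manage=ManageBlock(irrigation_trigger=0.99, max_single_irrigation=100.0,
                           fert_trigger=0.99, default_n_scale=1.0,
                           default_season_shift=0),
    )


def _gepic() -> SetupConfig:
    return SetupConfig(
        label="gepic",
        cult=CultBlock(rule="by_development", dev_threshold=0.8),
        soil_d=SoilDBlock(hydraulic_source="online_pedotransfer_B", n_layers=2),
        soil_p=SoilPBlock(handling="dynamic", continuity="decadal",
                          spinup_years=5, topsoil_loss_rate=0.003),
        coeff_n=CoeffNBlock(
            microbial_decay=1.0, n_volatilization=0.005,
            denitrification_rate=0.005, oxygen_coeff=0.90,
            oxygen_fn_anchors=((200.0, 0.05), (500.0, 0.90)),
        ),
        coeff_w=CoeffWBlock(hargreaves_lin=0.0032, hargreaves_exp=0.5,
                            soil_evap_coeff=2.5, cn_index_coeff=0.5),
        # narrower row spacing raises the potential biomass estimate
        manage=ManageBlock(irrigation_trigger=0.90, max_single_irrigation=1000.0,
                           fert_trigger=0.90, row_spacing_factor=1.08,
                           default_n_scale=0.7, default_season_shift=10),
    )


def _pepic() -> SetupConfig:
    return SetupConfig(
        label="pepic",
        cult=CultBlock(rule="by_development", dev_threshold=0.8),
        soil_d=SoilDBlock(hydraulic_source="online_pedotransfer_B", n_layers=4),
        soil_p=SoilPBlock(handling="dynamic", continuity="transient",
                          topsoil_loss_rate=0.002),
        coeff_n=CoeffNBlock(
            microbial_decay=1.0, n_volatilization=0.300,
            denitrification_rate=0.005, oxygen_coeff=0.90,
            oxygen_fn_anchors=((200.0, 0.05), (500.0, 0.90)),
        ),
        coeff_w=CoeffWBlock(hargreaves_lin=0.0023, hargreaves_exp=0.5,
                            soil_evap_coeff=1.5, cn_index_coeff=1.0),
        # rigid fertilizer timing: full annual rate at planting, no trigger
        manage=ManageBlock(irrigation_trigger=0.90, max_single_irrigation=500.0,
                           fixed_timing=True, default_n_scale=0.9,
                           default_season_shift=-5),
    )


PRESETS = {
    "boku": _boku,
    "iiasa": _iiasa,
    "tamu": _tamu,
    "gepic": _gepic,
    "pepic": _pepic,
}


def preset_labels() -> list[str]:
    return list(PRESETS)


def make_preset(name: str) -> SetupConfig:
    """Build a fresh copy of a shipped preset by name.

    ``eIIASA``/``gGEPIC`` are accepted aliases for the permutation pair.
    """
    alias = {"eiiasa": "iiasa", "ggepic": "gepic"}
    key = alias.get(name.lower(), name.lower())
    if key not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {list(PRESETS)}")
    return PRESETS[key]()


# ---------------------------------------------------------------------------
# YAML round trip (structured-text config)

def _config_to_dict(config: SetupConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cult"]["cultivars"] = {
        int(k): dataclasses.asdict(v) for k, v in config.cult.cultivars.items()
    }
    return d


def config_to_yaml(config: SetupConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def config_from_yaml(path) -> SetupConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    try:
        cult_d = dict(d["cult"])
        cult_d["cultivars"] = {
            int(k): CultivarParams(**v) for k, v in cult_d["cultivars"].items()
        }

        def _anchors(block):
            for key in ("moisture_fn_anchors", "oxygen_fn_anchors"):
                block[key] = tuple(tuple(p) for p in block[key])
            return block

        return SetupConfig(
            label=d["label"],
            cult=CultBlock(**cult_d),
            soil_d=SoilDBlock(**d["soil_d"]),
            soil_p=SoilPBlock(**d["soil_p"]),
            coeff_n=CoeffNBlock(**_anchors(dict(d["coeff_n"]))),
            coeff_w=CoeffWBlock(**d["coeff_w"]),
            manage=ManageBlock(**d["manage"]),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"incomplete setup config in {path}: {exc}") from exc
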