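"""Scenario configuration and default parameter sets.

All tunable parameters of the simulator live here, grouped by sub-model:
landscape initialization, crop economics, household finances, social
network / learning, vegetation carbon, and price dynamics.  A
:class:`ScenarioConfig` bundles one full parameterization of a run and can
be constructed from one of the six named scenario presets (``C0``, ``CI``,
``CIL``, ``H0``, ``HI``, ``HIL``) that cross two price regimes with three
inefficiency/learning settings.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

# Land-use codes used across all grid layers and exports.
FOREST = 0
OIL_PALM = 1
RUBBER = 2

CROP_NAMES = {OIL_PALM: "oil_palm", RUBBER: "rubber"}
CROP_CODES = {v: k for k, v in CROP_NAMES.items()}

#: Area of one grid cell in hectares (50 m x 50 m).
CELL_AREA_HA = 0.25
#: Edge length of one grid cell in meters.
CELL_SIZE_M = 50.0


@dataclass(frozen=True)
class CropParams:
    """Biophysical and cost parameters for one perennial crop.

    Yields follow a piecewise-linear age profile: zero while immature,
    a linear rise to a plateau, then a decline towards ``max_age`` where
    the plantation must be replanted.  Annual input costs are split into
    labor (hours x wage) and technical input (kg x unit price); immature
    stands require a reduced share of the mature input schedule.  The
    capital fixed in a plantation equals the establishment cost at
    planting and depreciates linearly to zero over ``max_age``.
    """

    name: str
    immature_years: int
    max_age: int
    #: Knot ages (years) of the piecewise-linear potential-yield profile.
    yield_knots_age: tuple
    #: Potential yield (t/ha/yr) at each knot age.
    yield_knots_value: tuple
    establishment_cost: float  # USD/ha, paid in the (re)planting year
    labor_hours_mature: float  # h/ha/yr on a mature stand
    labor_wage: float  # USD/h
    tinput_kg_mature: float  # kg/ha/yr on a mature stand
    tinput_price: float  # USD/kg
    immature_input_factor: float = 0.5  # input share applied while immature
    land_rent: float = 48.0  # USD/ha/yr
    capital_interest: float = 0.10  # fraction of capital stock per year


def default_oil_palm() -> CropParams:
    return CropParams(
        name="oil_palm",
        immature_years=3,
        max_age=25,
        yield_knots_age=(2, 9, 18, 25),
        yield_knots_value=(0.0, 22.0, 22.0, 8.0),
        establishment_cost=1200.0,
        labor_hours_mature=560.0,
        labor_wage=1.5,
        tinput_kg_mature=240.0,
        tinput_price=1.5,
    )


def default_rubber() -> CropParams:
    return CropParams(
        name="rubber",
        immature_years=6,
        max_age=40,
        yield_knots_age=(5, 12, 30, 40),
        yield_knots_value=(0.0, 1.8, 1.8, 0.4),
        establishment_cost=1000.0,
        labor_hours_mature=280.0,
        labor_wage=1.5,
        tinput_kg_mature=120.0,
        tinput_price=1.5,
    )


@dataclass(frozen=True)
class HouseholdParams:
    """Financial behaviour shared by all households.

    Consumption I (``subsistence + wealth_rate * wealth``) is deducted
    before the land-use decision; Consumption II (``profit_rate *
    positive net cash flow``) after production.  A household whose debts
    persist for ``freeze_threshold`` consecutive years becomes frozen and
    drops out of all further activity and reporting.
    """

    subsistence: float = 300.0  # USD/yr, fixed part of Consumption I
    wealth_rate: float = 0.05  # share of positive wealth consumed per year
    profit_rate: float = 0.20  # share of positive net cash flow (Consumption II)
    discount_rate: float = 0.10  # per year, used in expected NPV
    planning_horizon: int = 10  # years looked ahead in the land-use decision
    freeze_threshold: int = 20  # consecutive debt years before freezing
    external_income: float = 0.0  # USD/yr income outside agriculture


@dataclass(frozen=True)
class InitConfig:
    """Parameters of the synthetic landscape generator."""

    width: int = 100
    height: int = 100
    n_households: int = 100
    agri_fraction_target: float = 0.5
    household_area_mean: float = 50.0  # cells (12.5 ha)
    household_area_sd: float = 15.0  # cells
    household_area_min: int = 8
    field_size_min: int = 4
    field_size_max: int = 16
    max_fields_per_household: int = 4
    initial_rubber_share: float = 0.5
    wealth_lognormal_mu: float = math.log(2000.0)  # log-USD
    wealth_lognormal_sigma: float = 0.8
    ineff_gamma_shape: float = 2.0
    ineff_gamma_scale: float = 0.3
    age_range_op: tuple = (1, 20)
    age_range_rubber: tuple = (1, 25)
    road_spacing: int = 20


@dataclass(frozen=True)
class NetworkConfig:
    """Social-network construction and learning parameters."""

    mode: str = "stochastic"  # {deterministic, stochastic}
    #: Decay rate of the negative-exponential link kernel, per meter.
    lambda_per_m: float = 1.0 / 1500.0
    #: Maximum road distance at which households can be linked, meters.
    d_cap_m: float = 5000.0
    #: Annual partial-adjustment rate towards the network mean inefficiency.
    alpha: float = 0.25


@dataclass(frozen=True)
class CarbonParams:
    """Saturating-growth vegetation carbon model, per land use.

    Plantation stock is ``C_max * (1 - exp(-k * age))`` in t C/ha;
    secondary forest carries a constant stock.
    """

    c_max_op: float = 40.0
    k_op: float = 0.18
    c_max_rubber: float = 55.0
    k_rubber: float = 0.12
    forest_constant: float = 150.0


@dataclass(frozen=True)
class PriceConfig:
    """Exogenous, landscape-wide output price regime."""

    mode: str = "constant"  # {constant, series, random_walk}
    price_rubber: float = 1100.0  # USD/t dry rubber (constant mode / walk start)
    price_op: float = 90.0  # USD/t fresh fruit bunches
    sigma: float = 0.05  # log-scale SD of the random walk
    series_path: Optional[str] = None  # CSV path; None -> bundled series


#: Scenario presets: price regime x inefficiency/learning setting.
SCENARIOS = {
    "C0": {"price_mode": "constant", "inefficiency": False, "learning": False},
    "CI": {"price_mode": "constant", "inefficiency": True, "learning": False},
    "CIL": {"price_mode": "constant", "inefficiency": True, "learning": True},
    "H0": {"price_mode": "series", "inefficiency": False, "learning": False},
    "HI": {"price_mode": "series", "inefficiency": True, "learning": False},
    "HIL": {"price_mode": "series", "inefficiency": True, "learning": True},
}


@dataclass
class ScenarioConfig:
    """Complete parameterization of one simulation experiment."""

    scenario_id: Optional[str] = None
    years: int = 50
    n_replicates: int = 20
    seed: int = 0
    inefficiency: bool = False
    learning: bool = False
    init: InitConfig = field(default_factory=InitConfig)
    oil_palm: CropParams = field(default_factory=default_oil_palm)
    rubber: CropParams = field(default_factory=default_rubber)
    household: HouseholdParams = field(default_factory=HouseholdParams)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    carbon: CarbonParams = field(default_factory=CarbonParams)
    prices: PriceConfig = field(default_factory=PriceConfig)
    collect_ledger: bool = True

    @classmethod
    def from_scenario(cls, scenario_id: str, seed: int = 0, **overrides) -> "ScenarioConfig":
        """Build a config from one of the named scenario presets."""
        try:
            preset = SCENARIOS[scenario_id]
        except KeyError:
            raise ValueError(
                f"unknown scenario {scenario_id!r}; expected one of {sorted(SCENARIOS)}"
            ) from None
        cfg = cls(scenario_id=scenario_id, seed=seed, **overrides)
        cfg.inefficiency = preset["inefficiency"]
        cfg.learning = preset["learning"]
        cfg.prices = dataclasses.replace(cfg.prices, mode=preset["price_mode"])
        return cfg

    def crop_params(self, crop: int) -> CropParams:
        if crop == OIL_PALM:
            return self.oil_palm
        if crop == RUBBER:
            return self.rubber
        raise ValueError(f"unknown crop code {crop}")

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key, sub in (
            ("init", InitConfig),
            ("oil_palm", CropParams),
            ("rubber", CropParams),
            ("household", HouseholdParams),
            ("network", NetworkConfig),
            ("carbon", CarbonParams),
            ("prices", PriceConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                for k, v in sub_d.items():
                    if isinstance(v, list):
                        sub_d[k] = tuple(v)
                d[key] = sub(**sub_d)
        return cls(**d)

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
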