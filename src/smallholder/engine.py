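"""Annual simulation loop, scenario runner and RNG management.

Each simulated year executes, in order: (1) social-network learning (if
enabled), (2) Consumption I, (3) the per-field land-use decision and its
implementation, (4) production, costs and net cash flow, (5) Consumption
II, (6) the wealth/debt/freeze update, (7) the carbon update, (8) metric
recording, and (9) the price update for the next year together with
stand aging.  Decisions always use the current year's prices.

Randomness is split into named, independently seeded streams (landscape,
wealth, inefficiency, network, prices, tie-breaks) so that switching one
stochastic element on or off leaves the draws of the others untouched.
Replicate ``r`` of a scenario uses seed ``seed + r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import carbon as carbon_mod
from . import economy, metrics, network, prices as prices_mod
from .agents import Household
from .config import CELL_AREA_HA, OIL_PALM, RUBBER, ScenarioConfig
from .landscape import generate_landscape

RNG_STREAMS = ("landscape", "wealth", "inefficiency", "network", "prices", "tiebreak")

LEDGER_COLUMNS = [
    "replicate", "year", "h_id", "h_area", "h_wealth", "h_debts",
    "h_inefficiency_op", "h_inefficiency_rubber", "h_capitalstock",
    "h_exincome", "h_netcashflow", "h_consumption", "h_cost_investment",
    "h_cost_labor", "h_cost_tinput", "h_cost_capital", "h_cost_land",
    "h_revenue", "h_op_production", "h_rubber_production", "h_debt_years",
    "frozen",
]


def make_rng_streams(seed: int) -> Dict[str, np.random.Generator]:
    seqs = np.random.SeedSequence(seed).spawn(len(RNG_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(RNG_STREAMS, seqs)}


class Simulation:
    """One replicate of one scenario."""

    def __init__(self, config: ScenarioConfig, seed: Optional[int] = None,
                 replicate: int = 0):
        self.config = config
        self.replicate = replicate
        self.seed = config.seed if seed is None else seed
        self.rng = make_rng_streams(self.seed)
        self.crop_params = {OIL_PALM: config.oil_palm, RUBBER: config.rubber}
        self.yield_tables = {
            c: economy.yield_table(p) for c, p in self.crop_params.items()
        }
        self.landscape, self.households = generate_landscape(
            config.init,
            rng_map=self.rng["landscape"],
            rng_wealth=self.rng["wealth"],
            rng_ineff=self.rng["inefficiency"],
            inefficiency_enabled=config.inefficiency,
        )
        self.by_id = {hh.h_id: hh for hh in self.households}
        for hh in self.households:
            hh.external_income = config.household.external_income
        if config.learning:
            dist = network.road_distances(self.landscape, self.households)
            network.build_network(
                self.households, dist, config.network, self.rng["network"]
            )
        self.price_series = self._init_prices()
        self._walk_prices = (config.prices.price_rubber, config.prices.price_op)
        self.year = 0
        self.records: List[dict] = []
        self.ledger: List[dict] = []
        self._npv_cache: dict = {}
        # initial carbon state (year-0 stocks before any dynamics)
        carbon_mod.update_carbon(self.landscape, config.carbon)

    def _init_prices(self) -> Optional[prices_mod.PriceSeries]:
        cfg = self.config.prices
        if cfg.mode == "constant":
            return prices_mod.constant_prices(
                cfg.price_rubber, cfg.price_op, self.config.years
            )
        if cfg.mode == "series":
            series = prices_mod.load_price_series(cfg.series_path)
            if len(series) < self.config.years:
                raise ValueError(
                    f"price series has {len(series)} years, "
                    f"run needs {self.config.years}"
                )
            return series
        if cfg.mode == "random_walk":
            return None  # generated on the fly
        raise ValueError(f"unknown price mode {cfg.mode!r}")

    def current_prices(self) -> Dict[int, float]:
        if self.price_series is not None:
            pr, po = self.price_series.at(self.year)
        else:
            pr, po = self._walk_prices
        return {RUBBER: pr, OIL_PALM: po}

    # -- annual step ------------------------------------------------------

    def step_year(self) -> None:
        cfg = self.config
        prices = self.current_prices()
        active = [hh for hh in self.households if not hh.frozen]

        # (1) learning: simultaneous partial adjustment towards network means
        if cfg.learning:
            self._learning_step(active)

        # (2) Consumption I, deducted before the decision
        for hh in active:
            hh.reset_annual_flows()
            hh.consumption_1 = economy.consumption_1(hh, cfg.household)
            hh.balance -= hh.consumption_1

        # (3) land-use / management decision and implementation
        replanted: set = set()
        for hh in active:
            fields = [self.landscape.fields[fid] for fid in hh.field_ids]
            options = economy.choose_field_options(
                hh, fields, self.crop_params, prices,
                cfg.household.planning_horizon, cfg.household.discount_rate,
                budget=max(hh.balance, 0.0), npv_cache=self._npv_cache,
            )
            for opt in options:
                if opt.action == economy.KEEP:
                    continue
                f = self.landscape.fields[opt.field_id]
                if opt.action == economy.CONVERT:
                    f.landuse = RUBBER if f.landuse == OIL_PALM else OIL_PALM
                f.age = 0
                replanted.add(opt.field_id)

        # (4) production, costs, revenue, net cash flow
        for hh in active:
            self._produce(hh, prices, replanted)

        # (5) Consumption II
        for hh in active:
            hh.consumption_2 = economy.consumption_2(hh, cfg.household)
        # (6) wealth/debt/freeze update
        for hh in active:
            economy.update_wealth_debts(hh, cfg.household)

        # (7) carbon stocks; frozen households' cells keep their last value
        frozen_mask = ~metrics.active_cell_mask(self.landscape, self.households)
        frozen_mask &= self.landscape.owner >= 0
        carbon_mod.update_carbon(self.landscape, cfg.carbon, skip_mask=frozen_mask)

        # (8) observables
        self._record(prices)

        # (9) next year's prices and stand aging
        if self.price_series is None:
            pr, po = self._walk_prices
            sig = cfg.prices.sigma
            rng = self.rng["prices"]
            self._walk_prices = (
                prices_mod.random_walk_step(pr, sig, rng),
                prices_mod.random_walk_step(po, sig, rng),
            )
        for hh in self.households:
            if hh.frozen:
                continue
            for fid in hh.field_ids:
                f = self.landscape.fields[fid]
                f.age += 1
                self.landscape.sync_field(f)
        self.year += 1

    def _learning_step(self, active: List[Household]) -> None:
        alpha = self.config.network.alpha
        snapshot = {
            hh.h_id: (hh.ineff_op, hh.ineff_rubber) for hh in self.households
        }

        def snap_mean(hh: Household, crop: int) -> Optional[float]:
            vals = [
                snapshot[j][0 if crop == OIL_PALM else 1]
                for j in hh.connected
                if not self.by_id[j].frozen
            ]
            return float(np.mean(vals)) if vals else None

        updates = []
        for hh in active:
            crops = {self.landscape.fields[fid].landuse for fid in hh.field_ids}
            for crop in crops:
                m = snap_mean(hh, crop)
                if m is None:
                    continue
                own = hh.inefficiency(crop)
                if own > m:
                    updates.append((hh, crop, own - alpha * (own - m)))
        for hh, crop, val in updates:
            hh.set_inefficiency(crop, val)

    def _produce(self, hh: Household, prices: Dict[int, float], replanted: set) -> None:
        ls = self.landscape
        for fid in hh.field_ids:
            f = ls.fields[fid]
            params = self.crop_params[f.landuse]
            replant = fid in replanted
            costs = economy.annual_cost_per_cell(params, f.age, replant)
            n = f.size
            hh.cost_labor += costs["labor"] * n
            hh.cost_tinput += costs["tinput"] * n
            hh.cost_capital += costs["capital"] * n
            hh.cost_land += costs["land"] * n
            hh.cost_investment += costs["investment"] * n
            prod_cell = economy.actual_production_per_cell(
                params, f.age, hh.inefficiency(f.landuse)
            )
            if f.landuse == OIL_PALM:
                hh.op_production += prod_cell * n
            else:
                hh.rubber_production += prod_cell * n
            r, c = ls.unflat(f.cells)
            ls.production[r, c] = prod_cell
            ls.labor[r, c] = (
                params.labor_hours_mature * economy.input_factor(params, f.age)
                * CELL_AREA_HA
            )
            ls.tinput[r, c] = (
                params.tinput_kg_mature * economy.input_factor(params, f.age)
                * CELL_AREA_HA
            )
            ls.capitalstock[r, c] = (
                economy.capital_stock_per_ha(params, f.age) * CELL_AREA_HA
            )
            ls.sync_field(f)
        hh.revenue = (
            prices[RUBBER] * hh.rubber_production + prices[OIL_PALM] * hh.op_production
        )
        hh.net_cash_flow = economy.net_cash_flow(hh)

    def _record(self, prices: Dict[int, float]) -> None:
        ls = self.landscape
        active_mask = metrics.active_cell_mask(ls, self.households)
        active = [hh for hh in self.households if not hh.frozen]
        frac_op, frac_rub = metrics.landuse_fractions(ls, active_mask)
        rec = {
            "year": self.year,
            "n_active": metrics.survival(self.households),
            "frac_oilpalm": frac_op,
            "frac_rubber": frac_rub,
            "field_frac_rubber": metrics.field_fraction_rubber(ls, self.households),
            "mean_consumption": (
                float(np.mean([hh.consumption for hh in active])) if active else None
            ),
            "mean_wealth": (
                float(np.mean([hh.wealth for hh in active])) if active else None
            ),
            "carbon_agri": carbon_mod.landscape_carbon(ls, active_mask, "agricultural"),
            "carbon_op": metrics.crop_carbon_contribution(ls, active_mask, OIL_PALM),
            "carbon_rubber": metrics.crop_carbon_contribution(ls, active_mask, RUBBER),
            "yieldgap_op": metrics.yield_gap(ls, self.households, OIL_PALM, self.yield_tables),
            "yieldgap_rubber": metrics.yield_gap(ls, self.households, RUBBER, self.yield_tables),
            "price_rubber": prices[RUBBER],
            "price_op": prices[OIL_PALM],
        }
        self.records.append(rec)
        if self.config.collect_ledger:
            for hh in active:
                self.ledger.append({
                    "replicate": self.replicate,
                    "year": self.year,
                    "h_id": hh.h_id,
                    "h_area": hh.area,
                    "h_wealth": hh.wealth,
                    "h_debts": hh.debts,
                    "h_inefficiency_op": hh.ineff_op,
                    "h_inefficiency_rubber": hh.ineff_rubber,
                    "h_capitalstock": float(sum(
                        economy.capital_stock_per_ha(
                            self.crop_params[self.landscape.fields[fid].landuse],
                            self.landscape.fields[fid].age,
                        ) * CELL_AREA_HA * self.landscape.fields[fid].size
                        for fid in hh.field_ids
                    )),
                    "h_exincome": hh.external_income,
                    "h_netcashflow": hh.net_cash_flow,
                    "h_consumption": hh.consumption,
                    "h_cost_investment": hh.cost_investment,
                    "h_cost_labor": hh.cost_labor,
                    "h_cost_tinput": hh.cost_tinput,
                    "h_cost_capital": hh.cost_capital,
                    "h_cost_land": hh.cost_land,
                    "h_revenue": hh.revenue,
                    "h_op_production": hh.op_production,
                    "h_rubber_production": hh.rubber_production,
                    "h_debt_years": hh.debt_years,
                    "frozen": hh.frozen,
                })

    def run(self) -> pd.DataFrame:
        """Run the configured number of years; returns the annual records."""
        for _ in range(self.config.years):
            self.step_year()
        df = pd.DataFrame(self.records)
        df["replicate"] = self.replicate
        return df


@dataclass
class ScenarioResult:
    """Replicate-level records, their cross-replicate summary, and ledgers."""

    config: ScenarioConfig
    records: pd.DataFrame  # one row per (replicate, year)
    summary: pd.DataFrame  # per-year mean and SD across replicates
    ledger: Optional[pd.DataFrame] = None
    simulations: List[Simulation] = dc_field(default_factory=list)


def run_scenario(config: ScenarioConfig, keep_simulations: bool = False) -> ScenarioResult:
    """Run ``n_replicates`` independent replicates of one scenario.

    Replicate ``r`` is seeded with ``config.seed + r`` and regenerates
    the full landscape (map, wealth, inefficiency draws), so the
    cross-replicate SD reflects every stochastic model element.
    """
    frames = []
    ledgers = []
    sims = []
    for r in range(config.n_replicates):
        sim = Simulation(config, seed=config.seed + r, replicate=r)
        frames.append(sim.run())
        if config.collect_ledger:
            ledgers.append(pd.DataFrame(sim.ledger))
        if keep_simulations:
            sims.append(sim)
    records = pd.concat(frames, ignore_index=True)
    summary = metrics.summarize_replicates(records)
    ledger = pd.concat(ledgers, ignore_index=True) if ledgers else None
    return ScenarioResult(
        config=config, records=records, summary=summary,
        ledger=ledger, simulations=sims,
    )
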