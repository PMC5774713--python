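"""The annual economic household model.

Covers the full cash cycle of a farming household: age-dependent
potential yields, inefficiency-scaled actual production, the annual cost
breakdown (labor, technical input, capital, land rent, establishment
investment), net cash flow, expected net present value (NPV) of land-use
options under constant-price expectations, the per-field land-use
decision under a wealth constraint, the two consumption stages, and the
wealth/debt/freeze update.

Monetary quantities are in USD; per-cell quantities scale per-hectare
schedules by the 0.25 ha cell area.  Households forecast by holding
current prices and their own current inefficiency constant over the
planning horizon, and anticipate forced replanting at ``max_age`` inside
that projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .agents import Household
from .config import (
    CELL_AREA_HA,
    OIL_PALM,
    RUBBER,
    CropParams,
    HouseholdParams,
)
from .landscape import Field

KEEP = "keep"
REPLANT = "replant_same"
CONVERT = "convert_other"

_OTHER = {OIL_PALM: RUBBER, RUBBER: OIL_PALM}


@dataclass(frozen=True)
class DecisionOption:
    """Chosen action for one field with its valuation."""

    field_id: int
    action: str
    expected_npv: float
    investment_cost: float


# ---------------------------------------------------------------------------
# production and costs
# ---------------------------------------------------------------------------

def potential_yield(params: CropParams, age: int) -> float:
    """Potential yield in t/ha/yr at a given plantation age.

    Zero while immature and from ``max_age`` onwards; piecewise-linear
    interpolation of the crop's yield profile in between.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if age < params.immature_years or age >= params.max_age:
        return 0.0
    return float(
        np.interp(age, params.yield_knots_age, params.yield_knots_value)
    )


@lru_cache(maxsize=None)
def yield_table(params: CropParams) -> np.ndarray:
    """Potential yield (t/ha) indexed by age 0..max_age."""
    return np.array([potential_yield(params, a) for a in range(params.max_age + 1)])


def input_factor(params: CropParams, age: int) -> float:
    """Share of the mature input schedule applied at a given age.

    Immature stands need ``immature_input_factor``; producing stands
    scale between that floor and the full schedule in proportion to the
    yield ramp (harvest labor and inputs track harvest volume), reaching
    1 on the yield plateau.
    """
    if age < params.immature_years:
        return params.immature_input_factor
    peak = max(params.yield_knots_value)
    base = params.immature_input_factor
    return base + (1.0 - base) * potential_yield(params, age) / peak


def labor_cost_per_ha(params: CropParams, age: int) -> float:
    return params.labor_hours_mature * input_factor(params, age) * params.labor_wage


def tinput_cost_per_ha(params: CropParams, age: int) -> float:
    return params.tinput_kg_mature * input_factor(params, age) * params.tinput_price


def capital_stock_per_ha(params: CropParams, age: int) -> float:
    """Capital fixed in the plantation: linear depreciation over max_age."""
    return params.establishment_cost * max(0.0, 1.0 - age / params.max_age)


def annual_cost_per_cell(params: CropParams, age: int, replant: bool) -> Dict[str, float]:
    """Cost breakdown for one 0.25 ha cell in one year, USD.

    ``replant`` marks the year a field is (re)planted, adding the
    establishment investment (and implying ``age = 0``).
    """
    a = CELL_AREA_HA
    return {
        "labor": labor_cost_per_ha(params, age) * a,
        "tinput": tinput_cost_per_ha(params, age) * a,
        "capital": params.capital_interest * capital_stock_per_ha(params, age) * a,
        "land": params.land_rent * a,
        "investment": params.establishment_cost * a if replant else 0.0,
    }


def actual_production_per_cell(params: CropParams, age: int, inefficiency: float) -> float:
    """Realized production of one cell, t/yr: potential scaled by (1 - inefficiency)."""
    return potential_yield(params, age) * (1.0 - inefficiency) * CELL_AREA_HA


def cell_cashflow(
    params: CropParams, age: int, price: float, inefficiency: float, replant: bool
) -> float:
    """Net cash flow of one cell in one year, USD."""
    costs = annual_cost_per_cell(params, age, replant)
    revenue = actual_production_per_cell(params, age, inefficiency) * price
    return revenue - sum(costs.values())


def net_cash_flow(household: Household) -> float:
    """Ledger identity: revenue minus all annual cost components."""
    return household.revenue - (
        household.cost_investment
        + household.cost_labor
        + household.cost_tinput
        + household.cost_capital
        + household.cost_land
    )


# ---------------------------------------------------------------------------
# expected NPV of land-use options
# ---------------------------------------------------------------------------

def expected_npv_per_cell(
    crop_params: Dict[int, CropParams],
    crop: int,
    age: int,
    action: str,
    prices: Dict[int, float],
    inefficiency: Dict[int, float],
    horizon: int,
    discount_rate: float,
) -> float:
    """Expected NPV of one cell over the planning horizon, USD.

    Projects the field year by year under constant prices and constant
    inefficiency.  ``replant_same``/``convert_other`` plant at age 0 in
    the first projection year and pay the establishment cost; any stand
    reaching ``max_age`` inside the horizon is replanted (same crop) at
    further establishment cost — plantations past their maximum age are
    never carried.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if action == CONVERT:
        crop = _OTHER[crop]
    params = crop_params[crop]
    price = prices[crop]
    ineff = inefficiency[crop]
    replant = action in (REPLANT, CONVERT)
    if replant:
        age = 0
    elif age >= params.max_age:
        raise ValueError("cannot keep a plantation at or beyond max_age")
    npv = 0.0
    for y in range(horizon):
        if y > 0 and age >= params.max_age:
            age = 0
            replant = True
        npv += cell_cashflow(params, age, price, ineff, replant) / (
            (1.0 + discount_rate) ** y
        )
        replant = False
        age += 1
    return npv


def expected_npv(
    field: Field,
    action: str,
    crop_params: Dict[int, CropParams],
    prices: Dict[int, float],
    inefficiency: Dict[int, float],
    horizon: int,
    discount_rate: float,
) -> float:
    """Expected NPV of a whole field (per-cell NPV times field size)."""
    return field.size * expected_npv_per_cell(
        crop_params, field.landuse, field.age, action, prices,
        inefficiency, horizon, discount_rate,
    )


# ---------------------------------------------------------------------------
# the land-use / management decision
# ---------------------------------------------------------------------------

def choose_field_options(
    household: Household,
    fields: Sequence[Field],
    crop_params: Dict[int, CropParams],
    prices: Dict[int, float],
    horizon: int,
    discount_rate: float,
    budget: float,
    npv_cache: dict = None,
) -> List[DecisionOption]:
    """Select one action per field under the household's wealth constraint.

    Per field the candidate actions are *keep*, *replant with the same
    crop*, and *convert to the other crop*; a field at or beyond its
    maximum age must be replanted or converted.  The NPV-best action is
    desired for each field; desired investments are then admitted
    greedily in descending NPV-gain per USD of investment (ties broken
    by lower field id) while the budget lasts.  Voluntary investments
    are never debt-financed and revert to *keep* when unaffordable;
    forced replanting is unavoidable and may push the budget negative
    (debt), falling back to the cheapest forced option if the best one
    is unaffordable.
    """
    ineff = {
        OIL_PALM: household.ineff_op,
        RUBBER: household.ineff_rubber,
    }

    def npv(field: Field, action: str) -> float:
        if npv_cache is not None:
            full_key = (
                field.landuse, field.age, action, field.size,
                prices[OIL_PALM], prices[RUBBER],
                ineff[OIL_PALM], ineff[RUBBER],
            )
            hit = npv_cache.get(full_key)
            if hit is not None:
                return hit
        val = expected_npv(
            field, action, crop_params, prices, ineff, horizon, discount_rate
        )
        if npv_cache is not None:
            npv_cache[full_key] = val
        return val

    def invest_cost(field: Field, action: str) -> float:
        if action == KEEP:
            return 0.0
        crop = _OTHER[field.landuse] if action == CONVERT else field.landuse
        return crop_params[crop].establishment_cost * CELL_AREA_HA * field.size

    chosen: Dict[int, DecisionOption] = {}
    forced: List[Field] = []
    voluntary: List[Tuple[float, int, Field, DecisionOption, float]] = []

    for f in sorted(fields, key=lambda f: f.field_id):
        max_age = crop_params[f.landuse].max_age
        if f.age >= max_age:
            forced.append(f)
            continue
        options = [
            DecisionOption(f.field_id, a, npv(f, a), invest_cost(f, a))
            for a in (KEEP, REPLANT, CONVERT)
        ]
        keep_opt = options[0]
        best = max(options, key=lambda o: o.expected_npv)
        if best.action == KEEP or best.expected_npv <= keep_opt.expected_npv:
            chosen[f.field_id] = keep_opt
        else:
            gain = best.expected_npv - keep_opt.expected_npv
            ratio = gain / best.investment_cost
            voluntary.append((ratio, f.field_id, f, best, keep_opt.expected_npv))
            chosen[f.field_id] = keep_opt  # placeholder, may upgrade below

    # Forced replacements first: unavoidable, possibly debt-financed.
    for f in forced:
        options = [
            DecisionOption(f.field_id, a, npv(f, a), invest_cost(f, a))
            for a in (REPLANT, CONVERT)
        ]
        best = max(options, key=lambda o: o.expected_npv)
        if best.investment_cost <= budget:
            pick = best
        else:
            pick = min(options, key=lambda o: (o.investment_cost, o.field_id))
        chosen[f.field_id] = pick
        budget -= pick.investment_cost

    # Voluntary investments: greedy by NPV gain per USD, never into debt.
    voluntary.sort(key=lambda t: (-t[0], t[1]))
    for ratio, fid, f, best, keep_npv in voluntary:
        if best.investment_cost <= budget:
            chosen[fid] = best
            budget -= best.investment_cost

    return [chosen[fid] for fid in sorted(chosen)]


# ---------------------------------------------------------------------------
# consumption and wealth dynamics
# ---------------------------------------------------------------------------

def consumption_1(household: Household, params: HouseholdParams) -> float:
    """Subsistence plus wealth-based consumption, deducted before decisions."""
    return params.subsistence + params.wealth_rate * max(household.balance, 0.0)


def consumption_2(household: Household, params: HouseholdParams) -> float:
    """Profit-based consumption: a share of positive net cash flow."""
    return params.profit_rate * max(household.net_cash_flow, 0.0)


def update_wealth_debts(household: Household, params: HouseholdParams) -> None:
    """Year-end wealth update, debt bookkeeping and freezing.

    The internal signed balance accrues net cash flow plus external
    income minus profit-based consumption (Consumption I was already
    deducted before the decision).  A negative balance is carried as
    debt; after ``freeze_threshold`` consecutive indebted years the
    household freezes and stops acting.
    """
    household.balance += (
        household.net_cash_flow + household.external_income - household.consumption_2
    )
    if household.balance < 0:
        household.debt_years += 1
    else:
        household.debt_years = 0
    if household.debt_years >= params.freeze_threshold:
        household.frozen = True
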