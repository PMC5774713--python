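"""Household economics: yields, costs, NPV (vs brute-force oracle), decisions."""

import dataclasses

import numpy as np
import pytest

from smallholder import (
    CONVERT,
    KEEP,
    REPLANT,
    OIL_PALM,
    RUBBER,
    HouseholdParams,
    default_oil_palm,
    default_rubber,
)
from smallholder.agents import Household
from smallholder.economy import (
    actual_production_per_cell,
    annual_cost_per_cell,
    capital_stock_per_ha,
    cell_cashflow,
    choose_field_options,
    consumption_1,
    consumption_2,
    expected_npv_per_cell,
    input_factor,
    net_cash_flow,
    potential_yield,
    update_wealth_debts,
)
from smallholder.landscape import Field

CROPS = {OIL_PALM: default_oil_palm(), RUBBER: default_rubber()}
PRICES = {OIL_PALM: 90.0, RUBBER: 1100.0}
NO_INEFF = {OIL_PALM: 0.0, RUBBER: 0.0}


class TestPotentialYield:
    @pytest.mark.parametrize(
        "crop,age,expected",
        [
            (OIL_PALM, 1, 0.0),  # immature
            (OIL_PALM, 12, 22.0),  # plateau
            (OIL_PALM, 25, 0.0),  # past max age
            (RUBBER, 29, 1.8),  # plateau end
            (RUBBER, 35, 1.1),  # declining phase, linear interpolation
            (RUBBER, 3, 0.0),  # immature
            (RUBBER, 40, 0.0),  # past max age
        ],
    )
    def test_profile_values(self, crop, age, expected):
        assert potential_yield(CROPS[crop], age) == pytest.approx(expected)

    def test_rubber_productivity_drop_after_30(self):
        # the late-age decline that promotes replanting of old rubber
        assert potential_yield(CROPS[RUBBER], 35) < potential_yield(CROPS[RUBBER], 29)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            potential_yield(CROPS[OIL_PALM], -1)

    def test_unknown_crop_code_rejected(self):
        from smallholder import ScenarioConfig

        with pytest.raises(ValueError):
            ScenarioConfig().crop_params(99)


class TestProductionAndCosts:
    def test_inefficiency_scaling(self):
        p = CROPS[OIL_PALM]
        pot = potential_yield(p, 12)
        assert actual_production_per_cell(p, 12, 0.0) == pytest.approx(pot * 0.25)
        assert actual_production_per_cell(p, 12, 1.0) == 0.0
        assert actual_production_per_cell(p, 12, 0.25) == pytest.approx(4.125)

    def test_establishment_investment_per_cell(self):
        costs = annual_cost_per_cell(CROPS[OIL_PALM], 0, replant=True)
        assert costs["investment"] == pytest.approx(1200 * 0.25)
        assert annual_cost_per_cell(CROPS[OIL_PALM], 0, replant=False)["investment"] == 0

    def test_capital_cost_on_half_depreciated_stock(self):
        # stock of 150 USD/cell at 10% interest costs 15 USD
        p = dataclasses.replace(
            default_oil_palm(), establishment_cost=1200.0, max_age=2, capital_interest=0.10
        )
        assert capital_stock_per_ha(p, 1) == pytest.approx(600.0)
        assert annual_cost_per_cell(p, 1, False)["capital"] == pytest.approx(15.0)

    def test_input_factor_ramps_with_yield(self):
        p = CROPS[OIL_PALM]
        assert input_factor(p, 0) == p.immature_input_factor
        assert input_factor(p, 12) == pytest.approx(1.0)
        assert input_factor(p, 3) < input_factor(p, 6) < input_factor(p, 9)

    def test_net_cash_flow_identity(self):
        hh = Household(h_id=0, home=(0, 0))
        assert net_cash_flow(hh) == 0.0
        hh.revenue = 1000.0
        hh.cost_labor = 250.0
        hh.cost_tinput = 100.0
        hh.cost_capital = 30.0
        hh.cost_land = 20.0
        hh.cost_investment = 0.0
        assert net_cash_flow(hh) == pytest.approx(600.0)


def oracle_npv(crop, age, action, prices, ineff, horizon, discount):
    """Brute-force oracle: explicit timeline, component-wise cash flows,
    vectorized discounting — independent of the implementation's loop."""
    if action == CONVERT:
        crop = RUBBER if crop == OIL_PALM else OIL_PALM
    p = CROPS[crop]
    timeline = []
    cur = age if action == KEEP else 0
    invest = action != KEEP
    for y in range(horizon):
        if y > 0 and cur >= p.max_age:
            cur, invest = 0, True
        timeline.append((cur, invest))
        invest = False
        cur += 1
    peak = max(p.yield_knots_value)
    flows = []
    for a, inv in timeline:
        if p.immature_years <= a < p.max_age:
            yld = float(np.interp(a, p.yield_knots_age, p.yield_knots_value))
        else:
            yld = 0.0
        fac = p.immature_input_factor
        if a >= p.immature_years:
            fac = fac + (1 - fac) * yld / peak
        rev = yld * (1 - ineff[crop]) * 0.25 * prices[crop]
        cost = 0.25 * (
            p.labor_hours_mature * fac * p.labor_wage
            + p.tinput_kg_mature * fac * p.tinput_price
            + p.land_rent
            + p.capital_interest * p.establishment_cost * max(0.0, 1 - a / p.max_age)
        )
        if inv:
            cost += 0.25 * p.establishment_cost
        flows.append(rev - cost)
    disc = (1.0 + discount) ** -np.arange(horizon)
    return float(np.dot(flows, disc))


class TestExpectedNPV:
    def test_horizon_one_keep_is_single_undiscounted_cashflow(self):
        val = expected_npv_per_cell(CROPS, RUBBER, 15, KEEP, PRICES, NO_INEFF, 1, 0.10)
        assert val == pytest.approx(
            cell_cashflow(CROPS[RUBBER], 15, PRICES[RUBBER], 0.0, False)
        )

    def test_matches_brute_force_oracle_everywhere(self):
        ineff = {OIL_PALM: 0.15, RUBBER: 0.4}
        for crop in (OIL_PALM, RUBBER):
            for age in range(0, CROPS[crop].max_age + 1):
                for action in (KEEP, REPLANT, CONVERT):
                    if action == KEEP and age >= CROPS[crop].max_age:
                        continue
                    for horizon in (1, 2, 5, 10, 20):
                        got = expected_npv_per_cell(
                            CROPS, crop, age, action, PRICES, ineff, horizon, 0.10
                        )
                        want = oracle_npv(crop, age, action, PRICES, ineff, horizon, 0.10)
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_rubber_dominates_oil_palm_at_reference_prices(self):
        # zero-inefficiency bare-field comparison at 2012 farm-gate prices
        for horizon in range(1, 21):
            r = expected_npv_per_cell(CROPS, RUBBER, 0, REPLANT, PRICES, NO_INEFF, horizon, 0.10)
            o = expected_npv_per_cell(CROPS, OIL_PALM, 0, REPLANT, PRICES, NO_INEFF, horizon, 0.10)
            assert r > o

    def test_monotone_in_own_inefficiency(self):
        vals = [
            expected_npv_per_cell(
                CROPS, RUBBER, 10, KEEP, PRICES, {OIL_PALM: 0.0, RUBBER: e}, 10, 0.10
            )
            for e in np.linspace(0, 1, 11)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_monotone_in_own_price(self):
        vals = [
            expected_npv_per_cell(
                CROPS, RUBBER, 10, KEEP, {OIL_PALM: 90.0, RUBBER: p}, NO_INEFF, 10, 0.10
            )
            for p in np.linspace(200, 3000, 15)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_keep_beyond_max_age_rejected(self):
        with pytest.raises(ValueError):
            expected_npv_per_cell(
                CROPS, OIL_PALM, 25, KEEP, PRICES, NO_INEFF, 5, 0.10
            )


def _mk_fields(specs):
    return [
        Field(field_id=i, owner=0, cells=np.arange(n), landuse=lu, age=age)
        for i, (lu, age, n) in enumerate(specs)
    ]


def _choose(fields, budget, prices=PRICES, horizon=10):
    hh = Household(h_id=0, home=(0, 0))
    return choose_field_options(
        hh, fields, CROPS, prices, horizon, 0.10, budget
    )


class TestFieldDecision:
    def test_no_budget_no_forced_all_keep(self):
        fields = _mk_fields([(OIL_PALM, 10, 4), (RUBBER, 20, 4)])
        opts = _choose(fields, budget=0.0)
        assert [o.action for o in opts] == [KEEP, KEEP]
        assert all(o.investment_cost == 0.0 for o in opts)

    def test_budget_rations_conversions_tie_broken_by_field_id(self):
        # worthless oil palm: both fields want to convert; budget covers one
        cheap_op = {OIL_PALM: 1.0, RUBBER: 1100.0}
        fields = _mk_fields([(OIL_PALM, 10, 4), (OIL_PALM, 10, 4)])
        cost_one = 1000 * 0.25 * 4
        opts = _choose(fields, budget=cost_one, prices=cheap_op, horizon=20)
        assert [o.action for o in opts] == [CONVERT, KEEP]

    def test_sufficient_budget_converts_both(self):
        cheap_op = {OIL_PALM: 1.0, RUBBER: 1100.0}
        fields = _mk_fields([(OIL_PALM, 10, 4), (OIL_PALM, 10, 4)])
        opts = _choose(fields, budget=1e6, prices=cheap_op, horizon=20)
        assert [o.action for o in opts] == [CONVERT, CONVERT]

    def test_forced_at_max_age_even_without_budget(self):
        fields = _mk_fields([(OIL_PALM, 25, 4)])
        opts = _choose(fields, budget=0.0)
        assert opts[0].action in (REPLANT, CONVERT)
        # cheapest forced option is the rubber conversion (1000 < 1200 USD/ha)
        assert opts[0].action == CONVERT
        assert opts[0].investment_cost == pytest.approx(1000 * 0.25 * 4)

    def test_forced_with_budget_takes_best_npv(self):
        # with ample budget the forced choice is the NPV-best replacement,
        # which at reference prices is rubber
        fields = _mk_fields([(OIL_PALM, 25, 4)])
        opts = _choose(fields, budget=1e6)
        assert opts[0].action == CONVERT


class TestConsumptionAndWealth:
    # pinned rates so the arithmetic below is explicit
    P = HouseholdParams(subsistence=500.0, wealth_rate=0.05, profit_rate=0.10)

    def _hh(self, balance=0.0, ncf=0.0):
        hh = Household(h_id=0, home=(0, 0), balance=balance)
        hh.net_cash_flow = ncf
        return hh

    def test_consumption_1_wealth_based(self):
        assert consumption_1(self._hh(1000.0), self.P) == pytest.approx(550.0)
        assert consumption_1(self._hh(-400.0), self.P) == pytest.approx(500.0)
        zero = dataclasses.replace(self.P, subsistence=0.0, wealth_rate=0.0)
        assert consumption_1(self._hh(1000.0), zero) == 0.0

    def test_consumption_2_profit_based(self):
        assert consumption_2(self._hh(ncf=-100.0), self.P) == 0.0
        assert consumption_2(self._hh(ncf=1000.0), self.P) == pytest.approx(100.0)

    def test_consumption_total_identity(self):
        hh = self._hh(1000.0, ncf=1000.0)
        hh.consumption_1 = consumption_1(hh, self.P)
        hh.consumption_2 = consumption_2(hh, self.P)
        assert hh.consumption == pytest.approx(650.0)

    def test_debt_bookkeeping(self):
        p = dataclasses.replace(self.P, freeze_threshold=5)
        hh = self._hh(100.0, ncf=-300.0)
        update_wealth_debts(hh, p)
        assert hh.wealth == 0.0
        assert hh.debts == pytest.approx(200.0)
        assert hh.debt_years == 1

    def test_debt_years_reset_on_repayment(self):
        p = dataclasses.replace(self.P, freeze_threshold=5)
        hh = self._hh(-200.0)
        hh.net_cash_flow = 1000.0
        update_wealth_debts(hh, p)
        assert hh.debts == 0.0 and hh.debt_years == 0

    def test_freeze_after_threshold_consecutive_debt_years(self):
        p = dataclasses.replace(self.P, freeze_threshold=5)
        hh = self._hh(-100.0)
        for year in range(5):
            hh.net_cash_flow = -50.0
            update_wealth_debts(hh, p)
        assert hh.debt_years == 5 and hh.frozen
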