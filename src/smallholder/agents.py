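"""Household agent state.

A household owns a set of contiguous fields, holds wealth (or debts, when
its internal balance is negative), and carries crop-specific production
inefficiencies.  All annual monetary flows are recorded on the household
so that a complete per-year ledger can be exported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple


@dataclass
class Household:
    h_id: int
    home: Tuple[int, int]  # (row, col) of the home-base cell
    field_ids: List[int] = field(default_factory=list)
    area: int = 0  # cells owned
    #: Signed financial balance, USD. Exposed as wealth/debts via properties.
    balance: float = 0.0
    ineff_op: float = 0.0
    ineff_rubber: float = 0.0
    external_income: float = 0.0
    debt_years: int = 0
    frozen: bool = False
    connected: List[int] = field(default_factory=list)

    # annual flows, reset each simulated year
    consumption_1: float = 0.0
    consumption_2: float = 0.0
    cost_investment: float = 0.0
    cost_labor: float = 0.0
    cost_tinput: float = 0.0
    cost_capital: float = 0.0
    cost_land: float = 0.0
    revenue: float = 0.0
    op_production: float = 0.0
    rubber_production: float = 0.0
    net_cash_flow: float = 0.0

    @property
    def wealth(self) -> float:
        """Available funds, USD (zero while indebted)."""
        return max(self.balance, 0.0)

    @property
    def debts(self) -> float:
        """Outstanding debts, USD (zero while solvent)."""
        return max(-self.balance, 0.0)

    @property
    def consumption(self) -> float:
        """Total annual consumption (fixed + variable), USD."""
        return self.consumption_1 + self.consumption_2

    def inefficiency(self, crop: int) -> float:
        from .config import OIL_PALM, RUBBER

        if crop == OIL_PALM:
            return self.ineff_op
        if crop == RUBBER:
            return self.ineff_rubber
        raise ValueError(f"unknown crop code {crop}")

    def set_inefficiency(self, crop: int, value: float) -> None:
        from .config import OIL_PALM, RUBBER

        if not 0.0 <= value <= 1.0:
            raise ValueError("inefficiency must lie in [0, 1]")
        if crop == OIL_PALM:
            self.ineff_op = value
        elif crop == RUBBER:
            self.ineff_rubber = value
        else:
            raise ValueError(f"unknown crop code {crop}")

    def reset_annual_flows(self) -> None:
        self.consumption_1 = 0.0
        self.consumption_2 = 0.0
        self.cost_investment = 0.0
        self.cost_labor = 0.0
        self.cost_tinput = 0.0
        self.cost_capital = 0.0
        self.cost_land = 0.0
        self.revenue = 0.0
        self.op_production = 0.0
        self.rubber_production = 0.0
        self.net_cash_flow = 0.0
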