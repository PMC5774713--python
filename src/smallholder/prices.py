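"""Exogenous output price dynamics.

Prices are landscape-wide: every household faces the same farm-gate
price for dry rubber and for oil-palm fresh fruit bunches (FFB) in a
given year.  Three regimes are supported: constant prices, a loaded
annual series (a bundled 50-year synthetic series emulating historical
world-market swings ships with the package), and a drift-free Gaussian
random walk on log prices.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Union

import numpy as np
import pandas as pd

#: Name of the bundled synthetic "historical trends" series.
BUNDLED_SERIES = "prices_historical_synthetic.csv"


@dataclass(frozen=True)
class PriceSeries:
    """Annual output prices: USD/t dry rubber and USD/t FFB."""

    price_rubber: np.ndarray
    price_op: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "price_rubber", np.asarray(self.price_rubber, dtype=float))
        object.__setattr__(self, "price_op", np.asarray(self.price_op, dtype=float))
        if self.price_rubber.shape != self.price_op.shape:
            raise ValueError("price arrays must have equal length")
        if len(self) and (np.min(self.price_rubber) <= 0 or np.min(self.price_op) <= 0):
            raise ValueError("prices must be strictly positive")

    def __len__(self) -> int:
        return self.price_rubber.size

    def at(self, year: int):
        """Prices for a given year as ``(rubber, oil_palm)``."""
        return float(self.price_rubber[year]), float(self.price_op[year])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": np.arange(len(self)),
                "price_rubber": self.price_rubber,
                "price_op": self.price_op,
            }
        )


def constant_prices(p_rubber: float, p_op: float, years: int) -> PriceSeries:
    """A series of ``years`` identical prices."""
    if p_rubber <= 0 or p_op <= 0:
        raise ValueError("prices must be strictly positive")
    return PriceSeries(
        price_rubber=np.full(years, p_rubber), price_op=np.full(years, p_op)
    )


def load_price_series(path: Union[str, "object", None] = None) -> PriceSeries:
    """Load an annual price series from CSV.

    The file must have columns ``year, price_rubber, price_op`` with
    strictly positive numeric prices.  ``path=None`` loads the bundled
    synthetic historical-trends series.
    """
    if path is None:
        ref = resources.files("smallholder") / "data" / BUNDLED_SERIES
        with resources.as_file(ref) as p:
            return load_price_series(p)
    df = pd.read_csv(path)
    required = {"year", "price_rubber", "price_op"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"price series is missing column(s) {sorted(missing)}")
    for col in ("price_rubber", "price_op"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"invalid {col} at row {row}: {df[col].iloc[row]!r} "
                "(prices must be positive numbers)"
            )
        df[col] = vals
    df = df.sort_values("year")
    return PriceSeries(
        price_rubber=df["price_rubber"].to_numpy(),
        price_op=df["price_op"].to_numpy(),
    )


def write_price_series(series: PriceSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def random_walk_step(current: float, sigma: float, rng: np.random.Generator) -> float:
    """One step of the log-scale Gaussian random walk.

    ``next = current * exp(eps)`` with ``eps ~ N(0, sigma^2)``: outputs
    stay positive and the one-step forecast "no change" is unbiased on
    the log scale.  ``sigma = 0`` reduces to constant prices.
    """
    if current <= 0:
        raise ValueError("current price must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return current
    return float(current * np.exp(rng.normal(0.0, sigma)))
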