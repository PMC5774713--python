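"""Age-dependent vegetation carbon stocks.

Plantation cells accumulate carbon with stand age following a
saturating-growth curve ``C_max * (1 - exp(-k * age))`` (t C/ha);
secondary forest carries a constant stock.  Replanting or conversion
resets a cell's age, and with it its carbon, to zero — the mechanism by
which frequent land-use switching depresses landscape carbon.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import CELL_AREA_HA, FOREST, OIL_PALM, RUBBER, CarbonParams


def carbon_stock(landuse, age, params: CarbonParams):
    """Vegetation carbon stock in t C/ha for scalar or array inputs."""
    landuse = np.asarray(landuse)
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    known = np.isin(landuse, (FOREST, OIL_PALM, RUBBER))
    if not np.all(known):
        raise ValueError(f"unknown land use code(s) {np.unique(landuse[~known])}")
    out = np.where(
        landuse == FOREST,
        params.forest_constant,
        np.where(
            landuse == OIL_PALM,
            params.c_max_op * (1.0 - np.exp(-params.k_op * age)),
            params.c_max_rubber * (1.0 - np.exp(-params.k_rubber * age)),
        ),
    )
    if out.ndim == 0:
        return float(out)
    return out


def update_carbon(landscape, params: CarbonParams, skip_mask=None) -> None:
    """Recompute ``p_carbon`` (t C per 0.25 ha cell) for the whole grid.

    Cells in ``skip_mask`` (e.g. frozen households' fields) keep their
    previous value.
    """
    stock = carbon_stock(landscape.landuse, landscape.age, params)
    new = stock * CELL_AREA_HA
    if skip_mask is not None:
        new = np.where(skip_mask, landscape.carbon, new)
    landscape.carbon[:, :] = new


def landscape_carbon(
    landscape, active_mask: np.ndarray, scope: str = "agricultural"
) -> Optional[float]:
    """Mean carbon stock in t C/ha over the chosen scope.

    ``agricultural`` averages over active (non-frozen-owner) oil-palm and
    rubber cells; ``total`` over all non-road cells.  Returns ``None``
    when the scope is empty.
    """
    if scope == "agricultural":
        mask = (landscape.landuse != FOREST) & active_mask
    elif scope == "total":
        mask = ~landscape.road
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if not np.any(mask):
        return None
    return float(np.mean(landscape.carbon[mask]) / CELL_AREA_HA)
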