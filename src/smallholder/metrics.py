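"""Landscape- and household-level observables.

Per simulated year the model records land-use fractions of the active
agricultural area, mean household consumption, household survival,
agricultural vegetation carbon (total and per-crop contributions), and
per-crop yield gaps.  All metrics exclude frozen households and their
cells.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .agents import Household
from .config import CELL_AREA_HA, FOREST, OIL_PALM, RUBBER

RECORD_COLUMNS = [
    "year", "n_active", "frac_oilpalm", "frac_rubber", "mean_consumption",
    "mean_wealth", "carbon_agri", "carbon_op", "carbon_rubber",
    "yieldgap_op", "yieldgap_rubber", "field_frac_rubber",
]


def active_cell_mask(landscape, households: Sequence[Household]) -> np.ndarray:
    """Cells owned by non-frozen households."""
    active_ids = {hh.h_id for hh in households if not hh.frozen}
    mask = np.zeros(landscape.owner.shape, dtype=bool)
    if active_ids:
        mask = np.isin(landscape.owner, list(active_ids))
    return mask


def landuse_fractions(landscape, active_mask: np.ndarray) -> Tuple[Optional[float], Optional[float]]:
    """Cell-count shares of each crop among active agricultural cells."""
    agri = (landscape.landuse != FOREST) & active_mask
    total = int(agri.sum())
    if total == 0:
        return (None, None)
    n_op = int((landscape.landuse[agri] == OIL_PALM).sum())
    return (n_op / total, (total - n_op) / total)


def field_fraction_rubber(landscape, households: Sequence[Household]) -> Optional[float]:
    """Share of active households' fields planted with rubber (field count)."""
    fields = [
        landscape.fields[fid]
        for hh in households if not hh.frozen
        for fid in hh.field_ids
    ]
    if not fields:
        return None
    return sum(1 for f in fields if f.landuse == RUBBER) / len(fields)


def yield_gap(
    landscape, households: Sequence[Household], crop: int,
    yield_tables: Dict[int, np.ndarray],
) -> Optional[float]:
    """Unrealized fraction of potential production for one crop.

    ``1 - sum(actual) / sum(potential)`` over the cells of that crop
    currently cultivated by active households; ``None`` when total
    potential is zero (e.g. no mature stands).
    """
    actual = 0.0
    potential = 0.0
    table = yield_tables[crop]
    for hh in households:
        if hh.frozen:
            continue
        for fid in hh.field_ids:
            f = landscape.fields[fid]
            if f.landuse != crop:
                continue
            age = min(f.age, len(table) - 1)
            pot = table[age] * CELL_AREA_HA * f.size
            potential += pot
            actual += pot * (1.0 - hh.inefficiency(crop))
    if potential <= 0:
        return None
    return 1.0 - actual / potential


def survival(households: Sequence[Household]) -> int:
    """Number of non-frozen households."""
    return sum(1 for hh in households if not hh.frozen)


def crop_carbon_contribution(
    landscape, active_mask: np.ndarray, crop: int
) -> Optional[float]:
    """Contribution of one crop to agricultural carbon, t C/ha.

    Crop cell carbon summed over the active agricultural area divided by
    that whole area, so oil-palm and rubber contributions add up to the
    agricultural-scope mean stock.
    """
    agri = (landscape.landuse != FOREST) & active_mask
    total = int(agri.sum())
    if total == 0:
        return None
    sel = agri & (landscape.landuse == crop)
    return float(landscape.carbon[sel].sum() / (total * CELL_AREA_HA))


def summarize_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-year mean and SD of every metric across replicates.

    With a single replicate the SD columns are NaN (flagged, not zero).
    """
    value_cols = [c for c in records.columns if c not in ("year", "replicate")]
    grouped = records.groupby("year")[value_cols]
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=1).add_suffix("_sd")
    return pd.concat([mean, sd], axis=1).reset_index()
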