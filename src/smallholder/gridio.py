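"""Import/export of landscapes and run outputs.

Grid layers are written as ESRI ASCII rasters (one file per layer:
``landuse`` coded 0 = forest, 1 = oil palm, 2 = rubber; ``age``;
``owner``), households as a comma-separated table.  The ASCII raster
header uses a 50 m cell size so the files georeference consistently
with the model's spatial scale.
"""

from __future__ import annotations

import os
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .agents import Household
from .config import CELL_SIZE_M
from .landscape import Landscape

NODATA = -9999

HOUSEHOLD_COLUMNS = [
    "h_id", "home_row", "home_col", "h_area", "h_wealth",
    "h_inefficiency_op", "h_inefficiency_rubber",
]


def write_ascii_grid(path, array: np.ndarray, cellsize: float = CELL_SIZE_M) -> None:
    """Write one layer as an ESRI ASCII grid."""
    arr = np.asarray(array)
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {cellsize}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fmt = "%d" if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool else "%.4f"
        np.savetxt(fh, arr, fmt=fmt, delimiter=" ")


def read_ascii_grid(path) -> Tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (array, cellsize)."""
    header: Dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    expected = (int(header["nrows"]), int(header["ncols"]))
    if data.shape != expected:
        raise ValueError(f"grid shape {data.shape} does not match header {expected}")
    return data, header["cellsize"]


def export_landscape(out_dir, landscape: Landscape, households: Sequence[Household]) -> None:
    """Write land use, age and owner rasters plus the household table."""
    os.makedirs(out_dir, exist_ok=True)
    write_ascii_grid(os.path.join(out_dir, "landuse.asc"), landscape.landuse)
    write_ascii_grid(os.path.join(out_dir, "age.asc"), landscape.age)
    write_ascii_grid(os.path.join(out_dir, "owner.asc"), landscape.owner)
    write_ascii_grid(os.path.join(out_dir, "road.asc"), landscape.road.astype(np.int8))
    households_table(households).to_csv(
        os.path.join(out_dir, "households.csv"), index=False
    )


def households_table(households: Sequence[Household]) -> pd.DataFrame:
    rows = [
        {
            "h_id": hh.h_id,
            "home_row": hh.home[0],
            "home_col": hh.home[1],
            "h_area": hh.area,
            "h_wealth": hh.wealth,
            "h_inefficiency_op": hh.ineff_op,
            "h_inefficiency_rubber": hh.ineff_rubber,
        }
        for hh in households
    ]
    return pd.DataFrame(rows, columns=HOUSEHOLD_COLUMNS)


def write_network_edges(path, households: Sequence[Household], distances: np.ndarray) -> None:
    """Edge-list CSV (h_id_a, h_id_b, distance_m) of the social network."""
    index = {hh.h_id: i for i, hh in enumerate(households)}
    rows: List[dict] = []
    for hh in households:
        for j in hh.connected:
            if hh.h_id < j:
                rows.append({
                    "h_id_a": hh.h_id,
                    "h_id_b": j,
                    "distance_m": distances[index[hh.h_id], index[j]],
                })
    pd.DataFrame(rows, columns=["h_id_a", "h_id_b", "distance_m"]).to_csv(
        path, index=False
    )
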