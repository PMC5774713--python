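"""Synthetic landscape generation.

Builds the initial state of a simulation: a rectilinear road lattice,
household home bases adjacent to roads, contiguous agricultural fields
grown around the home bases by seeded region-growing, initial crops and
plantation ages, and initial household wealth and inefficiency draws.

Grid conventions: row-major, 0-based indices, 4-neighborhood contiguity,
no wrap-around.  Each cell is 50 m x 50 m (0.25 ha).  Land-use codes are
0 = secondary forest, 1 = oil palm, 2 = rubber; roads and home bases are
carried in separate layers and count as non-agricultural.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .agents import Household
from .config import FOREST, OIL_PALM, RUBBER, InitConfig

logger = logging.getLogger(__name__)

_NEIGH = ((-1, 0), (1, 0), (0, -1), (0, 1))
#: 4-neighborhood structuring element for connected-component labelling.
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Field:
    """A contiguous set of cells of one household under one use and age."""

    field_id: int
    owner: int
    cells: np.ndarray  # flat cell indices into the row-major grid
    landuse: int = FOREST
    age: int = 0

    @property
    def size(self) -> int:
        return int(self.cells.size)


@dataclass
class Landscape:
    """Grid state: one numpy layer per cell variable, plus the field table."""

    width: int
    height: int
    road: np.ndarray = None  # bool
    landuse: np.ndarray = None  # int8, FOREST/OIL_PALM/RUBBER
    age: np.ndarray = None  # int16, years since establishment
    owner: np.ndarray = None  # int32, household id or -1
    homebase: np.ndarray = None  # int32, household id or -1
    field_id: np.ndarray = None  # int32, field id or -1
    carbon: np.ndarray = None  # float64, t C per cell
    production: np.ndarray = None  # float64, t per cell and year
    labor: np.ndarray = None  # float64, hours per cell and year
    tinput: np.ndarray = None  # float64, kg per cell and year
    capitalstock: np.ndarray = None  # float64, USD per cell
    fields: Dict[int, Field] = field(default_factory=dict)

    def __post_init__(self):
        shape = (self.height, self.width)
        if self.road is None:
            self.road = np.zeros(shape, dtype=bool)
            self.landuse = np.zeros(shape, dtype=np.int8)
            self.age = np.zeros(shape, dtype=np.int16)
            self.owner = np.full(shape, -1, dtype=np.int32)
            self.homebase = np.full(shape, -1, dtype=np.int32)
            self.field_id = np.full(shape, -1, dtype=np.int32)
            self.carbon = np.zeros(shape, dtype=float)
            self.production = np.zeros(shape, dtype=float)
            self.labor = np.zeros(shape, dtype=float)
            self.tinput = np.zeros(shape, dtype=float)
            self.capitalstock = np.zeros(shape, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    def flat(self, r: int, c: int) -> int:
        return r * self.width + c

    def unflat(self, idx: np.ndarray):
        return np.divmod(idx, self.width)

    def sync_field(self, f: Field) -> None:
        """Write a field's land use / age / size back into the cell layers."""
        r, c = self.unflat(f.cells)
        self.landuse[r, c] = f.landuse
        self.age[r, c] = f.age
        self.owner[r, c] = f.owner
        self.field_id[r, c] = f.field_id

    def fieldsize_layer(self) -> np.ndarray:
        """p_fieldsize: number of cells in the owning field, 0 elsewhere."""
        out = np.zeros((self.height, self.width), dtype=np.int32)
        for f in self.fields.values():
            r, c = self.unflat(f.cells)
            out[r, c] = f.size
        return out

    def agricultural_mask(self) -> np.ndarray:
        return self.landuse != FOREST


def generate_roads(config: InitConfig, landscape: Landscape) -> set:
    """Lay a rectilinear road lattice with the configured spacing.

    Lines are offset by half the spacing from the grid edge so the
    lattice is centred.  A spacing exceeding both grid dimensions
    degenerates to a single central cross (with a warning).  The
    resulting road network is a single connected component.
    """
    if config.road_spacing < 2:
        raise ValueError("road_spacing must be >= 2")
    h, w = landscape.height, landscape.width
    s = config.road_spacing
    road = landscape.road
    road[:] = False
    if s > max(h, w):
        warnings.warn(
            f"road spacing {s} exceeds grid extent {h}x{w}; "
            "falling back to a single central cross"
        )
        road[h // 2, :] = True
        road[:, w // 2] = True
    else:
        for r in range(s // 2, h, s):
            road[r, :] = True
        for c in range(s // 2, w, s):
            road[:, c] = True
    rr, cc = np.nonzero(road)
    return set(zip(rr.tolist(), cc.tolist()))


def road_adjacent_cells(landscape: Landscape) -> List[Tuple[int, int]]:
    """Non-road cells 4-adjacent to at least one road cell, row-major order."""
    road = landscape.road
    near = np.zeros_like(road)
    near[1:, :] |= road[:-1, :]
    near[:-1, :] |= road[1:, :]
    near[:, 1:] |= road[:, :-1]
    near[:, :-1] |= road[:, 1:]
    near &= ~road
    rr, cc = np.nonzero(near)
    return list(zip(rr.tolist(), cc.tolist()))


def place_households(
    config: InitConfig, landscape: Landscape, rng: np.random.Generator
) -> List[Household]:
    """Sample distinct road-adjacent home-base cells, one per household."""
    candidates = road_adjacent_cells(landscape)
    if config.n_households > len(candidates):
        raise ValueError(
            f"cannot place {config.n_households} households: only "
            f"{len(candidates)} road-adjacent cells available"
        )
    picks = rng.choice(len(candidates), size=config.n_households, replace=False)
    households = []
    for h_id, k in enumerate(picks):
        r, c = candidates[k]
        landscape.homebase[r, c] = h_id
        households.append(Household(h_id=h_id, home=(r, c)))
    return households


def _draw_household_areas(config: InitConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw per-household target areas (cells) summing to the agricultural target."""
    n = config.n_households
    raw = rng.normal(config.household_area_mean, config.household_area_sd, size=n)
    raw = np.clip(raw, config.household_area_min, None)
    return raw


def allocate_fields(
    config: InitConfig, landscape: Landscape, households: List[Household],
    rng: np.random.Generator,
) -> List[Field]:
    """Grow contiguous fields around each home base by seeded region-growing.

    Household target areas are drawn around ``household_area_mean`` and
    rescaled so total agricultural cover approximates
    ``agri_fraction_target``; each household's area is split into at most
    ``max_fields_per_household`` fields.  Growth claims free (non-road,
    non-home-base, unowned) cells; a blocked field is truncated at its
    current size.
    """
    areas = _draw_household_areas(config, rng)
    target_total = config.agri_fraction_target * landscape.n_cells
    areas = areas * (target_total / areas.sum())
    areas = np.maximum(np.round(areas).astype(int), config.household_area_min)

    free = (~landscape.road) & (landscape.homebase < 0) & (landscape.owner < 0)
    next_fid = 0
    order = rng.permutation(len(households))
    for k in order:
        hh = households[k]
        area = int(areas[k])
        n_fields = int(
            np.clip(
                round(area / ((config.field_size_min + config.field_size_max) / 2)),
                1,
                config.max_fields_per_household,
            )
        )
        mean_size = max(config.field_size_min, -(-area // n_fields))
        # grow fields until the target area is met; truncated fields are
        # compensated with further (smaller) fields, up to an attempt cap
        remaining = area
        attempts = 0
        while remaining > 0 and attempts < config.max_fields_per_household + 4:
            attempts += 1
            size = min(remaining, mean_size)
            if 0 < remaining - size < config.field_size_min:
                size = remaining
            cells = _grow_field(landscape, hh.home, size, free, rng)
            if cells.size == 0:
                logger.debug("household %d: no free seed cell left", hh.h_id)
                break
            if cells.size < size:
                logger.debug(
                    "household %d: field %d truncated at %d/%d cells",
                    hh.h_id, next_fid, cells.size, size,
                )
            f = Field(field_id=next_fid, owner=hh.h_id, cells=cells)
            landscape.fields[next_fid] = f
            hh.field_ids.append(next_fid)
            r, c = landscape.unflat(cells)
            landscape.owner[r, c] = hh.h_id
            landscape.field_id[r, c] = next_fid
            free[r, c] = False
            next_fid += 1
            remaining -= int(cells.size)
        hh.area = int(sum(landscape.fields[fid].size for fid in hh.field_ids))
    return list(landscape.fields.values())


def _grow_field(
    landscape: Landscape, home: Tuple[int, int], size: int,
    free: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """Region-grow one contiguous field of up to ``size`` free cells.

    The seed is the free cell nearest to ``home`` (breadth-first over the
    whole grid, so later fields of the same household may start further
    away but stay internally contiguous).
    """
    h, w = free.shape
    seed = _nearest_free(free, home)
    if seed is None:
        return np.empty(0, dtype=np.int64)
    taken = [seed]
    in_field = {seed}
    frontier = []
    seen = set()

    def push_neighbors(cell):
        r, c = cell
        for dr, dc in _NEIGH:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and free[nr, nc] and (nr, nc) not in seen:
                seen.add((nr, nc))
                frontier.append((nr, nc))

    seen.add(seed)
    push_neighbors(seed)
    while len(taken) < size and frontier:
        i = rng.integers(len(frontier))
        cell = frontier.pop(i)
        if not free[cell]:
            continue
        taken.append(cell)
        in_field.add(cell)
        push_neighbors(cell)
    return np.array([r * w + c for r, c in taken], dtype=np.int64)


def _nearest_free(free: np.ndarray, home: Tuple[int, int]) -> Optional[Tuple[int, int]]:
    """Breadth-first search from ``home`` for the nearest free cell."""
    h, w = free.shape
    from collections import deque

    q = deque([home])
    visited = {home}
    while q:
        r, c = q.popleft()
        if free[r, c]:
            return (r, c)
        for dr, dc in _NEIGH:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and (nr, nc) not in visited:
                visited.add((nr, nc))
                q.append((nr, nc))
    return None


def assign_initial_landuse(
    config: InitConfig, landscape: Landscape, rng: np.random.Generator
) -> None:
    """Assign each field a crop and an age.

    Fields are visited in random order; each is given whichever crop is
    currently furthest below its target cell share (rubber target =
    ``initial_rubber_share``), which balances the realized share to
    within one field of the target.  Ages are drawn uniformly per field
    from the crop-specific initial range.
    """
    fields = list(landscape.fields.values())
    order = rng.permutation(len(fields))
    n_rubber = 0
    n_total = 0
    for k in order:
        f = fields[k]
        share = n_rubber / n_total if n_total else 0.0
        if config.initial_rubber_share > 0 and (
            share < config.initial_rubber_share or config.initial_rubber_share >= 1.0
        ):
            f.landuse = RUBBER
            lo, hi = config.age_range_rubber
            n_rubber += f.size
        else:
            f.landuse = OIL_PALM
            lo, hi = config.age_range_op
        f.age = int(rng.integers(lo, hi + 1))
        n_total += f.size
        landscape.sync_field(f)


def draw_initial_wealth(
    config: InitConfig, households: List[Household], rng: np.random.Generator
) -> None:
    """Draw lognormal wealth and rank-match it to household areas.

    The sorted draws are assigned so that the wealth ordering matches
    the area ordering: larger holdings receive larger endowments.
    """
    n = len(households)
    draws = np.sort(
        rng.lognormal(config.wealth_lognormal_mu, config.wealth_lognormal_sigma, size=n)
    )
    area_order = np.argsort([hh.area for hh in households], kind="stable")
    for rank, idx in enumerate(area_order):
        households[idx].balance = float(draws[rank])


def draw_inefficiencies(
    config: InitConfig, households: List[Household],
    rng: np.random.Generator, enabled: bool,
) -> None:
    """Draw per-household, per-crop inefficiencies from a gamma distribution.

    Draws above 1 are rejected and redrawn (truncation by resampling),
    keeping the distribution shape on [0, 1].  With ``enabled=False``
    (efficient scenarios) every inefficiency is exactly zero.
    """
    if not enabled:
        for hh in households:
            hh.ineff_op = 0.0
            hh.ineff_rubber = 0.0
        return
    for hh in households:
        hh.ineff_op = _truncated_gamma(config, rng)
        hh.ineff_rubber = _truncated_gamma(config, rng)


def _truncated_gamma(config: InitConfig, rng: np.random.Generator) -> float:
    while True:
        x = rng.gamma(config.ineff_gamma_shape, config.ineff_gamma_scale)
        if x <= 1.0:
            return float(x)


def derive_patches(landscape: Landscape, age_class_width: int = 5) -> np.ndarray:
    """Partition cells into habitat patches, ignoring ownership.

    A patch is a 4-connected component of cells sharing land use and age
    class (``age // age_class_width``).  Returns an int label array
    (-1 outside patches, i.e. on roads); forest forms patches too.
    """
    key = landscape.landuse.astype(np.int64) * 1000 + (
        landscape.age.astype(np.int64) // age_class_width
    )
    key[landscape.road] = -1
    labels = np.full(key.shape, -1, dtype=np.int64)
    next_label = 0
    for val in np.unique(key):
        if val < 0:
            continue
        mask = key == val
        lab, n = ndimage.label(mask, structure=_STRUCT4)
        labels[mask] = lab[mask] + next_label - 1
        next_label += n
    return labels


def generate_landscape(
    config: InitConfig,
    rng_map: np.random.Generator,
    rng_wealth: np.random.Generator,
    rng_ineff: np.random.Generator,
    inefficiency_enabled: bool = False,
) -> Tuple[Landscape, List[Household]]:
    """Run the full initialization pipeline with separate RNG streams."""
    ls = Landscape(width=config.width, height=config.height)
    generate_roads(config, ls)
    households = place_households(config, ls, rng_map)
    allocate_fields(config, ls, households, rng_map)
    assign_initial_landuse(config, ls, rng_map)
    draw_initial_wealth(config, households, rng_wealth)
    draw_inefficiencies(config, households, rng_ineff, inefficiency_enabled)
    return ls, households
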