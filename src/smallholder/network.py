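"""Social networks from road distances, and inefficiency learning.

Households are linked based on the shortest-path distance between their
home bases along the road network (50 m per road-cell step).  Networks
are built once at initialization, either deterministically (all pairs
within the distance cap) or stochastically (link probability decays as a
negative exponential of distance, still subject to the cap).  Learning
is a partial adjustment of a household's crop inefficiency towards the
mean inefficiency of its connected, active neighbours — only downwards,
and only for crops the household currently cultivates ("learning by
doing").
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np

from .agents import Household
from .config import CELL_SIZE_M, NetworkConfig
from .landscape import Landscape, _NEIGH


def access_road_cell(landscape: Landscape, home) -> tuple:
    """The road cell adjacent to a home base (deterministic: first in
    up/down/left/right order)."""
    r, c = home
    for dr, dc in _NEIGH:
        nr, nc = r + dr, c + dc
        if 0 <= nr < landscape.height and 0 <= nc < landscape.width and landscape.road[nr, nc]:
            return (nr, nc)
    raise ValueError(f"home base {home} is not adjacent to any road cell")


def road_graph(landscape: Landscape) -> nx.Graph:
    """Unit-step graph over road cells (4-neighborhood)."""
    g = nx.Graph()
    rr, cc = np.nonzero(landscape.road)
    cells = set(zip(rr.tolist(), cc.tolist()))
    g.add_nodes_from(cells)
    for (r, c) in cells:
        for dr, dc in ((0, 1), (1, 0)):
            nb = (r + dr, c + dc)
            if nb in cells:
                g.add_edge((r, c), nb)
    return g


def road_distances(
    landscape: Landscape, households: Sequence[Household]
) -> np.ndarray:
    """Pairwise road distances between home bases, meters.

    Distance is 50 m times the shortest-path step count between the two
    households' access road cells; ``inf`` for disconnected pairs and 0
    on the diagonal.
    """
    g = road_graph(landscape)
    access = [access_road_cell(landscape, hh.home) for hh in households]
    n = len(households)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    # one BFS per distinct access cell
    by_cell: Dict[tuple, List[int]] = {}
    for i, cell in enumerate(access):
        by_cell.setdefault(cell, []).append(i)
    for cell, idxs in by_cell.items():
        lengths = nx.single_source_shortest_path_length(g, cell)
        for j, other in enumerate(access):
            steps = lengths.get(other)
            if steps is not None:
                for i in idxs:
                    d = CELL_SIZE_M * steps if i != j else 0.0
                    dist[i, j] = d
    return dist


def road_distance(
    landscape: Landscape, a: Household, b: Household
) -> float:
    """Road distance between two households' home bases, meters."""
    i = road_distances(landscape, [a, b])
    return float(i[0, 1])


def build_network(
    households: Sequence[Household],
    distances: np.ndarray,
    config: NetworkConfig,
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Populate ``h_connected_hhs`` symmetrically.

    Candidate pairs are those within ``d_cap_m``.  Deterministic mode
    links every candidate pair; stochastic mode links each independently
    with probability ``exp(-lambda * d)``.
    """
    if config.mode == "stochastic" and rng is None:
        raise ValueError("stochastic network construction requires an RNG")
    n = len(households)
    for hh in households:
        hh.connected = []
    for i in range(n):
        for j in range(i + 1, n):
            d = distances[i, j]
            if d > config.d_cap_m or math.isinf(d):
                continue
            if config.mode == "deterministic":
                link = True
            else:
                link = rng.random() < math.exp(-config.lambda_per_m * d)
            if link:
                households[i].connected.append(households[j].h_id)
                households[j].connected.append(households[i].h_id)


def network_mean_inefficiency(
    household: Household,
    by_id: Dict[int, Household],
    crop: int,
) -> Optional[float]:
    """Mean inefficiency for ``crop`` over connected, non-frozen neighbours."""
    vals = [
        by_id[j].inefficiency(crop)
        for j in household.connected
        if not by_id[j].frozen
    ]
    if not vals:
        return None
    return float(np.mean(vals))


def learning_update(
    household: Household,
    by_id: Dict[int, Household],
    crops_cultivated: Sequence[int],
    alpha: float,
) -> None:
    """Adjust inefficiencies towards the network mean, one year's step.

    For each crop the household currently cultivates: if its own
    inefficiency exceeds the network mean ``m``, it moves down by
    ``alpha * (own - m)``; otherwise (or with an empty network) it is
    unchanged.  Learning never increases an inefficiency.
    """
    for crop in crops_cultivated:
        m = network_mean_inefficiency(household, by_id, crop)
        if m is None:
            continue
        own = household.inefficiency(crop)
        if own > m:
            household.set_inefficiency(crop, own - alpha * (own - m))
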