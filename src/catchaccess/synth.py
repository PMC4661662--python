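"""Seeded generators for synthetic monocentric cities and micro-systems.

The city generator emulates the structure the accessibility methods were
designed for: population density that decays exponentially with distance
from a single center, facilities preferentially located centrally, and bed
capacities drawn independently of location (so a capacity-catchment
correlation in downstream results reflects the algorithm, not the
generator).  A square road grid with faster classes in the inner rings
supplies travel times.

Everything is driven by an explicit integer seed; identical parameters and
seed give byte-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CatchmentRecord,
    CatchmentTable,
    FacilitySite,
    ODMatrix,
    PopulationSite,
)
from .travel import RoadNetwork

__all__ = ["CityParams", "generate_city", "write_city", "generate_figure1_system", "Figure1System"]


@dataclass(frozen=True)
class CityParams:
    """Parameters of the synthetic monocentric city.

    ``density_scale`` is the population count at the center;
    ``density_decay_m`` the exponential length scale of the decline;
    ``facility_central_bias`` in [0, 1] skews facility placement toward
    the center (0 = uniform over the disc); ``capacity_law`` is
    (min_beds, max_beds, shape) for a heavy-tailed log-interpolated draw
    (larger shape concentrates mass near min_beds with a long upper tail).
    """

    n_populations: int = 200
    n_facilities: int = 20
    radius_m: float = 20_000.0
    density_scale: float = 4_000.0
    density_decay_m: float = 8_000.0
    facility_central_bias: float = 0.6
    capacity_law: tuple[float, float, float] = (20.0, 800.0, 2.0)
    grid_spacing_m: float = 2_500.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_populations <= 0 or self.n_facilities <= 0:
            raise ValueError("site counts must be > 0")
        if self.radius_m <= 0:
            raise ValueError("radius_m must be > 0")
        if not 0 <= self.facility_central_bias <= 1:
            raise ValueError("facility_central_bias must be in [0, 1]")
        lo, hi, shape = self.capacity_law
        if not (0 < lo <= hi and shape > 0):
            raise ValueError("capacity_law must satisfy 0 < min <= max, shape > 0")


def _population_sites(params: CityParams, rng: np.random.Generator) -> list[PopulationSite]:
    # candidate grid points inside the disc, jittered; spacing shrinks if
    # the requested count exceeds the default grid's capacity
    spacing = params.grid_spacing_m
    while True:
        coords = np.arange(-params.radius_m, params.radius_m + spacing / 2, spacing)
        gx, gy = np.meshgrid(coords, coords)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= params.radius_m]
        if len(pts) >= params.n_populations:
            break
        spacing *= 0.7
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    pts = pts[order]
    chosen = rng.choice(len(pts), size=params.n_populations, replace=False)
    chosen.sort()
    sites = []
    for k, idx in enumerate(chosen):
        jitter = rng.uniform(-0.3, 0.3, size=2) * spacing
        x, y = pts[idx] + jitter
        r = math.hypot(x, y)
        pop = round(params.density_scale * math.exp(-r / params.density_decay_m))
        sites.append(PopulationSite(id=f"p{k:04d}", x=x, y=y, population=float(pop)))
    return sites


def _facility_sites(params: CityParams, rng: np.random.Generator) -> list[FacilitySite]:
    lo, hi, shape = params.capacity_law
    # radial exponent 0.5 gives a uniform draw over the disc; larger
    # exponents concentrate facilities centrally
    exponent = 0.5 + 2.5 * params.facility_central_bias
    sites = []
    for k in range(params.n_facilities):
        r = params.radius_m * rng.random() ** exponent
        theta = rng.uniform(0, 2 * math.pi)
        u = rng.random()
        capacity = round(lo * (hi / lo) ** (u**shape))
        sites.append(
            FacilitySite(
                id=f"f{k:03d}",
                x=r * math.cos(theta),
                y=r * math.sin(theta),
                capacity=float(max(capacity, 1)),
            )
        )
    return sites


def _road_grid(params: CityParams) -> RoadNetwork:
    """Square grid covering the disc; inner rings get faster classes."""
    spacing = params.grid_spacing_m
    coords = np.arange(-params.radius_m, params.radius_m + spacing / 2, spacing)
    net = RoadNetwork()
    index = {}
    for i, x in enumerate(coords):
        for j, y in enumerate(coords):
            if math.hypot(x, y) <= params.radius_m * 1.05:
                nid = f"n{i:03d}_{j:03d}"
                net.add_node(nid, x, y)
                index[(i, j)] = nid
    r = params.radius_m

    def edge_class(x: float, y: float) -> str:
        rr = math.hypot(x, y)
        if rr < r / 4:
            return "expressway"
        if rr < r / 2:
            return "main"
        if rr < 3 * r / 4:
            return "secondary"
        return "other"

    for (i, j), u in index.items():
        for di, dj in ((1, 0), (0, 1)):
            v = index.get((i + di, j + dj))
            if v is not None:
                ux, uy = net.graph.nodes[u]["x"], net.graph.nodes[u]["y"]
                vx, vy = net.graph.nodes[v]["x"], net.graph.nodes[v]["y"]
                mx, my = (ux + vx) / 2, (uy + vy) / 2
                net.add_edge(u, v, spacing, edge_class(mx, my))
    return net


def generate_city(
    params: CityParams,
) -> tuple[list[FacilitySite], list[PopulationSite], RoadNetwork]:
    """Generate facilities, populations and the road grid for one city."""
    rng = np.random.default_rng(params.seed)
    populations = _population_sites(params, rng)
    facilities = _facility_sites(params, rng)
    network = _road_grid(params)
    return facilities, populations, network


def write_city(
    facilities: list[FacilitySite],
    populations: list[PopulationSite],
    network: RoadNetwork,
    out_dir: str | Path,
) -> None:
    """Write facilities.csv, populations.csv, nodes.csv, edges.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"id": f.id, "x": f.x, "y": f.y, "capacity": f.capacity} for f in facilities]
    ).to_csv(out / "facilities.csv", index=False, float_format="%.10g")
    pd.DataFrame(
        [{"id": p.id, "x": p.x, "y": p.y, "population": p.population} for p in populations]
    ).to_csv(out / "populations.csv", index=False, float_format="%.10g")
    network.to_csv(out / "nodes.csv", out / "edges.csv")


@dataclass
class Figure1System:
    """A micro-system fixture for the catchment-mismatch narratives.

    The travel times are synthetic stand-ins chosen to satisfy the
    narrative inequalities (the side whose catchment is too small cannot
    reach the other location); catchments are preset rather than computed.
    """

    facilities: list[FacilitySite]
    populations: list[PopulationSite]
    od: ODMatrix
    catchments: CatchmentTable


def generate_figure1_system(which: str) -> Figure1System:
    """Two-facility / two-population micro-systems.

    ``system1``: facilities a, b with catchments 20 min; population A with
    catchment 5 min; d(a,A)=12 (inside a's catchment but outside A's — the
    pair a mutual rule must drop), d(b,A)=3.

    ``system2``: populations A, B with catchments 20 min; facility a with
    catchment 12 min; d(a,B)=15 (inside B's catchment but outside a's),
    d(a,A)=5.
    """
    if which == "system1":
        facilities = [
            FacilitySite("a", 0.0, 0.0, 100.0),
            FacilitySite("b", 9_000.0, 0.0, 100.0),
        ]
        populations = [PopulationSite("A", 12_000.0, 0.0, 1_000.0)]
        od = ODMatrix(t_max=120.0)
        od.set_time("a", "A", 12.0)
        od.set_time("b", "A", 3.0)
        catchments = CatchmentTable(
            facility={
                "a": CatchmentRecord(20.0, 0.01, False),
                "b": CatchmentRecord(20.0, 0.01, False),
            },
            population={"A": CatchmentRecord(5.0, math.nan, False)},
        )
    elif which == "system2":
        facilities = [FacilitySite("a", 0.0, 0.0, 100.0)]
        populations = [
            PopulationSite("A", 4_000.0, 0.0, 1_000.0),
            PopulationSite("B", 13_000.0, 0.0, 1_000.0),
        ]
        od = ODMatrix(t_max=120.0)
        od.set_time("a", "A", 5.0)
        od.set_time("a", "B", 15.0)
        catchments = CatchmentTable(
            facility={"a": CatchmentRecord(12.0, 0.01, False)},
            population={
                "A": CatchmentRecord(20.0, math.nan, False),
                "B": CatchmentRecord(20.0, math.nan, False),
            },
        )
    else:
        raise ValueError(f"unknown system {which!r}; expected 'system1' or 'system2'")
    return Figure1System(facilities, populations, od, catchments)
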