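"""Origin-destination travel times from a classed road network.

Each road edge carries a length (m) and a class; class determines speed
(expressway 60 km/h, main 50, secondary 40, other 30), so the edge cost in
minutes is ``length_km / speed * 60``.  Sites are snapped to their nearest
network node by Euclidean distance with no access-time penalty, and the OD
time for a pair is the shortest-path time between the snapped nodes,
truncated at ``t_max``.  The network is undirected, so times are symmetric
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import FacilitySite, ODMatrix, PopulationSite

__all__ = ["ROAD_SPEEDS_KMH", "RoadNetwork", "edge_time", "read_network", "od_from_network"]

ROAD_SPEEDS_KMH: dict[str, float] = {
    "expressway": 60.0,
    "main": 50.0,
    "secondary": 40.0,
    "other": 30.0,
}


def edge_time(length_m: float, road_class: str) -> float:
    """Traversal time of one edge in minutes at the class's standard speed."""
    if not length_m > 0:
        raise ValueError(f"edge length must be > 0, got {length_m}")
    try:
        speed = ROAD_SPEEDS_KMH[road_class]
    except KeyError:
        raise ValueError(
            f"unknown road class {road_class!r}; expected one of "
            f"{sorted(ROAD_SPEEDS_KMH)}"
        ) from None
    return (length_m / 1000.0) / speed * 60.0


@dataclass
class RoadNetwork:
    """Undirected road graph with planar node coordinates (meters)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, node_id: str, x: float, y: float) -> None:
        self.graph.add_node(node_id, x=float(x), y=float(y))

    def add_edge(self, u: str, v: str, length_m: float, road_class: str) -> None:
        if u not in self.graph or v not in self.graph:
            missing = u if u not in self.graph else v
            raise ValueError(f"edge endpoint {missing!r} is not a known node")
        self.graph.add_edge(
            u,
            v,
            length_m=float(length_m),
            road_class=road_class,
            minutes=edge_time(length_m, road_class),
        )

    def node_array(self) -> tuple[list[str], np.ndarray]:
        ids = sorted(self.graph.nodes)
        xy = np.array(
            [[self.graph.nodes[n]["x"], self.graph.nodes[n]["y"]] for n in ids]
        )
        return ids, xy

    def to_csv(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        ids, xy = self.node_array()
        pd.DataFrame({"id": ids, "x": xy[:, 0], "y": xy[:, 1]}).to_csv(
            nodes_path, index=False, float_format="%.10g"
        )
        rows = [
            {"from": u, "to": v, "length_m": d["length_m"], "class": d["road_class"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["from", "to", "length_m", "class"]).to_csv(
            edges_path, index=False, float_format="%.10g"
        )


def read_network(nodes_path: str | Path, edges_path: str | Path) -> RoadNetwork:
    """Read ``nodes.csv`` (`id,x,y`) and ``edges.csv`` (`from,to,length_m,class`)."""
    nodes = pd.read_csv(nodes_path, dtype={"id": str})
    edges = pd.read_csv(edges_path, dtype={"from": str, "to": str})
    for col in ("id", "x", "y"):
        if col not in nodes.columns:
            raise ValueError(f"{nodes_path}: missing column {col!r}")
    for col in ("from", "to", "length_m", "class"):
        if col not in edges.columns:
            raise ValueError(f"{edges_path}: missing column {col!r}")
    net = RoadNetwork()
    for row in nodes.itertuples(index=False):
        net.add_node(str(row.id), row.x, row.y)
    # 'from'/'class' are Python keywords, so itertuples would mangle them
    for u, v, length_m, road_class in edges[
        ["from", "to", "length_m", "class"]
    ].itertuples(index=False, name=None):
        net.add_edge(str(u), str(v), length_m, str(road_class))
    return net


def _snap(net: RoadNetwork, sites: Sequence) -> dict[str, str]:
    ids, xy = net.node_array()
    tree = cKDTree(xy)
    pts = np.array([[s.x, s.y] for s in sites])
    _, idx = tree.query(pts)
    return {s.id: ids[i] for s, i in zip(sites, idx)}


def od_from_network(
    net: RoadNetwork,
    facilities: Sequence[FacilitySite],
    populations: Sequence[PopulationSite],
    t_max: float = 120.0,
) -> ODMatrix:
    """Many-to-many shortest-path travel times, one Dijkstra per facility.

    Pairs over ``t_max`` or in disjoint components are left unreachable.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("road network is empty")
    od = ODMatrix(t_max=t_max)
    if not facilities or not populations:
        return od
    fac_node = _snap(net, facilities)
    pop_node = _snap(net, populations)
    for f in sorted(facilities, key=lambda s: s.id):
        dist = nx.single_source_dijkstra_path_length(
            net.graph, fac_node[f.id], cutoff=t_max, weight="minutes"
        )
        for p in populations:
            t = dist.get(pop_node[p.id])
            if t is not None and t <= t_max:
                od.set_time(f.id, p.id, t)
    return od
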