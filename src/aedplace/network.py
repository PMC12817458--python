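"""Road-network substrate: graph construction, intersections, isochrones, distances.

The walkable road network is an undirected graph whose nodes are planar
points (metres) and whose edges carry segment lengths in metres. Candidate
AED locations are road intersections (nodes of degree >= 3); each candidate
is characterized through the isochrone reachable within a walking-time
budget at a fixed speed (default 3 minutes at 1.65 m/s, i.e. 297 m of
network distance).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

#: default pedestrian speed in metres per second
WALK_SPEED = 1.65
#: walking-time budgets in seconds
BUDGET_3MIN = 180.0
BUDGET_5MIN = 300.0
#: the corresponding network radii in metres (budget x speed)
RADIUS_3MIN = BUDGET_3MIN * WALK_SPEED  # 297 m
RADIUS_5MIN = BUDGET_5MIN * WALK_SPEED  # 495 m
#: default snap tolerance for point-in-isochrone membership, metres
SNAP_TOLERANCE = 50.0

NodeId = Hashable


@dataclass(frozen=True)
class Point:
    """A planar location in metres (easting, northing)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


class RoadNetwork:
    """Undirected weighted graph of walkable road segments.

    Nodes carry ``x``/``y`` attributes in metres; edges carry a ``length``
    attribute in metres. Lengths must be positive, self-loops are rejected,
    and at least one connected component must contain two or more nodes.
    """

    def __init__(self, graph: nx.Graph):
        self._validate(graph)
        self.graph = graph
        self._kdtree: cKDTree | None = None
        self._kdtree_nodes: list[NodeId] | None = None

    @staticmethod
    def _validate(graph: nx.Graph) -> None:
        for u, v, data in graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop edge at node {u!r}")
            length = data.get("length")
            if length is None or not length > 0:
                raise ValueError(f"edge ({u!r}, {v!r}) has non-positive length {length!r}")
        for node, data in graph.nodes(data=True):
            if "x" not in data or "y" not in data:
                raise ValueError(f"node {node!r} lacks coordinates")
        if graph.number_of_nodes() and max(
            (len(c) for c in nx.connected_components(graph)), default=0
        ) < 2:
            raise ValueError("no connected component with >= 2 nodes")

    @classmethod
    def from_edges(
        cls,
        nodes: Mapping[NodeId, tuple[float, float]],
        edges: Iterable[tuple[NodeId, NodeId, float]],
    ) -> "RoadNetwork":
        """Build a network from a node-coordinate map and (u, v, length) triples."""
        g = nx.Graph()
        for node, (x, y) in nodes.items():
            g.add_node(node, x=float(x), y=float(y))
        for u, v, length in edges:
            g.add_edge(u, v, length=float(length))
        return cls(g)

    # -- basic queries ---------------------------------------------------
    def __contains__(self, node: NodeId) -> bool:
        return node in self.graph

    @property
    def nodes(self) -> list[NodeId]:
        return list(self.graph.nodes)

    def node_point(self, node: NodeId) -> Point:
        data = self.graph.nodes[node]
        return Point(data["x"], data["y"])

    def node_xy(self) -> tuple[list[NodeId], np.ndarray]:
        """All node ids with an (n, 2) coordinate array, in a fixed order."""
        if self._kdtree_nodes is None:
            self._kdtree_nodes = list(self.graph.nodes)
        coords = np.array(
            [[self.graph.nodes[n]["x"], self.graph.nodes[n]["y"]] for n in self._kdtree_nodes],
            dtype=float,
        ).reshape(-1, 2)
        return self._kdtree_nodes, coords

    def kdtree(self) -> tuple[cKDTree, list[NodeId]]:
        if self._kdtree is None:
            ids, coords = self.node_xy()
            self._kdtree = cKDTree(coords)
            self._kdtree_nodes = ids
        return self._kdtree, self._kdtree_nodes  # type: ignore[return-value]

    def snap(self, point: Point) -> tuple[NodeId, float]:
        """Nearest network node to a point and its Euclidean offset in metres."""
        tree, ids = self.kdtree()
        dist, idx = tree.query([point.x, point.y])
        return ids[int(idx)], float(dist)


@dataclass(frozen=True)
class Isochrone:
    """Nodes reachable from an origin within a walking-time budget.

    ``radius`` is exactly ``budget * speed`` (metres); ``reached`` holds every
    node whose shortest-path network distance from the origin is <= radius.
    """

    origin: NodeId
    budget: float
    speed: float
    reached: frozenset = field(default_factory=frozenset)

    @property
    def radius(self) -> float:
        return self.budget * self.speed


@dataclass
class CandidateLocation:
    """A road intersection considered as a possible AED location."""

    id: int
    node: NodeId
    point: Point
    features: dict[str, float] | None = None
    empirical_rate: float | None = None
    risk: int | None = None
    #: un-rounded model risk score, used only as a deterministic tie-break
    risk_score: float | None = None

    def copy(self) -> "CandidateLocation":
        feats = dict(self.features) if self.features is not None else None
        return CandidateLocation(
            self.id, self.node, self.point, feats, self.empirical_rate, self.risk, self.risk_score
        )


def extract_intersections(network: RoadNetwork) -> list[CandidateLocation]:
    """One candidate per node of degree >= 3, ids assigned in ascending node order.

    Degree-2 nodes are geometric bends of a single road, not junctions, and
    are skipped. The result is independent of edge-list insertion order.
    """
    out: list[CandidateLocation] = []
    nodes = sorted(network.graph.nodes, key=lambda n: (str(type(n)), n))
    for node in nodes:
        if network.graph.degree[node] >= 3:
            out.append(CandidateLocation(id=len(out), node=node, point=network.node_point(node)))
    return out


def isochrone(
    network: RoadNetwork,
    origin: NodeId,
    budget: float = BUDGET_3MIN,
    speed: float = WALK_SPEED,
) -> Isochrone:
    """Single-source Dijkstra ball of network radius ``budget * speed`` metres."""
    if origin not in network:
        raise KeyError(f"unknown node {origin!r}")
    if budget <= 0 or speed <= 0:
        raise ValueError("budget and speed must be positive")
    radius = budget * speed
    dists = nx.single_source_dijkstra_path_length(
        network.graph, origin, cutoff=radius, weight="length"
    )
    return Isochrone(origin=origin, budget=budget, speed=speed, reached=frozenset(dists))


def network_distance(network: RoadNetwork, u: NodeId, v: NodeId) -> float:
    """Shortest-path length in metres; ``math.inf`` when disconnected."""
    for node in (u, v):
        if node not in network:
            raise KeyError(f"unknown node {node!r}")
    if u == v:
        return 0.0
    try:
        return float(nx.dijkstra_path_length(network.graph, u, v, weight="length"))
    except nx.NetworkXNoPath:
        return math.inf


def distances_within(network: RoadNetwork, origin: NodeId, radius: float) -> dict[NodeId, float]:
    """All nodes within ``radius`` metres of ``origin`` with their distances."""
    if origin not in network:
        raise KeyError(f"unknown node {origin!r}")
    return {
        n: float(d)
        for n, d in nx.single_source_dijkstra_path_length(
            network.graph, origin, cutoff=radius, weight="length"
        ).items()
    }
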