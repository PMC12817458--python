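"""Demographic and infrastructural feature aggregation per isochrone.

Each candidate intersection is characterized by the population, sex ratio,
age structure and point-of-interest counts found inside its 3-minute
isochrone. The spatial extent of an isochrone is represented by its set of
reached network nodes; a point (population tile, POI or alert) lies inside
iff it is within a snap tolerance of at least one reached node. A pure
Euclidean-disc mode (radius = budget x speed around the origin) is available
for tiny or degenerate test networks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .network import (
    SNAP_TOLERANCE,
    CandidateLocation,
    Isochrone,
    Point,
    RoadNetwork,
)

POI_CATEGORIES = (
    "public_building",
    "residential",
    "industrial",
    "sport",
    "transport",
    "parking",
)

#: feature-vector column names, in canonical order
FEATURE_NAMES = (
    "population",
    "sex_ratio",
    "persons_65_plus",
    "n_public_buildings",
    "residential_flag",
    "industrial_flag",
    "n_sport_facilities",
    "n_transport_stations",
    "n_parking_spaces",
)

#: the default model feature list excludes the age structure, which can be
#: switched back in where age data exists
DEFAULT_MODEL_FEATURES = tuple(f for f in FEATURE_NAMES if f != "persons_65_plus")

_CATEGORY_TO_FEATURE = {
    "public_building": "n_public_buildings",
    "sport": "n_sport_facilities",
    "transport": "n_transport_stations",
    "parking": "n_parking_spaces",
}


@dataclass
class PopulationLayer:
    """Per-tile person counts at point locations (planar metres)."""

    points: list[Point] = field(default_factory=list)
    persons: list[float] = field(default_factory=list)
    persons_female: list[float] = field(default_factory=list)
    persons_65_plus: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.points)
        if not self.persons_65_plus:
            self.persons_65_plus = [0.0] * n
        if not (len(self.persons) == len(self.persons_female) == len(self.persons_65_plus) == n):
            raise ValueError("population layer columns have unequal lengths")
        for p, f in zip(self.persons, self.persons_female):
            if not (p >= f >= 0):
                raise ValueError(f"tile with persons={p}, persons_female={f} violates 0 <= female <= persons")

    def __len__(self) -> int:
        return len(self.points)

    def xy(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points], dtype=float).reshape(-1, 2)


@dataclass
class POILayer:
    """Categorised points of interest (planar metres)."""

    points: list[Point] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.points) != len(self.categories):
            raise ValueError("POI layer columns have unequal lengths")
        for i, c in enumerate(self.categories):
            if c not in POI_CATEGORIES:
                raise ValueError(f"POI {i} has unknown category {c!r}")

    def __len__(self) -> int:
        return len(self.points)

    def xy(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points], dtype=float).reshape(-1, 2)


class ExtentIndex:
    """Precomputed point-to-nearby-node lists for fast isochrone membership.

    For each query point, the network nodes within the snap tolerance are
    found once; a point is inside a given isochrone iff any of those nodes
    is in the isochrone's reached set.
    """

    def __init__(
        self,
        network: RoadNetwork,
        points_xy: np.ndarray,
        snap_tolerance: float = SNAP_TOLERANCE,
    ):
        self.snap_tolerance = snap_tolerance
        tree, ids = network.kdtree()
        pts = np.asarray(points_xy, dtype=float).reshape(-1, 2)
        self.points_xy = pts
        if len(pts):
            neighbor_lists = tree.query_ball_point(pts, r=snap_tolerance)
        else:
            neighbor_lists = []
        self.nearby_nodes: list[list] = [[ids[j] for j in lst] for lst in neighbor_lists]

    def membership(self, iso: Isochrone, mode: str = "snap") -> np.ndarray:
        """Boolean inside-mask over the indexed points for one isochrone."""
        if mode == "snap":
            reached = iso.reached
            return np.array(
                [any(n in reached for n in lst) for lst in self.nearby_nodes], dtype=bool
            )
        raise ValueError(f"unknown membership mode {mode!r}")


def points_in_extent(
    network: RoadNetwork,
    iso: Isochrone,
    points: Sequence[Point],
    mode: str = "snap",
    snap_tolerance: float = SNAP_TOLERANCE,
) -> np.ndarray:
    """Which points fall inside the isochrone's spatial extent.

    ``mode="snap"`` (default): within ``snap_tolerance`` of a reached node.
    ``mode="euclidean"``: within ``iso.radius`` of the origin node, ignoring
    the network — intended for degenerate/tiny test networks.
    """
    xy = np.array([[p.x, p.y] for p in points], dtype=float).reshape(-1, 2)
    if not len(xy):
        return np.zeros(0, dtype=bool)
    if mode == "euclidean":
        origin = network.node_point(iso.origin)
        d = np.hypot(xy[:, 0] - origin.x, xy[:, 1] - origin.y)
        return d <= iso.radius
    if mode == "snap":
        return ExtentIndex(network, xy, snap_tolerance).membership(iso)
    raise ValueError(f"unknown membership mode {mode!r}")


def _zero_features() -> dict[str, float]:
    return {name: 0.0 for name in FEATURE_NAMES}


def aggregate_features(
    candidate: CandidateLocation,
    iso: Isochrone,
    pop: PopulationLayer,
    poi: POILayer,
    network: RoadNetwork,
    mode: str = "snap",
    snap_tolerance: float = SNAP_TOLERANCE,
) -> dict[str, float]:
    """Aggregate demographic and POI features over one candidate's isochrone.

    Population is summed over tiles inside the extent; the sex ratio is the
    female fraction (0 when no persons); POI counts are per category, with
    residential/industrial reduced to presence flags.
    """
    if iso.origin != candidate.node:
        raise ValueError("isochrone origin does not match candidate node")
    feats = _zero_features()
    if len(pop):
        mask = points_in_extent(network, iso, pop.points, mode, snap_tolerance)
        persons = float(np.asarray(pop.persons, dtype=float)[mask].sum())
        female = float(np.asarray(pop.persons_female, dtype=float)[mask].sum())
        older = float(np.asarray(pop.persons_65_plus, dtype=float)[mask].sum())
        feats["population"] = persons
        feats["sex_ratio"] = female / persons if persons > 0 else 0.0
        feats["persons_65_plus"] = older
    if len(poi):
        mask = points_in_extent(network, iso, poi.points, mode, snap_tolerance)
        for inside, cat in zip(mask, poi.categories):
            if not inside:
                continue
            if cat == "residential":
                feats["residential_flag"] = 1.0
            elif cat == "industrial":
                feats["industrial_flag"] = 1.0
            else:
                feats[_CATEGORY_TO_FEATURE[cat]] += 1.0
    return feats


def count_alerts(
    candidate: CandidateLocation,
    iso: Isochrone,
    alert_points: Sequence[Point],
    network: RoadNetwork,
    mode: str = "snap",
    snap_tolerance: float = SNAP_TOLERANCE,
) -> int:
    """Number of alerts whose location lies within the candidate's isochrone."""
    if iso.origin != candidate.node:
        raise ValueError("isochrone origin does not match candidate node")
    if not alert_points:
        return 0
    mask = points_in_extent(network, iso, alert_points, mode, snap_tolerance)
    return int(mask.sum())


def feature_table(
    network: RoadNetwork,
    candidates: Sequence[CandidateLocation],
    isochrones: dict,
    pop: PopulationLayer,
    poi: POILayer,
    alert_points: Sequence[Point] | None = None,
    mode: str = "snap",
    snap_tolerance: float = SNAP_TOLERANCE,
) -> pd.DataFrame:
    """One row of aggregated features per candidate, indexed by candidate id.

    When alert points are given an ``alerts_observed`` column is appended.
    Uses a shared spatial index over each layer, so the whole table costs a
    single KDTree query per layer rather than one per candidate.
    """
    pop_idx = ExtentIndex(network, pop.xy(), snap_tolerance) if len(pop) else None
    poi_idx = ExtentIndex(network, poi.xy(), snap_tolerance) if len(poi) else None
    alerts_xy = (
        np.array([[p.x, p.y] for p in alert_points], dtype=float).reshape(-1, 2)
        if alert_points
        else None
    )
    alert_idx = ExtentIndex(network, alerts_xy, snap_tolerance) if alerts_xy is not None else None

    persons = np.asarray(pop.persons, dtype=float) if len(pop) else None
    female = np.asarray(pop.persons_female, dtype=float) if len(pop) else None
    older = np.asarray(pop.persons_65_plus, dtype=float) if len(pop) else None
    poi_cats = np.asarray(poi.categories) if len(poi) else None

    rows = []
    for cand in candidates:
        iso = isochrones[cand.id]
        feats = _zero_features()
        if pop_idx is not None:
            mask = pop_idx.membership(iso, mode)
            tot = float(persons[mask].sum())
            feats["population"] = tot
            feats["sex_ratio"] = float(female[mask].sum()) / tot if tot > 0 else 0.0
            feats["persons_65_plus"] = float(older[mask].sum())
        if poi_idx is not None:
            mask = poi_idx.membership(iso, mode)
            cats = poi_cats[mask]
            feats["n_public_buildings"] = float((cats == "public_building").sum())
            feats["residential_flag"] = float((cats == "residential").any())
            feats["industrial_flag"] = float((cats == "industrial").any())
            feats["n_sport_facilities"] = float((cats == "sport").sum())
            feats["n_transport_stations"] = float((cats == "transport").sum())
            feats["n_parking_spaces"] = float((cats == "parking").sum())
        if alert_idx is not None:
            feats["alerts_observed"] = int(alert_idx.membership(iso, mode).sum())
        rows.append(feats)
    df = pd.DataFrame(rows, index=[c.id for c in candidates])
    df.index.name = "candidate_id"
    return df
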