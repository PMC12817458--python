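"""Synthetic city generator with a planted spatial alert-intensity function.

Because real dispatch alerts and AED registries are not openly deposited,
every input layer is emulated: a jittered grid road network, population
tiles and POIs concentrated around Gaussian hotspots, suspected-OHCA alerts
drawn from a spatial Poisson process whose per-candidate rate is a softplus
of a linear feature score (dominated by population, mirroring the finding
that population density is the strongest driver of alert risk), and a
deliberately clustered status-quo AED set near the densest hotspot.

Population tiles and POIs are placed as road-adjacent address points (small
jitter around network nodes), matching how address and POI data sit on
streets and keeping them inside the node-based isochrone extents.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .features import (
    FEATURE_NAMES,
    POILayer,
    PopulationLayer,
    ExtentIndex,
    feature_table,
)
from .network import (
    BUDGET_3MIN,
    SNAP_TOLERANCE,
    WALK_SPEED,
    CandidateLocation,
    Isochrone,
    Point,
    RoadNetwork,
    extract_intersections,
    isochrone,
)
from .placement import AEDSite
from .risk import AlertRecord, ObservationWindow, bin_risk_area

DEFAULT_POI_RATES = {
    "public_building": 6.0,  # expected count per km^2
    "residential": 8.0,
    "industrial": 2.0,
    "sport": 3.0,
    "transport": 4.0,
    "parking": 6.0,
}

DEFAULT_INTENSITY_WEIGHTS = {
    "population": 1.0,
    "sex_ratio": 0.0,
    "persons_65_plus": 0.25,
    "n_public_buildings": 0.3,
    "residential_flag": 0.1,
    "industrial_flag": -0.1,
    "n_sport_facilities": 0.15,
    "n_transport_stations": 0.3,
    "n_parking_spaces": 0.1,
}


@dataclass
class CityParams:
    """Knobs of the synthetic city; defaults give ~400 candidates in ~8.4 km^2."""

    grid_nx: int = 20
    grid_ny: int = 20
    spacing: float = 150.0  # metres between adjacent intersections
    edge_jitter: float = 0.12  # node jitter as a fraction of spacing
    pop_hotspots: int = 3
    pop_total: int = 40_000
    poi_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_POI_RATES))
    intensity_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_WEIGHTS)
    )
    years: float = 5.64  # observation span emulating a multi-year dispatch record
    expected_alerts: float = 1_000.0
    baseline_aeds: int = 30
    window_start: date = date(2018, 10, 7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.spacing <= 0 or self.pop_total <= 0 or self.years <= 0:
            raise ValueError("spacing, pop_total and years must be positive")

    @property
    def area_km2(self) -> float:
        return (self.grid_nx * self.spacing) * (self.grid_ny * self.spacing) / 1e6

    def window(self) -> ObservationWindow:
        days = round(self.years * 365.25)
        return ObservationWindow(self.window_start, self.window_start + timedelta(days=days))


@dataclass
class SyntheticCity:
    """A fully realised city: all five input layers plus derived structures."""

    params: CityParams
    network: RoadNetwork
    population: PopulationLayer
    pois: POILayer
    candidates: list[CandidateLocation]
    hotspot_centers: np.ndarray
    hotspot_weights: np.ndarray
    isochrones: dict[int, Isochrone] = field(default_factory=dict)
    feature_df: pd.DataFrame | None = None
    intensity: np.ndarray | None = None
    alerts: list[AlertRecord] = field(default_factory=list)
    baseline_aeds: list[AEDSite] = field(default_factory=list)

    @property
    def window(self) -> ObservationWindow:
        return self.params.window()

    def alert_points(self) -> list[Point]:
        return [a.point for a in self.alerts]


def _hotspot_density(xy: np.ndarray, centers: np.ndarray, weights: np.ndarray,
                     sigma: float, floor: float = 0.05) -> np.ndarray:
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    dens = (weights[None, :] * np.exp(-d2 / (2 * sigma**2))).sum(axis=1)
    return dens + floor * (weights.sum() if len(weights) else 1.0)


def generate_city(params: CityParams) -> SyntheticCity:
    """Jittered grid network with hotspot-structured population and POI layers.

    Interior nodes have degree 4 and boundary (non-corner) nodes degree 3,
    all valid intersections; the total population is allocated across
    road-adjacent tiles by a multinomial draw over hotspot-mixture weights,
    so tile persons sum exactly to ``pop_total``.
    """
    rng = np.random.default_rng(params.seed)
    nx_, ny_, s = params.grid_nx, params.grid_ny, params.spacing

    jitter = params.edge_jitter * s
    coords = {}
    for j in range(ny_):
        for i in range(nx_):
            node = j * nx_ + i
            dx, dy = rng.uniform(-jitter, jitter, size=2) if jitter > 0 else (0.0, 0.0)
            coords[node] = (i * s + dx, j * s + dy)
    edges = []
    for j in range(ny_):
        for i in range(nx_):
            u = j * nx_ + i
            for v in ((j * nx_ + i + 1) if i + 1 < nx_ else None,
                      ((j + 1) * nx_ + i) if j + 1 < ny_ else None):
                if v is not None:
                    length = math.dist(coords[u], coords[v])
                    edges.append((u, v, length))
    network = RoadNetwork.from_edges(coords, edges)
    node_ids, node_xy = network.node_xy()

    width, height = (nx_ - 1) * s, (ny_ - 1) * s
    margin = 0.15
    n_hot = max(1, params.pop_hotspots)
    centers = np.column_stack(
        [
            rng.uniform(margin * width, (1 - margin) * width, size=n_hot),
            rng.uniform(margin * height, (1 - margin) * height, size=n_hot),
        ]
    )
    weights = rng.uniform(0.5, 1.5, size=n_hot)
    weights[0] = weights.max() * 1.2  # a dominant city-centre hotspot
    sigma = 0.2 * max(width, height)

    # population tiles: one road-adjacent address point per node
    tile_jitter = rng.uniform(-30, 30, size=node_xy.shape)
    tile_xy = node_xy + tile_jitter
    dens = _hotspot_density(tile_xy, centers, weights, sigma)
    probs = dens / dens.sum()
    persons = rng.multinomial(params.pop_total, probs)
    p_female = np.clip(rng.normal(0.51, 0.02, size=len(persons)), 0.3, 0.7)
    female = rng.binomial(persons, p_female)
    p_old = np.clip(rng.normal(0.20, 0.04, size=len(persons)), 0.05, 0.45)
    older = rng.binomial(persons, p_old)
    population = PopulationLayer(
        points=[Point(float(x), float(y)) for x, y in tile_xy],
        persons=[float(v) for v in persons],
        persons_female=[float(v) for v in female],
        persons_65_plus=[float(v) for v in older],
    )

    # POIs: category-specific spatial preferences, snapped near road nodes
    industrial_anchor = np.array([width, 0.0])
    poi_points: list[Point] = []
    poi_cats: list[str] = []
    node_dens = _hotspot_density(node_xy, centers, weights, sigma)
    for cat in sorted(params.poi_rates):
        rate = params.poi_rates[cat]
        count = rng.poisson(rate * params.area_km2)
        if count == 0:
            continue
        if cat == "industrial":
            d2 = ((node_xy - industrial_anchor[None, :]) ** 2).sum(axis=1)
            w = np.exp(-d2 / (2 * (0.25 * max(width, height)) ** 2)) + 1e-6
        elif cat == "residential":
            w = node_dens
        else:
            w = node_dens**1.5
        w = w / w.sum()
        chosen = rng.choice(len(node_xy), size=count, p=w)
        offsets = rng.uniform(-40, 40, size=(count, 2))
        for k, idx in enumerate(chosen):
            x, y = node_xy[idx] + offsets[k]
            poi_points.append(Point(float(x), float(y)))
            poi_cats.append(cat)
    pois = POILayer(points=poi_points, categories=poi_cats)

    candidates = extract_intersections(network)
    return SyntheticCity(
        params=params,
        network=network,
        population=population,
        pois=pois,
        candidates=candidates,
        hotspot_centers=centers,
        hotspot_weights=weights,
    )


def planted_intensity(
    feature_df: pd.DataFrame,
    weights: dict[str, float],
    expected_alerts: float,
    years: float,
) -> np.ndarray:
    """Expected alerts/year per candidate: scaled softplus of a feature score.

    Features are z-scored across candidates before weighting, and the final
    multiplicative scaling makes the expected total alert count over the
    window equal ``expected_alerts`` while preserving the candidate ranking.
    """
    score = np.zeros(len(feature_df))
    for name, w in weights.items():
        if w == 0 or name not in feature_df.columns:
            continue
        col = feature_df[name].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            continue
        score += w * (col - col.mean()) / sd
    raw = np.logaddexp(0.0, score - 1.0)  # softplus, shifted so most areas are quiet
    total = raw.sum() * years
    if total <= 0:
        return np.zeros_like(raw)
    return raw * (expected_alerts / total)


def sample_alerts(
    intensity: np.ndarray,
    candidates: Sequence[CandidateLocation],
    isochrones: dict[int, Isochrone],
    network: RoadNetwork,
    window: ObservationWindow,
    seed: int,
    scatter_radius: float = 0.9 * SNAP_TOLERANCE,
) -> list[AlertRecord]:
    """Poisson-sample alerts per candidate and scatter them in its extent.

    Each alert lands within ``scatter_radius`` of a uniformly chosen reached
    node of the candidate's 3-minute isochrone, so it is inside the extent
    under the snap-membership rule; timestamps are uniform over the window.
    """
    rng = np.random.default_rng(seed)
    years = window.years
    total_days = (window.end - window.start).days
    start_dt = datetime.combine(window.start, datetime.min.time())
    alerts: list[AlertRecord] = []
    for cand, lam in zip(candidates, intensity):
        k = rng.poisson(lam * years)
        if k == 0:
            continue
        iso = isochrones[cand.id]
        reached = sorted(iso.reached)
        node_choice = rng.integers(0, len(reached), size=k)
        angles = rng.uniform(0, 2 * math.pi, size=k)
        radii = scatter_radius * np.sqrt(rng.uniform(0, 1, size=k))
        day_offsets = rng.uniform(0, total_days, size=k)
        for m in range(k):
            p = network.node_point(reached[node_choice[m]])
            pt = Point(p.x + radii[m] * math.cos(angles[m]), p.y + radii[m] * math.sin(angles[m]))
            ts = start_dt + timedelta(days=float(day_offsets[m]))
            alerts.append(AlertRecord(id=len(alerts), point=pt, timestamp=ts))
    return alerts


def place_baseline_aeds(
    candidates: Sequence[CandidateLocation],
    center: np.ndarray,
    count: int,
    seed: int,
    scale: float = 400.0,
) -> list[AEDSite]:
    """Clustered status-quo AEDs: sampled preferentially near the city centre.

    Emulates unplanned historical installation concentrated in the densest
    hotspot rather than ranked by risk; deliberately suboptimal coverage.
    """
    if count > len(candidates):
        raise ValueError("cannot place more baseline AEDs than candidates")
    if count == 0:
        return []
    rng = np.random.default_rng(seed)
    xy = np.array([[c.point.x, c.point.y] for c in candidates])
    d2 = ((xy - np.asarray(center)[None, :]) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2 * scale**2)) + 1e-9
    idx = rng.choice(len(candidates), size=count, replace=False, p=w / w.sum())
    return [
        AEDSite(id=i, point=candidates[j].point, node=candidates[j].node, always_available=True)
        for i, j in enumerate(sorted(idx))
    ]


def build_city(params: CityParams) -> SyntheticCity:
    """Generate a city and derive everything the analysis consumes.

    Runs the full emulation chain: network and layers, 3-minute isochrones
    and aggregated features per candidate, the planted intensity, the Poisson
    alert sample, empirical alert counts / rates / risk areas per candidate,
    and the clustered baseline AED set.
    """
    city = generate_city(params)
    net = city.network
    city.isochrones = {
        c.id: isochrone(net, c.node, BUDGET_3MIN, WALK_SPEED) for c in city.candidates
    }
    feats = feature_table(net, city.candidates, city.isochrones, city.population, city.pois)
    window = params.window()
    city.intensity = planted_intensity(
        feats, params.intensity_weights, params.expected_alerts, window.years
    )
    city.alerts = sample_alerts(
        city.intensity, city.candidates, city.isochrones, net, window, seed=params.seed + 1
    )
    alert_xy = np.array([[a.point.x, a.point.y] for a in city.alerts]).reshape(-1, 2)
    alert_idx = ExtentIndex(net, alert_xy)
    counts = np.array(
        [alert_idx.membership(city.isochrones[c.id]).sum() for c in city.candidates], dtype=float
    )
    feats["alerts_observed"] = counts.astype(int)
    feats["rate"] = counts / window.years
    feats["risk_area"] = [bin_risk_area(r) for r in feats["rate"]]
    city.feature_df = feats
    for c in city.candidates:
        c.features = {name: float(feats.loc[c.id, name]) for name in FEATURE_NAMES}
        c.empirical_rate = float(feats.loc[c.id, "rate"])
        c.risk = int(feats.loc[c.id, "risk_area"])
    city.baseline_aeds = place_baseline_aeds(
        city.candidates, city.hotspot_centers[0], params.baseline_aeds, seed=params.seed + 2
    )
    return city
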