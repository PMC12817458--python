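"""GeoJSON/CSV readers and writers, local projection, configuration, pipeline.

All core computation runs in a planar frame in metres. Geographic inputs
(lon/lat, detected by coordinate range unless the file carries the package's
own ``crs: local-metres`` stamp) are projected once at read time with a
local azimuthal equidistant projection about a reference point, which keeps
distances at city scale faithful to within a fraction of a percent.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluation import ScenarioResult, canonical_scenarios, run_scenario, scenario_table
from .features import (
    DEFAULT_MODEL_FEATURES,
    FEATURE_NAMES,
    POILayer,
    POI_CATEGORIES,
    PopulationLayer,
    ExtentIndex,
    feature_table,
)
from .network import (
    BUDGET_3MIN,
    SNAP_TOLERANCE,
    WALK_SPEED,
    CandidateLocation,
    Point,
    RoadNetwork,
    extract_intersections,
    isochrone,
)
from .placement import AEDSite, PlacementResult
from .risk import AlertRecord, ObservationWindow, bin_risk_area, fit_risk_tree, screen_features
from .synthetic import CityParams, SyntheticCity, build_city

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_008.8
LOCAL_CRS_STAMP = "local-metres"


class LocalProjection:
    """Azimuthal equidistant projection about a reference lon/lat (degrees)."""

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = math.radians(lon0)
        self.lat0 = math.radians(lat0)

    def forward(self, lon: float, lat: float) -> tuple[float, float]:
        lam, phi = math.radians(lon), math.radians(lat)
        dlam = lam - self.lon0
        cos_c = math.sin(self.lat0) * math.sin(phi) + math.cos(self.lat0) * math.cos(phi) * math.cos(dlam)
        c = math.acos(min(1.0, max(-1.0, cos_c)))
        k = 1.0 if c == 0 else c / math.sin(c)
        x = EARTH_RADIUS_M * k * math.cos(phi) * math.sin(dlam)
        y = EARTH_RADIUS_M * k * (
            math.cos(self.lat0) * math.sin(phi)
            - math.sin(self.lat0) * math.cos(phi) * math.cos(dlam)
        )
        return x, y


def _load_geojson(path: str | Path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    return data


def _all_coords(data: dict):
    for feat in data.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") == "Point":
            yield geom["coordinates"]
        elif geom.get("type") == "LineString":
            yield from geom["coordinates"]


def _looks_geographic(data: dict) -> bool:
    if data.get("crs") == LOCAL_CRS_STAMP:
        return False
    coords = list(_all_coords(data))
    if not coords:
        return False
    return all(abs(c[0]) <= 180 and abs(c[1]) <= 90 for c in coords)


def _projection_for(data: dict, projection: LocalProjection | None) -> LocalProjection | None:
    if not _looks_geographic(data):
        return None
    if projection is not None:
        return projection
    coords = np.array(list(_all_coords(data)), dtype=float)
    return LocalProjection(float(coords[:, 0].mean()), float(coords[:, 1].mean()))


def _project(coord: Sequence[float], proj: LocalProjection | None) -> tuple[float, float]:
    if proj is None:
        return float(coord[0]), float(coord[1])
    return proj.forward(float(coord[0]), float(coord[1]))


def read_network(
    path: str | Path,
    projection: LocalProjection | None = None,
    dedupe_tolerance: float = 0.5,
) -> RoadNetwork:
    """Road network from GeoJSON LineStrings.

    Consecutive vertices of each line become edges; the ``length_m`` property
    overrides the geometric length of a whole feature when present. Nodes are
    deduplicated by coordinate within half a metre.
    """
    data = _load_geojson(path)
    proj = _projection_for(data, projection)
    key_to_node: dict[tuple[int, int], int] = {}
    coords: dict[int, tuple[float, float]] = {}
    edges: list[tuple[int, int, float]] = []

    def node_for(xy: tuple[float, float]) -> int:
        key = (round(xy[0] / dedupe_tolerance), round(xy[1] / dedupe_tolerance))
        if key not in key_to_node:
            key_to_node[key] = len(key_to_node)
            coords[key_to_node[key]] = xy
        return key_to_node[key]

    for i, feat in enumerate(data["features"]):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise ValueError(f"feature {i}: expected LineString, got {geom.get('type')!r}")
        pts = [_project(c, proj) for c in geom["coordinates"]]
        if len(pts) < 2:
            raise ValueError(f"feature {i}: LineString needs >= 2 coordinates")
        geom_len = sum(math.dist(a, b) for a, b in zip(pts, pts[1:]))
        override = (feat.get("properties") or {}).get("length_m")
        for a, b in zip(pts, pts[1:]):
            u, v = node_for(a), node_for(b)
            if u == v:
                continue
            seg = math.dist(a, b)
            length = seg * (override / geom_len) if override else seg
            edges.append((u, v, length))
    return RoadNetwork.from_edges(coords, edges)


def _read_points(path: str | Path, projection: LocalProjection | None):
    data = _load_geojson(path)
    proj = _projection_for(data, projection)
    for i, feat in enumerate(data["features"]):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"feature {i}: expected Point, got {geom.get('type')!r}")
        x, y = _project(geom["coordinates"], proj)
        yield i, Point(x, y), (feat.get("properties") or {})


def read_population(path: str | Path, projection: LocalProjection | None = None) -> PopulationLayer:
    points, persons, female, older = [], [], [], []
    for i, pt, props in _read_points(path, projection):
        if "persons" not in props:
            raise ValueError(f"feature {i}: missing field 'persons'")
        points.append(pt)
        persons.append(float(props["persons"]))
        female.append(float(props.get("persons_female", 0.0)))
        older.append(float(props.get("persons_65_plus", 0.0)))
    return PopulationLayer(points, persons, female, older)


def read_pois(path: str | Path, projection: LocalProjection | None = None) -> POILayer:
    points, cats = [], []
    for i, pt, props in _read_points(path, projection):
        cat = props.get("category")
        if cat not in POI_CATEGORIES:
            raise ValueError(f"feature {i}: unknown category {cat!r}")
        points.append(pt)
        cats.append(cat)
    return POILayer(points, cats)


def read_alerts(path: str | Path, projection: LocalProjection | None = None) -> list[AlertRecord]:
    alerts = []
    for i, pt, props in _read_points(path, projection):
        ts = props.get("timestamp")
        if ts is None:
            raise ValueError(f"feature {i}: missing field 'timestamp'")
        alerts.append(AlertRecord(id=int(props.get("id", i)), point=pt,
                                  timestamp=datetime.fromisoformat(ts)))
    return alerts


def read_aeds(path: str | Path, projection: LocalProjection | None = None) -> list[AEDSite]:
    aeds = []
    for i, pt, props in _read_points(path, projection):
        aeds.append(
            AEDSite(
                id=int(props.get("id", i)),
                point=pt,
                always_available=bool(props.get("always_available", True)),
            )
        )
    return aeds


READERS = {
    "network": read_network,
    "population": read_population,
    "pois": read_pois,
    "alerts": read_alerts,
    "aeds": read_aeds,
}


def read_layer(path: str | Path, kind: str, projection: LocalProjection | None = None):
    """Typed reader dispatch; ``kind`` is one of network/population/pois/alerts/aeds."""
    if kind not in READERS:
        raise ValueError(f"unknown layer kind {kind!r}")
    return READERS[kind](path, projection)


# -- writers -------------------------------------------------------------


def _dump_geojson(path: str | Path, features: list[dict], extra: dict | None = None) -> None:
    doc = {"type": "FeatureCollection", "crs": LOCAL_CRS_STAMP}
    if extra:
        doc.update(extra)
    doc["features"] = features
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _point_feature(pt: Point, props: dict) -> dict:
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [round(pt.x, 3), round(pt.y, 3)]},
        "properties": props,
    }


def write_network(path: str | Path, network: RoadNetwork) -> None:
    feats = []
    for u, v, data in sorted(network.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        pu, pv = network.node_point(u), network.node_point(v)
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [round(pu.x, 3), round(pu.y, 3)],
                        [round(pv.x, 3), round(pv.y, 3)],
                    ],
                },
                "properties": {"length_m": round(data["length"], 3)},
            }
        )
    _dump_geojson(path, feats)


def write_population(path: str | Path, layer: PopulationLayer) -> None:
    feats = [
        _point_feature(
            pt,
            {
                "persons": layer.persons[i],
                "persons_female": layer.persons_female[i],
                "persons_65_plus": layer.persons_65_plus[i],
            },
        )
        for i, pt in enumerate(layer.points)
    ]
    _dump_geojson(path, feats)


def write_pois(path: str | Path, layer: POILayer) -> None:
    feats = [
        _point_feature(pt, {"category": layer.categories[i]}) for i, pt in enumerate(layer.points)
    ]
    _dump_geojson(path, feats)


def write_alerts(path: str | Path, alerts: Sequence[AlertRecord]) -> None:
    feats = [
        _point_feature(a.point, {"id": a.id, "timestamp": a.timestamp.isoformat()}) for a in alerts
    ]
    _dump_geojson(path, feats)


def write_aeds(path: str | Path, aeds: Sequence[AEDSite]) -> None:
    feats = [
        _point_feature(a.point, {"id": a.id, "always_available": a.always_available}) for a in aeds
    ]
    _dump_geojson(path, feats)


def write_placement(path: str | Path, result: PlacementResult, config_hash: str = "") -> None:
    """Selected sites as GeoJSON points with iteration index and risk at selection."""
    feats = [
        _point_feature(
            cand.point,
            {
                "iteration": i,
                "candidate_id": cand.id,
                "risk_at_selection": result.log[i].risk_at_selection,
            },
        )
        for i, cand in enumerate(result.selected)
    ]
    _dump_geojson(path, feats, extra={"config_hash": config_hash,
                                      "reduction_constant": result.reduction_constant})


def write_audit_log(path: str | Path, result: PlacementResult, config_hash: str = "") -> None:
    doc = {
        "config_hash": config_hash,
        "reduction_constant": result.reduction_constant,
        "iterations": [
            {
                "chosen_id": rec.chosen_id,
                "risk_at_selection": rec.risk_at_selection,
                "removed_ids": rec.removed_ids,
                "decayed": [list(t) for t in rec.decayed],
            }
            for rec in result.log
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


# -- configuration and pipeline -----------------------------------------


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; serialisable to/from YAML."""

    synthetic: dict | None = None  # CityParams overrides; None => read files
    network_path: str | None = None
    population_path: str | None = None
    pois_path: str | None = None
    alerts_path: str | None = None
    aeds_path: str | None = None
    window_start: str = "2018-10-07"
    window_end: str = "2024-05-28"
    speed: float = WALK_SPEED
    budget_3min: float = 180.0
    budget_5min: float = 300.0
    snap_tolerance: float = SNAP_TOLERANCE
    coverage_mode: str = "euclidean_300"
    reduction_constant: int = 2
    scenarios: tuple[str, ...] = ("0", "1", "2", "A", "B", "C")
    include_age_feature: bool = False
    seed: int = 0
    outdir: str = "aedplace_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.scenarios = tuple(cfg.scenarios)
        return cfg

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["scenarios"] = list(self.scenarios)
        return d

    def hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class PipelineState:
    """Intermediate products of a run, filled in stage by stage."""

    config: RunConfig
    network: RoadNetwork | None = None
    population: PopulationLayer | None = None
    pois: POILayer | None = None
    alerts: list[AlertRecord] = field(default_factory=list)
    existing_aeds: list[AEDSite] = field(default_factory=list)
    window: ObservationWindow | None = None
    candidates: list[CandidateLocation] = field(default_factory=list)
    isochrones: dict = field(default_factory=dict)
    feature_df: pd.DataFrame | None = None
    selected_features: list[str] = field(default_factory=list)
    model: object | None = None
    results: list[ScenarioResult] = field(default_factory=list)
    city: SyntheticCity | None = None


def load_inputs(config: RunConfig) -> PipelineState:
    """Stage 1: synthesize or read the five input layers."""
    state = PipelineState(config=config)
    if config.synthetic is not None:
        overrides = dict(config.synthetic)
        overrides.setdefault("seed", config.seed)
        city = build_city(CityParams(**overrides))
        state.city = city
        state.network = city.network
        state.population = city.population
        state.pois = city.pois
        state.alerts = city.alerts
        state.existing_aeds = city.baseline_aeds
        state.window = city.window
        state.candidates = city.candidates
        state.isochrones = city.isochrones
        state.feature_df = city.feature_df
    else:
        proj: LocalProjection | None = None
        data = _load_geojson(config.network_path)
        if _looks_geographic(data):
            coords = np.array(list(_all_coords(data)), dtype=float)
            proj = LocalProjection(float(coords[:, 0].mean()), float(coords[:, 1].mean()))
        state.network = read_network(config.network_path, proj)
        state.population = read_population(config.population_path, proj)
        state.pois = read_pois(config.pois_path, proj)
        state.alerts = read_alerts(config.alerts_path, proj)
        state.existing_aeds = read_aeds(config.aeds_path, proj) if config.aeds_path else []
        state.window = ObservationWindow(
            date.fromisoformat(config.window_start), date.fromisoformat(config.window_end)
        )
    return state


def characterize(state: PipelineState) -> PipelineState:
    """Stage 2: candidates, isochrones, features, empirical rates and risk areas."""
    cfg = state.config
    if not state.candidates:
        state.candidates = extract_intersections(state.network)
    if not state.isochrones:
        state.isochrones = {
            c.id: isochrone(state.network, c.node, cfg.budget_3min, cfg.speed)
            for c in state.candidates
        }
    if state.feature_df is None:
        feats = feature_table(
            state.network, state.candidates, state.isochrones, state.population, state.pois,
            snap_tolerance=cfg.snap_tolerance,
        )
        alert_xy = np.array([[a.point.x, a.point.y] for a in state.alerts]).reshape(-1, 2)
        idx = ExtentIndex(state.network, alert_xy, cfg.snap_tolerance)
        counts = np.array(
            [idx.membership(state.isochrones[c.id]).sum() for c in state.candidates], dtype=float
        )
        feats["alerts_observed"] = counts.astype(int)
        feats["rate"] = counts / state.window.years
        feats["risk_area"] = [bin_risk_area(r) for r in feats["rate"]]
        state.feature_df = feats
        for c in state.candidates:
            c.features = {n: float(feats.loc[c.id, n]) for n in FEATURE_NAMES}
            c.empirical_rate = float(feats.loc[c.id, "rate"])
            c.risk = int(feats.loc[c.id, "risk_area"])
    return state


def train(state: PipelineState) -> PipelineState:
    """Stage 3: feature screening and the regression-tree fit."""
    cfg = state.config
    pool = list(FEATURE_NAMES) if cfg.include_age_feature else list(DEFAULT_MODEL_FEATURES)
    state.selected_features = screen_features(state.feature_df, features=pool)
    state.model = fit_risk_tree(state.feature_df, state.selected_features, seed=cfg.seed)
    return state


def scenarios(state: PipelineState) -> PipelineState:
    """Stage 4: run the configured scenarios and collect coverage reports."""
    cfg = state.config
    n_existing = len(state.existing_aeds)
    n_match = n_existing if n_existing else 95
    specs = canonical_scenarios(n_match=n_match, n_additional=max(1, round(0.2 * n_match)))
    state.results = [
        run_scenario(
            specs[sid], state.candidates, state.network, state.alerts, state.existing_aeds,
            model=state.model, reduction_constant=cfg.reduction_constant,
            coverage_mode=cfg.coverage_mode,
        )
        for sid in cfg.scenarios
    ]
    return state


def run_pipeline(config: RunConfig, write: bool = True) -> pd.DataFrame:
    """Full run: load -> characterize -> train -> scenarios, artifacts on disk.

    Returns the scenario comparison table; when ``write`` is set, all
    artifacts (feature table, model summary, placements, audit logs, table)
    are written under ``config.outdir``, each carrying the config hash.
    """
    chash = config.hash()
    t0 = time.perf_counter()
    state = load_inputs(config)
    logger.info("inputs ready in %.2fs", time.perf_counter() - t0)
    for stage in (characterize, train, scenarios):
        t = time.perf_counter()
        state = stage(state)
        logger.info("stage %s done in %.2fs", stage.__name__, time.perf_counter() - t)
    table = scenario_table(state.results)

    if write:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash: {chash}\n"
        (out / "features.csv").write_text(header + state.feature_df.to_csv())
        (out / "scenario_table.csv").write_text(header + table.to_csv(index=False))
        model_doc = state.model.to_dict()
        model_doc["config_hash"] = chash
        (out / "model.json").write_text(json.dumps(model_doc, indent=1) + "\n")
        for res in state.results:
            if res.placement is not None:
                write_placement(out / f"placement_{res.spec.id}.geojson", res.placement, chash)
                write_audit_log(out / f"audit_{res.spec.id}.json", res.placement, chash)
        run_doc = {"config": config.to_dict(), "config_hash": chash, "seed": config.seed}
        (out / "run.yaml").write_text(yaml.safe_dump(run_doc, sort_keys=True))
    return table


def write_city(outdir: str | Path, city: SyntheticCity) -> None:
    """Write all five synthetic layers plus a params provenance stamp."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_network(out / "network.geojson", city.network)
    write_population(out / "population.geojson", city.population)
    write_pois(out / "pois.geojson", city.pois)
    write_alerts(out / "alerts.geojson", city.alerts)
    write_aeds(out / "aeds.geojson", city.baseline_aeds)
    params = dict(city.params.__dict__)
    params["window_start"] = city.params.window_start.isoformat()
    (out / "params.yaml").write_text(yaml.safe_dump(params, sort_keys=True))
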