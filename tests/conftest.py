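"""Shared fixtures: tiny hand-built networks, a reference synthetic city,
and the multi-seed replication study used by the scenario-ordering checks."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from aedplace import (
    DEFAULT_MODEL_FEATURES,
    CandidateLocation,
    CityParams,
    RoadNetwork,
    Termination,
    build_city,
    canonical_scenarios,
    coverage,
    fit_risk_tree,
    run_scenario,
    screen_features,
)


@pytest.fixture
def star_network() -> RoadNetwork:
    """Centre node 0 joined to three leaves: the only degree->=3 node."""
    nodes = {0: (0.0, 0.0), 1: (100.0, 0.0), 2: (0.0, 100.0), 3: (-100.0, 0.0)}
    edges = [(0, 1, 100.0), (0, 2, 100.0), (0, 3, 100.0)]
    return RoadNetwork.from_edges(nodes, edges)


@pytest.fixture
def path_network() -> RoadNetwork:
    """Path a-b-c with edge lengths 100 and 250 metres."""
    nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0), "c": (350.0, 0.0)}
    edges = [("a", "b", 100.0), ("b", "c", 250.0)]
    return RoadNetwork.from_edges(nodes, edges)


def line_network(n: int = 10, step: float = 120.0) -> RoadNetwork:
    nodes = {i: (i * step, 0.0) for i in range(n)}
    edges = [(i, i + 1, step) for i in range(n - 1)]
    return RoadNetwork.from_edges(nodes, edges)


def line_candidates(network: RoadNetwork, risks=None) -> list[CandidateLocation]:
    cands = [
        CandidateLocation(id=i, node=n, point=network.node_point(n))
        for i, n in enumerate(sorted(network.graph.nodes))
    ]
    if risks is not None:
        for c, r in zip(cands, risks):
            c.risk = int(r)
    return cands


def random_geometric_network(rng: np.random.Generator, n_nodes: int) -> RoadNetwork:
    """Random planar graph: uniform points, each joined to its 2-3 nearest."""
    xy = rng.uniform(0, 1000, size=(n_nodes, 2))
    nodes = {i: (float(xy[i, 0]), float(xy[i, 1])) for i in range(n_nodes)}
    edges = set()
    for i in range(n_nodes):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        order = np.argsort(d)
        k = int(rng.integers(2, 4))
        for j in order[1 : k + 1]:
            a, b = min(i, int(j)), max(i, int(j))
            if a != b:
                edges.add((a, b, float(max(d[j], 1e-6))))
    return RoadNetwork.from_edges(nodes, list(edges))


@pytest.fixture(scope="session")
def city7():
    """The reference synthetic city at the default study scale (seed 7)."""
    return build_city(CityParams(seed=7))


@pytest.fixture(scope="session")
def model7(city7):
    """Screened features and fitted regression tree for the reference city."""
    selected = screen_features(city7.feature_df, features=list(DEFAULT_MODEL_FEATURES))
    return fit_risk_tree(city7.feature_df, selected, seed=7)


@dataclass
class SeedOutcome:
    baseline_pct: float
    model_pct: float
    historical_pct: float
    scenario_a_pct: float
    scenario_b_n: int
    scenario_c_n: int
    scenario_c_pct: float
    baseline_mean_pairwise: float
    greedy_mean_pairwise: float


def _mean_pairwise(sites) -> float:
    xy = np.array([[s.point.x, s.point.y] for s in sites])
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    iu = np.triu_indices(len(xy), 1)
    return float(d[iu].mean())


@pytest.fixture(scope="session")
def replication_study():
    """End-to-end run on 20 independent synthetic cities.

    Per seed: build the city, fit the risk model, and run the status-quo,
    matched-count (model and historical), +20%, and risk-threshold scenarios.
    """
    outcomes = []
    for seed in range(20):
        params = CityParams(seed=seed)
        city = build_city(params)
        selected = screen_features(city.feature_df, features=list(DEFAULT_MODEL_FEATURES))
        model = fit_risk_tree(city.feature_df, selected, seed=seed)
        n = params.baseline_aeds
        specs = canonical_scenarios(n_match=n, n_additional=max(1, round(0.2 * n)))
        run = lambda sid: run_scenario(  # noqa: E731
            specs[sid], city.candidates, city.network, city.alerts,
            city.baseline_aeds, model=model,
        )
        res = {sid: run(sid) for sid in ("0", "1", "2", "A", "B", "C")}
        outcomes.append(
            SeedOutcome(
                baseline_pct=res["0"].coverage.percent,
                model_pct=res["1"].coverage.percent,
                historical_pct=res["2"].coverage.percent,
                scenario_a_pct=res["A"].coverage.percent,
                scenario_b_n=res["B"].n_aeds,
                scenario_c_n=res["C"].n_aeds,
                scenario_c_pct=res["C"].coverage.percent,
                baseline_mean_pairwise=_mean_pairwise(city.baseline_aeds),
                greedy_mean_pairwise=_mean_pairwise(res["1"].placement.selected),
            )
        )
    return outcomes
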