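"""Coverage metric and the scenario engine.

Coverage is the fraction of historical alerts with a 24/7 AED nearby. The
validation definition is an AED within 300 m straight-line distance of the
event (``euclidean_300``, the default); an equivalent 3-minute-walk rule on
the network (297 m network distance between nearest nodes, ``network_297``)
is available as a flag since both readings are defensible.

Six scenarios compare placement strategies:

    0 : coverage of the installed AEDs as they stand
    1 : ignore installed; place the same number by the predictive model
    2 : ignore installed; place the same number by historical alert risk
    A : keep installed; add 20% more devices by the model
    B : keep installed; add devices until risk area 5 is exhausted
    C : keep installed; add devices until risk area 3 is exhausted

Scenarios 1 and 2 score only the newly placed set, for a fair comparison
with the status quo; A, B and C score the union of installed and new.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network import (
    RADIUS_3MIN,
    CandidateLocation,
    RoadNetwork,
    distances_within,
    network_distance,
)
from .placement import (
    AEDSite,
    PlacementResult,
    Termination,
    greedy_place,
    preprocess_existing,
)
from .risk import AlertRecord, RiskModel, bin_risk_area, predict_risk

COVERAGE_RADIUS_M = 300.0


@dataclass(frozen=True)
class CoverageReport:
    """Covered/total alert counts and the percentage (one decimal)."""

    n_alerts: int
    n_covered: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_covered <= self.n_alerts:
            raise ValueError("covered count out of range")

    @property
    def percent(self) -> float:
        return round(100.0 * self.n_covered / self.n_alerts, 1)


def _available(aeds: Sequence[AEDSite]) -> list[AEDSite]:
    return [a for a in aeds if a.always_available]


def is_covered(
    alert: AlertRecord,
    aeds: Sequence[AEDSite],
    network: RoadNetwork | None = None,
    mode: str = "euclidean_300",
) -> bool:
    """Whether at least one 24/7 AED is within reach of the alert."""
    aeds = _available(aeds)
    if not aeds:
        return False
    if mode == "euclidean_300":
        return any(alert.point.distance_to(a.point) <= COVERAGE_RADIUS_M for a in aeds)
    if mode == "network_297":
        if network is None:
            raise ValueError("network_297 mode requires a network")
        alert_node, _ = network.snap(alert.point)
        for a in aeds:
            node = a.node if a.node is not None and a.node in network else network.snap(a.point)[0]
            if network_distance(network, alert_node, node) <= RADIUS_3MIN:
                return True
        return False
    raise ValueError(f"unknown coverage mode {mode!r}")


def coverage(
    alerts: Sequence[AlertRecord],
    aeds: Sequence[AEDSite],
    network: RoadNetwork | None = None,
    mode: str = "euclidean_300",
) -> CoverageReport:
    """Covered-alert count and percentage for an AED set."""
    if not alerts:
        raise ValueError("coverage undefined for an empty alert list")
    aeds = _available(aeds)
    if not aeds:
        return CoverageReport(n_alerts=len(alerts), n_covered=0)
    if mode == "euclidean_300":
        a = np.array([[al.point.x, al.point.y] for al in alerts])
        s = np.array([[ae.point.x, ae.point.y] for ae in aeds])
        d2 = (s[:, None, 0] - a[None, :, 0]) ** 2 + (s[:, None, 1] - a[None, :, 1]) ** 2
        covered = int(np.any(d2 <= COVERAGE_RADIUS_M**2, axis=0).sum())
        return CoverageReport(n_alerts=len(alerts), n_covered=covered)
    if mode == "network_297":
        if network is None:
            raise ValueError("network_297 mode requires a network")
        # union of 3-minute balls around the AED nodes, then one snap per alert
        covered_nodes: set = set()
        for a in aeds:
            node = a.node if a.node is not None and a.node in network else network.snap(a.point)[0]
            covered_nodes.update(distances_within(network, node, RADIUS_3MIN))
        covered = sum(1 for al in alerts if network.snap(al.point)[0] in covered_nodes)
        return CoverageReport(n_alerts=len(alerts), n_covered=int(covered))
    raise ValueError(f"unknown coverage mode {mode!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """One evaluation configuration: installed-AED handling, stop rule, risk source."""

    id: str
    consider_installed: bool
    termination: Termination | None
    risk_source: str  # "model" | "historical" | "none"

    def __post_init__(self) -> None:
        if self.risk_source not in ("model", "historical", "none"):
            raise ValueError(f"unknown risk source {self.risk_source!r}")
        if self.risk_source == "none" and self.termination is not None:
            raise ValueError("a scenario without placement takes no termination")
        if self.risk_source != "none" and self.termination is None:
            raise ValueError("a placement scenario needs a termination rule")


def canonical_scenarios(n_match: int = 95, n_additional: int = 19) -> dict[str, ScenarioSpec]:
    """The six standard scenarios; device counts scale with the city."""
    return {
        "0": ScenarioSpec("0", True, None, "none"),
        "1": ScenarioSpec("1", False, Termination.count(n_match), "model"),
        "2": ScenarioSpec("2", False, Termination.count(n_match), "historical"),
        "A": ScenarioSpec("A", True, Termination.count(n_additional), "model"),
        "B": ScenarioSpec("B", True, Termination.risk(5), "model"),
        "C": ScenarioSpec("C", True, Termination.risk(3), "model"),
    }


def assign_risk(
    candidates: Sequence[CandidateLocation],
    source: str,
    model: RiskModel | None = None,
) -> list[CandidateLocation]:
    """Fresh candidate copies carrying risk levels from the chosen source.

    ``model``: tree prediction (rounded, clamped), with the un-rounded score
    kept for tie-breaking. ``historical``: the empirical alerts-per-year
    rate binned into its risk area, with the raw rate as the tie-break score.
    """
    out = []
    for c in candidates:
        cand = c.copy()
        if source == "model":
            if model is None:
                raise ValueError("model risk source requires a fitted model")
            if cand.features is None:
                raise ValueError(f"candidate {cand.id} has no features")
            cand.risk = predict_risk(model, cand.features)
            cand.risk_score = float(model.predict_score(cand.features)[0])
        elif source == "historical":
            if cand.empirical_rate is None:
                raise ValueError(f"candidate {cand.id} has no empirical rate")
            cand.risk = bin_risk_area(cand.empirical_rate)
            cand.risk_score = float(cand.empirical_rate)
        else:
            raise ValueError(f"unknown risk source {source!r}")
        out.append(cand)
    return out


@dataclass
class ScenarioResult:
    """Placement (if any), the AED set evaluated, and its coverage."""

    spec: ScenarioSpec
    placement: PlacementResult | None
    aeds_evaluated: list[AEDSite]
    coverage: CoverageReport

    @property
    def n_aeds(self) -> int:
        return len(self.aeds_evaluated)


def run_scenario(
    spec: ScenarioSpec,
    candidates: Sequence[CandidateLocation],
    network: RoadNetwork,
    alerts: Sequence[AlertRecord],
    existing_aeds: Sequence[AEDSite],
    model: RiskModel | None = None,
    reduction_constant: int = 2,
    coverage_mode: str = "euclidean_300",
) -> ScenarioResult:
    """Execute one scenario end-to-end and score its coverage."""
    existing = _available(existing_aeds)
    if spec.risk_source == "none":
        report = coverage(alerts, existing, network, coverage_mode)
        return ScenarioResult(spec, None, list(existing), report)

    cands = assign_risk(candidates, spec.risk_source, model)
    if spec.consider_installed:
        cands = preprocess_existing(cands, existing, network, reduction_constant)
    placement = greedy_place(cands, network, spec.termination, reduction_constant)
    new_sites = placement.aed_sites(id_offset=10_000)
    evaluated = list(existing) + new_sites if spec.consider_installed else new_sites
    report = coverage(alerts, evaluated, network, coverage_mode)
    return ScenarioResult(spec, placement, evaluated, report)


def scenario_table(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Comparison table: scenario id, device count, covered alerts, percent."""
    if not results:
        raise ValueError("need at least one scenario result")
    rows = [
        {
            "scenario": r.spec.id,
            "n_aeds": r.n_aeds,
            "n_covered": r.coverage.n_covered,
            "n_alerts": r.coverage.n_alerts,
            "percent": r.coverage.percent,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
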