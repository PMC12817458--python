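"""Greedy prioritization of AED placements.

The algorithm repeatedly selects the remaining candidate with the highest
current risk area, removes every candidate within the selected site's
3-minute isochrone (297 m network distance) to avoid redundant coverage,
and reduces by a constant (default 2, floored at level 1) the risk of
candidates within the 5-minute isochrone (495 m) to balance partial overlap.
It stops when a fixed device count is reached or when no remaining candidate
has a risk at or above a threshold level. Where AEDs are already installed,
candidates are first pre-processed against them with the same two radii.

A brute-force exhaustive search over n-subsets is provided as a coverage
oracle for small instances; the greedy heuristic can fall short of this
global optimum.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .network import (
    RADIUS_3MIN,
    RADIUS_5MIN,
    CandidateLocation,
    Point,
    RoadNetwork,
    distances_within,
)

logger = logging.getLogger(__name__)

MIN_RISK_LEVEL = 1
DEFAULT_REDUCTION_CONSTANT = 2


@dataclass(frozen=True)
class AEDSite:
    """An installed or planned AED; only 24/7-available devices count."""

    id: int
    point: Point
    node: object | None = None
    always_available: bool = True


@dataclass(frozen=True)
class Termination:
    """Stop rule: a fixed device count, or exhaustion of a risk level."""

    mode: str
    n: int | None = None
    min_risk: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "count":
            if self.n is None or self.n < 0 or self.min_risk is not None:
                raise ValueError("count termination needs n >= 0 and no min_risk")
        elif self.mode == "risk_threshold":
            if self.min_risk is None or not (1 <= self.min_risk <= 9) or self.n is not None:
                raise ValueError("risk_threshold termination needs min_risk in 1..9 and no n")
        else:
            raise ValueError(f"unknown termination mode {self.mode!r}")

    @classmethod
    def count(cls, n: int) -> "Termination":
        return cls(mode="count", n=n)

    @classmethod
    def risk(cls, min_risk: int) -> "Termination":
        return cls(mode="risk_threshold", min_risk=min_risk)


@dataclass
class IterationRecord:
    """Audit entry for one greedy step."""

    chosen_id: int
    risk_at_selection: int
    removed_ids: list[int]
    decayed: list[tuple[int, int, int]]  # (id, before, after)


@dataclass
class PlacementResult:
    """Ordered selection of AED sites plus the per-iteration audit log."""

    selected: list[CandidateLocation]
    log: list[IterationRecord]
    reduction_constant: int

    @property
    def selected_ids(self) -> list[int]:
        return [c.id for c in self.selected]

    def aed_sites(self, id_offset: int = 0) -> list[AEDSite]:
        return [
            AEDSite(id=id_offset + i, point=c.point, node=c.node, always_available=True)
            for i, c in enumerate(self.selected)
        ]


def _require_risk(candidates: Sequence[CandidateLocation]) -> None:
    for c in candidates:
        if c.risk is None:
            raise ValueError(f"candidate {c.id} has no risk level")


def preprocess_existing(
    candidates: Sequence[CandidateLocation],
    existing: Sequence[AEDSite],
    network: RoadNetwork,
    reduction_constant: int = DEFAULT_REDUCTION_CONSTANT,
    removal_radius: float = RADIUS_3MIN,
    decay_radius: float = RADIUS_5MIN,
) -> list[CandidateLocation]:
    """Remove/decay candidates already served by installed AEDs.

    Candidates within the 3-minute network radius of any 24/7 AED are
    removed; remaining candidates within the 5-minute radius have their risk
    reduced by the constant (floored at level 1, cumulative over multiple
    nearby AEDs). Off-network AEDs are snapped to the nearest node first.
    """
    _require_risk(candidates)
    result = {c.id: c.copy() for c in candidates}
    node_to_ids: dict = {}
    for c in candidates:
        node_to_ids.setdefault(c.node, []).append(c.id)

    for aed in existing:
        if not aed.always_available:
            continue
        node = aed.node
        if node is None or node not in network:
            node, snap_dist = network.snap(aed.point)
            logger.debug("AED %s snapped to node %r (%.1f m off-network)", aed.id, node, snap_dist)
        dists = distances_within(network, node, decay_radius)
        for nbr_node, d in dists.items():
            for cid in node_to_ids.get(nbr_node, ()):
                if cid not in result:
                    continue
                if d <= removal_radius:
                    del result[cid]
                else:
                    cand = result[cid]
                    cand.risk = max(MIN_RISK_LEVEL, cand.risk - reduction_constant)
    return [result[c.id] for c in candidates if c.id in result]


def greedy_place(
    candidates: Sequence[CandidateLocation],
    network: RoadNetwork,
    termination: Termination,
    reduction_constant: int = DEFAULT_REDUCTION_CONSTANT,
    removal_radius: float = RADIUS_3MIN,
    decay_radius: float = RADIUS_5MIN,
) -> PlacementResult:
    """Iterative highest-risk selection with removal and decay updates.

    Ties at equal risk level are broken by the larger un-rounded risk score
    when present, then by the smaller candidate id, making the run fully
    deterministic. Decay is cumulative across iterations and floored at
    level 1; removed candidates never return.
    """
    _require_risk(candidates)
    if reduction_constant < 0:
        raise ValueError("reduction_constant must be >= 0")

    work = {c.id: c.copy() for c in candidates}
    node_to_ids: dict = {}
    for c in candidates:
        node_to_ids.setdefault(c.node, []).append(c.id)

    selected: list[CandidateLocation] = []
    log: list[IterationRecord] = []

    while work:
        if termination.mode == "count" and len(selected) >= termination.n:
            break
        best = max(
            work.values(),
            key=lambda c: (
                c.risk,
                c.risk_score if c.risk_score is not None else -math.inf,
                -c.id,
            ),
        )
        if termination.mode == "risk_threshold" and best.risk < termination.min_risk:
            break

        del work[best.id]
        dists = distances_within(network, best.node, decay_radius)
        removed: list[int] = []
        decayed: list[tuple[int, int, int]] = []
        for nbr_node, d in dists.items():
            for cid in node_to_ids.get(nbr_node, ()):
                if cid not in work:
                    continue
                if d <= removal_radius:
                    del work[cid]
                    removed.append(cid)
                elif reduction_constant > 0:
                    cand = work[cid]
                    before = cand.risk
                    cand.risk = max(MIN_RISK_LEVEL, before - reduction_constant)
                    if cand.risk != before:
                        decayed.append((cid, before, cand.risk))
        selected.append(best)
        log.append(
            IterationRecord(
                chosen_id=best.id,
                risk_at_selection=best.risk,
                removed_ids=sorted(removed),
                decayed=sorted(decayed),
            )
        )

    if termination.mode == "count" and len(selected) < termination.n:
        logger.warning(
            "requested %d devices but only %d placeable candidates", termination.n, len(selected)
        )
    return PlacementResult(selected=selected, log=log, reduction_constant=reduction_constant)


def _coverage_matrix(
    candidates: Sequence[CandidateLocation],
    alert_points: Sequence[Point],
    radius: float,
) -> np.ndarray:
    """covered[i, j]: alert j within straight-line ``radius`` of candidate i."""
    c = np.array([[cand.point.x, cand.point.y] for cand in candidates]).reshape(-1, 2)
    a = np.array([[p.x, p.y] for p in alert_points]).reshape(-1, 2)
    if not len(c) or not len(a):
        return np.zeros((len(c), len(a)), dtype=bool)
    d2 = (c[:, None, 0] - a[None, :, 0]) ** 2 + (c[:, None, 1] - a[None, :, 1]) ** 2
    return d2 <= radius**2


def brute_force_best(
    candidates: Sequence[CandidateLocation],
    alert_points: Sequence[Point],
    n: int,
    radius: float = 300.0,
    max_subsets: int = 10_000,
) -> list[CandidateLocation]:
    """Exhaustive n-subset search maximizing covered alerts (small instances).

    Ties resolve to the lexicographically smallest id tuple. Serves as the
    global-optimum oracle against which the greedy heuristic is benchmarked.
    """
    n = min(n, len(candidates))
    if math.comb(len(candidates), n) > max_subsets:
        raise ValueError("instance too large for exhaustive search")
    cands = sorted(candidates, key=lambda c: c.id)
    cov = _coverage_matrix(cands, alert_points, radius)
    best_subset: tuple[int, ...] | None = None
    best_count = -1
    for subset in combinations(range(len(cands)), n):
        count = int(np.any(cov[list(subset)], axis=0).sum()) if len(subset) else 0
        if count > best_count:
            best_count = count
            best_subset = subset
    return [cands[i] for i in (best_subset or ())]


def covered_alert_count(
    sites: Sequence[AEDSite] | Sequence[CandidateLocation],
    alert_points: Sequence[Point],
    radius: float = 300.0,
) -> int:
    """Alerts with at least one site within straight-line ``radius`` metres."""
    pts = np.array([[s.point.x, s.point.y] for s in sites]).reshape(-1, 2)
    a = np.array([[p.x, p.y] for p in alert_points]).reshape(-1, 2)
    if not len(a) or not len(pts):
        return 0
    d2 = (pts[:, None, 0] - a[None, :, 0]) ** 2 + (pts[:, None, 1] - a[None, :, 1]) ** 2
    return int(np.any(d2 <= radius**2, axis=0).sum())


@dataclass
class SweepResult:
    """Coverage percentage per reduction constant, with the argmax flagged."""

    coverage_by_constant: dict[int, float]
    best_constant: int


def sensitivity_sweep(
    candidates: Sequence[CandidateLocation],
    network: RoadNetwork,
    alert_points: Sequence[Point],
    termination: Termination,
    constants: Sequence[int],
    radius: float = 300.0,
) -> SweepResult:
    """Run the greedy placement once per decay constant and compare coverage."""
    if not constants:
        raise ValueError("constants must be non-empty")
    if not alert_points:
        raise ValueError("alerts must be non-empty")
    out: dict[int, float] = {}
    for k in constants:
        if k < 0:
            raise ValueError("constants must be >= 0")
        result = greedy_place(candidates, network, termination, reduction_constant=k)
        covered = covered_alert_count(result.selected, alert_points, radius)
        out[int(k)] = round(100.0 * covered / len(alert_points), 1)
    best = max(sorted(out), key=lambda k: out[k])
    return SweepResult(coverage_by_constant=out, best_constant=best)
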