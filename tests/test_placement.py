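"""Greedy placement, pre-processing against installed AEDs, brute-force oracle."""
from __future__ import annotations

import math

import numpy as np
import pytest

from aedplace import (
    AEDSite,
    CandidateLocation,
    Point,
    Termination,
    brute_force_best,
    greedy_place,
    network_distance,
    preprocess_existing,
    sensitivity_sweep,
)
from aedplace.placement import covered_alert_count

from conftest import line_candidates, line_network


def naive_greedy(risks: dict[int, int], positions: dict[int, float], termination_n: int,
                 constant: int = 2) -> list[int]:
    """Independent re-implementation of the loop on a line (1-D distances)."""
    alive = dict(risks)
    chosen = []
    while alive and len(chosen) < termination_n:
        best = max(alive, key=lambda i: (alive[i], -i))
        chosen.append(best)
        for j in list(alive):
            d = abs(positions[j] - positions[best])
            if d <= 297:
                del alive[j]
            elif d <= 495:
                alive[j] = max(1, alive[j] - constant)
    return chosen


class TestPreprocessExisting:
    def test_no_existing_is_identity(self):
        net = line_network()
        cands = line_candidates(net, risks=[5] * 10)
        out = preprocess_existing(cands, [], net)
        assert [(c.id, c.risk) for c in out] == [(c.id, c.risk) for c in cands]

    def test_candidate_within_three_minutes_removed(self):
        net = line_network(n=4, step=100.0)
        cands = line_candidates(net, risks=[5, 5, 5, 5])
        aed = AEDSite(id=0, point=Point(0.0, 0.0))
        out = preprocess_existing(cands, [aed], net)
        # nodes at 0, 100, 200 m are within 297 m; node at 300 m survives decayed
        assert [c.id for c in out] == [3]

    def test_decay_ring_reduces_by_constant(self):
        net = line_network(n=3, step=200.0)  # nodes at 0, 200, 400 m
        cands = line_candidates(net, risks=[7, 7, 7])
        aed = AEDSite(id=0, point=Point(0.0, 0.0))
        out = preprocess_existing(cands, [aed], net, reduction_constant=2)
        assert [c.id for c in out] == [2]
        assert out[0].risk == 5  # 297 < 400 <= 495

    def test_unavailable_aeds_ignored(self):
        net = line_network(n=3, step=200.0)
        cands = line_candidates(net, risks=[7, 7, 7])
        aed = AEDSite(id=0, point=Point(0.0, 0.0), always_available=False)
        out = preprocess_existing(cands, [aed], net)
        assert [(c.id, c.risk) for c in out] == [(0, 7), (1, 7), (2, 7)]


class TestGreedyPlace:
    def test_single_candidate(self):
        net = line_network(n=2)
        cands = line_candidates(net, risks=[4, 1])[:1]
        result = greedy_place(cands, net, Termination.count(1))
        assert result.selected_ids == [0]

    def test_mutual_removal_exhausts_candidates(self):
        net = line_network(n=2, step=100.0)
        cands = line_candidates(net, risks=[9, 9])
        result = greedy_place(cands, net, Termination.count(2))
        assert len(result.selected) == 1
        assert result.log[0].removed_ids == [1]

    def test_matches_naive_reimplementation(self):
        rng = np.random.default_rng(3)
        net = line_network(n=10, step=120.0)
        risks = rng.integers(1, 10, size=10)
        cands = line_candidates(net, risks=risks)
        result = greedy_place(cands, net, Termination.count(3))
        expected = naive_greedy(
            {i: int(r) for i, r in enumerate(risks)},
            {i: i * 120.0 for i in range(10)},
            termination_n=3,
        )
        assert result.selected_ids == expected

    def test_risk_threshold_termination(self):
        net = line_network(n=10, step=600.0)  # far apart: no interaction
        cands = line_candidates(net, risks=[9, 8, 7, 5, 5, 4, 3, 2, 1, 1])
        result = greedy_place(cands, net, Termination.risk(5))
        assert [c.risk for c in result.selected] == [9, 8, 7, 5, 5]

    def test_tie_broken_by_score_then_id(self):
        net = line_network(n=3, step=600.0)
        cands = line_candidates(net, risks=[5, 5, 5])
        cands[1].risk_score = 5.4
        cands[0].risk_score = 5.1
        cands[2].risk_score = 5.1
        result = greedy_place(cands, net, Termination.count(3))
        assert result.selected_ids == [1, 0, 2]

    def test_determinism_including_log(self, city7):
        cands = [c.copy() for c in city7.candidates]
        a = greedy_place(cands, city7.network, Termination.count(20))
        b = greedy_place(cands, city7.network, Termination.count(20))
        assert a.selected_ids == b.selected_ids
        assert a.log == b.log

    def test_pairwise_separation_exceeds_three_minutes(self, city7):
        result = greedy_place(city7.candidates, city7.network, Termination.count(25))
        sel = result.selected
        for i in range(len(sel)):
            for j in range(i + 1, len(sel)):
                d = network_distance(city7.network, sel[i].node, sel[j].node)
                assert d > 297.0

    def test_coverage_monotone_in_device_count(self, city7):
        pts = city7.alert_points()
        prev = -1
        for n in (5, 10, 20, 30):
            result = greedy_place(city7.candidates, city7.network, Termination.count(n))
            cov = covered_alert_count(result.selected, pts)
            assert cov >= prev
            prev = cov

    def test_risk_floor_and_ceiling_respected(self, city7):
        initial = {c.id: c.risk for c in city7.candidates}
        result = greedy_place(city7.candidates, city7.network, Termination.count(30))
        for rec in result.log:
            assert 1 <= rec.risk_at_selection <= initial[rec.chosen_id]
            for cid, before, after in rec.decayed:
                assert 1 <= after < before <= initial[cid]

    def test_count_exceeding_pool_warns_and_returns_all(self, caplog):
        net = line_network(n=2, step=600.0)
        cands = line_candidates(net, risks=[3, 3])
        with caplog.at_level("WARNING"):
            result = greedy_place(cands, net, Termination.count(10))
        assert len(result.selected) == 2
        assert any("placeable" in r.message for r in caplog.records)


class TestBruteForce:
    def _random_instance(self, rng):
        n_c = int(rng.integers(6, 13))
        net = line_network(n=n_c, step=float(rng.uniform(150, 400)))
        cands = line_candidates(net, risks=None)
        alert_pts = [Point(float(x), float(y))
                     for x, y in rng.uniform([0, -200], [n_c * 400, 200], size=(30, 2))]
        for c in cands:
            c.risk = min(9, 1 + sum(c.point.distance_to(p) <= 300 for p in alert_pts) // 2)
        return net, cands, alert_pts

    def test_n_equal_to_pool_returns_all(self):
        net = line_network(n=4, step=600.0)
        cands = line_candidates(net, risks=[1, 2, 3, 4])
        best = brute_force_best(cands, [Point(0, 0)], n=4)
        assert sorted(c.id for c in best) == [0, 1, 2, 3]

    def test_single_alert_covered_when_possible(self):
        net = line_network(n=3, step=600.0)
        cands = line_candidates(net, risks=[1, 1, 1])
        best = brute_force_best(cands, [Point(620.0, 0.0)], n=1)
        assert covered_alert_count(best, [Point(620.0, 0.0)]) == 1

    def test_too_large_instance_rejected(self):
        net = line_network(n=10, step=600.0)
        cands = line_candidates(net, risks=[1] * 10)
        with pytest.raises(ValueError, match="too large"):
            brute_force_best(cands * 3, [Point(0, 0)], n=10, max_subsets=10)

    def test_greedy_never_beats_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net, cands, alert_pts = self._random_instance(rng)
            n = int(rng.integers(1, 5))
            greedy = greedy_place(cands, net, Termination.count(n))
            best = brute_force_best(cands, alert_pts, n=n)
            assert covered_alert_count(greedy.selected, alert_pts) <= covered_alert_count(
                best, alert_pts
            )


class TestSensitivitySweep:
    def test_single_constant(self, city7):
        sweep = sensitivity_sweep(
            city7.candidates, city7.network, city7.alert_points(),
            Termination.count(20), constants=[2],
        )
        assert list(sweep.coverage_by_constant) == [2]
        assert sweep.best_constant == 2

    def test_range_and_argmax_consistent_with_rerun(self, city7):
        pts = city7.alert_points()
        term = Termination.count(20)
        sweep = sensitivity_sweep(city7.candidates, city7.network, pts, term,
                                  constants=[0, 1, 2, 3, 4])
        assert all(0.0 <= v <= 100.0 for v in sweep.coverage_by_constant.values())
        manual = {}
        for k in (0, 1, 2, 3, 4):
            res = greedy_place(city7.candidates, city7.network, term, reduction_constant=k)
            manual[k] = round(100.0 * covered_alert_count(res.selected, pts) / len(pts), 1)
        assert sweep.coverage_by_constant == manual
        assert sweep.best_constant == max(sorted(manual), key=lambda k: manual[k])
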