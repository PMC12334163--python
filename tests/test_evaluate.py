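import numpy as np
import pytest

import regentrack as rt
from regentrack.evaluate import (
    AOGMWeights,
    aogm,
    depth_stratified_scores,
    det_score,
    detection_scores,
    evaluate_forests,
    linking_scores,
    match_spots,
    proofreading_effort,
    tra_on_gt,
    tra_score,
)

from conftest import make_chain
from oracles import min_edit_cost, random_instance


def chain_forest(n=5, **kw):
    f = rt.LineageForest()
    make_chain(f, 1, 0, n, **kw)
    return f


def copy_forest(f):
    return f.copy()


class TestMatchSpots:
    def test_identical_sets_all_tp(self):
        gt = chain_forest(4)
        m = match_spots(gt, copy_forest(gt))
        assert (m.tp, m.ns, m.fn, m.fp) == (4, 0, 0, 0)

    def test_one_pred_between_two_gt_gives_ns(self):
        gt = rt.LineageForest()
        gt.add_spot(rt.Spot(1, 0, (0, 0, 0), radius=2.0))
        gt.add_spot(rt.Spot(2, 0, (0, 3, 0), radius=2.0))
        pred = rt.LineageForest()
        pred.add_spot(rt.Spot(1, 0, (0, 1.5, 0), radius=2.0))
        m = match_spots(gt, pred)
        assert (m.tp, m.ns, m.fp, m.fn) == (1, 1, 0, 0)

    def test_offset_beyond_radius_is_fn_plus_fp(self):
        gt = rt.LineageForest([rt.Spot(1, 0, (0, 0, 0), radius=2.0)])
        pred = rt.LineageForest([rt.Spot(1, 0, (0, 5, 0), radius=2.0)])
        m = match_spots(gt, pred)
        assert (m.tp, m.fn, m.fp, m.ns) == (0, 1, 1, 0)

    def test_assignment_minimises_total_distance(self):
        gt = rt.LineageForest()
        gt.add_spot(rt.Spot(1, 0, (0, 0, 0), radius=2.0))
        gt.add_spot(rt.Spot(2, 0, (0, 1.8, 0), radius=2.0))
        pred = rt.LineageForest()
        pred.add_spot(rt.Spot(11, 0, (0, 0.2, 0), radius=2.0))
        pred.add_spot(rt.Spot(12, 0, (0, 1.6, 0), radius=2.0))
        m = match_spots(gt, pred)
        assert m.pairs == {1: 11, 2: 12}


class TestDetectionScores:
    def test_direct_substitution(self):
        from regentrack.evaluate import SpotMatching

        m = SpotMatching(pairs={i: i for i in range(3)}, fp_ids=[9], fn_ids=[7, 8])
        assert detection_scores(m) == (0.75, 0.6)

    def test_perfect_prediction(self):
        gt = chain_forest(3)
        assert detection_scores(match_spots(gt, copy_forest(gt))) == (1.0, 1.0)

    def test_empty_pred_convention(self):
        gt = chain_forest(5)
        m = match_spots(gt, rt.LineageForest())
        assert detection_scores(m) == (1.0, 0.0)


class TestAOGM:
    def interior_deletion_instance(self):
        gt = chain_forest(5)
        pred = rt.LineageForest()
        for s in gt:
            if s.id != 3:
                pred.add_spot(rt.Spot(s.id, s.t, s.pos, s.radius))
        pred.add_link(1, 2)
        pred.add_link(4, 5)
        return gt, pred

    def test_identical_costs_zero(self):
        gt = chain_forest(6)
        counts, cost = aogm(gt, copy_forest(gt))
        assert cost == 0.0
        assert all(v == 0 for v in counts.values())

    def test_missing_interior_spot_cost_13(self):
        gt, pred = self.interior_deletion_instance()
        counts, cost = aogm(gt, pred)
        assert counts["FN"] == 1 and counts["EA"] == 2
        assert cost == 10 + 2 * 1.5

    def test_spurious_unlinked_spot_cost_1(self):
        gt = chain_forest(4)
        pred = copy_forest(gt)
        pred.add_spot(rt.Spot(99, 0, (50, 50, 50), radius=2.0))
        counts, cost = aogm(gt, pred)
        assert counts["FP"] == 1 and cost == 1.0

    def test_division_semantics_change_counts_ec(self):
        gt = rt.LineageForest()
        make_chain(gt, 1, 0, 2)
        gt.add_spot(rt.Spot(3, 2, (0, 0, 3)))
        gt.add_spot(rt.Spot(4, 2, (0, 0, -3)))
        gt.add_link(2, 3)
        gt.add_link(2, 4)
        pred = rt.LineageForest()
        for s in gt:
            pred.add_spot(rt.Spot(s.id, s.t, s.pos, s.radius))
        pred.add_link(1, 2)
        pred.add_link(2, 3)  # second daughter link missing
        counts, _ = aogm(gt, pred)
        assert counts["EA"] == 1  # missing 2->4
        assert counts["EC"] == 1  # 2->3 is a division link only in gt

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            gt, pred = random_instance(rng)
            _, cost = aogm(gt, pred)
            assert cost == pytest.approx(min_edit_cost(gt, pred))


class TestDetTra:
    def test_perfect_prediction_scores_one(self):
        gt = chain_forest(5)
        assert det_score(gt, copy_forest(gt)) == 1.0
        assert tra_score(gt, copy_forest(gt)) == 1.0

    def test_empty_prediction_scores_zero(self):
        gt = chain_forest(5)
        assert det_score(gt, rt.LineageForest()) == 0.0
        assert tra_score(gt, rt.LineageForest()) == 0.0

    def test_interior_deletion_tra_arithmetic(self):
        gt, pred = TestAOGM().interior_deletion_instance()
        assert tra_score(gt, pred) == pytest.approx(1 - 13 / 56)

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            det_score(rt.LineageForest(), rt.LineageForest())

    def test_adding_false_positive_never_increases_tra(self):
        gt = chain_forest(5)
        pred = copy_forest(gt)
        base = tra_score(gt, pred)
        pred.add_spot(rt.Spot(99, 0, (40, 40, 40), radius=2.0))
        assert tra_score(gt, pred) <= base

    def test_scores_within_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            gt, pred = random_instance(rng)
            if gt.n_spots == 0:
                continue
            assert 0.0 <= det_score(gt, pred) <= 1.0
            assert 0.0 <= tra_score(gt, pred) <= 1.0


class TestLinkingScores:
    def test_perfect(self):
        gt = chain_forest(4)
        assert linking_scores(gt, copy_forest(gt)) == (1.0, 1.0)

    def test_reversed_division_parent(self):
        # 4 spots: A0 divides into B1, C1 in gt; pred links D0 (other cell) to C1
        gt = rt.LineageForest()
        gt.add_spot(rt.Spot(1, 0, (0, 0, 0), radius=2.0))
        gt.add_spot(rt.Spot(2, 0, (0, 10, 0), radius=2.0))
        gt.add_spot(rt.Spot(3, 1, (0, 1, 0), radius=2.0))
        gt.add_spot(rt.Spot(4, 1, (0, 9, 0), radius=2.0))
        gt.add_link(1, 3)
        gt.add_link(2, 4)
        pred = rt.LineageForest()
        for s in gt:
            pred.add_spot(rt.Spot(s.id, s.t, s.pos, s.radius))
        pred.add_link(1, 3)
        pred.add_link(1, 4)  # wrong parent for 4
        p, r = linking_scores(gt, pred)
        assert p == pytest.approx(0.5)
        assert r == pytest.approx(0.5)

    def test_tra_on_gt_with_exact_flow_is_perfect(self, mini_sim, mini_flow):
        _, forest, _, _ = mini_sim
        _, (p, r) = tra_on_gt(forest, mini_flow)
        assert (p, r) == (1.0, 1.0)


class TestProofreadingEffort:
    def test_zero_for_perfect(self):
        gt = chain_forest(4)
        assert proofreading_effort(gt, copy_forest(gt)) == 0.0

    def test_additive_over_disjoint_union(self):
        gt1, pred1 = TestAOGM().interior_deletion_instance()
        single = proofreading_effort(gt1, pred1)
        gt2, pred2 = gt1.copy(), pred1.copy()
        for src, dst in ((gt1, gt2), (pred1, pred2)):
            for s in src:
                dst.add_spot(rt.Spot(s.id + 100, s.t, tuple(np.add(s.pos, (0, 80, 0))), s.radius))
            for a, b in src.links:
                dst.add_link(a + 100, b + 100)
        assert proofreading_effort(gt2, pred2) == pytest.approx(2 * single)


class TestDepthStratified:
    def test_single_shallow_bin_perfect(self):
        gt = chain_forest(3, pos=(2.0, 5.0, 5.0))
        table = depth_stratified_scores(gt, copy_forest(gt))
        assert len(table) == 1
        assert table.iloc[0][["precision", "recall"]].tolist() == [1.0, 1.0]

    def test_missing_deep_spots(self):
        gt = rt.LineageForest()
        for i, z in enumerate((1.0, 7.0, 22.0, 24.0), start=1):
            gt.add_spot(rt.Spot(i, 0, (z, 5, 5), radius=2.0))
        pred = rt.LineageForest()
        for s in gt:
            if s.pos[0] < 20:
                pred.add_spot(rt.Spot(s.id, s.t, s.pos, s.radius))
        table = depth_stratified_scores(gt, pred).set_index("z_lo")
        assert table.loc[0.0, "recall"] == 1.0
        assert table.loc[5.0, "recall"] == 1.0
        assert table.loc[20.0, "recall"] == 0.0

    def test_bins_without_gt_omitted(self):
        gt = chain_forest(2, pos=(2.0, 5.0, 5.0))
        pred = copy_forest(gt)
        pred.add_spot(rt.Spot(99, 0, (18.0, 5.0, 5.0), radius=2.0))
        table = depth_stratified_scores(gt, pred)
        assert table["z_lo"].tolist() == [0.0]


def test_evaluate_forests_report_consistency(mini_sim, mini_flow):
    _, forest, _, _ = mini_sim
    spots = [rt.Spot(s.id, s.t, s.pos, s.radius) for s in forest]
    pred = rt.link_forward(spots, flow=mini_flow)
    report = evaluate_forests(forest, pred, depth_bin=5.0)
    assert report.det == 1.0 and report.tra == 1.0
    assert report.effort == report.aogm_cost == 0.0
    assert report.depth_table["recall"].min() == 1.0
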