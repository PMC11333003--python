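"""Self-avoidance indices, zones, coverage, and regrowth measurements."""

import math

import numpy as np
import pytest

import pvdarbor as pa
from pvdarbor.core import ArborGraph, BranchOrder
from pvdarbor.morphometrics import (InputError, MorphometricsConfig,
                                    UndefinedStatisticError, interval_clip,
                                    interval_length, interval_subtract,
                                    interval_union, tertiary_pairs)

from oracle import brute_mean_gap, brute_tbai


def build_menorah_row(body, intervals, side_sign=1):
    """Labeled arbor with one menorah per (a, b) base interval, one side."""
    g = ArborGraph(body)
    O = BranchOrder
    g.add_node(1, s=body.soma_s_um, theta=body.lateral_theta, swc_hint=1)
    labels = {}
    prev = 1
    nid = 2
    theta3 = body.theta_at_arc(side_sign * 20.0)
    for a, b in sorted(intervals, reverse=True):
        mid = 0.5 * (a + b)
        att = g.add_node(nid, s=mid, theta=body.lateral_theta, parent=prev)
        labels[(prev, att)] = O.PRIMARY
        nid += 1
        stem = g.add_node(nid, s=mid, theta=theta3, parent=att)
        labels[(att, stem)] = O.SECONDARY
        nid += 1
        for tip_s in (a, b):
            t = g.add_node(nid, s=tip_s, theta=theta3, parent=stem)
            labels[(stem, t)] = O.TERTIARY
            nid += 1
        prev = att
    tail = g.add_node(nid, s=min(i[0] for i in intervals) - 10,
                      theta=body.lateral_theta, parent=prev)
    labels[(prev, tail)] = O.PRIMARY
    for e, o in labels.items():
        g.set_order(e, o)
    return g


class TestIntervalArithmetic:
    def test_zone_worked_example(self):
        """Menorah [0,50]u[40,100] minus trapped [90,120] leaves 90 um;
        the trapped zone clipped to a 200-um window is 30 um."""
        men = interval_subtract(interval_union([(0, 50), (40, 100)]),
                                [(90, 120)])
        assert interval_length(interval_clip(men, 0, 200)) == pytest.approx(90)
        assert interval_length(interval_clip([(90, 120)], 0, 200)) == \
            pytest.approx(30)

    def test_union_merge_gap(self):
        assert interval_union([(0, 10), (13, 20)], merge_gap=5) == [(0, 20)]
        assert interval_union([(0, 10), (16, 20)], merge_gap=5) == \
            [(0, 10), (16, 20)]


class TestTbai:
    def test_single_menorah_has_no_pairs(self, body):
        g = build_menorah_row(body, [(600, 630)])
        tb, M, G = pa.tbai(g)
        assert (tb, M, G) == (0.0, 1, 0)

    def test_five_menorahs_all_gaps(self, body):
        """5 menorahs in a row, 4 visible gaps: TBAI = 0.8."""
        ivs = [(500 + 26 * k, 520 + 26 * k) for k in range(5)]
        g = build_menorah_row(body, ivs)
        tb, M, G = pa.tbai(g)
        assert (M, G) == (5, 4)
        assert tb == pytest.approx(0.8)

    def test_hand_arbor(self, hand_arbor):
        graph, _ = hand_arbor
        tb, M, G = pa.tbai(pa.assign_orders(graph))
        assert (M, G) == (3, 1)
        assert tb == pytest.approx(1 / 3)

    def test_no_menorahs_is_undefined_not_zero(self):
        g, t = pa.generate_arbor(pa.ArborSimParams(p_branch=0.0,
                                                   p_trapped=0.0))
        with pytest.raises(UndefinedStatisticError):
            pa.tbai(pa.labeled_from_truth(g, t))

    def test_cohort_direction_matches_phenotype(self):
        tb = {}
        for name in ("wildtype_like", "xr58_like"):
            vals = []
            for seed in range(40):
                g, t = pa.generate_arbor(pa.preset(name, seed=seed))
                vals.append(pa.tbai(pa.labeled_from_truth(g, t))[0])
            tb[name] = np.mean(vals)
        assert tb["xr58_like"] < tb["wildtype_like"] - 0.3

    def test_mirror_invariance(self):
        """TBAI is unchanged by an anterior/posterior mirror of the arbor."""
        body = pa.WormBody(length_um=1000, radius_um=25, soma_s_um=500,
                           mouth_s_um=20)
        g, t = pa.generate_arbor(pa.preset("wildtype_like", seed=4), body)
        lab = pa.assign_orders(g)
        mirror = g.copy()
        for n in mirror.nodes():
            mirror.g.nodes[n]["s"] = 2 * body.soma_s_um - mirror.g.nodes[n]["s"]
        lab_m = pa.assign_orders(mirror)
        assert pa.tbai(lab_m)[:2] == pa.tbai(lab)[:2]


class TestPairPartition:
    def test_gaps_and_overlaps_partition_adjacent_pairs(self):
        p = pa.preset("dma1_oe_like", seed=8)
        g, t = pa.generate_arbor(p)
        lab = pa.labeled_from_truth(g, t)
        cfg = MorphometricsConfig(tbai_window_um=200.0)
        pairs = tertiary_pairs(lab, window_um=200.0)
        _, _, G = pa.tbai(lab, cfg)
        n_over = pa.count_overlapped_tertiary(lab, cfg)
        assert G + n_over == len(pairs)

    def test_no_avoidance_overlap_count(self):
        """With p_sa=0 every adjacent in-window pair is a contact."""
        p = pa.ArborSimParams(p_branch=1.0, p_trapped=0.0, p_sa=0.0,
                              jitter_um=0.0, seed=1)
        g, t = pa.generate_arbor(p)
        lab = pa.labeled_from_truth(g, t)
        # 6 menorahs per side attach within 200 um anterior of the soma
        assert pa.count_overlapped_tertiary(lab) == 2 * (6 - 1)

    def test_fully_separated_arbor_has_no_overlaps(self, body):
        g = build_menorah_row(body, [(500 + 40 * k, 520 + 40 * k)
                                     for k in range(4)])
        assert pa.count_overlapped_tertiary(g) == 0


class TestMeanGap:
    def test_arithmetic_mean(self, body):
        """Two gaps of 4 and 6 um average to 5 um."""
        g = build_menorah_row(body, [(560, 580), (584, 600), (606, 630)])
        assert pa.mean_tertiary_gap(g) == pytest.approx(5.0)

    def test_generator_law_exact(self):
        p = pa.ArborSimParams(p_branch=1.0, p_trapped=0.0, p_sa=1.0,
                              jitter_um=0.0, gap_um=7.0, seed=6)
        g, t = pa.generate_arbor(p)
        assert pa.mean_tertiary_gap(pa.labeled_from_truth(g, t)) == \
            pytest.approx(7.0, abs=1e-12)

    def test_overexpression_widens_gaps(self):
        """A larger retraction gap shifts the measured mean upward."""
        means = []
        for gap in (5.0, 12.0):
            vals = []
            for seed in range(20):
                g, t = pa.generate_arbor(pa.preset("wildtype_like",
                                                   seed=seed, gap_um=gap))
                vals.append(pa.mean_tertiary_gap(pa.labeled_from_truth(g, t)))
            means.append(np.mean(vals))
        assert means[1] > means[0] + 5.0

    def test_no_gaps_is_undefined(self, body):
        g = build_menorah_row(body, [(600, 630)])
        with pytest.raises(UndefinedStatisticError):
            pa.mean_tertiary_gap(g)


class TestZones:
    def test_no_trapped_means_zero_trapped_zone(self):
        g, t = pa.generate_arbor(pa.preset("wildtype_like", seed=0,
                                           p_trapped=0.0))
        _, tz = pa.coverage_zones(pa.labeled_from_truth(g, t))
        assert tz == 0.0

    def test_branching_failure_raises_trapped_zone(self):
        means = {}
        for name in ("wildtype_like", "gk8_like"):
            vals = []
            for seed in range(20):
                g, t = pa.generate_arbor(pa.preset(name, seed=seed))
                vals.append(pa.coverage_zones(pa.labeled_from_truth(g, t))[1])
            means[name] = np.mean(vals)
        assert means["gk8_like"] > means["wildtype_like"] + 20.0

    def test_zones_bounded_by_window(self, wt_labeled):
        cfg = MorphometricsConfig()
        mz, tz = pa.coverage_zones(wt_labeled, cfg)
        assert 0 <= mz <= cfg.zone_window_um
        assert 0 <= tz <= cfg.zone_window_um


class TestQuaternaryCount:
    def test_no_quaternary(self, body):
        g = build_menorah_row(body, [(600, 630)])
        assert pa.quaternary_count(g) == 0

    def test_hand_arbor_counts_anterior_candles(self, hand_arbor):
        graph, _ = hand_arbor
        assert pa.quaternary_count(pa.assign_orders(graph)) == 2

    def test_matches_ground_truth(self):
        from oracle import brute_quaternary_anterior
        for seed in range(5):
            g, t = pa.generate_arbor(pa.preset("wildtype_like", seed=seed))
            lab = pa.assign_orders(g)
            assert pa.quaternary_count(lab) == brute_quaternary_anterior(g, t)


class TestSecondaryBranchingDefect:
    def test_healthy_arbor(self):
        g, t = pa.generate_arbor(pa.ArborSimParams(p_branch=1.0,
                                                   p_trapped=0.0, seed=0))
        defect, grade = pa.secondary_branching_defect(pa.labeled_from_truth(g, t))
        assert not defect and grade == 0

    def test_grade_monotone_in_trapping(self):
        grades = []
        for p_tr in (0.1, 0.5, 0.9):
            gs = []
            for seed in range(30):
                p = pa.ArborSimParams(p_branch=0.3, p_trapped=p_tr, seed=seed)
                g, t = pa.generate_arbor(p)
                gs.append(pa.secondary_branching_defect(
                    pa.labeled_from_truth(g, t))[1])
            grades.append(np.mean(gs))
        assert grades[0] <= grades[1] <= grades[2]


class TestReceptiveFieldIndex:
    def test_no_anterior_dendrites(self, body):
        g = ArborGraph(body)
        g.add_node(1, s=body.soma_s_um, theta=body.lateral_theta, swc_hint=1)
        g.add_node(2, s=body.soma_s_um + 100, theta=body.lateral_theta,
                   parent=1)
        g.set_order((1, 2), BranchOrder.PRIMARY)
        assert pa.receptive_field_index(g) == 0.0

    def test_single_axial_dendrite_rectangle(self):
        """One primary spanning a 400-um strip with reach 10 um covers a
        400 x 20 rectangle of the 400 x 50*pi strip."""
        body = pa.WormBody(length_um=1000, radius_um=25, soma_s_um=420,
                           mouth_s_um=20)
        g = ArborGraph(body)
        g.add_node(1, s=420, theta=body.lateral_theta, swc_hint=1)
        g.add_node(2, s=20, theta=body.lateral_theta, parent=1)
        g.set_order((1, 2), BranchOrder.PRIMARY)
        cfg = MorphometricsConfig(rfi_reach_um=10.0, rfi_cell_um=1.0)
        expected = 20.0 / (50.0 * math.pi)
        tol = 2 * cfg.rfi_cell_um / body.circumference_um
        assert abs(pa.receptive_field_index(g, cfg) - expected) <= tol

    def test_saturated_coverage(self):
        """Dense axial lines tiling the full circumference give rfi ~ 1."""
        body = pa.WormBody(length_um=600, radius_um=25, soma_s_um=420,
                           mouth_s_um=20)
        g = ArborGraph(body)
        g.add_node(1, s=420, theta=body.lateral_theta, swc_hint=1)
        nid = 2
        for k in range(8):
            theta = body.lateral_theta + k * math.pi / 4
            a = g.add_node(nid, s=420, theta=theta, parent=1)
            g.set_order((1, a), BranchOrder.PRIMARY)
            nid += 1
            b = g.add_node(nid, s=20, theta=theta, parent=a)
            g.set_order((a, b), BranchOrder.PRIMARY)
            nid += 1
        rfi = pa.receptive_field_index(g)
        assert 0.97 <= rfi <= 1.02

    def test_bad_strip_raises(self):
        body = pa.WormBody(length_um=1000, radius_um=25, soma_s_um=650,
                           mouth_s_um=20)
        g = ArborGraph(body)
        g.add_node(1, s=650, theta=body.lateral_theta, swc_hint=1)
        object.__setattr__(body, "mouth_s_um", 700.0)  # corrupt on purpose
        with pytest.raises(InputError):
            pa.receptive_field_index(g)


class TestRegrowth:
    def _pre(self, body):
        g = build_menorah_row(body, [(560, 580), (600, 630)])
        return g

    def test_no_regrowth(self, body):
        pre = self._pre(body)
        assert pa.regrowth_length(pre, pre.copy(), cut_node=2) == 0.0

    def test_single_axial_branch(self, body):
        pre = self._pre(body)
        post = pre.copy()
        cut = 2
        post.add_node(900, s=post.s(cut) - 80.0, theta=body.lateral_theta,
                      parent=cut)
        assert pa.regrowth_length(pre, post, cut) == pytest.approx(80.0)

    def test_branched_regrowth_sums_terminal_contours(self, body):
        pre = self._pre(body)
        post = pre.copy()
        cut = 2
        mid = post.add_node(900, s=post.s(cut) - 50.0,
                            theta=body.lateral_theta, parent=cut)
        post.add_node(901, s=post.s(mid) - 30.0, theta=body.lateral_theta,
                      parent=mid)
        post.add_node(902, s=post.s(mid), theta=body.theta_at_arc(15.0),
                      parent=mid)
        # two regrown terminals: 50+30 and 50+15 from the cut site
        assert pa.regrowth_length(pre, post, cut) == pytest.approx(145.0)

    def test_cut_off_primary_rejected(self, body):
        pre = self._pre(body)
        stem_tip = next(e[1] for e in pre.edges_of_order(BranchOrder.SECONDARY))
        with pytest.raises(InputError):
            pa.regrowth_length(pre, pre.copy(), stem_tip)


def test_report_matches_oracle_on_one_arbor(wt, wt_labeled):
    graph, truth = wt
    rep = pa.compute_report(wt_labeled)
    tb, M, G = brute_tbai(graph, truth)
    assert (rep.n_menorahs, rep.n_gaps) == (M, G)
    assert rep.tbai == pytest.approx(tb, abs=1e-12)
    mg = brute_mean_gap(graph, truth)
    assert rep.mean_tertiary_gap_um == pytest.approx(mg, abs=1e-9)
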