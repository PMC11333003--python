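"""Recovery normalisation and fitting, puncta statistics and enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pvdarbor as pa
from pvdarbor.core import BranchOrder
from pvdarbor.fluor import (DegenerateNormalizationError, FluorTrace,
                            Punctum, PunctaSet, compare_recovery,
                            fit_recovery, landmark_enrichment_test,
                            puncta_stats, recovery_fraction,
                            tertiary_branch_count)


def make_trace(values, f_p=200.0):
    t = 5.0 * np.arange(len(values))
    return FluorTrace(t_s=t, f=np.asarray(values, float), f_p=f_p,
                      f_0=float(values[0]))


class TestRecoveryFraction:
    def test_methods_formula(self):
        """(F_n - F_0)/(F_p - F_0): 125 between 50 and 200 is half recovery."""
        curve = recovery_fraction(make_trace([50.0, 125.0, 200.0]))
        assert curve.recovery_frac == pytest.approx([0.0, 0.5, 1.0])

    def test_degenerate_normalisation(self):
        with pytest.raises(DegenerateNormalizationError):
            recovery_fraction(make_trace([50.0, 60.0], f_p=50.0))

    @given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance(self, shift, scale):
        """Adding a constant or scaling all intensities leaves fractions fixed."""
        base = np.array([50.0, 80.0, 110.0, 140.0, 170.0])
        c1 = recovery_fraction(make_trace(base))
        c2 = recovery_fraction(make_trace(base * scale + shift,
                                          f_p=200.0 * scale + shift))
        assert np.allclose(c1.recovery_frac, c2.recovery_frac, atol=1e-9)


class TestFitRecovery:
    def test_noiseless_parameters_recovered(self):
        tr = pa.generate_fluor_trace(pa.FluorSimParams(
            k_per_s=0.01, r_inf=0.8, noise_sd=0.0))
        k, r_inf, rmse = fit_recovery(recovery_fraction(tr))
        assert abs(k - 0.01) < 1e-6
        assert abs(r_inf - 0.8) < 1e-6
        assert rmse < 1e-9

    def test_flat_zero_curve(self):
        tr = pa.generate_fluor_trace(pa.FluorSimParams(k_per_s=0.0,
                                                       noise_sd=0.0))
        k, r_inf, rmse = fit_recovery(recovery_fraction(tr))
        assert k == 0.0 or r_inf == 0.0
        assert rmse == 0.0

    def test_too_few_samples(self):
        from pvdarbor.fluor import FitError, RecoveryCurve
        with pytest.raises(FitError):
            fit_recovery(RecoveryCurve(t_s=np.arange(5.0),
                                       recovery_frac=np.zeros(5)))

    def test_rate_error_shrinks_with_noise(self):
        """Median |k_hat - k|/k decreases monotonically over a noise grid."""
        meds = []
        for noise in (15.0, 7.5, 1.5, 0.0):
            errs = []
            for seed in range(25):
                tr = pa.generate_fluor_trace(pa.FluorSimParams(
                    k_per_s=0.01, r_inf=0.8, noise_sd=noise, seed=seed))
                k, _, _ = fit_recovery(recovery_fraction(tr))
                errs.append(abs(k - 0.01) / 0.01)
            meds.append(np.median(errs))
        assert meds[0] >= meds[1] >= meds[2] >= meds[3]


class TestCompareRecovery:
    def _cohort(self, k, seeds, noise=7.5):
        return [recovery_fraction(pa.generate_fluor_trace(
            pa.FluorSimParams(k_per_s=k, noise_sd=noise, seed=s)))
            for s in seeds]

    def test_self_comparison_is_null(self):
        """A cohort against a copy of itself: group F ~ 0, p ~ 1."""
        a = self._cohort(0.01, range(4))
        res = compare_recovery(a, [pa.RecoveryCurve(c.t_s.copy(),
                                                    c.recovery_frac.copy())
                                   for c in a])
        assert res["group_F"] < 1e-10
        assert res["group_p"] > 0.999

    def test_mismatched_grids_rejected(self):
        a = self._cohort(0.01, range(2))
        b = self._cohort(0.01, range(2))
        b[0].t_s = b[0].t_s + 1.0
        with pytest.raises(ValueError):
            compare_recovery(a, b)

    def test_doubled_rate_detected_with_power(self):
        """k_B = 2 k_A with 8 curves/cohort at 5% noise: the group effect is
        detected (p < 0.05) in well over 90% of replicate experiments."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            a = self._cohort(0.01, range(rep * 16, rep * 16 + 8))
            b = self._cohort(0.02, range(rep * 16 + 8, rep * 16 + 16))
            if compare_recovery(a, b)["group_p"] < 0.05:
                hits += 1
        assert hits / n_rep > 0.9


class TestPunctaStats:
    def test_empty(self, wt_labeled):
        res = puncta_stats(PunctaSet(puncta=[]), wt_labeled)
        assert res["mean_per_tertiary"] == 0.0
        assert not res["has_tertiary_puncta"]

    def test_six_puncta_on_three_branches(self, hand_arbor):
        graph, _ = hand_arbor
        lab = pa.assign_orders(graph)
        assert tertiary_branch_count(lab) == 3
        base_edges = lab.edges_of_order(BranchOrder.TERTIARY)
        puncta = [Punctum(i, base_edges[i % len(base_edges)], 1.0,
                          BranchOrder.TERTIARY) for i in range(6)]
        res = puncta_stats(PunctaSet(puncta=puncta), lab)
        assert res["mean_per_tertiary"] == pytest.approx(2.0)

    def test_order_restricted_generation(self, wt, wt_labeled):
        graph, truth = wt
        ps = pa.generate_puncta(graph, truth,
                                pa.PunctaSimParams(n_puncta=50, seed=2),
                                orders=(BranchOrder.TERTIARY,))
        assert all(p.order is BranchOrder.TERTIARY for p in ps.puncta)
        res = puncta_stats(ps, wt_labeled)
        assert res["n_tertiary_puncta"] == 50


class TestEnrichmentTest:
    def test_extreme_enrichment_floor_p(self, wt, wt_labeled):
        """With all puncta on landmarks, p reaches its 1/(n_perm+1) floor."""
        graph, truth = wt
        ps = pa.generate_puncta(graph, truth, pa.PunctaSimParams(
            n_puncta=200, landmark_enrichment=1e9, seed=5))
        lm = [(l.s, l.theta, l.kind) for l in truth.landmarks]
        obs, p = landmark_enrichment_test(ps, lm, wt_labeled, n_perm=999,
                                          seed=1)
        assert obs > 0.95
        assert p == pytest.approx(1 / 1000)

    def test_strong_enrichment_detected(self, wt, wt_labeled):
        graph, truth = wt
        lm = [(l.s, l.theta, l.kind) for l in truth.landmarks]
        hits = 0
        for rep in range(20):
            ps = pa.generate_puncta(graph, truth, pa.PunctaSimParams(
                n_puncta=200, landmark_enrichment=5.0, seed=rep))
            _, p = landmark_enrichment_test(ps, lm, wt_labeled, n_perm=199,
                                            seed=rep)
            hits += p < 0.05
        assert hits >= 18

    def test_requires_puncta_and_landmarks(self, wt_labeled):
        with pytest.raises(ValueError):
            landmark_enrichment_test(PunctaSet(puncta=[]), [(0, 0, "x")],
                                     wt_labeled)
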