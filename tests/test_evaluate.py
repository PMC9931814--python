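import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from anevrix.annotate import MaskStats
from anevrix.evaluate import (
    chi_squared,
    froc,
    match_detections,
    wilcoxon_signed_rank,
    wilson_ci,
)
from anevrix.infer import Candidate


def lesion(centroid, diameter=5.0):
    return MaskStats(tuple(map(float, centroid)), diameter, 10)


def cand(center, score, count=10):
    return Candidate(tuple(map(float, center)), score, count)


class TestMatchDetections:
    def test_no_candidates(self):
        res = match_detections([], [lesion((0, 0, 0)), lesion((20, 0, 0))])
        assert res.n_hits == 0
        assert res.n_fp == 0
        assert len(res.missed_lesions) == 2

    def test_exact_centroid_hit(self):
        res = match_detections([cand((1, 2, 3), 0.9)], [lesion((1, 2, 3))])
        assert res.n_hits == 1
        assert res.n_fp == 0

    def test_10mm_from_5mm_lesion_is_fp(self):
        res = match_detections([cand((10, 0, 0), 0.9)], [lesion((0, 0, 0), 5.0)])
        assert res.n_hits == 0
        assert res.n_fp == 1
        assert res.missed_lesions == [0]

    def test_each_lesion_matched_once_extra_hits_discarded(self):
        cands = [cand((0, 0, 0), 0.9), cand((1, 0, 0), 0.8)]
        res = match_detections(cands, [lesion((0, 0, 0), 5.0)])
        assert res.n_hits == 1
        assert res.n_fp == 0  # second hit on same lesion is neither TP nor FP

    def test_greedy_descending_score(self):
        # the higher-score candidate claims the lesion
        cands = [cand((1, 0, 0), 0.5), cand((0, 0, 0), 0.9)]
        res = match_detections(cands, [lesion((0, 0, 0), 5.0)])
        assert res.matched[0][0].score == 0.9

    def test_order_invariance_distinct_scores(self):
        cands = [cand((0, 0, 0), 0.9), cand((30, 0, 0), 0.6), cand((0, 3, 0), 0.7)]
        lesions = [lesion((0, 0, 0), 5.0), lesion((0, 4, 0), 5.0)]
        base = match_detections(cands, lesions)
        for perm in itertools.permutations(cands):
            res = match_detections(list(perm), lesions)
            assert res.n_hits == base.n_hits
            assert res.n_fp == base.n_fp

    def test_floor_mm(self):
        res = match_detections([cand((2, 0, 0), 0.9)], [lesion((0, 0, 0), 0.5)],
                               floor_mm=3.0)
        assert res.n_hits == 1


class TestFroc:
    def test_oracle_detector(self):
        lesions = {f"s{i}": [lesion((0, 0, 0))] for i in range(3)}
        cands = {f"s{i}": [cand((0, 0, 0), 1.0)] for i in range(3)}
        curve = froc(cands, lesions, thresholds=[0.9, 0.5, 0.1])
        assert curve.sensitivity == [1.0, 1.0, 1.0]
        assert curve.fp_per_subject == [0.0, 0.0, 0.0]
        assert all(a == pytest.approx(1.0) for a in curve.per_subject_auc.values())

    def test_empty_detector_auc_zero(self):
        lesions = {"s0": [lesion((0, 0, 0))]}
        curve = froc({"s0": []}, lesions, thresholds=[0.9, 0.5])
        assert curve.per_subject_auc["s0"] == 0.0

    def test_hand_computed_operating_points(self):
        # 1 subject, 1 lesion, hit@0.9 and FP@0.6; thresholds .95/.8/.5:
        # points (fp, sens) = (0,0), (0,1), (1,1); extended to the cap the
        # normalized trapezoid is 1.0
        lesions = {"s0": [lesion((0, 0, 0), 5.0)]}
        cands = {"s0": [cand((0, 0, 0), 0.9), cand((50, 0, 0), 0.6)]}
        curve = froc(cands, lesions, thresholds=[0.95, 0.8, 0.5])
        assert curve.fp_per_subject == [0.0, 0.0, 1.0]
        assert curve.sensitivity == [0.0, 1.0, 1.0]
        assert curve.per_subject_auc["s0"] == pytest.approx(1.0)

    def test_control_subject_contributes_fp_only(self):
        lesions = {"s0": [lesion((0, 0, 0))], "ctrl": []}
        cands = {"s0": [cand((0, 0, 0), 0.9)],
                 "ctrl": [cand((5, 5, 5), 0.7)]}
        curve = froc(cands, lesions, thresholds=[0.8, 0.5])
        assert curve.sensitivity == [1.0, 1.0]  # ctrl excluded from mean
        assert curve.fp_per_subject == [0.0, 0.5]
        assert "ctrl" not in curve.per_subject_auc

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            froc({}, {}, thresholds=[0.1, 0.9])

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_monotonicity_under_threshold_sweep(self, seed):
        rng = np.random.default_rng(seed)
        cands, lesions = {}, {}
        for i in range(4):
            s = f"s{i}"
            lesions[s] = [lesion(rng.uniform(0, 50, 3), rng.uniform(3, 8))
                          for _ in range(rng.integers(0, 3))]
            cands[s] = [cand(rng.uniform(0, 50, 3), rng.random())
                        for _ in range(rng.integers(0, 6))]
        thr = sorted(np.round(rng.random(8), 3).tolist(), reverse=True)
        curve = froc(cands, lesions, thresholds=thr)
        assert all(b >= a - 1e-12 for a, b in
                   zip(curve.fp_per_subject, curve.fp_per_subject[1:]))
        assert all(b >= a - 1e-12 for a, b in
                   zip(curve.sensitivity, curve.sensitivity[1:]))


class TestWilsonCI:
    def test_k0_n1(self):
        lo, hi = wilson_ci(0, 1)
        assert lo == 0.0
        assert hi == pytest.approx(0.79345, abs=1e-4)

    def test_symmetry(self):
        lo1, hi1 = wilson_ci(3, 10)
        lo2, hi2 = wilson_ci(7, 10)
        assert lo1 == pytest.approx(1 - hi2)
        assert hi1 == pytest.approx(1 - lo2)

    def test_101_of_127(self):
        lo, hi = wilson_ci(101, 127)
        assert lo == pytest.approx(0.71693, abs=1e-4)
        assert hi == pytest.approx(0.85629, abs=1e-4)

    def test_direct_formula(self):
        # independent re-derivation of the closed form
        from scipy.stats import norm

        k, n = 13, 40
        z = norm.ppf(0.975)
        phat = k / n
        lo = (phat + z**2 / (2 * n) - z * np.sqrt(
            phat * (1 - phat) / n + z**2 / (4 * n**2))) / (1 + z**2 / n)
        hi = (phat + z**2 / (2 * n) + z * np.sqrt(
            phat * (1 - phat) / n + z**2 / (4 * n**2))) / (1 + z**2 / n)
        assert wilson_ci(k, n) == pytest.approx((lo, hi))

    def test_n0_errors(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


def _enumerated_p(d):
    """Full 2^n sign enumeration oracle for the two-sided exact p."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    wobs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    n = len(d)
    count = sum(
        1 for signs in itertools.product([1, -1], repeat=n)
        if sum(r for r, s in zip(ranks, signs) if s > 0) <= wobs)
    return min(1.0, 2 * count / 2 ** n)


class TestWilcoxon:
    def test_spec_example(self):
        w, p, n = wilcoxon_signed_rank([1, 2, 3], [0, 0, 0])
        assert w == 0
        assert p == pytest.approx(0.25)
        assert n == 3

    def test_all_zero_diffs_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2])

    def test_sign_symmetry(self):
        x = np.array([0.3, -1.2, 2.5, 0.7])
        w1, p1, _ = wilcoxon_signed_rank(x, np.zeros(4))
        w2, p2, _ = wilcoxon_signed_rank(-x, np.zeros(4))
        assert w1 == w2
        assert p1 == pytest.approx(p2)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        d = rng.normal(size=n)
        while len(set(np.abs(d))) < n or (d == 0).any():
            d = rng.normal(size=n)
        _, p, _ = wilcoxon_signed_rank(d, np.zeros(n))
        assert p == pytest.approx(_enumerated_p(d))

    def test_matches_scipy_exact(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(7)
        d = rng.normal(size=10)
        _, p, _ = wilcoxon_signed_rank(d, np.zeros(10))
        ref = scipy_wilcoxon(d, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(ref)


class TestChiSquared:
    def test_cohort_sex_table(self):
        # printed demographic 2x2 table reproduces ~5.9
        chi2, dof, p = chi_squared([[53, 104], [61, 66]])
        assert dof == 1
        assert chi2 == pytest.approx(5.9, abs=0.1)
        assert p == pytest.approx(0.0147, abs=1e-3)

    def test_independence(self):
        chi2, dof, p = chi_squared([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        chi2, _, _ = chi_squared([[5, 0], [0, 5]])
        assert chi2 == pytest.approx(10.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
    def test_closed_form_property(self, cells):
        a, b, c, d = cells
        chi2, dof, _ = chi_squared([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(closed)
        assert dof == 1

    def test_matches_scipy(self):
        from scipy.stats import chi2_contingency

        table = [[12, 7, 9], [3, 14, 8]]
        chi2, dof, p = chi_squared(table)
        ref = chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert dof == ref.dof
        assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [1, 2]])
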