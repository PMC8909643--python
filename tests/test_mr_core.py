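import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mrmediate as mm
from mrmediate.mr_core import InsufficientInstrumentsError, wald_ratio

from conftest import make_h


class TestWaldRatio:
    def test_ratio_and_first_order_se(self):
        ratio, se = wald_ratio(0.2, 0.02, 0.01)
        assert ratio == pytest.approx(0.1)
        assert se == pytest.approx(0.05)

    def test_unit_exposure_is_identity(self):
        assert wald_ratio(1.0, 0.05, 0.01) == (0.05, 0.01)

    def test_zero_outcome_effect(self):
        ratio, se = wald_ratio(-0.5, 0.0, 0.01)
        assert ratio == 0.0 and se == pytest.approx(0.02)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.1, 0.01)


class TestIvw:
    def test_fixed_effect_closed_form(self):
        h = make_h([1.0, 1.0], [0.1, 0.3], [0.1, 0.1])
        r = mm.ivw(h, model="fixed")
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(np.sqrt(1 / 200), abs=1e-12)
        assert r.q_stat == pytest.approx(2.0)

    def test_random_effects_inflates_by_dispersion(self):
        h = make_h([1.0, 1.0], [0.1, 0.3], [0.1, 0.1])
        r = mm.ivw(h, model="random")
        assert r.se == pytest.approx(np.sqrt(1 / 200) * np.sqrt(2.0), abs=1e-12)

    def test_single_snp_reduces_to_wald(self):
        h = make_h([1.0], [0.05], [0.01])
        r = mm.ivw(h)
        assert r.method == "wald"
        assert (r.beta, r.se) == wald_ratio(1.0, 0.05, 0.01)

    def test_random_never_below_fixed(self, homogeneous_h):
        assert mm.ivw(homogeneous_h, "random").se >= mm.ivw(homogeneous_h, "fixed").se

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000))
    def test_equals_weighted_mean_of_wald_ratios(self, seed):
        rng = np.random.default_rng(seed)
        j = rng.integers(2, 12)
        bx = rng.uniform(0.02, 0.5, j) * rng.choice([-1, 1], j)
        by = rng.normal(0, 0.1, j)
        sy = rng.uniform(0.005, 0.1, j)
        h = make_h(bx, by, sy)
        w = bx**2 / sy**2
        expected = np.sum(w * (by / bx)) / np.sum(w)
        assert mm.ivw(h).beta == pytest.approx(expected, abs=1e-10)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.1, 10.0), st.integers(0, 1000))
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.3, 6)
        by, sy = rng.normal(0, 0.05, 6), rng.uniform(0.01, 0.05, 6)
        r1 = mm.ivw(make_h(bx, by, sy))
        r2 = mm.ivw(make_h(bx, c * by, c * sy))
        assert r2.beta == pytest.approx(c * r1.beta, rel=1e-10)
        assert r2.se == pytest.approx(c * r1.se, rel=1e-10)


class TestEgger:
    def test_closed_form_line(self):
        h = make_h([1.0, 2.0, 3.0], [0.3, 0.5, 0.7], [0.1] * 3)
        r = mm.mr_egger(h)
        assert r.beta == pytest.approx(0.2, abs=1e-10)
        assert r.egger_intercept == pytest.approx(0.1, abs=1e-10)

    def test_proportional_data_has_zero_intercept(self):
        h = make_h([0.5, 1.0, 2.0], [0.25, 0.5, 1.0], [0.1] * 3)
        r = mm.mr_egger(h)
        assert r.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert r.beta == pytest.approx(0.5, abs=1e-12)

    def test_orientation_invariance(self):
        bx = np.array([0.2, -0.3, 0.4, -0.5])
        by = 0.3 * bx + 0.05 * np.sign(bx)
        sy = np.full(4, 0.02)
        r1 = mm.mr_egger(make_h(bx, by, sy))
        r2 = mm.mr_egger(make_h(np.abs(bx), 0.3 * np.abs(bx) + 0.05, sy))
        assert r1.beta == pytest.approx(r2.beta, rel=1e-10)
        assert r1.egger_intercept == pytest.approx(r2.egger_intercept, rel=1e-10)

    def test_too_few_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            mm.mr_egger(make_h([1.0, 2.0], [0.1, 0.2], [0.1, 0.1]))

    def test_constant_bx_is_singular(self):
        with pytest.raises(ValueError):
            mm.mr_egger(make_h([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.1] * 3))


class TestMedians:
    def test_simple_median_odd_count(self):
        h = make_h([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], [0.1] * 3)
        assert mm.simple_median(h, n_boot=50).beta == pytest.approx(0.2)

    def test_weighted_median_interpolation(self):
        # ratios (0.1, 0.2, 0.3) with weights (1, 1, 2)
        sy = np.array([1.0, 1.0, np.sqrt(0.5)])
        h = make_h([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], sy, sx=[[1e-9] * 3])
        assert mm.weighted_median(h, n_boot=50).beta == pytest.approx(0.23333, abs=1e-4)

    def test_constant_ratios_recovered_with_small_se(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_h(bx, 0.7 * bx, np.full(4, 1e-4), sx=np.full((1, 4), 1e-6))
        r = mm.simple_median(h, n_boot=200, seed=5)
        assert r.beta == pytest.approx(0.7, abs=1e-3)
        assert r.se < 0.01
        assert r.pval < 1e-10

    def test_weighted_median_robust_to_minority_invalid_weight(self):
        """<50% invalid weight: weighted median stays near the true effect."""
        rng = np.random.default_rng(7)
        reps, hits = 60, 0
        for i in range(reps):
            r = np.random.default_rng(100 + i)
            bx = r.uniform(0.05, 0.2, 20)
            sy = np.full(20, 0.01)
            by = 0.3 * bx + r.normal(0, sy)
            by[:6] += 0.15  # ~30% of weight invalid (uniform weights regime)
            h = make_h(bx, by, sy, sx=np.full((1, 20), 1e-6))
            est = mm.weighted_median(h, n_boot=50, seed=i).beta
            hits += abs(est - 0.3) < 0.1
        assert hits / reps > 0.9


class TestPerSnp:
    def test_single_snp_rows_match_wald(self):
        h = make_h([0.1, 0.2, 0.4], [0.02, 0.05, 0.08], [0.01] * 3)
        df = mm.single_snp_analysis(h)
        assert len(df) == 3
        for i in range(3):
            ratio, se = wald_ratio(h.bx[0, i], h.by[i], h.sy[i])
            assert df.loc[i, "ratio"] == pytest.approx(ratio)
            assert df.loc[i, "ratio_se"] == pytest.approx(se)

    def test_zero_bx_marked_undefined(self):
        h = make_h([0.0, 0.2, 0.4], [0.02, 0.05, 0.08], [0.01] * 3)
        df = mm.single_snp_analysis(h)
        assert np.isnan(df.loc[0, "ratio"]) and "bx = 0" in df.loc[0, "note"]

    def test_homogeneous_ratios_all_equal(self, homogeneous_h):
        df = mm.single_snp_analysis(homogeneous_h)
        np.testing.assert_allclose(df["ratio"], 0.25, atol=1e-12)


class TestLeaveOneOut:
    def test_homogeneous_estimates_equal_full(self, homogeneous_h):
        full = mm.ivw(homogeneous_h).beta
        df = mm.leave_one_out(homogeneous_h)
        np.testing.assert_allclose(df["beta"], full, atol=1e-12)

    def test_outlier_exclusion_moves_estimate_most(self):
        bx = np.full(8, 0.2)
        by = 0.1 * bx
        by[3] = 0.5  # gross outlier
        h = make_h(bx, by, np.full(8, 0.02))
        full = mm.ivw(h).beta
        df = mm.leave_one_out(h)
        shifts = np.abs(df["beta"] - full)
        assert df.loc[shifts.idxmax(), "left_out_snp"] == "rs4"

    def test_three_snps_match_complementary_pairs(self):
        h = make_h([0.1, 0.2, 0.3], [0.02, 0.03, 0.1], [0.01, 0.02, 0.03])
        df = mm.leave_one_out(h, model="fixed")
        for i, snp in enumerate(h.snp_ids):
            keep = [j for j in range(3) if j != i]
            pair = make_h(h.bx[0, keep], h.by[keep], h.sy[keep])
            assert df.loc[i, "beta"] == pytest.approx(mm.ivw(pair, "fixed").beta)


class TestCoverage:
    def test_ivw_covers_truth_at_nominal_rate(self):
        """95% CI coverage of the total effect under no pleiotropy."""
        reps, cover = 300, 0
        for s in range(reps):
            e, _, o, _ = mm.simulate_mediation_sumstats(mm.MediationTruth(seed=s))
            ids = [r.snp_id for r in mm.select_genomewide(e).records]
            res = mm.ivw(mm.harmonize(e.subset(ids), o))
            cover += abs(res.beta - 0.3) < 1.96 * res.se
        # 3 Monte-Carlo SEs around 0.95 at 300 reps
        assert 0.95 - 3 * 0.0126 < cover / reps <= 1.0

    def test_egger_intercept_rejects_under_directional_pleiotropy(self):
        """Strong directional pleiotropy drives the intercept test to reject."""
        rejected = 0
        for s in range(20):
            truth = mm.MediationTruth(
                seed=s, invalid_fraction=1.0, pleiotropy_mean=0.05,
                pleiotropy_sd=0.005,
            )
            e, _, o, _ = mm.simulate_mediation_sumstats(truth)
            ids = [r.snp_id for r in mm.select_genomewide(e).records]
            res = mm.mr_egger(mm.harmonize(e.subset(ids), o))
            rejected += res.egger_intercept_p < 0.05
        assert rejected >= 18
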