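import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrmediate import uvmr
from mrmediate.uvmr import (
    egger_simex,
    i2_gx,
    ivw,
    leave_one_out,
    max_likelihood,
    mr_egger,
    mr_presso,
    q_contributions,
    radial_ivw,
    radial_q,
    ratio_estimates,
    weighted_median,
)

from conftest import make_hset


def random_hset(seed, J=12, theta=0.3, sx=0.01, sy=0.02, het=0.0):
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.05, 0.2, J)
    bx = gamma + sx * rng.standard_normal(J)
    by = theta * gamma + het * rng.standard_normal(J) + sy * rng.standard_normal(J)
    return make_hset(bx, sx, by, sy)


class TestRatioEstimates:
    def test_first_order(self):
        h = make_hset([0.5], 0.05, [0.2], [0.1])
        r = ratio_estimates(h)
        assert r["ratio"].iloc[0] == pytest.approx(0.4)
        assert r["se"].iloc[0] == pytest.approx(0.2)

    def test_sign(self):
        h = make_hset([-0.5], 0.05, [0.2], [0.1])
        assert ratio_estimates(h)["ratio"].iloc[0] == pytest.approx(-0.4)

    def test_second_order_closed_form(self):
        h = make_hset([0.5], 0.05, [0.2], [0.1])
        se = ratio_estimates(h, second_order=True)["se"].iloc[0]
        expect = np.sqrt(0.1**2 / 0.5**2 + 0.2**2 * 0.05**2 / 0.5**4)
        assert se == pytest.approx(expect, rel=1e-12)

    def test_zero_beta_x_dropped(self):
        h = make_hset([0.0, 0.5], 0.05, [0.1, 0.2], [0.1, 0.1])
        with pytest.warns(UserWarning, match="beta_x = 0"):
            r = ratio_estimates(h)
        assert len(r) == 1


class TestIvw:
    def test_exact_fit(self):
        h = make_hset([1.0, 2.0, 0.5], 0.0, [0.4, 0.8, 0.2], [0.1, 0.1, 0.1])
        fit = ivw(h, "fixed")
        assert fit.estimate == pytest.approx(0.4, rel=1e-12)
        assert fit.heterogeneity.Q == pytest.approx(0.0, abs=1e-20)
        assert fit.heterogeneity.I2 == 0.0

    def test_hand_computed_wls(self, three_snp_hset):
        fit = ivw(three_snp_hset, "fixed")
        assert fit.estimate == pytest.approx(0.3, abs=1e-10)
        assert fit.se == pytest.approx(0.1 / np.sqrt(6.0), abs=1e-10)

    def test_single_snp_degrades_to_wald(self):
        h = make_hset([0.5], 0.05, [0.2], [0.1])
        fit = ivw(h)
        assert fit.method == "wald-ratio"
        assert fit.estimate == pytest.approx(0.4)

    def test_auto_picks_random_on_heterogeneity(self):
        h = random_hset(1, J=20, het=0.2)
        fit = ivw(h, "auto")
        assert fit.heterogeneity.p_Q < 0.05 and fit.heterogeneity.I2 > 0.25
        assert fit.method == "ivw-random"
        assert fit.se > ivw(h, "fixed").se

    def test_auto_stays_fixed_when_homogeneous(self):
        fit = ivw(random_hset(2, J=20, sx=0.0), "auto")
        assert fit.method == "ivw-fixed"

    def test_q_additivity(self):
        h = random_hset(3, J=15, het=0.05)
        fit = ivw(h, "fixed")
        assert q_contributions(h)["q_contribution"].sum() == pytest.approx(
            fit.heterogeneity.Q, rel=1e-12
        )

    def test_recovery_on_simulated_valid_instruments(self):
        from mrmediate.harmonize import harmonize_pair
        from mrmediate.synthgen import (
            SimTruth, compute_gwas_summary, simulate_cohort, trait_subsamples,
        )

        ests = []
        for seed in range(10):
            t = SimTruth(J=30, n_per_trait=8000, gamma=0.25, maf=0.4,
                         alpha=-0.17, beta_m=0.41, theta_d=-0.37, seed=seed)
            c = simulate_cohort(t)
            subs = trait_subsamples(t)
            X = compute_gwas_summary(c, "X", subs["X"], "X")
            Y = compute_gwas_summary(c, "Y", subs["Y"], "Y")
            ests.append(ivw(harmonize_pair(X, Y), "fixed").estimate)
        sem = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(-0.4397, abs=4 * sem + 0.01)


class TestEgger:
    def test_exact_linear_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.1 + 0.3 * bx
        fit = mr_egger(make_hset(bx, 0.01, by, 0.02))
        assert fit.egger_intercept[0] == pytest.approx(0.1, abs=1e-10)
        assert fit.estimate == pytest.approx(0.3, abs=1e-10)

    def test_orientation_applied(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = 0.05 + 0.3 * np.abs(bx)
        by = by * np.sign(bx)
        # after orienting bx >= 0: by = 0.05 + 0.3 bx exactly
        fit = mr_egger(make_hset(bx, 0.01, by, 0.02))
        assert fit.estimate == pytest.approx(0.3, abs=1e-10)
        assert fit.egger_intercept[0] == pytest.approx(0.05, abs=1e-10)

    def test_min_snps(self):
        with pytest.raises(ValueError, match="3"):
            mr_egger(make_hset([0.1, 0.2], 0.01, [0.1, 0.2], [0.1, 0.1]))

    def test_directional_pleiotropy_detected(self):
        rng = np.random.default_rng(11)
        J = 200
        gamma = rng.uniform(0.05, 0.3, J)
        by = 0.05 + 0.3 * gamma + 0.005 * rng.standard_normal(J)
        fit = mr_egger(make_hset(gamma, 0.0, by, 0.02))
        assert fit.egger_intercept[0] == pytest.approx(0.05, abs=0.01)
        assert fit.egger_intercept[2] < 0.01


class TestWeightedMedian:
    def test_simple_median_equal_weights(self):
        h = make_hset([1.0, 1.0, 1.0], 0.0, [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        fit = weighted_median(h, n_boot=50, seed=1)
        assert fit.estimate == pytest.approx(2.0, rel=1e-12)

    def test_four_ratios_cumulative_walk_oracle(self):
        # independent oracle: centred cumulative weights p_j = cum_j - w_j/2,
        # linear interpolation at 0.5 -> between ratios 2 and 3 -> 2.5
        ratios = np.array([1.0, 2.0, 3.0, 10.0])
        w = np.full(4, 0.25)
        p = np.cumsum(w) - w / 2
        expect = np.interp(0.5, p, ratios)
        assert expect == pytest.approx(2.5)
        h = make_hset(np.ones(4), 0.0, ratios, np.ones(4))
        fit = weighted_median(h, n_boot=50, seed=1)
        assert fit.estimate == pytest.approx(expect, rel=1e-12)

    def test_resists_gross_outlier(self):
        rng = np.random.default_rng(21)
        J = 21
        gamma = rng.uniform(0.1, 0.2, J)
        by = 0.4 * gamma
        by[0] += 20 * 0.02
        h = make_hset(gamma, 0.005, by, 0.02)
        wm = weighted_median(h, seed=3)
        iv = ivw(h, "fixed")
        assert abs(wm.estimate - 0.4) < 2 * wm.se
        assert abs(iv.estimate - 0.4) > 3 * wm.se  # IVW visibly displaced
        assert abs(iv.estimate - 0.4) > 10 * abs(wm.estimate - 0.4)

    def test_penalized_downweights_outlier(self):
        rng = np.random.default_rng(22)
        J = 15
        gamma = rng.uniform(0.1, 0.2, J)
        by = 0.4 * gamma
        by[3] += 0.5
        h = make_hset(gamma, 0.005, by, 0.02)
        pen = weighted_median(h, penalized=True, seed=4)
        assert pen.method == "penalized-weighted-median"
        assert abs(pen.estimate - 0.4) < 3 * pen.se

    def test_seeded_reproducibility(self):
        h = random_hset(5)
        a = weighted_median(h, seed=9)
        b = weighted_median(h, seed=9)
        assert (a.estimate, a.se) == (b.estimate, b.se)
        c = weighted_median(h, seed=10)
        assert c.se != a.se


class TestMaxLikelihood:
    def test_zero_exposure_se_equals_ivw(self):
        h = random_hset(6, sx=0.0)
        ml = max_likelihood(h)
        iv = ivw(h, "fixed")
        assert ml.estimate == pytest.approx(iv.estimate, abs=1e-6)

    def test_exact_fit(self):
        h = make_hset([0.1, 0.2, 0.3], 0.01, [0.04, 0.08, 0.12], [0.02, 0.02, 0.02])
        assert max_likelihood(h).estimate == pytest.approx(0.4, abs=1e-8)

    def test_calibration_small_study(self):
        cover = 0
        for seed in range(40):
            h = random_hset(seed, J=25, theta=0.3, sx=0.01, sy=0.02)
            fit = max_likelihood(h)
            cover += fit.ci_low <= 0.3 <= fit.ci_high
        assert cover >= 33  # ≈95% with binomial slack


class TestRadial:
    @pytest.mark.parametrize("seed", range(5))
    def test_identical_to_ivw(self, seed):
        h = random_hset(seed, het=0.03)
        assert radial_ivw(h).estimate == pytest.approx(
            ivw(h, "fixed").estimate, abs=1e-10
        )

    def test_exact_fit_zero_q(self):
        h = make_hset([1.0, 2.0], 0.0, [0.4, 0.8], [0.1, 0.1])
        assert radial_q(h)["radial_q"].abs().max() < 1e-20

    def test_outlier_has_max_q(self):
        h = random_hset(7, J=10, sx=0.0)
        t = h.table.copy()
        t.loc[4, "beta_y"] += 0.5
        from mrmediate.harmonize import HarmonizedSet

        q = radial_q(HarmonizedSet(t))
        assert q["radial_q"].idxmax() == 4


class TestPresso:
    def test_internal_consistency_estimate_after(self):
        rng = np.random.default_rng(31)
        J = 15
        gamma = rng.uniform(0.1, 0.2, J)
        by = 0.3 * gamma + 0.02 * rng.standard_normal(J)
        by[2] += 10 * 0.02
        h = make_hset(gamma, 0.005, by, 0.02)
        res = mr_presso(h, nb_sim=1000, seed=2)
        assert "rs3" in res.outlier_snp_ids
        kept = [s for s in h.snp_ids if s not in res.outlier_snp_ids]
        assert res.estimate_after.estimate == pytest.approx(
            ivw(h.subset(kept), "auto").estimate, rel=1e-12
        )

    def test_min_snps_and_sims(self):
        h = make_hset([0.1, 0.2, 0.3], 0.01, [0.1, 0.2, 0.3], [0.1] * 3)
        with pytest.raises(ValueError, match="4"):
            mr_presso(h, nb_sim=1000, seed=1)
        h5 = random_hset(1, J=5)
        with pytest.raises(ValueError, match="100"):
            mr_presso(h5, nb_sim=10, seed=1)

    def test_resolution_warning(self):
        h = random_hset(2, J=20)
        with pytest.warns(UserWarning, match="nb_sim"):
            mr_presso(h, nb_sim=150, seed=1)

    def test_seeded_reproducibility(self):
        h = random_hset(3, J=10, het=0.02)
        a = mr_presso(h, nb_sim=200, seed=5)
        b = mr_presso(h, nb_sim=200, seed=5)
        assert a.global_rss_p == b.global_rss_p
        assert a.outlier_snp_ids == b.outlier_snp_ids


class TestLeaveOneOut:
    def test_row_count(self):
        h = random_hset(8, J=7)
        assert len(leave_one_out(h)) == 8

    def test_homogeneous_estimates_close(self):
        h = make_hset([0.1, 0.2, 0.3, 0.4], 0.0,
                      [0.04, 0.08, 0.12, 0.16], [0.02] * 4)
        out = leave_one_out(h)
        assert out["estimate"].std() < 1e-12

    def test_outlier_departs_most(self):
        rng = np.random.default_rng(41)
        J = 10
        gamma = rng.uniform(0.1, 0.2, J)
        by = 0.3 * gamma
        by[6] += 0.3
        h = make_hset(gamma, 0.0, by, 0.02)
        out = leave_one_out(h)
        full = out.loc[out["dropped"] == "none", "estimate"].iloc[0]
        dev = (out.loc[out["dropped"] != "none"]
               .assign(d=lambda d: (d["estimate"] - full).abs()))
        assert dev.loc[dev["d"].idxmax(), "dropped"] == "rs7"


class TestSimex:
    def test_no_dilution_when_sx_zero(self):
        h = random_hset(9, J=10, sx=0.0)
        corrected = egger_simex(h, B=25, seed=1)
        naive = mr_egger(h)
        assert corrected.estimate == pytest.approx(naive.estimate, rel=1e-6)

    def test_i2_gx_formula(self):
        h = random_hset(10, J=12, sx=0.02)
        bx, sx = np.abs(h.beta_x), h.se_x
        wm = np.sum(bx / sx**2) / np.sum(1 / sx**2)
        Q = np.sum(((bx - wm) / sx) ** 2)
        expect = max(0.0, (Q - (len(bx) - 1)) / Q)
        assert i2_gx(h) == pytest.approx(expect, rel=1e-12)
        # the arithmetic at Q = 2(J-1) gives exactly 0.5
        J = len(bx)
        assert (2 * (J - 1) - (J - 1)) / (2 * (J - 1)) == 0.5

    def test_corrects_attenuation(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            J = 60
            gamma = rng.uniform(0.1, 0.3, J)
            sx = 0.05  # strong dilution, no sign flips
            bx = gamma + sx * rng.standard_normal(J)
            by = 0.01 + 0.4 * gamma + 0.01 * rng.standard_normal(J)
            h = make_hset(bx, sx, by, 0.01)
            naive = mr_egger(h).estimate
            corr = egger_simex(h, B=100, seed=seed).estimate
            hits += abs(corr - 0.4) < abs(naive - 0.4)
        assert hits >= 18  # true improvement rate ≈84%; binomial slack

    def test_seeded_reproducibility(self):
        h = random_hset(11, J=8, sx=0.02)
        a = egger_simex(h, B=30, seed=7)
        b = egger_simex(h, B=30, seed=7)
        assert a.estimate == b.estimate


class TestInvariances:
    @pytest.mark.parametrize("c", [0.5, 2.0, -1.5])
    def test_outcome_scale_equivariance(self, c):
        h = random_hset(12, J=10)
        t = h.table.copy()
        t["beta_y"] *= c
        t["se_y"] *= abs(c)
        from mrmediate.harmonize import HarmonizedSet

        hc = HarmonizedSet(t)
        for fn in (lambda x: ivw(x, "fixed"), max_likelihood, radial_ivw):
            a, b = fn(h), fn(hc)
            assert b.estimate == pytest.approx(c * a.estimate, rel=1e-5)
            assert b.se == pytest.approx(abs(c) * a.se, rel=1e-4)
        wm_a = weighted_median(h, n_boot=50, seed=3)
        wm_b = weighted_median(hc, n_boot=50, seed=3)
        assert wm_b.estimate == pytest.approx(c * wm_a.estimate, rel=1e-10)

    def test_orientation_invariance(self):
        h = random_hset(13, J=9)
        t = h.table.copy()
        flip = [0, 3, 5]
        t.loc[flip, "beta_x"] *= -1
        t.loc[flip, "beta_y"] *= -1
        from mrmediate.harmonize import HarmonizedSet

        hf = HarmonizedSet(t)
        assert ivw(hf, "fixed").estimate == pytest.approx(
            ivw(h, "fixed").estimate, rel=1e-12
        )
        assert radial_ivw(hf).estimate == pytest.approx(
            radial_ivw(h).estimate, rel=1e-12
        )
        assert max_likelihood(hf).estimate == pytest.approx(
            max_likelihood(h).estimate, abs=1e-8
        )
        assert weighted_median(hf, n_boot=10, seed=1).estimate == pytest.approx(
            weighted_median(h, n_boot=10, seed=1).estimate, rel=1e-12
        )


@given(st.integers(0, 10_000))
@settings(max_examples=20, deadline=None)
def test_property_radial_equals_ivw(seed):
    h = random_hset(seed, J=6, het=0.05)
    assert radial_ivw(h).estimate == pytest.approx(ivw(h, "fixed").estimate, abs=1e-10)
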