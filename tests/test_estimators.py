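import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mrmediate as mm
from mrmediate.estimators import _weighted_median


def random_pairs(rng, j=20, beta=0.3):
    g = rng.uniform(0.05, 0.3, j) * rng.choice([-1.0, 1.0], j)
    se_x = rng.uniform(0.003, 0.01, j)
    se_y = rng.uniform(0.01, 0.05, j)
    bx = g + rng.normal(0, se_x)
    by = beta * g + rng.normal(0, se_y)
    return bx, se_x, by, se_y


class TestWaldRatio:
    def test_first_order_ratio_and_se(self):
        res = mm.wald_ratio((0.2, 0.05, 0.05, 0.02))
        assert res.beta == pytest.approx(0.25)
        assert res.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        assert mm.wald_ratio((0.2, 0.05, 0.0, 0.02)).beta == 0.0

    def test_orientation_invariance(self):
        a = mm.wald_ratio((0.2, 0.05, 0.05, 0.02))
        b = mm.wald_ratio((-0.2, 0.05, -0.05, 0.02))
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_zero_exposure_effect_is_degenerate(self):
        with pytest.raises(mm.DegenerateInstrumentError):
            mm.wald_ratio((0.0, 0.05, 0.05, 0.02))


class TestIVW:
    def test_homogeneous_ratios_give_q_zero_fixed_model(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 0.25 * bx
        res, rep = mm.ivw((bx, np.full(3, 0.01), by, np.full(3, 0.02)))
        assert res.beta == pytest.approx(0.25)
        assert rep.q_stat == pytest.approx(0.0, abs=1e-20)
        assert res.model == "fixed"

    def test_two_pair_closed_form(self):
        # ratios {0.2, 0.4} with ratio SEs {0.1, 0.1}:
        # weighted mean 0.3, fixed se (sum 1/se^2)^-1/2 = 0.1/sqrt(2)
        bx = np.array([1.0, 1.0])
        res, _ = mm.ivw((bx, np.full(2, 1e-6), np.array([0.2, 0.4]), np.full(2, 0.1)))
        assert res.beta == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1 / math.sqrt(2))

    def test_matches_zero_intercept_wls_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        for _ in range(20):
            bx, sx, by, sy = random_pairs(rng)
            res, _ = mm.ivw((bx, sx, by, sy))
            wls = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
            assert res.beta == pytest.approx(wls.params[0], rel=1e-10)

    def test_single_pair_routed_to_wald_ratio(self):
        with pytest.raises(mm.InsufficientInstrumentsError, match="wald_ratio"):
            mm.ivw((np.array([0.1]), np.array([0.01]),
                    np.array([0.02]), np.array([0.01])))

    def test_q_invariant_to_pair_order(self):
        rng = np.random.default_rng(8)
        bx, sx, by, sy = random_pairs(rng, j=12)
        _, rep1 = mm.ivw((bx, sx, by, sy))
        perm = rng.permutation(12)
        _, rep2 = mm.ivw((bx[perm], sx[perm], by[perm], sy[perm]))
        assert rep1.q_stat == pytest.approx(rep2.q_stat, rel=1e-12)

    def test_heterogeneity_switches_to_random_effects(self):
        # wildly discordant ratios with tiny SEs must trigger the switch
        bx = np.ones(5)
        by = np.array([0.1, 0.5, -0.3, 0.8, -0.6])
        res, rep = mm.ivw((bx, np.full(5, 1e-6), by, np.full(5, 0.01)))
        assert rep.q_pval < 0.05
        assert res.model == "multiplicative_random"
        assert res.se == pytest.approx(
            (5 * (1 / 0.01**2)) ** -0.5 * math.sqrt(rep.q_stat / 4), rel=1e-12)


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3, 0.4])
        by = 0.02 + 0.3 * bx
        res, rep = mm.egger((bx, np.full(5, 0.01), by, np.full(5, 0.02)))
        assert res.beta == pytest.approx(0.3, rel=1e-10)
        assert rep.egger_intercept == pytest.approx(0.02, rel=1e-10)

    def test_matches_statsmodels_wls_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        bx, sx, by, sy = random_pairs(rng, j=15)
        sgn = np.where(bx < 0, -1.0, 1.0)
        res, rep = mm.egger((bx, sx, by, sy))
        X = sm.add_constant(bx * sgn)
        wls = sm.WLS(by * sgn, X, weights=1.0 / sy**2).fit()
        assert res.beta == pytest.approx(wls.params[1], rel=1e-10)
        assert rep.egger_intercept == pytest.approx(wls.params[0], rel=1e-10)
        # with dispersion above 1 the SEs coincide with the WLS ones too
        if wls.scale > 1:
            assert res.se == pytest.approx(wls.bse[1], rel=1e-10)

    def test_joint_sign_flip_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(3)
        bx, sx, by, sy = random_pairs(rng, j=10)
        res1, rep1 = mm.egger((bx, sx, by, sy))
        flip = rng.choice([-1.0, 1.0], 10)
        res2, rep2 = mm.egger((bx * flip, sx, by * flip, sy))
        assert res1.beta == pytest.approx(res2.beta, rel=1e-12)
        assert rep1.egger_intercept == pytest.approx(rep2.egger_intercept, rel=1e-12)

    def test_balanced_pleiotropy_intercept_centers_on_zero(self):
        # intercept truth 0; mean over replicates within Monte-Carlo error
        rng = np.random.default_rng(99)
        reps = 10_000
        intercepts = np.empty(reps)
        for i in range(reps):
            g = rng.uniform(0.05, 0.3, 10)
            se_x, se_y = np.full(10, 0.002), np.full(10, 0.02)
            alpha = rng.normal(0.0, 0.02, 10)
            bx = g + rng.normal(0, se_x)
            by = 0.25 * g + alpha + rng.normal(0, se_y)
            intercepts[i] = mm.egger((bx, se_x, by, se_y))[1].egger_intercept
        mc_se = intercepts.std(ddof=1) / math.sqrt(reps)
        assert abs(intercepts.mean()) < 3.5 * mc_se

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(mm.InsufficientInstrumentsError):
            mm.egger((np.ones(2), np.full(2, 0.01), np.ones(2), np.full(2, 0.01)))


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        bx = np.ones(3)
        by = np.array([1.0, 2.0, 9.0])
        res = mm.weighted_median((bx, np.full(3, 1e-6), by, np.ones(3)),
                                 n_boot=50, seed=0)
        assert res.beta == pytest.approx(2.0, abs=1e-12)

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=15).filter(
        lambda v: len(v) % 2 == 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equal_weights_odd_j_equals_sample_median(self, ratios):
        j = len(ratios)
        bx = np.ones(j)
        by = np.array(ratios, dtype=float)
        res = mm.weighted_median((bx, np.full(j, 1e-6), by, np.ones(j)),
                                 n_boot=4, seed=0)
        assert res.beta == pytest.approx(float(np.median(by)), abs=1e-9)

    def test_dominant_weight_brackets_estimate(self):
        # brute-force oracle over cumulative-weight crossings
        rng = np.random.default_rng(12)
        for _ in range(20):
            j = 7
            ratios = np.sort(rng.normal(0, 1, j))
            w = rng.uniform(0.01, 0.1, j)
            dom = rng.integers(0, j)
            w[dom] = w.sum() * 1.5  # one ratio holds > 50% of total weight
            est = _weighted_median(ratios, w)
            order = np.argsort(ratios)
            ws, bs = w[order], ratios[order]
            p = (np.cumsum(ws) - 0.5 * ws) / ws.sum()
            k = int(np.searchsorted(p, 0.5))
            lo = bs[max(k - 1, 0)]
            hi = bs[min(k, j - 1)]
            assert lo - 1e-12 <= est <= hi + 1e-12
            assert min(abs(est - ratios[dom]), abs(lo - ratios[dom]),
                       abs(hi - ratios[dom])) < 1e-12

    def test_robust_to_forty_percent_invalid_instruments(self):
        # directional pleiotropy on 8/20 instruments, strong-GWAS-scale SEs:
        # the weighted median stays within 10% of truth, IVW does not
        truth = 0.5
        rng = np.random.default_rng(31)
        wm, iv = [], []
        for _ in range(500):
            j = 20
            g = rng.uniform(0.15, 0.4, j)
            se_x = np.full(j, 0.004)
            se_y = np.full(j, 0.0073)  # ~ n=50,000 at maf 0.25
            alpha = np.zeros(j)
            alpha[:8] = rng.normal(0.15, 0.03, 8)
            bx = g + rng.normal(0, se_x)
            by = truth * g + alpha + rng.normal(0, se_y)
            perm = rng.permutation(j)
            pairs = (bx[perm], se_x[perm], by[perm], se_y[perm])
            wm.append(mm.weighted_median(pairs, n_boot=16, seed=1).beta)
            iv.append(mm.ivw(pairs)[0].beta)
        assert abs(np.median(wm) - truth) / truth < 0.10
        assert abs(np.median(iv) - truth) / truth > 0.10

    def test_bootstrap_se_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        pairs = random_pairs(rng, j=8)
        a = mm.weighted_median(pairs, n_boot=200, seed=7)
        b = mm.weighted_median(pairs, n_boot=200, seed=7)
        c = mm.weighted_median(pairs, n_boot=200, seed=8)
        assert a.se == b.se
        assert a.se != c.se


class TestRunMR:
    def test_consistent_positive_battery(self):
        rng = np.random.default_rng(17)
        fit = mm.run_mr(random_pairs(rng, j=12, beta=0.4), seed=1, n_boot=100)
        assert set(fit.results) == {"ivw", "egger", "weighted_median"}
        assert fit.consistency is True

    def test_discordant_directions_flagged(self):
        # slope negative but intercept positive pushes IVW positive
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        by = 0.06 - 0.15 * bx
        fit = mm.run_mr((bx, np.full(4, 0.001), by, np.full(4, 0.02)),
                        seed=1, n_boot=100)
        assert fit.results["ivw"].beta > 0 > fit.results["egger"].beta
        assert fit.consistency is False

    def test_two_pairs_runs_ivw_only(self):
        fit = mm.run_mr((np.array([0.1, 0.2]), np.full(2, 0.01),
                         np.array([0.02, 0.05]), np.full(2, 0.01)), seed=1)
        assert set(fit.results) == {"ivw"}
        assert fit.consistency is None

    def test_single_pair_falls_back_to_wald(self):
        fit = mm.run_mr((np.array([0.1]), np.array([0.01]),
                         np.array([0.02]), np.array([0.01])), seed=1)
        assert set(fit.results) == {"wald_ratio"}
        assert fit.consistency is None

    def test_eleven_snp_recovery_within_two_se(self):
        # headline analysis shape: 11 instruments, truth ln(1.221)
        truth = math.log(1.221)
        rng = np.random.default_rng(4)
        g = rng.uniform(0.06, 0.25, 11)
        se_x = np.full(11, 0.012)
        se_y = np.full(11, 0.018)
        bx = g + rng.normal(0, se_x)
        by = truth * g + rng.normal(0, se_y)
        fit = mm.run_mr((bx, se_x, by, se_y), seed=2, n_boot=200)
        res = fit.results["ivw"]
        assert abs(res.beta - truth) < 2 * res.se

    def test_ivw_single_pair_equals_wald_ratio(self):
        pair = (0.15, 0.01, 0.04, 0.012)
        wald = mm.wald_ratio(pair)
        fit = mm.run_mr(tuple(np.array([v]) for v in pair), seed=0)
        assert fit.results["wald_ratio"].beta == pytest.approx(wald.beta)


class TestModelSurface:
    def test_model_fit_summary_and_frame(self):
        rng = np.random.default_rng(6)
        bx, sx, by, sy = random_pairs(rng, j=10)
        model = mm.MRModel(bx, sx, by, sy, label="demo")
        results = model.fit("all", seed=3, n_boot=100)
        text = results.summary()
        assert "Inverse variance weighted" in text and "Egger intercept" in text
        frame = results.to_frame()
        assert len(frame) == 3 and (frame["nsnp"] == 10).all()

    def test_from_odds_ratio_round_trip(self):
        res = mm.MRResult.from_odds_ratio(1.292, 1.110, 1.503, nsnp=11)
        assert res.beta == pytest.approx(math.log(1.292))
        assert res.or_ci[0] == pytest.approx(1.110, rel=1e-9)
        assert res.se == pytest.approx(
            (math.log(1.503) - math.log(1.110)) / (2 * 1.959964))

    def test_plot_smoke(self):
        import matplotlib
        matplotlib.use("Agg")
        rng = np.random.default_rng(6)
        bx, sx, by, sy = random_pairs(rng, j=8)
        ax = mm.MRModel(bx, sx, by, sy).fit("all", seed=1, n_boot=20).plot()
        assert ax.get_xlabel() == "SNP effect on exposure"
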