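import numpy as np
import pytest
from scipy import stats

from mrmediate.estimators import (
    EstimationError,
    cochran_q,
    egger,
    ivw,
    mode_estimate,
    mr_raps,
    wald_ratio,
    weighted_median,
)
from mrmediate.synthetic_data import SimulationConfig, simulate_mediation_gwas
from mrmediate import instruments as ins

from conftest import make_pair, pairs_from_ratios


def clean_pairs(seed=1, m_snps=50, **kw):
    cfg = SimulationConfig(m_snps=m_snps, seed=seed, **kw)
    study = simulate_mediation_gwas(cfg)
    sig = ins.filter_by_pvalue(study.exposure, 5e-8)
    pairs, _ = ins.harmonize(sig, study.outcome)
    return ins.filter_weak(pairs), cfg


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(make_pair(beta_exp=0.1, se_exp=0.02, beta_out=0.05, se_out=0.01))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        est = wald_ratio(make_pair(beta_out=0.0))
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(EstimationError):
            wald_ratio(make_pair(beta_exp=0.0))

    def test_second_order_se_matches_symbolic_delta(self):
        # se^2 = sy^2/gx^2 + gy^2*sx^2/gx^4 evaluated symbolically
        import sympy

        gx, sx, gy, sy = sympy.symbols("gx sx gy sy", positive=True)
        expr = sympy.sqrt(sy**2 / gx**2 + gy**2 * sx**2 / gx**4)
        expected = float(expr.subs({gx: 0.1, sx: 0.02, gy: 0.05, sy: 0.01}))
        est = wald_ratio(
            make_pair(beta_exp=0.1, se_exp=0.02, beta_out=0.05, se_out=0.01),
            second_order=True,
        )
        assert est.se == pytest.approx(expected, rel=1e-12)


class TestIVW:
    def test_identical_ratios_zero_q_random_equals_fixed(self):
        pairs = pairs_from_ratios([0.5, 0.5], [0.1, 0.1])
        fixed = ivw(pairs, model="fixed")
        random = ivw(pairs, model="random")
        assert fixed.beta == pytest.approx(0.5)
        assert fixed.extras["cochran_q"] == pytest.approx(0.0)
        assert random.se == fixed.se

    def test_two_snp_hand_summed_oracle(self):
        # ratios {0.4, 0.6}, both with ratio SE 0.1 -> weights {100, 100}:
        # beta = 0.5, Q = 100*(0.1)^2 + 100*(0.1)^2 = 2 by direct summation
        pairs = pairs_from_ratios([0.4, 0.6], [0.1, 0.1])
        est = ivw(pairs, model="fixed")
        assert est.beta == pytest.approx(0.5)
        assert est.extras["cochran_q"] == pytest.approx(2.0)
        assert est.se == pytest.approx((100 + 100) ** -0.5)

    def test_single_pair_delegates_to_wald(self):
        pair = make_pair()
        assert ivw([pair]).beta == wald_ratio(pair).beta

    def test_recovers_generator_truth_within_three_se(self):
        pairs, cfg = clean_pairs(seed=1)
        est = ivw(pairs)
        assert abs(est.beta - cfg.theta_total) < 3 * est.se


class TestCochranQ:
    def test_identical_ratios(self):
        q, df, p = cochran_q(pairs_from_ratios([0.5, 0.5], [0.1, 0.1]))
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_snp_case_against_chi2_tail(self):
        q, df, p = cochran_q(pairs_from_ratios([0.4, 0.6], [0.1, 0.1]))
        assert (q, df) == (pytest.approx(2.0), 1)
        assert p == pytest.approx(float(stats.chi2.sf(2.0, 1)), rel=1e-12)
        assert p == pytest.approx(0.1573, abs=2e-4)

    def test_power_against_heterogeneity(self):
        # large spread in true ratios: Q should reject in nearly all replicates
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            ratios = 0.5 + rng.normal(0, 0.5, size=10)  # tau large vs se 0.05
            obs = ratios + rng.normal(0, 0.05, size=10)
            _, _, p = cochran_q(pairs_from_ratios(obs, np.full(10, 0.05)))
            rejections += p < 0.05
        assert rejections / n_rep > 0.95


class TestEgger:
    def test_exact_linear_configuration(self):
        gammas = np.array([0.05, 0.1, 0.15, 0.2])
        pairs = [
            make_pair(f"rs{i}", beta_exp=g, se_exp=0.01,
                      beta_out=0.01 + 0.5 * g, se_out=0.01)
            for i, g in enumerate(gammas)
        ]
        slope, intercept, i2 = egger(pairs)
        assert slope.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept.beta == pytest.approx(0.01, abs=1e-10)
        assert slope.extras["residual_scale"] == pytest.approx(1.0)

    def test_equal_gammas_floor_i2_at_zero(self):
        pairs = [
            make_pair(f"rs{i}", beta_exp=0.1, se_exp=0.01,
                      beta_out=0.05 + 0.001 * i, se_out=0.01)
            for i in range(4)
        ]
        _, _, i2 = egger(pairs)
        assert i2 == 0.0

    def test_recovers_directional_pleiotropy_intercept(self):
        cfg = SimulationConfig(
            m_snps=100, seed=7, pleiotropy_mode="directional", gamma_nonnegative=True,
            pleiotropy_mean=0.02, pleiotropy_sd=0.002, pleiotropy_fraction=1.0,
        )
        study = simulate_mediation_gwas(cfg)
        sig = ins.filter_by_pvalue(study.exposure, 5e-8)
        pairs, _ = ins.harmonize(sig, study.outcome)
        _, intercept, _ = egger(ins.filter_weak(pairs))
        assert abs(intercept.beta - 0.02) < 3 * intercept.se

    def test_needs_three_snps(self):
        with pytest.raises(EstimationError):
            egger(pairs_from_ratios([0.4, 0.6]))


class TestWeightedMedian:
    def test_equal_weights_middle_element(self):
        est = weighted_median(pairs_from_ratios([0.1, 0.5, 0.9]), n_boot=50)
        assert est.beta == pytest.approx(0.5)

    def test_unequal_weights_cumulative_walk_oracle(self):
        # weights {0.6, 0.2, 0.2} on ratios {0.5, 5, 5}; centred cumulative
        # weights are {0.3, 0.7, 0.9}; interpolating to 0.5 between the
        # first two ratios gives 0.5 + 4.5 * (0.5-0.3)/(0.7-0.3) = 2.75,
        # below the first crossing ratio of 5
        ses = 1.0 / np.sqrt(np.array([0.6, 0.2, 0.2]))
        est = weighted_median(pairs_from_ratios([0.5, 5.0, 5.0], ses), n_boot=50)
        assert est.beta == pytest.approx(2.75)
        assert est.beta <= 5.0

    def test_breakdown_under_49_percent_invalid_weight(self):
        # 51% of weight on valid ratios at the truth, 49% biased by +1
        rng = np.random.default_rng(17)
        truth = 0.05
        n_valid, n_invalid = 26, 24  # equal weights per SNP
        ratios = np.concatenate([
            truth + rng.normal(0, 0.02, n_valid),
            truth + 1.0 + rng.normal(0, 0.02, n_invalid),
        ])
        est = weighted_median(pairs_from_ratios(ratios, np.full(50, 0.05)), n_boot=300, seed=5)
        assert abs(est.beta - truth) < 3 * est.se

    def test_bootstrap_se_reproducible_under_seed(self):
        pairs = pairs_from_ratios([0.1, 0.4, 0.5, 0.9])
        a = weighted_median(pairs, n_boot=100, seed=9)
        b = weighted_median(pairs, n_boot=100, seed=9)
        assert a.se == b.se


class TestMode:
    def test_majority_cluster_ignores_outlier(self):
        est = mode_estimate(
            pairs_from_ratios([0.5, 0.5, 0.5, 5.0]), weighted=False, n_boot=50
        )
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_all_identical_degenerate_branch(self):
        est = mode_estimate(pairs_from_ratios([0.3, 0.3, 0.3]), n_boot=10)
        assert est.beta == 0.3
        assert est.extras["bandwidth"] == 0.0

    def test_bimodal_weighted_mode_tracks_heavy_cluster(self):
        # 70% of weight at 0.0, 30% at 0.5: the weighted mode must sit on
        # the heavy cluster, within one grid step of 0
        rng = np.random.default_rng(23)
        r0 = rng.normal(0.0, 0.01, 14)
        r1 = rng.normal(0.5, 0.01, 6)
        ratios = np.concatenate([r0, r1])
        est = mode_estimate(pairs_from_ratios(ratios, np.full(20, 0.05)), n_boot=50)
        grid_step = (ratios.max() - ratios.min() + 6 * est.extras["bandwidth"]) / 511
        assert abs(est.beta - 0.0) < max(grid_step, 0.05)


class TestRaps:
    def test_exact_linear_data_zero_tau(self):
        gammas = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
        pairs = [
            make_pair(f"rs{i}", beta_exp=g, se_exp=0.001,
                      beta_out=0.5 * g, se_out=0.01)
            for i, g in enumerate(gammas)
        ]
        est = mr_raps(pairs)
        assert est.beta == pytest.approx(0.5, abs=1e-6)
        assert est.extras["tau2"] == pytest.approx(0.0, abs=1e-10)

    def test_gross_outlier_hurts_raps_less_than_ivw(self):
        rng = np.random.default_rng(11)
        truth = 0.05
        gammas = rng.uniform(0.05, 0.2, 21)
        outs = truth * gammas + rng.normal(0, 0.004, 21)
        outs[-1] += 0.2  # one gross pleiotropic outlier
        pairs = [
            make_pair(f"rs{i}", beta_exp=float(g), se_exp=0.004,
                      beta_out=float(o), se_out=0.004)
            for i, (g, o) in enumerate(zip(gammas, outs))
        ]
        raps_err = abs(mr_raps(pairs).beta - truth)
        ivw_err = abs(ivw(pairs, model="fixed").beta - truth)
        assert raps_err < ivw_err

    def test_tukey_loss_runs(self):
        pairs, _ = clean_pairs(seed=2)
        est = mr_raps(pairs, loss="tukey")
        assert np.isfinite(est.beta) and est.se > 0


class TestCrossMethodProperties:
    def test_sign_equivariance(self):
        pairs, _ = clean_pairs(seed=4)
        flipped = [
            make_pair(p.snp_id, beta_exp=p.beta_exp, se_exp=p.se_exp,
                      beta_out=-p.beta_out, se_out=p.se_out)
            for p in pairs
        ]
        for fn in (lambda q: ivw(q), lambda q: mr_raps(q)):
            a, b = fn(pairs), fn(flipped)
            assert b.beta == pytest.approx(-a.beta, rel=1e-9)
            assert b.se == pytest.approx(a.se, rel=1e-9)
        sa, ia, _ = egger(pairs)
        sb, ib, _ = egger(flipped)
        assert sb.beta == pytest.approx(-sa.beta, rel=1e-9)
        assert ib.beta == pytest.approx(-ia.beta, rel=1e-9)
        assert sb.se == pytest.approx(sa.se, rel=1e-9)
        wa = weighted_median(pairs, n_boot=2, seed=0).beta
        wb = weighted_median(flipped, n_boot=2, seed=0).beta
        assert wb == pytest.approx(-wa, rel=1e-9)

    def test_estimator_consistency_without_pleiotropy(self):
        pairs, cfg = clean_pairs(seed=6)
        ests = [
            ivw(pairs),
            egger(pairs)[0],
            weighted_median(pairs, n_boot=200, seed=1),
            mode_estimate(pairs, weighted=True, n_boot=200, seed=2),
            mr_raps(pairs),
        ]
        for a in ests:
            for b in ests:
                joint = np.hypot(a.se, b.se)
                assert abs(a.beta - b.beta) < 3 * joint
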