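import numpy as np
import pandas as pd
import pytest

from dirdom._kernels import (
    auxiliary_moments,
    dominance_moments,
    lambda_moments,
    loc_moments,
    sample_trunc_nonneg,
)
from dirdom.genotypes import qc_filter
from dirdom.gibbs_sampler import (
    ModelSpec,
    PhenotypeTable,
    PosteriorDraws,
    fit,
    model_spec,
    update_auxiliary,
    update_dominance_effect,
    update_lambda,
    update_location_block,
    update_variance,
)
from dirdom.synthetic_data import SimScenario, simulate


class TestConditionalMoments:
    def test_sample_mean_conditional(self, rng):
        # flat prior, intercept column of 100 ones, residual+offset mean 3
        e = rng.normal(3.0, 1.0, 100) - 0.0
        w = np.ones(100)
        mean, var = loc_moments(100.0, float(w @ e), 1.0, 0.0)
        assert mean == pytest.approx(e.mean())
        assert var == pytest.approx(1 / 100)

    def test_infinite_prior_precision_forces_zero(self):
        mean, var = loc_moments(10.0, 5.0, 1.0, 1e12)
        assert abs(mean) < 1e-9 and var < 1e-11

    def test_ridge_hand_example(self):
        # w = [1,0,1,2], y* = [1,2,3,4], sigma_e2=2, sigma_a2=1:
        # mean = w'y*/(w'w + 2) = 12/8, var = 2/8
        mean, var = loc_moments(6.0, 12.0, 2.0, 1.0)
        assert mean == pytest.approx(1.5)
        assert var == pytest.approx(0.25)

    def test_dominance_conditional_plug_in(self):
        # k'k=1, sigma_e2=1, sigma_d2=1, lam*u=1, k'y*=3 -> N(2, 0.5)
        mean, var = dominance_moments(1.0, 3.0, 1.0, 1.0, 1.0)
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(0.5)

    def test_dominance_reduces_to_ridge_when_symmetric(self):
        m1 = dominance_moments(4.0, 6.0, 2.0, 0.5, 0.0)
        m2 = loc_moments(4.0, 6.0, 2.0, 1 / 0.5)
        assert m1 == pytest.approx(m2)

    @pytest.mark.parametrize(
        "d_j,lam,sig_d2,expected",
        [
            (2.0, 1.0, 1.0, (1.0, 0.5)),
            (0.0, 3.0, 1.0, (0.0, 0.1)),
        ],
    )
    def test_auxiliary_conditional(self, d_j, lam, sig_d2, expected):
        assert auxiliary_moments(d_j, lam, sig_d2) == pytest.approx(expected)

    def test_lambda_conditional_plug_in(self):
        # u=(1,1), d=(2,2), sigma_d2=1 -> N(2, 0.5)
        mean, var = lambda_moments(4.0, 2.0, 1.0)
        assert (mean, var) == pytest.approx((2.0, 0.5))


class TestUpdateOperations:
    def test_location_block_updates_residual(self, rng):
        w = np.array([1.0, 0.0, 1.0, 2.0])
        e = np.array([1.0, 2.0, 3.0, 4.0])
        e0 = e.copy()
        new = update_location_block(w, e, old=0.0, sigma_e2=2.0, prior_prec=1.0, rng=rng)
        np.testing.assert_allclose(e, e0 - w * new)

    def test_flat_prior_empty_column_rejected(self, rng):
        with pytest.raises(ValueError, match="flat-prior"):
            update_location_block(np.zeros(4), np.ones(4), 0.0, 1.0, 0.0, rng)

    def test_dominance_no_data_draws_from_prior(self, rng):
        # all-zero design column: draws are N(lam*u, sigma_d2)
        draws = [
            update_dominance_effect(np.zeros(5), np.zeros(5), 0.0, 1.0, 0.25,
                                    lam=2.0, u_j=1.0, rng=rng)
            for _ in range(4000)
        ]
        assert np.mean(draws) == pytest.approx(2.0, abs=3 * 0.5 / np.sqrt(4000))
        assert np.var(draws) == pytest.approx(0.25, rel=0.15)

    def test_auxiliary_nonnegative_and_half_normal_at_lambda_zero(self, rng):
        draws = np.array([update_auxiliary(1.0, 0.0, 1.0, rng) for _ in range(4000)])
        assert (draws >= 0).all()
        assert draws.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.05)

    def test_lambda_centered_at_zero_for_null_d(self, rng):
        u = np.abs(rng.standard_normal(200))
        draws = [update_lambda(u, np.zeros(200), 1.0, rng) for _ in range(2000)]
        assert np.mean(draws) == pytest.approx(0.0, abs=3 / np.sqrt(2000 * (u @ u)))

    def test_lambda_degenerate_u_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            update_lambda(np.zeros(3), np.ones(3), 1.0, rng)

    def test_lambda_recovery_from_linear_relation(self, rng):
        # d_j = 0.8 u_j + small noise at m=5000: conditional concentrates at 0.8
        u = np.abs(rng.standard_normal(5000))
        d = 0.8 * u + rng.normal(0, 0.05, 5000)
        draws = [update_lambda(u, d, 0.05**2, rng) for _ in range(200)]
        assert np.mean(draws) == pytest.approx(0.8, abs=0.01)

    def test_variance_concentrates_at_mean_square(self, rng):
        draws = [update_variance(2e6, 10**6, (0.0, 1.0), rng) for _ in range(50)]
        assert np.mean(draws) == pytest.approx(2.0, rel=0.01)

    def test_variance_long_run_mean(self, rng):
        # inverse-chi-square mean: (sum_sq + nu S2) / (n + nu - 2)
        draws = [update_variance(30.0, 20, (4.0, 1.0), rng) for _ in range(20000)]
        assert np.mean(draws) == pytest.approx(34.0 / 22.0, rel=0.02)

    def test_variance_prior_only_draw(self, rng):
        draws = np.array([update_variance(0.0, 0, (4.0, 1.0), rng) for _ in range(20000)])
        # 4/chi2_4: median at 4/3.357
        assert np.median(draws) == pytest.approx(4.0 / 3.357, rel=0.05)

    def test_variance_improper_rejected(self, rng):
        with pytest.raises(ValueError, match="improper"):
            update_variance(1.0, 0, (0.0, 1.0), rng)

    def test_kernel_truncated_sampler_deep_tail(self):
        np.random.seed(0)
        draws = np.array([sample_trunc_nonneg(-8.0, 1.0) for _ in range(20000)])
        assert np.isfinite(draws).all() and (draws >= 0).all()
        assert draws.max() < 1.5  # conditional mass hugs the truncation point


class TestFit:
    def test_same_seed_bit_identical(self, small_sim):
        G, _ = qc_filter(small_sim.genotypes)
        spec = model_spec("SC", n_iter=120, burn_in=40, n_chains=2, seed=77)
        d1 = fit(G, small_sim.phenotypes, spec)
        d2 = fit(G, small_sim.phenotypes, spec)
        pd.testing.assert_frame_equal(d1.scalars, d2.scalars)
        np.testing.assert_array_equal(d1.fitted, d2.fitted)

    def test_unknown_animal_rejected(self, small_sim):
        G, _ = qc_filter(small_sim.genotypes)
        P = PhenotypeTable(small_sim.phenotypes.records.assign(animal_id="ghost"))
        with pytest.raises(ValueError, match="without genotypes"):
            fit(G, P, model_spec("SN", n_iter=20, burn_in=10, n_chains=1))

    def test_residual_consistency_at_checkpoints(self, small_sim):
        G, _ = qc_filter(small_sim.genotypes)
        spec = model_spec("Full", n_iter=250, burn_in=50, n_chains=1, seed=3,
                          check_every=100)
        d = fit(G, small_sim.phenotypes, spec)
        assert d.max_resid_err < 1e-8

    def test_additive_truth_recovered_by_sn(self):
        # no dominance, no directional dominance: mu covered, V_D small
        sim = simulate(SimScenario(n_sows=120, n_snp=300, n_groups=40,
                                   lambda_true=0.0, b_true=0.0,
                                   sigma_d2_true=0.0, seed=31))
        G, _ = qc_filter(sim.genotypes)
        d = fit(G, sim.phenotypes, model_spec("SN", n_iter=1200, burn_in=400,
                                              n_chains=1, seed=31))
        mu = d.scalars["mu"]
        lo, hi = np.quantile(mu, [0.025, 0.975])
        assert lo - 4 * mu.std() < 11.7 < hi + 4 * mu.std()
        # the residual variance is well identified by 300+ records
        se2 = d.scalars["sig_e2"]
        lo, hi = np.quantile(se2, [0.025, 0.975])
        assert lo - 4 * se2.std() < 6.57 < hi + 4 * se2.std()
        # with no simulated dominance the dominance share stays the smaller one
        assert d.scalars["V_D"].mean() < d.scalars["V_A"].mean()

    def test_draw_count_contract(self, small_sim):
        G, _ = qc_filter(small_sim.genotypes)
        spec = model_spec("SN", n_iter=100, burn_in=40, thin=3, n_chains=2, seed=1)
        d = fit(G, small_sim.phenotypes, spec)
        assert d.n_draws == 2 * spec.n_keep_per_chain
        assert spec.n_keep_per_chain == 20

    def test_save_load_round_trip(self, small_sim, tmp_path):
        G, _ = qc_filter(small_sim.genotypes)
        d = fit(G, small_sim.phenotypes,
                model_spec("SC", n_iter=80, burn_in=30, n_chains=1, seed=5))
        d.save(tmp_path / "store")
        back = PosteriorDraws.load(tmp_path / "store")
        pd.testing.assert_frame_equal(
            back.scalars, d.scalars, check_exact=False, rtol=1e-12)
        np.testing.assert_allclose(back.fitted, d.fitted)
        assert back.dataset_hash == d.dataset_hash
        assert back.spec.model_name == "SC"


class TestModelSpecContract:
    def test_four_named_models(self):
        assert model_spec("SN").model_name == "SN"
        assert model_spec("SC").include_b and not model_spec("SC").include_lambda
        assert model_spec("AN").include_lambda and not model_spec("AN").include_b
        assert model_spec("Full").include_b and model_spec("Full").include_lambda

    def test_invalid_chain_settings_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(n_iter=100, burn_in=100)
        with pytest.raises(ValueError, match="unknown model"):
            model_spec("XX")
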