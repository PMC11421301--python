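import numpy as np
import pytest
from scipy.stats import multivariate_normal

from dcsm import (
    AgeGrid,
    DCSMParams,
    DCSMSpec,
    build_latent_loadings,
    fiml_loglik,
    implied_moments,
)
from dcsm.data_model import PairDataset, PersonTrajectory
from dcsm.dcsm_core import bind_data, loglik_and_grad, loglik_bound
from dcsm.estimation import ParamTransform

from _helpers import dataset_from_vectors


class TestLoadings:
    def test_linear_growth_when_dynamics_off(self):
        """With beta = gamma = 0 the recursion is a plain linear growth
        curve: bin t loads t on the slope and 1 on the intercept."""
        spec = DCSMSpec(traits=("fi",), proportional=(False,), grid=AgeGrid())
        params = DCSMParams.zeros(spec)
        L = build_latent_loadings(spec, params)
        n = spec.grid.n_bins
        assert np.allclose(L[0, :, 0], 1.0)
        assert np.allclose(L[0, :, 1], np.arange(n))

    def test_proportional_recursion_matches_stepwise_oracle(self):
        """Latent mean under self-feedback equals the explicit iteration
        f <- (1+beta) f + slope from the age-50 intercept."""
        spec = DCSMSpec(traits=("fi",), proportional=(True,), grid=AgeGrid())
        params = DCSMParams.zeros(spec)
        params.mu_intercept[:] = 6.01
        params.mu_slope[:] = -0.69
        params.beta[:] = 0.15
        L = build_latent_loadings(spec, params)
        mean = L[0] @ params.factor_mean(0)
        f = 6.01
        expected = [f]
        for _ in range(spec.grid.n_bins - 1):
            f = 1.15 * f - 0.69
            expected.append(f)
        assert np.allclose(mean, expected, atol=1e-10)
        assert mean[5] == pytest.approx(7.436013634375, abs=1e-9)

    def test_coupling_propagates_monotonically(self, toy_bivariate):
        """Raising the clock intercept raises the FI mean at every later
        bin when the clock-to-FI coupling is positive."""
        spec, params = toy_bivariate
        base = build_latent_loadings(spec, params)[0] @ params.factor_mean(0)
        shifted = params.copy()
        shifted.mu_intercept[1] += 1.0
        up = build_latent_loadings(spec, shifted)[0] @ shifted.factor_mean(0)
        assert np.all(up[1:] > base[1:])
        assert up[0] == base[0]  # bin 0 loads only on the FI intercept


class TestImpliedMoments:
    def test_no_pair_variance_means_no_cross_twin_covariance(self, toy_bivariate):
        spec, params = toy_bivariate
        p = params.copy()
        p.sigma_pair = np.zeros((4, 4))
        mom = implied_moments(spec, p)
        m = mom.layout.per_twin
        assert np.allclose(mom.covariance[:m, m:], 0.0)

    def test_residual_only_covariance_is_block_diagonal(self, toy_bivariate):
        spec, params = toy_bivariate
        p = params.copy()
        p.sigma_ind = np.zeros((4, 4))
        p.sigma_pair = np.zeros((4, 4))
        mom = implied_moments(spec, p)
        n = spec.grid.n_bins
        m = mom.layout.per_twin
        cov = mom.covariance
        assert np.allclose(cov[:m, m:], 0.0)
        for t in range(n):
            i_fi = mom.layout.index(0, 0, t)
            i_ck = mom.layout.index(0, 1, t)
            assert cov[i_fi, i_fi] == pytest.approx(p.resid_var[0])
            assert cov[i_ck, i_ck] == pytest.approx(p.resid_var[1])
            assert cov[i_fi, i_ck] == pytest.approx(p.resid_cov)
            for s in range(n):
                if s != t:
                    assert cov[i_fi, mom.layout.index(0, 0, s)] == 0.0

    def test_pure_pair_variance_gives_perfect_twin_correlation(self, toy_bivariate):
        """With no individual-level variance, co-twins share their whole
        latent trajectory (family factor only)."""
        spec, params = toy_bivariate
        p = params.copy()
        p.sigma_ind = np.zeros((4, 4))
        p.resid_var[:] = 1e-8
        p.resid_cov = 0.0
        mom = implied_moments(spec, p)
        m = mom.layout.per_twin
        latent_within = mom.covariance[:m, :m] - 1e-8 * np.eye(m)
        assert np.allclose(mom.covariance[:m, m:], latent_within, atol=1e-7)

    def test_covariance_symmetric_psd(self, toy_bivariate):
        spec, params = toy_bivariate
        mom = implied_moments(spec, params, sexes=(1, 0))
        assert np.allclose(mom.covariance, mom.covariance.T)
        assert np.linalg.eigvalsh(mom.covariance).min() > -1e-8

    def test_twin_relabeling_permutes_moments(self, toy_bivariate):
        spec, params = toy_bivariate
        mom01 = implied_moments(spec, params, sexes=(0, 1))
        mom10 = implied_moments(spec, params, sexes=(1, 0))
        m = mom01.layout.per_twin
        perm = np.concatenate([np.arange(m, 2 * m), np.arange(m)])
        assert np.allclose(mom10.mean, mom01.mean[perm])
        assert np.allclose(mom10.covariance, mom01.covariance[np.ix_(perm, perm)])

    def test_non_psd_input_rejected(self, toy_bivariate):
        spec, params = toy_bivariate
        bad = params.copy()
        bad.sigma_ind = np.array([
            [1.0, 2.0, 0, 0], [2.0, 1.0, 0, 0], [0, 0, 1.0, 0], [0, 0, 0, 1.0]
        ])
        with pytest.raises(ValueError, match="positive semi-definite"):
            implied_moments(spec, bad)


class TestFimlLoglik:
    def test_complete_data_equals_dense_mvn_density(self, toy_bivariate):
        """On complete data FIML reduces to the ordinary multivariate
        normal log-density with the full implied moments."""
        spec, params = toy_bivariate
        rng = np.random.default_rng(11)
        sexes = [(0, 0), (0, 1), (1, 1)]
        moms = {s: implied_moments(spec, params, sexes=s) for s in set(sexes)}
        Y = np.stack([
            rng.multivariate_normal(moms[s].mean, moms[s].covariance) for s in sexes
        ])
        ds = dataset_from_vectors(spec, Y, sexes)
        expected = sum(
            multivariate_normal(moms[s].mean, moms[s].covariance).logpdf(y)
            for s, y in zip(sexes, Y)
        )
        assert fiml_loglik(spec, params, ds) == pytest.approx(expected, abs=1e-8)

    def test_missing_pattern_equals_marginal_density(self, toy_bivariate):
        """A pair's contribution is the marginal normal density of just
        its observed entries."""
        spec, params = toy_bivariate
        rng = np.random.default_rng(5)
        mom = implied_moments(spec, params, sexes=(1, 0))
        y = rng.multivariate_normal(mom.mean, mom.covariance)
        keep = sorted(rng.choice(len(y), size=7, replace=False))
        ds = dataset_from_vectors(spec, y[None, :], [(1, 0)], observed=[keep])
        sub = np.ix_(keep, keep)
        expected = multivariate_normal(mom.mean[keep], mom.covariance[sub]).logpdf(y[keep])
        assert fiml_loglik(spec, params, ds) == pytest.approx(float(expected), abs=1e-8)

    def test_all_missing_person_contributes_nothing(self, toy_bivariate):
        spec, params = toy_bivariate
        rng = np.random.default_rng(3)
        mom = implied_moments(spec, params, sexes=(0, 0))
        y = rng.multivariate_normal(mom.mean, mom.covariance)
        ds = dataset_from_vectors(spec, y[None, :], [(0, 0)])
        ll = fiml_loglik(spec, params, ds)
        ghost = PersonTrajectory(person_id="ghost", pair_id="gp", sex=0)
        ghost2 = PersonTrajectory(person_id="ghost2", pair_id="gp", sex=1)
        ds.pairs.append((ghost, ghost2))
        assert fiml_loglik(spec, params, ds) == ll

    def test_invariance_to_pair_order_and_twin_labels(self, toy_bivariate):
        spec, params = toy_bivariate
        rng = np.random.default_rng(17)
        mom = implied_moments(spec, params, sexes=(0, 1))
        Y = rng.multivariate_normal(mom.mean, mom.covariance, size=4)
        ds = dataset_from_vectors(spec, Y, [(0, 1)] * 4)
        ll = fiml_loglik(spec, params, ds)
        # permute pairs
        ds_perm = PairDataset(grid=ds.grid, pairs=ds.pairs[::-1],
                              trait_labels=ds.trait_labels)
        assert fiml_loglik(spec, params, ds_perm) == pytest.approx(ll, abs=1e-10)
        # swap twin A/B within each pair
        ds_swap = PairDataset(grid=ds.grid, pairs=[(b, a) for a, b in ds.pairs],
                              trait_labels=ds.trait_labels)
        assert fiml_loglik(spec, params, ds_swap) == pytest.approx(ll, abs=1e-8)

    def test_zero_dynamics_matches_independent_growth_curve_likelihood(self):
        """With beta = gamma = 0 the model is a latent linear growth
        curve; compare against a separately coded growth-curve likelihood
        (explicit [1, t] design, no recursion)."""
        grid = AgeGrid(n_bins=4)
        spec = DCSMSpec(traits=("fi",), proportional=(False,), pair_level="full",
                        grid=grid, sex_effects=False)
        params = DCSMParams.zeros(spec)
        params.mu_intercept[:] = 5.0
        params.mu_slope[:] = 0.8
        params.sigma_ind = np.array([[2.0, 0.3], [0.3, 0.5]])
        params.sigma_pair = np.array([[1.0, -0.1], [-0.1, 0.2]])
        params.resid_var[:] = 1.5

        n = grid.n_bins
        Z = np.column_stack([np.ones(n), np.arange(n)])  # growth-curve design
        mean_1 = Z @ np.array([5.0, 0.8])
        within = Z @ (params.sigma_ind + params.sigma_pair) @ Z.T + 1.5 * np.eye(n)
        across = Z @ params.sigma_pair @ Z.T
        mean = np.concatenate([mean_1, mean_1])
        cov = np.block([[within, across], [across, within]])

        rng = np.random.default_rng(2)
        Y = rng.multivariate_normal(mean, cov, size=5)
        ds = dataset_from_vectors(spec, Y, [(0, 0)] * 5)
        expected = sum(multivariate_normal(mean, cov).logpdf(y) for y in Y)
        assert fiml_loglik(spec, params, ds) == pytest.approx(expected, abs=1e-8)


class TestAnalyticGradient:
    def test_matches_finite_differences(self, toy_bivariate):
        spec, params = toy_bivariate
        rng = np.random.default_rng(23)
        mom = implied_moments(spec, params, sexes=(0, 1))
        Y = rng.multivariate_normal(mom.mean, mom.covariance, size=6)
        observed = [sorted(rng.choice(mom.layout.size, size=8, replace=False))
                    for _ in range(6)]
        ds = dataset_from_vectors(spec, Y, [(0, 1)] * 6, observed=observed)
        bound = bind_data(spec, ds)
        tr = ParamTransform(spec)
        x = tr.pack(params) + rng.normal(scale=0.03, size=tr.n_working)
        _, grads = loglik_and_grad(tr.unpack(x), bound)
        g = tr.grad_to_working(x, grads)
        for i in range(len(x)):
            h = 1e-6 * (1 + abs(x[i]))
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (loglik_bound(tr.unpack(xp), bound)
                  - loglik_bound(tr.unpack(xm), bound)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)
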