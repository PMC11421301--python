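import numpy as np
import pandas as pd
import pytest

from dcsm import (
    AgeGrid,
    DCSMParams,
    DCSMSpec,
    StudyDesign,
    baseline_correlations,
    simulate_dataset,
    trajectory_curve,
    vector_field,
)
from dcsm.data_model import BinObservation, PairDataset, PersonTrajectory
from dcsm.estimation import FitResult, ParamTransform
from dcsm.reporting import plot_trajectory, plot_vector_field


def fake_fit(spec, params, converged=True):
    """A FitResult wrapper without running the optimizer (reporting only
    reads spec/estimates/converged)."""
    tr = ParamTransform(spec)
    return FitResult(
        spec=spec, estimates=params, loglik=0.0, n_free=tr.n_free,
        converged=converged, n_evaluations=0, names=tr.natural_names(),
        natural_estimates=tr.natural_vector(params),
    )


def fi_params(spec, beta=0.15):
    params = DCSMParams.zeros(spec)
    params.mu_intercept[:] = 6.01
    params.mu_slope[:] = -0.69
    params.beta[:] = beta
    params.resid_var[:] = 1.0
    return params


@pytest.fixture
def univariate_spec():
    return DCSMSpec(traits=("fi",), proportional=(True,), coupling=(),
                    pair_level="full", residual_cross_trait=False, grid=AgeGrid())


class TestTrajectoryCurve:
    def test_linear_when_proportional_zero(self, univariate_spec):
        fit = fake_fit(univariate_spec, fi_params(univariate_spec, beta=0.0))
        curve = trajectory_curve(fit)
        d = np.diff(curve["value"])
        assert np.allclose(d, -0.69)

    def test_proportional_curve_is_convex_and_matches_oracle(self, univariate_spec):
        """FI-like self-feedback produces increments that grow with age;
        the age-60 value agrees with the explicit stepwise iteration."""
        fit = fake_fit(univariate_spec, fi_params(univariate_spec))
        curve = trajectory_curve(fit)
        vals = curve["value"].to_numpy()
        incr = np.diff(vals)
        assert np.all(np.diff(incr) > 0)  # accelerating growth
        f = 6.01
        for _ in range(5):
            f = 1.15 * f - 0.69
        age60 = curve.loc[curve["age"] == 60.0, "value"].item()
        assert age60 == pytest.approx(f, abs=1e-10)

    def test_sex_effect_propagates_through_dynamics(self, univariate_spec):
        params = fi_params(univariate_spec)
        params.sex_intercept[:] = 2.39
        fit = fake_fit(univariate_spec, params)
        men = trajectory_curve(fit, sex_mix=0.0)["value"].to_numpy()
        women = trajectory_curve(fit, sex_mix=1.0)["value"].to_numpy()
        shift = women - men
        assert shift[0] == pytest.approx(2.39)
        # the intercept shift compounds through the proportional term
        assert np.all(np.diff(shift) > 0)
        assert shift[5] == pytest.approx(2.39 * 1.15 ** 5, abs=1e-8)

    def test_unconverged_fit_rejected(self, univariate_spec):
        fit = fake_fit(univariate_spec, fi_params(univariate_spec), converged=False)
        with pytest.raises(ValueError, match="converged"):
            trajectory_curve(fit)


def bivariate_fit(gamma_c2f=1.19, gamma_f2c=0.0, mu_slope=(-12.31, 0.06),
                  beta=(0.06, 0.0)):
    spec = DCSMSpec(traits=("fi", "clock"), proportional=(True, False),
                    coupling=((1, 0), (0, 1)), pair_level="full",
                    residual_cross_trait=True, grid=AgeGrid())
    params = DCSMParams.zeros(spec)
    params.mu_intercept[:] = [6.55, 10.04]
    params.mu_slope[:] = mu_slope
    params.beta[:] = beta
    params.gamma[0, 1] = gamma_c2f
    params.gamma[1, 0] = gamma_f2c
    params.resid_var[:] = [14.5, 1.0]
    return fake_fit(spec, params)


class TestVectorField:
    def test_zero_dynamics_give_zero_arrows(self):
        fit = bivariate_fit(gamma_c2f=0.0, gamma_f2c=0.0, mu_slope=(0.0, 0.0),
                            beta=(0.0, 0.0))
        vf = vector_field(fit, clock_scale=10.0)
        assert np.allclose(vf.points["d_fi"], 0.0)
        assert np.allclose(vf.points["d_clock"], 0.0)

    def test_fi_change_increases_with_clock_under_positive_coupling(self):
        vf = vector_field(bivariate_fit(), clock_scale=10.0)
        pts = vf.points
        for fi_val, g in pts.groupby("fi"):
            g = g.sort_values("clock")
            assert np.all(np.diff(g["d_fi"]) > 0)

    def test_no_reverse_coupling_means_constant_clock_change_in_fi(self):
        """Without FI-to-clock coupling the horizontal arrow component
        does not vary along vertical (constant-clock) lines."""
        vf = vector_field(bivariate_fit(gamma_f2c=0.0), clock_scale=10.0)
        for c_val, g in vf.points.groupby("clock"):
            assert np.ptp(g["d_clock"]) == pytest.approx(0.0, abs=1e-12)

    def test_arrows_match_change_equation_exactly(self):
        fit = bivariate_fit()
        vf = vector_field(fit, clock_scale=10.0)
        p = fit.estimates
        row = vf.points.iloc[37]
        expected_dfi = p.mu_slope[0] + p.beta[0] * row.fi + p.gamma[0, 1] * 10 * row.clock
        assert row.d_fi == pytest.approx(expected_dfi, abs=1e-12)

    def test_univariate_fit_rejected(self, univariate_spec):
        fit = fake_fit(univariate_spec, fi_params(univariate_spec))
        with pytest.raises(ValueError, match="bivariate"):
            vector_field(fit)

    def test_ellipse_covers_95_percent_of_matching_normal_sample(self):
        """The 95% ellipse from baseline points contains about 95% of a
        large bivariate normal sample with the same moments."""
        rng = np.random.default_rng(77)
        mean = np.array([1.05, 9.8])
        cov = np.array([[0.0225, 0.05], [0.05, 67.0]])
        xy = rng.multivariate_normal(mean, cov, size=400)
        pairs = []
        for i, (c, f) in enumerate(xy):
            traj = PersonTrajectory(person_id=f"p{i}", pair_id=f"s{i}", sex=0)
            traj.observations[5] = BinObservation(age=60.0, values={"fi": f, "clock": c})
            ghost = PersonTrajectory(person_id=f"g{i}", pair_id=f"s{i}", sex=0)
            pairs.append((traj, ghost))
        data = PairDataset(grid=AgeGrid(), pairs=pairs, trait_labels=("fi", "clock"))
        vf = vector_field(bivariate_fit(), data=data, clock_scale=1.0)
        assert vf.ellipse is not None
        big = rng.multivariate_normal(mean, cov, size=20_000)
        frac = vf.ellipse.contains(big[:, [0, 1]]).mean()
        assert frac == pytest.approx(0.95, abs=0.02)


class TestBaselineCorrelations:
    @staticmethod
    def make_data(values):
        """values: list of (age, fi, clock) triples, one person each."""
        pairs = []
        for i, (age, fi, clock) in enumerate(values):
            traj = PersonTrajectory(person_id=f"p{i}", pair_id=f"s{i}", sex=0)
            t = AgeGrid().assign(age)
            vals = {}
            if fi is not None:
                vals["fi"] = fi
            if clock is not None:
                vals["clock"] = clock
            traj.observations[t] = BinObservation(age=age, values=vals)
            ghost = PersonTrajectory(person_id=f"g{i}", pair_id=f"s{i}", sex=0)
            pairs.append((traj, ghost))
        return PairDataset(grid=AgeGrid(), pairs=pairs, trait_labels=("fi", "clock"))

    def test_identical_traits_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        vals = [(a, v, v) for a, v in zip(rng.uniform(50, 88, 30), rng.normal(10, 3, 30))]
        out = baseline_correlations(self.make_data(vals))
        assert out["r"] == pytest.approx(1.0)
        assert out["n"] == 30

    def test_age_driven_correlation_vanishes_after_adjustment(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(50, 88, 200)
        vals = [(a, 0.5 * a + rng.normal(), 0.2 * a + rng.normal()) for a in ages]
        out = baseline_correlations(self.make_data(vals))
        assert out["r"] > 0.5  # shared age trend induces correlation
        assert abs(out["r_age_adjusted"]) < 0.2

    def test_incomplete_baselines_are_dropped(self):
        vals = [(60.0, 5.0, 1.0), (62.0, 6.0, None), (64.0, 7.0, 1.2),
                (66.0, 8.0, 1.3)]
        out = baseline_correlations(self.make_data(vals))
        assert out["n"] == 3

    def test_too_few_cases_is_an_error(self):
        vals = [(60.0, 5.0, 1.0), (62.0, 6.0, 1.1)]
        with pytest.raises(ValueError, match="complete baseline"):
            baseline_correlations(self.make_data(vals))

    def test_synthetic_factor_structure_matches_analytic_correlation(self):
        """Simulated baseline correlation agrees with the value implied
        by the generating covariance structure at the baseline bin."""
        from dcsm import implied_moments

        spec = DCSMSpec(traits=("fi", "clock"), proportional=(False, False),
                        coupling=(), pair_level="none", sex_effects=False,
                        residual_cross_trait=True, grid=AgeGrid(n_bins=2))
        params = DCSMParams.zeros(spec)
        params.mu_intercept[:] = [10.0, 60.0]
        params.mu_slope[:] = [0.5, 1.0]
        params.sigma_ind = np.array([
            [20.0, 0.0, 6.0, 0.0],
            [0.0, 0.1, 0.0, 0.0],
            [6.0, 0.0, 9.0, 0.0],
            [0.0, 0.0, 0.0, 0.05],
        ])
        params.resid_var[:] = [2.0, 1.0]
        params.resid_cov = 0.2
        design = StudyDesign(n_individuals=4000, pair_fraction=0.0,
                             entry_age_range=(50.0, 51.9),
                             wave_count_distribution=(1.0, 0, 0, 0, 0, 0))
        data = simulate_dataset(spec, params, design, seed=19)
        out = baseline_correlations(data)
        mom = implied_moments(spec, params)
        i_fi = mom.layout.index(0, 0, 0)
        i_ck = mom.layout.index(0, 1, 0)
        r_true = mom.covariance[i_fi, i_ck] / np.sqrt(
            mom.covariance[i_fi, i_fi] * mom.covariance[i_ck, i_ck])
        assert out["r"] == pytest.approx(r_true, abs=3.0 / np.sqrt(out["n"]))


class TestPlots:
    def test_plot_helpers_return_axes(self, univariate_spec, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        fit = fake_fit(univariate_spec, fi_params(univariate_spec))
        ax = plot_trajectory(trajectory_curve(fit))
        assert ax.get_xlabel() == "age (years)"
        vf = vector_field(bivariate_fit(), clock_scale=10.0)
        ax2 = plot_vector_field(vf)
        fig = ax2.get_figure()
        out = tmp_path / "vf.png"
        fig.savefig(out)
        assert out.stat().st_size > 0
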