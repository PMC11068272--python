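"""The nine trajectory priors: default constants, component densities
against scipy closed forms, ancestral samplers, and the trans-dimensional
models' induced distributions."""

import math

import numpy as np
import pytest
from scipy import stats

import coalsky as ck
from coalsky.priors import (
    PriorSpec,
    _lpdf_exponential,
    _lpdf_gamma,
    _lpdf_halfcauchy,
    _lpdf_lognormal,
    _lpdf_loguniform,
    _lpdf_uniform,
    _lpmf_poisson,
    default_hyperparams,
    lognormal_spread_constant,
    make_prior_model,
    skyfish_trajectory_from_state,
)


class TestDefaults:
    def test_gmrf_smoothing_constant_for_50_intervals(self):
        assert default_hyperparams("gmrf", 50)["zeta"] == 0.0195

    def test_hsmrf_smoothing_constant_for_50_intervals(self):
        assert default_hyperparams("hsmrf", 50)["zeta"] == 0.0051

    def test_skyfish_lognormal_half_sd(self):
        assert default_hyperparams("skyfish")["H"] == 0.587405

    def test_skyfish_sigma_rate_scales_with_horizon(self):
        h = default_hyperparams("skyfish", t_max=8e5)
        assert h["sigma_rate"] == 1e5
        assert h["rho1_median"] == 2e5

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            default_hyperparams("skypilot")

    def test_spread_constant_solves_the_95pc_two_orders_condition(self):
        h = lognormal_spread_constant()
        sd = 2 * h
        # the central 95% interval of the lognormal spans a factor of 100
        hi = math.exp(stats.norm.ppf(0.975) * sd)
        lo = math.exp(stats.norm.ppf(0.025) * sd)
        assert hi / lo == pytest.approx(100.0, rel=1e-9)


class TestComponentDensities:
    """Hand-coded log-densities vs scipy's, over a grid of arguments."""

    xs = np.array([0.013, 0.7, 1.0, 4.2, 950.0, 8.1e6])

    def test_uniform(self):
        assert _lpdf_uniform(self.xs, 0.0, 1e8) == pytest.approx(
            stats.uniform.logpdf(self.xs, 0, 1e8).sum()
        )
        assert _lpdf_uniform(np.array([2e8]), 0, 1e8) == -np.inf

    def test_loguniform(self):
        assert _lpdf_loguniform(self.xs, 1e-2, 1e8) == pytest.approx(
            stats.loguniform.logpdf(self.xs, 1e-2, 1e8).sum()
        )

    def test_exponential(self):
        assert _lpdf_exponential(self.xs, 0.25) == pytest.approx(
            stats.expon.logpdf(self.xs, scale=4.0).sum()
        )

    def test_gamma(self):
        assert _lpdf_gamma(3.3, 0.001, 0.001) == pytest.approx(
            stats.gamma.logpdf(3.3, 0.001, scale=1000.0)
        )

    def test_halfcauchy(self):
        assert _lpdf_halfcauchy(self.xs, 1.0) == pytest.approx(
            stats.halfcauchy.logpdf(self.xs).sum()
        )

    def test_lognormal(self):
        assert _lpdf_lognormal(self.xs, 1.7, 0.6) == pytest.approx(
            stats.lognorm.logpdf(self.xs, s=0.6, scale=math.exp(1.7)).sum()
        )

    def test_poisson(self):
        for k in (0, 3, 10, 25):
            assert _lpmf_poisson(k, 10.0) == pytest.approx(stats.poisson.logpmf(k, 10.0))


class TestLogPrior:
    def test_constant_uniform_density(self):
        lp = ck.log_prior(PriorSpec("constant"), {"rho": np.array([5e7])})
        assert lp == pytest.approx(-math.log(1e8))

    def test_bsp_first_interval_is_loguniform(self):
        pm = make_prior_model(PriorSpec("bsp"), 1, None)
        lp = pm.log_prior({"rho": np.array([100.0])})
        assert lp == pytest.approx(-math.log(100) - math.log(math.log(1e10)))

    def test_bsp_autocorrelated_exponential_step(self):
        pm = make_prior_model(PriorSpec("bsp"), 2, None)
        lp2 = pm.log_prior({"rho": np.array([100.0, 100.0])})
        lp1 = pm.log_prior({"rho": np.array([100.0])})
        # conditional density of ρ2 = 100 given ρ1 = 100: Exp(rate 1/100)
        assert lp2 - lp1 == pytest.approx(-math.log(100) - 1.0)

    def test_outside_support_is_minus_inf(self):
        assert ck.log_prior(PriorSpec("constant"), {"rho": np.array([2e8])}) == -np.inf
        pm = make_prior_model(PriorSpec("skyfish"), 1, t_max=100.0)
        bad = {"kappa": 1, "xi": np.array([150.0]), "sigma": 1.0, "rho": np.ones(2)}
        assert pm.log_prior(bad) == -np.inf

    def test_skyride_and_skygrid_share_the_same_density(self):
        state = {"rho": np.array([50.0, 80.0, 60.0]), "tau": 2.5}
        a = ck.log_prior(PriorSpec("skyride"), state)
        b = ck.log_prior(PriorSpec("skygrid"), state)
        assert a == b

    def test_markov_lognormal_increment_uses_precision(self):
        pm = make_prior_model(PriorSpec("skyride"), 2, None)
        tau = 4.0
        s2 = {"rho": np.array([100.0, 130.0]), "tau": tau}
        s1 = {"rho": np.array([100.0]), "tau": tau}
        diff = pm.log_prior(s2) - make_prior_model(PriorSpec("skyride"), 1, None).log_prior(s1)
        expected = stats.lognorm.logpdf(130.0, s=tau**-0.5, scale=100.0)
        assert diff == pytest.approx(expected)

    def test_gmrf_increment_sd_is_gamma_times_zeta(self):
        pm = make_prior_model(PriorSpec("gmrf"), 2, None)
        gamma = 2.0
        zeta = 0.0195
        s = {"rho": np.array([100.0, 101.0]), "gamma": gamma}
        base = {"rho": np.array([100.0]), "gamma": gamma}
        diff = pm.log_prior(s) - make_prior_model(PriorSpec("gmrf"), 1, None).log_prior(base)
        expected = stats.lognorm.logpdf(101.0, s=gamma * zeta, scale=100.0)
        assert diff == pytest.approx(expected)

    def test_hsmrf_local_scales(self):
        pm = make_prior_model(PriorSpec("hsmrf"), 3, None)
        s = {
            "rho": np.array([100.0, 90.0, 95.0]),
            "gamma": 1.5,
            "sigma": np.array([0.7, 2.0]),
        }
        lp = pm.log_prior(s)
        sds = s["sigma"] * 1.5 * 0.0051
        expected = (
            stats.halfcauchy.logpdf(1.5)
            + stats.halfcauchy.logpdf(s["sigma"]).sum()
            + stats.uniform.logpdf(100.0, 0, 1e8)
            + stats.lognorm.logpdf(90.0, s=sds[0], scale=100.0)
            + stats.lognorm.logpdf(95.0, s=sds[1], scale=90.0)
        )
        assert lp == pytest.approx(expected)

    def test_skyfish_joint_density_closed_form(self):
        t_max = 1000.0
        pm = make_prior_model(PriorSpec("skyfish"), 1, t_max=t_max)
        state = {
            "kappa": 2,
            "xi": np.array([100.0, 400.0]),
            "sigma": 0.004,
            "rho": np.array([200.0, 300.0, 250.0]),
        }
        lp = pm.log_prior(state)
        H = 0.587405
        expected = (
            stats.poisson.logpmf(2, 10.0)
            + stats.expon.logpdf(0.004, scale=8.0 / t_max)
            + math.lgamma(3) - 2 * math.log(t_max)
            + stats.lognorm.logpdf(200.0, s=2 * H, scale=t_max / 4)
            + stats.lognorm.logpdf(300.0, s=0.004 * 100.0, scale=200.0)
            + stats.lognorm.logpdf(250.0, s=0.004 * 300.0, scale=300.0)
        )
        assert lp == pytest.approx(expected)


class TestSamplePrior:
    def test_constant_mean(self, rng):
        draws = np.array(
            [ck.sample_prior(PriorSpec("constant"), rng)["rho"][0] for _ in range(20_000)]
        )
        se = 1e8 / math.sqrt(12) / math.sqrt(len(draws))
        assert abs(draws.mean() - 5e7) < 3 * se

    def test_skyfish_changepoint_count_poisson_mean(self, rng):
        pm = make_prior_model(PriorSpec("skyfish"), 1, t_max=1e6)
        ks = np.array([pm.sample_prior(rng)["kappa"] for _ in range(20_000)])
        se = math.sqrt(10.0 / len(ks))
        assert abs(ks.mean() - 10.0) < 3 * se

    def test_gmrf_log_increments_are_centered(self, rng):
        pm = make_prior_model(PriorSpec("gmrf"), 5, None)
        incs = []
        for _ in range(4000):
            rho = pm.sample_prior(rng)["rho"]
            incs.extend(np.diff(np.log(rho)))
        # symmetric normal increments: median exactly 0
        assert abs(np.median(incs)) < 0.01

    @pytest.mark.parametrize("model", ["bsp", "skyride", "gmrf", "hsmrf"])
    def test_sampler_matches_independent_scipy_chain(self, model, rng):
        """Two-sample KS between our ancestral sampler and an independently
        coded scipy generative chain for the final interval's size."""
        L = 3
        pm = make_prior_model(PriorSpec(model), L, None)
        mine = np.array([pm.sample_prior(rng)["rho"][-1] for _ in range(4000)])
        oracle_rng = np.random.default_rng(987)
        oracle = np.empty(4000)
        for i in range(4000):
            if model == "bsp":
                r = stats.loguniform.rvs(1e-2, 1e8, random_state=oracle_rng)
                for _ in range(L - 1):
                    r = stats.expon.rvs(scale=r, random_state=oracle_rng)
            elif model == "skyride":
                tau = max(stats.gamma.rvs(0.001, scale=1000.0, random_state=oracle_rng), 1e-290)
                r = stats.loguniform.rvs(1e-2, 1e8, random_state=oracle_rng)
                for _ in range(L - 1):
                    lr = np.clip(
                        math.log(r) + stats.norm.rvs(0, tau**-0.5, random_state=oracle_rng),
                        -700, 700,
                    )
                    r = math.exp(lr)
            else:
                zeta = 0.0195 if model == "gmrf" else 0.0051
                gamma = abs(stats.cauchy.rvs(random_state=oracle_rng))
                r = stats.uniform.rvs(0, 1e8, random_state=oracle_rng)
                for _ in range(L - 1):
                    sd = gamma * zeta
                    if model == "hsmrf":
                        sd *= abs(stats.cauchy.rvs(random_state=oracle_rng))
                    lr = np.clip(
                        math.log(r) + stats.norm.rvs(0, max(sd, 1e-300), random_state=oracle_rng),
                        -700, 700,
                    )
                    r = math.exp(lr)
            oracle[i] = r
        assert stats.ks_2samp(mine, oracle).pvalue > 1e-3

    def test_ebsp_interval_count_is_binomial(self, rng):
        """Active change-points over prior draws follow Binomial(k, 1−α_eq)."""
        L = 9  # eight candidate change-points
        pm = make_prior_model(PriorSpec("ebsp", {"alpha_eq": 0.3}), L, None)
        counts = np.array(
            [pm.sample_prior(rng)["active"].sum() for _ in range(20_000)]
        )
        k, p = L - 1, 0.7
        se = math.sqrt(k * p * (1 - p) / len(counts))
        assert abs(counts.mean() - k * p) < 3 * se

    def test_ebsp_effective_sizes_copy_forward(self):
        pm = make_prior_model(PriorSpec("ebsp"), 4, None)
        state = {
            "mean": 10.0,
            "active": np.array([False, True, False]),
            "values": np.array([5.0, 99.0, 7.0, 99.0]),
        }
        np.testing.assert_array_equal(pm.rho_vector(state), [5.0, 5.0, 7.0, 7.0])


class TestSkyfishTrajectory:
    def test_zero_changepoints_gives_constant_trajectory(self):
        traj = skyfish_trajectory_from_state(
            {"xi": np.array([]), "rho": np.array([42.0])}, t_max=1e3
        )
        assert traj.n_intervals == 1
        assert traj.ne_at(500.0) == 42.0

    def test_two_changepoints(self):
        traj = skyfish_trajectory_from_state(
            {"xi": np.array([100.0, 200.0]), "rho": np.array([1.0, 2.0, 3.0])},
            t_max=1e3,
        )
        np.testing.assert_array_equal(traj.change_points, [0.0, 100.0, 200.0])
        assert traj.ne_at(150.0) == 2.0
        assert traj.ne_at(5000.0) == 3.0

    def test_out_of_range_changepoints_rejected(self):
        with pytest.raises(ValueError):
            skyfish_trajectory_from_state(
                {"xi": np.array([2e3]), "rho": np.array([1.0, 2.0])}, t_max=1e3
            )
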