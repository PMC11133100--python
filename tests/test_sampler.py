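"""Blocked random-walk Metropolis engine: starting values, tuning,
posterior correctness at small scale, chunked runs and restarts."""

import numpy as np
import pytest
from scipy import stats

from hbirt.data import ResponseMatrix
from hbirt.diagnostics import ConvergenceConfig
from hbirt.model import ModelSpec, PriorConfig
from hbirt.sampler import (
    SamplerConfig,
    _Sampler,
    initialize_state,
    run_chunked,
    tune_proposals,
    two_stage_start,
)
from hbirt.simulation import generate_replicate


class TestInitializeState:
    def test_defaults(self):
        spec = ModelSpec(item_names=["y1", "y2"])
        state = initialize_state(spec, PriorConfig(), n_persons=4)
        assert np.allclose(state.a[:, 0], 1.0)
        assert np.allclose(state.d, 0.0)
        assert np.allclose(state.theta, 0.0)
        assert state.mu_a[0] == 0.0  # mean of U(-6, 6)
        assert state.var_a[0] > 0 and state.var_d > 0

    def test_positivity_violating_override_rejected(self):
        spec = ModelSpec(item_names=["y1", "y2"])
        with pytest.raises(ValueError, match="positivity"):
            initialize_state(spec, PriorConfig(), 4, overrides={"a_y1_dim1": -0.5})

    def test_unknown_override_rejected(self):
        spec = ModelSpec(item_names=["y1", "y2"])
        with pytest.raises(ValueError, match="unknown"):
            initialize_state(spec, PriorConfig(), 4, overrides={"a_y9_dim1": 1.0})

    def test_correlation_start_values(self):
        from hbirt.factors import correlation_from_regressions
        from hbirt.factors import CovarSpec

        spec = ModelSpec(
            item_names=["y1", "y2", "y3", "y4"], n_factors=2,
            loading_pattern=np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=bool),
            covar=CovarSpec.parse("1#2[0.5]"),
        )
        state = initialize_state(spec, PriorConfig(), 4)
        R = correlation_from_regressions(state.beta)
        assert R[0, 1] == pytest.approx(0.5, abs=1e-8)


def _tiny_sampler(y, priors=None, seed=0, n_persons=None):
    data = ResponseMatrix(np.asarray(y, dtype=float))
    spec = ModelSpec(item_names=list(data.item_names))
    priors = priors or PriorConfig(priors="user")
    state = initialize_state(spec, priors, data.n_persons)
    rng = np.random.default_rng(seed)
    return _Sampler(data, spec, priors, state, rng), spec, priors


class TestSweep:
    def test_zero_scale_proposals_keep_state_and_accept(self):
        smp, _, _ = _tiny_sampler([[1.0, 0.0], [0.0, 1.0]])
        for k in smp.scales:
            smp.scales[k] = np.zeros_like(smp.scales[k])
        a0, d0, t0 = smp.state.a.copy(), smp.state.d.copy(), smp.state.theta.copy()
        for _ in range(10):
            smp.sweep()
        rates = smp.acceptance_rates()
        assert np.allclose(smp.state.a, a0)
        assert np.allclose(smp.state.d, d0)
        assert np.allclose(smp.state.theta, t0)
        assert np.allclose(rates["theta"], 1.0)
        assert np.allclose(rates["item"], 1.0)

    def test_constrained_slope_never_negative(self, user_fit):
        draws = user_fit["draws"]
        col = draws.column("a_y1_dim1")  # the auto positivity constraint
        assert np.all(col >= 0.0)

    def test_conjugate_var_d_matches_closed_form(self):
        """10^5 conjugate draws at fixed d, mu_d match the inverse-gamma
        full conditional IG(alpha + J/2, beta + 0.5 sum (d - mu_d)^2)
        (KS distance < 0.01)."""
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, (30, 6)).astype(float)
        smp, spec, _ = _tiny_sampler(y, priors=PriorConfig(), seed=1)
        smp.state.d = np.linspace(-1.5, 1.5, 6)
        smp.state.mu_d = 0.2
        draws = np.array([smp._draw_var_d_conjugate() for _ in range(100_000)])
        alpha, beta = 0.01, 0.01
        a_post = alpha + 6 / 2.0
        b_post = beta + 0.5 * ((smp.state.d - 0.2) ** 2).sum()
        ks = stats.kstest(draws, stats.invgamma(a_post, scale=b_post).cdf).statistic
        assert ks < 0.01

    def test_empty_hierarchical_set_returns_prior(self):
        """With no items under the hierarchical intercept prior, the var_d
        full conditional reduces to the hyperprior itself."""
        data = ResponseMatrix(np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))
        spec = ModelSpec(item_names=["y1", "y2"],
                         intercept_hier=np.array([False, False]))
        priors = PriorConfig()
        state = initialize_state(spec, priors, 3)
        smp = _Sampler(data, spec, priors, state, np.random.default_rng(0))
        # J_h = 0: posterior shape alpha + 0, scale beta + 0 = the hyperprior
        draws = np.array([smp._draw_var_d_conjugate() for _ in range(50_000)])
        ks = stats.kstest(draws, stats.invgamma(0.01, scale=0.01).cdf).statistic
        assert ks < 0.02

    def test_posterior_matches_numerical_integration(self):
        """One item, three persons with traits frozen at 0: the posterior of
        d under a N(0, 4) prior is compared with a dense-grid quadrature
        posterior (mean/SD within 3 Monte Carlo SEs)."""
        y = [[1.0], [0.0], [1.0]]
        smp, _, _ = _tiny_sampler(y, seed=3)
        smp.scales["theta"] = np.zeros(3)  # freeze theta at 0
        smp.scales["item"] = np.full(1, 1.2)
        for _ in range(500):
            smp.sweep()
        keep_d, keep_a = [], []
        for _ in range(40_000):
            smp.sweep()
            keep_d.append(smp.state.d[0])
            keep_a.append(smp.state.a[0, 0])
        keep_d = np.array(keep_d)
        # independent oracle: with theta = 0, p = sigmoid(-d) for every person
        grid = np.linspace(-10, 10, 4001)
        p = 1.0 / (1.0 + np.exp(grid))
        loglik = 2 * np.log(p) + np.log1p(-p)
        post = np.exp(loglik + stats.norm.logpdf(grid, 0, 2))
        post /= np.trapezoid(post, grid)
        mean = np.trapezoid(grid * post, grid)
        sd = np.sqrt(np.trapezoid((grid - mean) ** 2 * post, grid))
        from hbirt.diagnostics import ess

        mc_se = keep_d.std() / np.sqrt(ess(keep_d))
        assert keep_d.mean() == pytest.approx(mean, abs=3 * mc_se)
        assert keep_d.std(ddof=1) == pytest.approx(sd, rel=0.1)
        # with theta frozen at 0 the slope's posterior is its truncated prior
        keep_a = np.array(keep_a)
        assert np.all(keep_a >= 0)
        tn_mean = stats.truncnorm(0, np.inf, loc=0, scale=2).mean()
        mc_se_a = keep_a.std() / np.sqrt(ess(keep_a))
        assert keep_a.mean() == pytest.approx(tn_mean, abs=3 * mc_se_a)


class TestTuning:
    def test_zero_loops_keeps_scales(self):
        rep = generate_replicate(40, 5, seed=0)
        spec = ModelSpec(item_names=list(rep.data.item_names))
        priors = PriorConfig(priors="user")
        state = initialize_state(spec, priors, 40)
        cfg = SamplerConfig(maxtune=0)
        scales = tune_proposals(rep.data, spec, priors, state, cfg,
                                np.random.default_rng(0))
        assert np.allclose(scales["item"], 0.3)

    def test_oversized_scale_tuned_into_band(self):
        """Starting from an absurd proposal scale, tuning brings the item
        blocks back into the target acceptance band on a 500-sweep probe."""
        rep = generate_replicate(120, 4, seed=1)
        spec = ModelSpec(item_names=list(rep.data.item_names))
        priors = PriorConfig(priors="user")
        state = initialize_state(spec, priors, 120)
        smp = _Sampler(rep.data, spec, priors, state, np.random.default_rng(2))
        smp.scales["item"] = np.full(4, 100.0)
        smp.tune(max_loops=40, ntu=300)
        smp.reset_counters()
        for _ in range(500):
            smp.sweep()
        rates = smp.acceptance_rates()
        assert np.all(rates["item"] > 0.15) and np.all(rates["item"] < 0.6)

    def test_halving_oversized_scale_does_not_reduce_acceptance(self):
        """Monte-Carlo probe of the adaptation direction."""
        rep = generate_replicate(120, 3, seed=5)
        spec = ModelSpec(item_names=list(rep.data.item_names))
        priors = PriorConfig(priors="user")

        def probe(scale, seed):
            state = initialize_state(spec, priors, 120)
            smp = _Sampler(rep.data, spec, priors, state, np.random.default_rng(seed))
            smp.scales["item"] = np.full(3, scale)
            for _ in range(300):
                smp.sweep()
            return smp.acceptance_rates()["item"].mean()

        assert probe(2.0, 7) <= probe(4.0, 7) + 0.05  # sanity: both tiny
        assert probe(2.0, 8) >= probe(4.0, 8) - 0.02


class TestTwoStageStart:
    def test_hyperparameters_seeded_from_stage_one(self):
        rep = generate_replicate(300, 10, seed=6)
        spec = ModelSpec(item_names=list(rep.data.item_names))
        priors = PriorConfig()
        cfg = SamplerConfig(nbi=400, iterationsteps=600, maxtune=2, ntu=200)
        state = two_stage_start(rep.data, spec, priors, cfg, np.random.default_rng(3))
        assert state.var_a[0] > 0 and state.var_d > 0
        # stage-one slope estimates should already track the truth
        r = np.corrcoef(state.a[:, 0], rep.a)[0, 1]
        assert r > 0.5

    def test_full_override_table_skips_stage_one(self):
        rep = generate_replicate(30, 3, seed=7)
        spec = ModelSpec(item_names=list(rep.data.item_names))
        priors = PriorConfig()
        overrides = {"a_y1_dim1": 1.1, "a_y2_dim1": 0.9, "a_y3_dim1": 1.0,
                     "d_y1": 0.1, "d_y2": -0.2, "d_y3": 0.0,
                     "mua1": 1.0, "vara1": 0.1, "mud": 0.0, "vard": 1.0}
        cfg = SamplerConfig(nbi=50, iterationsteps=100, hmaxtune=0)
        conv = ConvergenceConfig(psr_conv=0.0, ess_conv=0.0)
        draws, _, _ = run_chunked(rep.data, spec, priors, cfg, conv, seed=1,
                                  overrides=overrides)
        assert draws.n_kept == 100  # ran; starting state came from the table


class TestRunChunked:
    def test_fixed_length_run(self):
        """Both criteria disabled: exactly one chunk of kept iterations."""
        rep = generate_replicate(40, 5, seed=8)
        spec = ModelSpec(item_names=list(rep.data.item_names))
        priors = PriorConfig(priors="user")
        cfg = SamplerConfig(nbi=100, iterationsteps=200, maxtune=0)
        conv = ConvergenceConfig(psr_conv=0.0, ess_conv=0.0)
        draws, report, _ = run_chunked(rep.data, spec, priors, cfg, conv, seed=2)
        assert draws.n_kept == 200
        assert len(draws.chunk_bounds) == 1
        assert not report.converged

    def test_seeded_runs_bit_identical(self):
        rep = generate_replicate(40, 5, seed=9)
        spec = ModelSpec(item_names=list(rep.data.item_names))
        priors = PriorConfig(priors="user")
        cfg = SamplerConfig(nbi=100, iterationsteps=300, maxtune=0)
        conv = ConvergenceConfig(psr_conv=0.0, ess_conv=0.0)
        d1, _, _ = run_chunked(rep.data, spec, priors, cfg, conv, seed=33)
        d2, _, _ = run_chunked(rep.data, spec, priors, cfg, conv, seed=33)
        assert np.array_equal(d1.matrix, d2.matrix)
        assert np.array_equal(d1.theta, d2.theta)

    def test_restart_and_concat_bookkeeping(self):
        rep = generate_replicate(40, 5, seed=10)
        spec = ModelSpec(item_names=list(rep.data.item_names))
        priors = PriorConfig(priors="user")
        cfg = SamplerConfig(nbi=100, iterationsteps=200, maxtune=0)
        conv = ConvergenceConfig(psr_conv=0.0, ess_conv=0.0)
        d1, _, state = run_chunked(rep.data, spec, priors, cfg, conv, seed=3)
        cfg2 = cfg.replace(nbi=0)
        d2, _, _ = run_chunked(rep.data, spec, priors, cfg2, conv, seed=4,
                               start_state=state)
        combined = d1.concat(d2)
        assert combined.n_kept == d1.n_kept + d2.n_kept
        assert combined.chunk_bounds == [200, 400]

    def test_thinning_halves_kept_draws_same_posterior(self):
        rep = generate_replicate(150, 6, seed=11)
        spec = ModelSpec(item_names=list(rep.data.item_names))
        priors = PriorConfig(priors="user")
        conv = ConvergenceConfig(psr_conv=0.0, ess_conv=0.0)
        cfg1 = SamplerConfig(nbi=500, iterationsteps=4000, thin=1, maxtune=0)
        cfg2 = cfg1.replace(thin=2)
        d1, _, _ = run_chunked(rep.data, spec, priors, cfg1, conv, seed=5)
        d2, _, _ = run_chunked(rep.data, spec, priors, cfg2, conv, seed=6)
        assert d2.n_kept == d1.n_kept // 2
        m1 = d1.second_half().mean(axis=0)
        m2 = d2.second_half().mean(axis=0)
        sd = d1.second_half().std(axis=0)
        # agreement within Monte-Carlo error, relative to the posterior scale
        assert np.max(np.abs(m1 - m2) / (sd + 0.05)) < 1.5

    def test_constant_item_rejected_up_front(self):
        data = ResponseMatrix(np.array([[1.0, 1.0], [0.0, 1.0], [1.0, 1.0]]))
        spec = ModelSpec(item_names=["y1", "y2"])
        with pytest.raises(ValueError, match="variability"):
            run_chunked(data, spec, PriorConfig(priors="user"),
                        SamplerConfig(nbi=10, iterationsteps=10, maxtune=0),
                        ConvergenceConfig(psr_conv=0.0, ess_conv=0.0), seed=0)

    def test_hierarchical_run_converges_and_recovers(self, hier_fit):
        """On simulated N=500, k=25 data the hierarchical chain terminates
        with all PSR below 1.1 and slope estimates tracking the truth."""
        report = hier_fit["report"]
        assert report.converged
        assert report.psr.max() < 1.1
        draws, rep = hier_fit["draws"], hier_fit["replicate"]
        half = draws.second_half()
        est = np.array([half[:, draws.parameters.index(f"a_{n}_dim1")].mean()
                        for n in rep.data.item_names])
        assert np.corrcoef(est, rep.a)[0, 1] > 0.6

    def test_1pl_shared_slope_recovered(self):
        """Under the 1PL the per-factor slope is a single parameter with a
        truncated-normal prior; it should recover a common generating slope."""
        from scipy.special import expit

        rng = np.random.default_rng(21)
        N, J, a_true = 400, 8, 1.2
        d = rng.normal(0, 1, J)
        th = rng.normal(0, 1, N)
        y = (rng.random((N, J)) < expit(np.outer(th, np.full(J, a_true)) - d)).astype(float)
        data = ResponseMatrix(y)
        spec = ModelSpec(item_names=list(data.item_names), model="1PL")
        priors = PriorConfig(priors="user", prior_mean_a=1.0, prior_var_a=4.0)
        cfg = SamplerConfig(nbi=800, iterationsteps=2500, maxtune=3, ntu=200)
        conv = ConvergenceConfig(psr_conv=0.0, ess_conv=0.0)
        draws, _, _ = run_chunked(data, spec, priors, cfg, conv, seed=22)
        assert draws.parameters[0] == "a_dim1"
        est = draws.second_half()[:, 0].mean()
        assert est == pytest.approx(a_true, abs=0.25)
        assert np.all(draws.matrix[:, 0] >= 0)

    def test_probit_link_rescales_slopes(self):
        """Fitting logistic-generated data with a probit link shrinks the
        slopes by roughly sqrt(pi^2/3) ~ 1.7."""
        from scipy.special import expit

        rng = np.random.default_rng(23)
        N, J = 1500, 6
        a_true = np.full(J, 1.2)
        d = rng.normal(0, 1, J)
        th = rng.normal(0, 1, N)
        y = (rng.random((N, J)) < expit(np.outer(th, a_true) - d)).astype(float)
        data = ResponseMatrix(y)
        priors = PriorConfig(priors="user", prior_mean_a=0.7, prior_var_a=4.0)
        cfg = SamplerConfig(nbi=1500, iterationsteps=4000, maxtune=5, ntu=300)
        conv = ConvergenceConfig(psr_conv=0.0, ess_conv=0.0)
        spec = ModelSpec(item_names=list(data.item_names), link="probit")
        draws, _, _ = run_chunked(data, spec, priors, cfg, conv, seed=24)
        a_cols = [draws.parameters.index(f"a_y{j + 1}_dim1") for j in range(J)]
        mean_slope = draws.second_half()[:, a_cols].mean()
        assert mean_slope == pytest.approx(1.2 / np.sqrt(np.pi**2 / 3), abs=0.15)

    def test_missing_at_random_estimates_agree_with_full_data(self):
        """Deleting 20% of cells completely at random leaves estimates
        within combined Monte-Carlo/posterior uncertainty at N=500."""
        rep = generate_replicate(500, 10, seed=12)
        spec = ModelSpec(item_names=list(rep.data.item_names))
        priors = PriorConfig(priors="user", prior_mean_a=1.0, prior_var_a=4.0)
        cfg = SamplerConfig(nbi=1000, iterationsteps=2500, maxtune=0)
        conv = ConvergenceConfig(psr_conv=0.0, ess_conv=0.0)
        d_full, _, _ = run_chunked(rep.data, spec, priors, cfg, conv, seed=7)
        rng = np.random.default_rng(13)
        y = rep.data.values.copy()
        y[rng.random(y.shape) < 0.2] = np.nan
        data_mar = ResponseMatrix(y, item_names=rep.data.item_names)
        d_mar, _, _ = run_chunked(data_mar, spec, priors, cfg, conv, seed=8)
        a_cols = [d_full.parameters.index(f"a_{n}_dim1") for n in rep.data.item_names]
        est_full = d_full.second_half()[:, a_cols].mean(axis=0)
        est_mar = d_mar.second_half()[:, a_cols].mean(axis=0)
        sd = d_mar.second_half()[:, a_cols].std(axis=0)
        assert np.all(np.abs(est_full - est_mar) < 3.5 * sd)
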