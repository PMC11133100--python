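"""Simulation harness: data generation, metrics, shrinkage regression."""

import numpy as np
import pytest

from hbirt.simulation import (
    ArmResult,
    Replicate,
    SimCondition,
    compute_metrics,
    eap_metrics,
    generate_numeracy_fixture,
    generate_replicate,
    run_condition,
    shrinkage_regression,
)


class TestGenerator:
    def test_parameter_distributions(self):
        """Slopes ~ N(1, 0.04), intercepts ~ N(0, 1) across many items."""
        rng = np.random.default_rng(0)
        rep = generate_replicate(2, 10_000, seed=rng)
        assert rep.a.mean() == pytest.approx(1.0, abs=0.01)
        assert rep.a.var() == pytest.approx(0.04, abs=0.003)
        assert rep.d.mean() == pytest.approx(0.0, abs=0.03)
        assert rep.d.var() == pytest.approx(1.0, abs=0.05)

    def test_implied_difficulty_variance(self):
        """Var(d/a) with d ~ N(0,1), a ~ N(1, 0.04) is about 1.15."""
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 0.2, 1_000_000)
        d = rng.normal(0.0, 1.0, 1_000_000)
        assert np.var(d / a) == pytest.approx(1.15, abs=0.03)

    def test_seeded_replicate_bit_reproducible(self):
        r1 = generate_replicate(50, 25, seed=99)
        r2 = generate_replicate(50, 25, seed=99)
        assert np.array_equal(r1.data.values, r2.data.values)
        assert np.array_equal(r1.a, r2.a)

    def test_response_marginal_matches_model(self):
        """Empirical P(y=1) tracks logistic(a*theta - d) cell-wise."""
        rep = generate_replicate(100_000, 3, seed=2)
        from scipy.special import expit

        p = expit(np.outer(rep.theta, rep.a) - rep.d).mean(axis=0)
        assert np.allclose(rep.data.values.mean(axis=0), p, atol=0.01)

    def test_inestimable_flagging(self):
        # N=2 makes constant items likely; flag must match the data
        for seed in range(30):
            rep = generate_replicate(2, 25, seed=seed)
            has_const = bool(len(rep.data.constant_items()))
            assert rep.estimable == (not has_const)


class TestNumeracyFixture:
    def test_shape_and_columns(self):
        data = generate_numeracy_fixture(seed=3)
        assert data.values.shape == (140, 30)
        assert data.item_names[0] == "y1" and data.item_names[-1] == "y30"
        assert not np.isnan(data.values).any()

    def test_stronger_facets_have_higher_item_rest_correlations(self):
        """Facet 3 loadings (mean 2) dominate facet 1 (mean 1)."""
        corrs = {1: [], 3: []}
        for seed in range(5):
            data = generate_numeracy_fixture(seed=seed)
            y = data.values
            total = y.sum(axis=1)
            for j in range(30):
                rest = total - y[:, j]
                r = np.corrcoef(y[:, j], rest)[0, 1]
                if j < 10:
                    corrs[1].append(r)
                elif j >= 20:
                    corrs[3].append(r)
        assert np.mean(corrs[3]) > np.mean(corrs[1])


class TestComputeMetrics:
    def test_matches_naive_loop_oracle(self):
        """Bias / variance / RMSE / coverage on a 3-replicate toy equal an
        independent hand computation."""
        est = np.array([[1.1, 0.9, 1.0], [1.2, 1.0, 0.8], [0.9, 1.1, 1.0]])
        true = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        var = np.full((3, 3), 0.04)
        lo, hi = est - 0.25, est + 0.25
        results, reps = [], []
        from hbirt.data import ResponseMatrix

        for r in range(3):
            intervals = {"hpd": {"a": (lo[r], hi[r]), "d": (lo[r], hi[r])}}
            results.append(ArmResult("correct", est[r], est[r], var[r], var[r],
                                     intervals, True))
            data = ResponseMatrix(np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]))
            reps.append(Replicate(data, true[r], true[r], np.zeros(2), True))
        df = compute_metrics(results, reps, n_boot=100, seed=0)
        sub = df[df.parameter == "a"].set_index("metric")["value"]
        errs = (est - true).ravel()
        assert sub["bias"] == pytest.approx(errs.mean())
        assert sub["variance"] == pytest.approx(0.04)
        assert sub["rmse"] == pytest.approx(np.sqrt((errs**2).mean()))
        covered = sum((l <= t <= h) for l, t, h in
                      zip(lo.ravel(), true.ravel(), hi.ravel()))
        assert sub["coverage_hpd"] == pytest.approx(covered / 9)
        assert sub["length_hpd_mean"] == pytest.approx(0.5)

    def test_exact_estimates_give_zero_bias_and_flagged_coverage(self):
        est = np.array([[1.0, 1.0], [1.0, 1.0]])
        zero = np.zeros((2, 2))
        results, reps = [], []
        from hbirt.data import ResponseMatrix

        for r in range(2):
            intervals = {"hpd": {"a": (est[r], est[r]), "d": (est[r], est[r])}}
            results.append(ArmResult("correct", est[r], est[r], zero[r], zero[r],
                                     intervals, True))
            data = ResponseMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
            reps.append(Replicate(data, est[r], est[r], np.zeros(2), True))
        df = compute_metrics(results, reps, n_boot=50, seed=0)
        sub = df[df.parameter == "a"].set_index("metric")["value"]
        assert sub["bias"] == 0.0 and sub["rmse"] == 0.0
        assert np.isnan(sub["coverage_hpd"])  # zero-width intervals flagged

    def test_single_replicate_bootstrap_degenerates(self):
        from hbirt.data import ResponseMatrix

        est = np.array([[1.1, 0.9]])
        intervals = {"hpd": {"a": (est[0] - 1, est[0] + 1),
                             "d": (est[0] - 1, est[0] + 1)}}
        results = [ArmResult("correct", est[0], est[0],
                             np.zeros(2), np.zeros(2), intervals, True)]
        reps = [Replicate(ResponseMatrix(np.array([[1.0, 0.0], [0.0, 1.0]])),
                          np.ones(2), np.ones(2), np.zeros(2), True)]
        df = compute_metrics(results, reps, n_boot=50, seed=0)
        row = df[(df.parameter == "a") & (df.metric == "bias")].iloc[0]
        assert row.ci_low == row.ci_high == pytest.approx(row.value)


class TestShrinkageRegression:
    def test_exact_linear_relation(self):
        """Errors constructed as -0.5 * centered truth: slope -0.5, R^2 = 1."""
        rng = np.random.default_rng(4)
        truths = rng.normal(1, 0.2, size=(5, 10))
        errors = -0.5 * (truths - truths.mean())
        out = shrinkage_regression(errors, truths)
        assert out["slope"] == pytest.approx(-0.5, abs=1e-10)
        assert out["r2"] == pytest.approx(1.0, abs=1e-10)

    def test_cluster_permutation_invariance(self):
        rng = np.random.default_rng(5)
        truths = rng.normal(1, 0.2, size=(4, 6))
        errors = rng.normal(0, 0.1, size=(4, 6)) - 0.3 * (truths - 1)
        s1 = shrinkage_regression(errors, truths)
        perm = rng.permutation(4)
        s2 = shrinkage_regression(errors[perm], truths[perm])
        assert s1["slope"] == pytest.approx(s2["slope"])
        assert s1["se"] == pytest.approx(s2["se"])

    def test_cr1_sandwich_hand_computation(self):
        """2 clusters x 2 points: CR1 sandwich computed explicitly."""
        truths = np.array([[0.5, 1.5], [0.8, 1.2]])
        errors = np.array([[0.2, -0.1], [0.05, -0.3]])
        out = shrinkage_regression(errors, truths)
        # independent matrix computation
        x = (truths - truths.mean()).ravel()
        y = errors.ravel()
        X = np.column_stack([np.ones(4), x])
        bhat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ bhat
        G, n, k = 2, 4, 2
        meat = np.zeros((2, 2))
        for g, idx in enumerate([(0, 1), (2, 3)]):
            Xg = X[list(idx)]
            ug = resid[list(idx)]
            s = Xg.T @ ug
            meat += np.outer(s, s)
        c = (G / (G - 1)) * ((n - 1) / (n - k))
        bread = np.linalg.inv(X.T @ X)
        V = c * bread @ meat @ bread
        assert out["slope"] == pytest.approx(bhat[1])
        assert out["se"] == pytest.approx(np.sqrt(V[1, 1]), rel=1e-6)

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError):
            shrinkage_regression(np.zeros((2, 3)), np.ones((2, 3)))


class TestEAPMetrics:
    def test_perfect_scores(self):
        from hbirt.data import ResponseMatrix

        theta = np.linspace(-2, 2, 10)
        data = ResponseMatrix(np.tile([1.0, 0.0], (10, 1)))
        rep = Replicate(data, np.ones(2), np.zeros(2), theta, True)
        res = ArmResult("correct", np.ones(2), np.zeros(2), np.zeros(2),
                        np.zeros(2), {}, True, eap=theta,
                        eap_sd=np.full(10, 0.2))
        out = eap_metrics([res], [rep])
        assert out["coverage"] == 1.0
        assert out["reliability_true"] == pytest.approx(1.0)
        assert out["reliability_estimated"] == pytest.approx(np.var(theta, ddof=1))

    def test_zero_scores_have_zero_reliability(self):
        from hbirt.data import ResponseMatrix

        theta = np.linspace(-2, 2, 10)
        data = ResponseMatrix(np.tile([1.0, 0.0], (10, 1)))
        rep = Replicate(data, np.ones(2), np.zeros(2), theta, True)
        res = ArmResult("uninformative", np.ones(2), np.zeros(2), np.zeros(2),
                        np.zeros(2), {}, True, eap=np.zeros(10),
                        eap_sd=np.full(10, 3.0))
        out = eap_metrics([res], [rep])
        assert out["reliability_estimated"] == 0.0


@pytest.fixture(scope="module")
def small_runs():
    """3 replicates each of the uninformative and hierarchical arms at
    N=50 (shared across the ordering assertions)."""
    out = {}
    for arm in ("uninformative", "hierarchical"):
        cond = SimCondition(N=50, k=25, replicates=3, seed=17, arm=arm)
        out[arm] = run_condition(cond)
    return out


class TestArmOrdering:
    def test_prior_informativeness_orders_interval_length_and_bias(self, small_runs):
        """Hierarchical priors yield markedly shorter slope intervals and
        smaller slope bias than flat priors in very small samples."""
        lengths, biases = {}, {}
        for arm, out in small_runs.items():
            df = compute_metrics(out["results"], out["replicates"],
                                 n_boot=200, seed=0)
            sub = df[df.parameter == "a"].set_index("metric")["value"]
            lengths[arm] = sub["length_hpd_mean"]
            biases[arm] = sub["bias"]
        assert lengths["hierarchical"] < lengths["uninformative"]
        assert biases["hierarchical"] < biases["uninformative"]

    def test_shrinkage_direction_by_prior_type(self, small_runs):
        """Flat priors push slope errors up with the truth (positive slope);
        hierarchical priors shrink toward the pooled mean (negative)."""
        slopes = {}
        for arm, out in small_runs.items():
            est = np.array([r.est_a for r in out["results"]])
            true = np.array([rep.a for rep in out["replicates"]])
            slopes[arm] = shrinkage_regression(est - true, true)["slope"]
        assert slopes["hierarchical"] < 0
        assert slopes["uninformative"] > slopes["hierarchical"]


class TestCondition:
    def test_invalid_arm_rejected(self):
        with pytest.raises(ValueError):
            SimCondition(arm="bogus")

    def test_run_condition_reports_counts(self):
        cond = SimCondition(N=60, k=6, replicates=2, seed=19, arm="ML")
        out = run_condition(cond)
        assert len(out["results"]) == 2
        assert out["n_regenerated"] >= 0
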