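"""Small-sample simulation harness for the unidimensional 2PL.

The design: item slopes a ~ N(1, 0.04), intercepts d ~ N(0, 1) and traits
theta ~ N(0, 1) are redrawn for every data replicate; responses are
Bernoulli(logistic(a * theta - d)) with k = 25 items and N in {50, 100,
500}.  Each replicate is analyzed by five estimation arms: marginal ML and
Bayesian estimation with uninformative (a ~ N(1, 100), d ~ N(0, 100)),
informative (a ~ N(1, 4), d ~ N(0, 4)), hierarchical (default hyperpriors),
or correct (a ~ N(1, 0.04), d ~ N(0, 1)) priors.  The metric battery pools
items x replicates: bias, estimation variance (squared SE or posterior
variance), RMSE, interval coverage and lengths, EAP coverage and
reliability, and the shrinkage regression of estimation error on the
centered population parameter with cluster-robust standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .data import ResponseMatrix
from .diagnostics import ConvergenceConfig
from .ml import fit_em
from .model import ModelSpec, PriorConfig
from .sampler import SamplerConfig, run_chunked
from .summaries import eap_scores, equal_tail_interval, hpd_interval

__all__ = [
    "ARMS",
    "ARM_PRIORS",
    "SimCondition",
    "Replicate",
    "ArmResult",
    "generate_replicate",
    "generate_numeracy_fixture",
    "run_arm",
    "run_condition",
    "compute_metrics",
    "shrinkage_regression",
    "eap_metrics",
]

ARMS = ("ML", "uninformative", "informative", "hierarchical", "correct")

#: Constant-prior settings per Bayesian arm (mean, variance) for (a, d).
ARM_PRIORS = {
    "uninformative": dict(prior_mean_a=1.0, prior_var_a=100.0,
                          prior_mean_d=0.0, prior_var_d=100.0),
    "informative": dict(prior_mean_a=1.0, prior_var_a=4.0,
                        prior_mean_d=0.0, prior_var_d=4.0),
    "correct": dict(prior_mean_a=1.0, prior_var_a=0.04,
                    prior_mean_d=0.0, prior_var_d=1.0),
}

#: Generating distributions: slope mean/SD, intercept mean/SD.
TRUE_A_MEAN, TRUE_A_SD = 1.0, 0.2
TRUE_D_MEAN, TRUE_D_SD = 0.0, 1.0


@dataclass
class SimCondition:
    N: int = 50
    k: int = 25
    replicates: int = 100
    seed: int = 0
    arm: str = "hierarchical"

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; choose from {ARMS}")
        if self.N < 1 or self.k < 1 or self.replicates < 1:
            raise ValueError("N, k and replicates must be positive")


@dataclass
class Replicate:
    data: ResponseMatrix
    a: np.ndarray
    d: np.ndarray
    theta: np.ndarray
    estimable: bool


def generate_replicate(N: int, k: int = 25, seed=None) -> Replicate:
    """One simulated data set with freshly drawn item and person parameters.

    Flagged not estimable when some item shows no variability (all 0 or all
    1), which carries no information about that item's slope.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = rng.normal(TRUE_A_MEAN, TRUE_A_SD, size=k)
    d = rng.normal(TRUE_D_MEAN, TRUE_D_SD, size=k)
    theta = rng.normal(0.0, 1.0, size=N)
    p = expit(np.outer(theta, a) - d)
    y = (rng.random((N, k)) < p).astype(float)
    estimable = bool(np.all(y.min(axis=0) < y.max(axis=0)))
    data = ResponseMatrix(y, item_names=[f"y{j + 1}" for j in range(k)])
    return Replicate(data, a, d, theta, estimable)


def generate_estimable_replicate(N: int, k: int = 25, seed=None,
                                 max_tries: int = 100) -> tuple[Replicate, int]:
    """Regenerate under fresh sub-seeds until every item shows variability;
    returns the replicate and the number of discarded draws."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for tries in range(max_tries):
        rep = generate_replicate(N, k, rng)
        if rep.estimable:
            return rep, tries
    raise RuntimeError("could not generate an estimable replicate")


def generate_numeracy_fixture(N: int = 140, seed=None,
                              factor_corr: float = 0.5) -> ResponseMatrix:
    """Synthetic three-facet numeracy-style data set: 30 items (10 per
    facet) for N children, simple structure, loading means 1, 1.5 and 2 for
    facets 1-3 and inter-facet correlation ``factor_corr``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    F, per = 3, 10
    k = F * per
    R = np.full((F, F), factor_corr)
    np.fill_diagonal(R, 1.0)
    theta = rng.multivariate_normal(np.zeros(F), R, size=N)
    load_means = (1.0, 1.5, 2.0)
    a = np.zeros((k, F))
    for f in range(F):
        a[f * per:(f + 1) * per, f] = rng.normal(load_means[f], TRUE_A_SD, size=per)
    d = rng.normal(0.0, 1.0, size=k)
    p = expit(theta @ a.T - d)
    y = (rng.random((N, k)) < p).astype(float)
    return ResponseMatrix(y, person_ids=list(range(1, N + 1)),
                          item_names=[f"y{j + 1}" for j in range(k)])


@dataclass
class ArmResult:
    """Per-replicate output of one estimation arm."""

    arm: str
    est_a: np.ndarray
    est_d: np.ndarray
    var_a: np.ndarray  # squared SE (ML) or posterior variance (Bayes)
    var_d: np.ndarray
    intervals: dict    # {"wald"|"hpd"|"eti": {"a": (lo, hi), "d": (lo, hi)}}
    converged: bool
    eap: np.ndarray | None = None
    eap_sd: np.ndarray | None = None


def _sim_sampler_config(arm: str) -> SamplerConfig:
    # the study settings: tuning only for the hierarchical arm, shorter
    # convergence-check chunks than the general-purpose defaults
    return SamplerConfig(nbi=5000, iterationsteps=2500,
                         maxtune=0, hmaxtune=100)


def run_arm(rep: Replicate, arm: str, seed=None,
            sampler: SamplerConfig | None = None,
            convergence: ConvergenceConfig | None = None) -> ArmResult:
    """Analyze one replicate with one estimation arm.

    The Bayesian arms use a unidimensional 2PL with the default single
    positivity constraint and PSR < 1.1 stopping; estimates are posterior
    means, uncertainty is the posterior variance, and both HPD and
    equal-tail 95% intervals are recorded.  The ML arm uses EM marginal ML
    with Wald intervals.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    data = rep.data
    k = data.n_items
    if arm == "ML":
        fit = fit_em(data)
        z = norm.ppf(0.975)
        intervals = {"wald": {
            "a": (fit.slope - z * fit.se_slope, fit.slope + z * fit.se_slope),
            "d": (fit.intercept - z * fit.se_intercept, fit.intercept + z * fit.se_intercept),
        }}
        return ArmResult(arm, fit.slope, fit.intercept,
                         fit.se_slope**2, fit.se_intercept**2,
                         intervals, fit.converged)
    spec = ModelSpec(item_names=list(data.item_names))
    if arm == "hierarchical":
        priors = PriorConfig()
    else:
        priors = PriorConfig(priors="user", **ARM_PRIORS[arm])
    sampler = sampler or _sim_sampler_config(arm)
    convergence = convergence or ConvergenceConfig(psr_conv=1.1, ess_conv=0.0)
    draws, report, _ = run_chunked(data, spec, priors, sampler, convergence,
                                   seed=seed, keep_theta=True)
    half = draws.second_half()
    names = draws.parameters
    a_cols = [names.index(f"a_{it}_dim1") for it in data.item_names]
    d_cols = [names.index(f"d_{it}") for it in data.item_names]
    est_a = half[:, a_cols].mean(axis=0)
    est_d = half[:, d_cols].mean(axis=0)
    var_a = half[:, a_cols].var(axis=0, ddof=1)
    var_d = half[:, d_cols].var(axis=0, ddof=1)
    hpd_a = np.array([hpd_interval(half[:, c]) for c in a_cols])
    hpd_d = np.array([hpd_interval(half[:, c]) for c in d_cols])
    eti_a = np.array([equal_tail_interval(half[:, c]) for c in a_cols])
    eti_d = np.array([equal_tail_interval(half[:, c]) for c in d_cols])
    intervals = {
        "hpd": {"a": (hpd_a[:, 0], hpd_a[:, 1]), "d": (hpd_d[:, 0], hpd_d[:, 1])},
        "eti": {"a": (eti_a[:, 0], eti_a[:, 1]), "d": (eti_d[:, 0], eti_d[:, 1])},
    }
    scores = eap_scores(draws.second_half_theta())
    return ArmResult(arm, est_a, est_d, var_a, var_d, intervals,
                     report.converged, scores.eap[:, 0], scores.post_sd[:, 0])


def run_condition(cond: SimCondition, sampler: SamplerConfig | None = None,
                  regenerate_inestimable: bool = True,
                  progress: bool = False) -> dict:
    """Run one condition x arm cell: generate replicates and analyze each.

    Returns a dict with the replicate truths, arm results, and counts of
    regenerated (zero-variance) and non-converged replicates.
    """
    rng = np.random.default_rng(cond.seed)
    reps, results, dropped = [], [], 0
    for r in range(cond.replicates):
        sub = np.random.default_rng(rng.integers(2**31))
        if regenerate_inestimable:
            rep, tries = generate_estimable_replicate(cond.N, cond.k, sub)
            dropped += tries
        else:
            rep = generate_replicate(cond.N, cond.k, sub)
        reps.append(rep)
        results.append(run_arm(rep, cond.arm, seed=np.random.default_rng(rng.integers(2**31)),
                               sampler=sampler))
        if progress:
            print(f"  replicate {r + 1}/{cond.replicates} done", flush=True)
    n_nonconv = sum(not res.converged for res in results)
    return {"condition": cond, "replicates": reps, "results": results,
            "n_regenerated": dropped, "n_nonconverged": n_nonconv}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _bootstrap_ci(per_replicate: np.ndarray, n_boot: int, rng,
                  transform=None) -> tuple[float, float]:
    """Percentile CI of the mean of per-replicate statistics, resampling
    replicates with replacement.  ``transform`` maps the bootstrap mean
    (e.g. sqrt for RMSE)."""
    R = per_replicate.shape[0]
    if R == 1:
        v = float(per_replicate[0])
        v = transform(v) if transform else v
        return v, v
    idx = rng.integers(0, R, size=(n_boot, R))
    means = per_replicate[idx].mean(axis=1)
    if transform:
        means = transform(means)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def compute_metrics(results: list, replicates: list, n_boot: int = 10_000,
                    seed: int = 0, exclude_nonconverged: bool = True) -> pd.DataFrame:
    """The per-condition metric battery, pooled over items x replicates.

    Bias = mean(est - true); variance = mean(SE^2 or posterior variance);
    RMSE = sqrt(mean((est - true)^2)); coverage = fraction of intervals
    containing the truth; CI length mean and 5th/50th/95th percentiles.
    95% bootstrap CIs resample replicates with replacement.  Non-converged
    replicates are excluded when ``exclude_nonconverged``.
    """
    if len(results) != len(replicates) or len(results) < 1:
        raise ValueError("results and replicates must align")
    rng = np.random.default_rng(seed)
    keep = [i for i, res in enumerate(results)
            if res.converged or not exclude_nonconverged]
    rows = []
    for par in ("a", "d"):
        est = np.array([getattr(results[i], f"est_{par}") for i in keep])
        true = np.array([getattr(replicates[i], par) for i in keep])
        var = np.array([getattr(results[i], f"var_{par}") for i in keep])
        err = est - true
        per_rep_bias = err.mean(axis=1)
        per_rep_mse = (err**2).mean(axis=1)
        per_rep_var = np.nanmean(var, axis=1)
        bias = float(err.mean())
        rmse = float(np.sqrt((err**2).mean()))
        rows.append({"parameter": par, "metric": "bias", "value": bias,
                     **dict(zip(("ci_low", "ci_high"),
                                _bootstrap_ci(per_rep_bias, n_boot, rng)))})
        rows.append({"parameter": par, "metric": "variance",
                     "value": float(np.nanmean(var)),
                     **dict(zip(("ci_low", "ci_high"),
                                _bootstrap_ci(per_rep_var, n_boot, rng)))})
        rows.append({"parameter": par, "metric": "rmse", "value": rmse,
                     **dict(zip(("ci_low", "ci_high"),
                                _bootstrap_ci(per_rep_mse, n_boot, rng,
                                              transform=np.sqrt)))})
        itypes = results[keep[0]].intervals.keys()
        for itype in itypes:
            lo = np.array([results[i].intervals[itype][par][0] for i in keep])
            hi = np.array([results[i].intervals[itype][par][1] for i in keep])
            ok = ~(np.isnan(lo) | np.isnan(hi))
            length = hi - lo
            degenerate = bool(np.all(length[ok] == 0)) if ok.any() else True
            covered = (lo <= true) & (true <= hi)
            cov_pooled = float(covered[ok].mean()) if ok.any() else np.nan
            rows.append({"parameter": par, "metric": f"coverage_{itype}",
                         "value": np.nan if degenerate else cov_pooled,
                         "ci_low": np.nan, "ci_high": np.nan})
            rows.append({"parameter": par, "metric": f"length_{itype}_mean",
                         "value": float(np.nanmean(length)),
                         "ci_low": np.nan, "ci_high": np.nan})
            for q in (5, 50, 95):
                rows.append({"parameter": par,
                             "metric": f"length_{itype}_p{q}",
                             "value": float(np.nanpercentile(length, q)),
                             "ci_low": np.nan, "ci_high": np.nan})
        try:
            shr = shrinkage_regression(err, true)
        except ValueError:  # constant truths or a single replicate
            shr = {k: np.nan for k in ("slope", "se", "p", "ci_low",
                                       "ci_high", "r2")}
        for kname, v in shr.items():
            rows.append({"parameter": par, "metric": f"shrinkage_{kname}",
                         "value": v, "ci_low": np.nan, "ci_high": np.nan})
    df = pd.DataFrame(rows)
    df["n_replicates"] = len(keep)
    return df


def shrinkage_regression(errors: np.ndarray, truths: np.ndarray) -> dict:
    """Regression of estimation error on the centered population parameter.

    OLS of (est - true) on (true - grand mean) with intercept; standard
    errors are cluster-robust (CR1) with replicates as clusters.  A negative
    slope is the signature of shrinkage toward the prior mean.
    """
    import statsmodels.api as sm

    errors = np.atleast_2d(errors)
    truths = np.atleast_2d(truths)
    R = errors.shape[0]
    if R < 2:
        raise ValueError("need at least 2 replicate clusters")
    y = errors.ravel()
    x = (truths - truths.mean()).ravel()
    if np.all(x == x[0]):
        raise ValueError("constant regressor")
    clusters = np.repeat(np.arange(R), errors.shape[1])
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    rob = ols.get_robustcov_results(cov_type="cluster", groups=clusters)
    ci = rob.conf_int()[1]
    return {"slope": float(rob.params[1]), "se": float(rob.bse[1]),
            "p": float(rob.pvalues[1]), "ci_low": float(ci[0]),
            "ci_high": float(ci[1]), "r2": float(ols.rsquared)}


def eap_metrics(results: list, replicates: list, z: float = 1.96) -> dict:
    """EAP coverage and reliabilities, pooled over persons x replicates.

    Coverage: fraction of true traits inside EAP +/- z * posterior SD.
    Estimated reliability: variance of the EAP scores (trait variance fixed
    at 1), averaged over replicates.  True reliability: squared correlation
    of EAP scores with the generating traits, averaged over replicates.
    """
    cov_n = cov_hit = 0
    est_rel, true_rel = [], []
    for res, rep in zip(results, replicates):
        if res.eap is None:
            continue
        lo = res.eap - z * res.eap_sd
        hi = res.eap + z * res.eap_sd
        cov_hit += int(((rep.theta >= lo) & (rep.theta <= hi)).sum())
        cov_n += rep.theta.size
        est_rel.append(float(np.var(res.eap, ddof=1)))
        if np.std(res.eap) > 0:
            true_rel.append(float(np.corrcoef(res.eap, rep.theta)[0, 1] ** 2))
        else:
            true_rel.append(0.0)
    return {"coverage": cov_hit / cov_n if cov_n else np.nan,
            "reliability_estimated": float(np.mean(est_rel)) if est_rel else np.nan,
            "reliability_true": float(np.mean(true_rel)) if true_rel else np.nan}
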