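"""Estimator classes: the public fitting surface.

:class:`BayesianIRT` wraps the blocked random-walk Metropolis sampler with
automated convergence control; :class:`MarginalML2PL` wraps the Bock–Aitkin
EM fit.  Both follow scikit-learn conventions (constructor parameters are
configuration only, ``fit`` learns, fitted attributes carry a trailing
underscore) and compose with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import ResponseMatrix
from .diagnostics import ConvergenceConfig
from .ml import fit_em, wald_interval
from .model import ModelSpec, PriorConfig, difficulty_from_intercept
from .sampler import SamplerConfig, run_chunked
from .summaries import cpo_table, dic, eap_scores, hpd_interval, summarize

__all__ = ["BayesianIRT", "MarginalML2PL"]


def _as_response_matrix(X, id_column=None) -> ResponseMatrix:
    if isinstance(X, ResponseMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return ResponseMatrix.from_dataframe(X, id_column=id_column)
    return ResponseMatrix(np.asarray(X, dtype=float))


class BayesianIRT(BaseEstimator):
    """Hierarchical Bayesian uni-/multidimensional 1PL/2PL for binary items.

    Parameters
    ----------
    spec : ModelSpec or None
        Factor structure and constraints; None fits a unidimensional 2PL on
        all columns with the default single positivity constraint.
    priors : PriorConfig or None
        Hierarchical priors by default.
    sampler : SamplerConfig or None
        Burn-in, chunk length, tuning limits.
    convergence : ConvergenceConfig or None
        PSR / ESS stopping rule (default: all PSR < 1.1).
    alpha : float
        Credible-interval level for the summary table (default 0.05).
    ratio_cpo : float
        If > 0, fraction of second-half draws used to accumulate the CPO
        table (``cpo_`` fitted attribute).
    keep_person_draws : bool
        Store per-iteration person-parameter draws (needed for EAP scores
        and CPO).
    random_state : int, Generator or None

    Attributes
    ----------
    draws_ : PosteriorDraws
    report_ : ConvergenceReport
    summary_ : DataFrame (Parameter, Estimate, StdDev, constr, hprior,
        alpha, ETI/HPD bounds, PSR, converged)
    scores_ : PersonScores (EAP, posterior SD, EAP reliability)
    dic_ : float
    converged_ : bool
    state_ : ParameterState (for warm restarts)
    """

    def __init__(self, spec=None, priors=None, sampler=None, convergence=None,
                 alpha=0.05, ratio_cpo=0.0, keep_person_draws=True,
                 start_state=None, start_values=None, random_state=None):
        self.spec = spec
        self.priors = priors
        self.sampler = sampler
        self.convergence = convergence
        self.alpha = alpha
        self.ratio_cpo = ratio_cpo
        self.keep_person_draws = keep_person_draws
        self.start_state = start_state
        self.start_values = start_values
        self.random_state = random_state

    def fit(self, X, y=None):
        data = _as_response_matrix(X)
        spec = self.spec or ModelSpec(item_names=list(data.item_names))
        priors = self.priors or PriorConfig()
        sampler = self.sampler or SamplerConfig()
        convergence = self.convergence or ConvergenceConfig()
        keep_theta = self.keep_person_draws or self.ratio_cpo > 0
        draws, report, state = run_chunked(
            data, spec, priors, sampler, convergence,
            seed=self.random_state, start_state=self.start_state,
            overrides=self.start_values, keep_theta=keep_theta,
        )
        self.spec_ = spec
        self.priors_ = priors
        self.data_ = data
        self.draws_ = draws
        self.report_ = report
        self.state_ = state
        self.converged_ = report.converged
        self.n_iter_ = draws.n_kept * sampler.thin
        self.summary_ = summarize(draws, self.alpha, convergence)
        self.dic_ = dic(draws.second_half_loglik())
        if keep_theta:
            self.scores_ = eap_scores(draws.second_half_theta(), data.person_ids)
        if self.ratio_cpo > 0:
            self.cpo_ = cpo_table(data, spec, draws, self.ratio_cpo)
        return self

    def score_persons(self):
        """EAP person scores for the fitted data."""
        self._check_fitted()
        return self.scores_

    def difficulty_summary(self, convention: str = "d/a") -> pd.DataFrame:
        """Posterior summary of classical difficulties b = d/a
        (unidimensional 2PL only), computed per posterior draw."""
        self._check_fitted()
        if self.spec_.n_factors != 1 or self.spec_.model != "2PL":
            raise ValueError("difficulties are defined for unidimensional 2PL models")
        half = self.draws_.second_half()
        names = self.draws_.parameters
        rows = []
        for item in self.spec_.item_names:
            a = half[:, names.index(f"a_{item}_dim1")]
            d = half[:, names.index(f"d_{item}")]
            b = difficulty_from_intercept(d, a, convention)
            lo, hi = hpd_interval(b, self.alpha)
            rows.append({"item": item, "b": float(b.mean()),
                         "sd": float(b.std(ddof=1)),
                         "HPD_lower": lo, "HPD_upper": hi})
        return pd.DataFrame(rows)

    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise RuntimeError("estimator is not fitted")


class MarginalML2PL(BaseEstimator):
    """Frequentist comparator: marginal ML 2PL (logit link, intercept/slope
    parameterization) by EM with Gauss–Hermite quadrature.

    Attributes after ``fit``: ``slope_``, ``intercept_``, ``se_slope_``,
    ``se_intercept_``, ``converged_``, ``loglik_``, ``n_iter_``,
    ``loglik_path_`` (monotone up to the EM tolerance).
    """

    def __init__(self, quadrature_points=41, max_iter=1000, tol=1e-8,
                 compute_se=True):
        self.quadrature_points = quadrature_points
        self.max_iter = max_iter
        self.tol = tol
        self.compute_se = compute_se

    def fit(self, X, y=None):
        data = _as_response_matrix(X)
        res = fit_em(data, self.quadrature_points, self.max_iter, self.tol,
                     self.compute_se)
        self.fit_ = res
        self.item_names_ = res.item_names
        self.slope_ = res.slope
        self.intercept_ = res.intercept
        self.se_slope_ = res.se_slope
        self.se_intercept_ = res.se_intercept
        self.converged_ = res.converged
        self.loglik_ = res.loglik
        self.n_iter_ = res.n_iter
        self.loglik_path_ = res.loglik_path
        return self

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald intervals, estimate +/- z * SE."""
        if not hasattr(self, "fit_"):
            raise RuntimeError("estimator is not fitted")
        return wald_interval(self.fit_, level)
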