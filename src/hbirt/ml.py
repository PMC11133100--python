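"""Marginal maximum likelihood estimation of the unidimensional 2PL.

Bock–Aitkin EM with Gauss–Hermite quadrature over a standard-normal latent
trait.  The model uses the same intercept/slope parameterization as the
Bayesian sampler, p(y_j = 1 | theta) = logistic(a_j * theta - d_j), so
estimates are directly comparable.  Standard errors come from the observed
information of the marginal log-likelihood, obtained by central finite
differences of the analytic score (Fisher's identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .data import ResponseMatrix

__all__ = ["MLFit", "fit_em", "wald_interval"]

_P_EPS = 1e-12


@dataclass
class MLFit:
    item_names: list
    slope: np.ndarray
    intercept: np.ndarray
    se_slope: np.ndarray
    se_intercept: np.ndarray
    converged: bool
    loglik: float
    n_iter: int
    loglik_path: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "item": self.item_names,
            "a": self.slope, "se_a": self.se_slope,
            "d": self.intercept, "se_d": self.se_intercept,
        })


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Hermite nodes/weights transformed to the N(0,1) measure."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _item_prob(a, d, nodes):
    """p(y=1) at each node: items x nodes."""
    eta = np.outer(a, nodes) - d[:, None]
    return np.clip(expit(eta), _P_EPS, 1.0 - _P_EPS)


def _marginal_loglik_and_post(y, mask, a, d, nodes, logw):
    """Marginal log-likelihood and posterior node weights per person."""
    P = _item_prob(a, d, nodes)  # J x Q
    logP, log1mP = np.log(P), np.log1p(-P)
    # person x node log-likelihoods; missing cells contribute 0
    ll = (y * mask) @ logP + ((1.0 - y) * mask) @ log1mP  # N x Q
    ll = ll + logw
    m = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - m)
    tot = w.sum(axis=1, keepdims=True)
    marg = float((m[:, 0] + np.log(tot[:, 0])).sum())
    return marg, w / tot


def _score(y, mask, a, d, nodes, logw):
    """Analytic score of the marginal log-likelihood, order (a_1..a_J, d_1..d_J)."""
    P = _item_prob(a, d, nodes)
    _, W = _marginal_loglik_and_post(y, mask, a, d, nodes, logw)
    R = (y * mask).T @ W      # J x Q expected correct
    Nq = mask.T @ W           # J x Q expected exposure
    resid = R - Nq * P
    g_a = resid @ nodes
    g_d = -resid.sum(axis=1)
    return np.concatenate([g_a, g_d])


def fit_em(
    data: ResponseMatrix,
    quadrature_points: int = 41,
    max_iter: int = 1000,
    tol: float = 1e-8,
    compute_se: bool = True,
    newton_steps: int = 3,
    slope_bound: float = 10.0,
) -> MLFit:
    """Fit the 2PL by marginal ML (EM, Gauss–Hermite quadrature).

    Convergence is declared when successive marginal log-likelihoods differ
    by less than ``tol``.  The fit is flagged non-converged when
    ``max_iter`` is reached first, or when some slope exceeds
    ``slope_bound`` in absolute value: for quasi-separated items the
    marginal likelihood has no interior maximum and the slope drifts
    without bound, so no ML estimate exists (common in small samples;
    estimates are still returned).  A singular information matrix yields
    missing (NaN) standard errors.
    """
    const = data.constant_items()
    if const:
        raise ValueError(f"items without variability are inestimable: {const}")
    y = np.nan_to_num(data.values)
    mask = data.mask.astype(float)
    J = data.n_items
    nodes, wq = _gh_nodes(quadrature_points)
    logw = np.log(wq)
    a = np.ones(J)
    d = np.zeros(J)
    path = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        marg, W = _marginal_loglik_and_post(y, mask, a, d, nodes, logw)
        path.append(marg)
        if marg - prev < tol and it > 1:
            converged = True
            break
        prev = marg
        # M-step: per-item weighted logistic regressions on the node grid,
        # a few Newton steps each (items vectorized)
        R = (y * mask).T @ W
        Nq = mask.T @ W
        for _ in range(newton_steps):
            P = _item_prob(a, d, nodes)
            resid = R - Nq * P
            V = Nq * P * (1.0 - P)
            g_a = resid @ nodes
            g_d = -resid.sum(axis=1)
            h_aa = V @ (nodes**2)
            h_dd = V.sum(axis=1)
            h_ad = -(V @ nodes)
            det = h_aa * h_dd - h_ad**2
            det = np.where(np.abs(det) < 1e-12, np.nan, det)
            da = (h_dd * g_a - h_ad * g_d) / det
            dd = (h_aa * g_d - h_ad * g_a) / det
            step = np.sqrt(da**2 + dd**2)
            lim = np.where(step > 1.0, 1.0 / step, 1.0)  # damp huge steps
            a = a + np.nan_to_num(da * lim)
            d = d + np.nan_to_num(dd * lim)
    # align sign: the likelihood is invariant to flipping all slopes
    if a.mean() < 0:
        a, d = -a, -d
    if np.max(np.abs(a)) > slope_bound:
        converged = False
    loglik, _ = _marginal_loglik_and_post(y, mask, a, d, nodes, logw)
    se_a = np.full(J, np.nan)
    se_d = np.full(J, np.nan)
    if compute_se:
        info = _observed_information(y, mask, a, d, nodes, logw)
        try:
            cov = np.linalg.inv(info)
            var = np.diag(cov)
            if np.all(var > 0):
                se = np.sqrt(var)
                se_a, se_d = se[:J], se[J:]
        except np.linalg.LinAlgError:
            pass
    return MLFit(
        item_names=list(data.item_names),
        slope=a, intercept=d, se_slope=se_a, se_intercept=se_d,
        converged=converged, loglik=loglik, n_iter=it,
        loglik_path=np.asarray(path),
    )


def _observed_information(y, mask, a, d, nodes, logw, h: float = 1e-5) -> np.ndarray:
    """Observed information: minus the central-difference Jacobian of the
    analytic score, symmetrized."""
    J = a.size
    p0 = np.concatenate([a, d])
    n = p0.size
    H = np.empty((n, n))
    for k in range(n):
        pp, pm = p0.copy(), p0.copy()
        pp[k] += h
        pm[k] -= h
        gp = _score(y, mask, pp[:J], pp[J:], nodes, logw)
        gm = _score(y, mask, pm[:J], pm[J:], nodes, logw)
        H[:, k] = (gp - gm) / (2.0 * h)
    return -0.5 * (H + H.T)


def wald_interval(fit: MLFit, level: float = 0.95):
    """Wald confidence intervals, estimate +/- z * SE; missing SEs give
    missing bounds."""
    import pandas as pd

    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    for j, item in enumerate(fit.item_names):
        for pname, est, se in (
            ("a", fit.slope[j], fit.se_slope[j]),
            ("d", fit.intercept[j], fit.se_intercept[j]),
        ):
            rows.append({
                "item": item, "parameter": pname, "estimate": est, "se": se,
                "lower": est - z * se, "upper": est + z * se,
            })
    return pd.DataFrame(rows)
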