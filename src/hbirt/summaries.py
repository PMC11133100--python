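"""Posterior summaries: parameter tables, credible intervals, person
scores, EAP reliability, and the DIC / CPO model-comparison indices.

All summaries are computed from the second half of the total kept chain;
the first half is always treated as additional burn-in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ResponseMatrix
from .diagnostics import ConvergenceConfig, stopping_decision
from .model import ModelSpec, inverse_link
from .sampler import PosteriorDraws

__all__ = [
    "equal_tail_interval",
    "hpd_interval",
    "summarize",
    "eap_scores",
    "PersonScores",
    "dic",
    "cpo",
    "cpo_table",
]


def equal_tail_interval(draws: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Equal-tail credible interval: the (alpha/2, 1 - alpha/2) empirical
    quantiles with linear interpolation of order statistics."""
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0], method="linear")
    return float(lo), float(hi)


def hpd_interval(draws: np.ndarray, alpha: float = 0.05, grid: int = 201) -> tuple[float, float]:
    """Highest-posterior-density interval via the empirical quantile function.

    The shortest interval [Q(t), Q(t + 1 - alpha)] is searched over a grid of
    lower-tail probabilities t in [0, alpha] that includes t = alpha/2, so by
    construction the HPD interval is never longer than the equal-tail one.
    """
    draws = np.sort(np.asarray(draws, dtype=float))
    t = np.linspace(0.0, alpha, grid)
    t = np.union1d(t, [alpha / 2.0])
    lo = np.quantile(draws, t, method="linear")
    hi = np.quantile(draws, t + (1.0 - alpha), method="linear")
    k = int(np.argmin(hi - lo))
    return float(lo[k]), float(hi[k])


def summarize(draws: PosteriorDraws, alpha: float = 0.05,
              convergence: ConvergenceConfig | None = None) -> pd.DataFrame:
    """Posterior summary table from the second half of the kept chain.

    Columns follow the estimation-output layout: Parameter, Estimate
    (posterior mean), StdDev, constr, hprior, alpha, equal-tail bounds
    (ETI_lower/ETI_upper), HPD bounds (HPD_lower/HPD_upper), PSR, converged.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    half = draws.second_half()
    if half.shape[0] < 10:
        raise ValueError("fewer than 10 draws in the second half of the chain")
    convergence = convergence or ConvergenceConfig()
    report = stopping_decision(draws.matrix, draws.parameters, convergence)
    rows = []
    for k, name in enumerate(draws.parameters):
        col = half[:, k]
        eti = equal_tail_interval(col, alpha)
        hpd = hpd_interval(col, alpha)
        rows.append({
            "Parameter": name,
            "Estimate": float(col.mean()),
            "StdDev": float(col.std(ddof=1)),
            "constr": draws.constr[k] if draws.constr else "",
            "hprior": draws.hprior[k] if draws.hprior else "",
            "alpha": alpha,
            "ETI_lower": eti[0],
            "ETI_upper": eti[1],
            "HPD_lower": hpd[0],
            "HPD_upper": hpd[1],
            "PSR": float(report.psr[k]),
            "converged": int(report.converged),
        })
    return pd.DataFrame(rows)


class PersonScores:
    """EAP person scores: per person x factor posterior mean and SD, plus the
    per-factor EAP reliability (variance of the EAP scores, with the latent
    trait variance fixed at 1)."""

    def __init__(self, eap: np.ndarray, post_sd: np.ndarray, reliability: np.ndarray,
                 person_ids=None):
        self.eap = np.atleast_2d(eap)
        self.post_sd = np.atleast_2d(post_sd)
        self.reliability = np.atleast_1d(reliability)
        self.person_ids = list(person_ids) if person_ids is not None else list(
            range(1, self.eap.shape[0] + 1))

    def to_frame(self) -> pd.DataFrame:
        n, F = self.eap.shape
        df = pd.DataFrame({"id": self.person_ids})
        for f in range(F):
            df[f"eap_dim{f + 1}"] = self.eap[:, f]
            df[f"sd_dim{f + 1}"] = self.post_sd[:, f]
        for f in range(F):
            df[f"reliability_dim{f + 1}"] = self.reliability[f]
        return df


def eap_scores(theta_draws: np.ndarray, person_ids=None) -> PersonScores:
    """EAP estimates from second-half theta draws (iterations x N x F).

    Reliability per factor is the between-person variance of the EAP scores;
    because the population trait variance is fixed at 1 this underestimates
    the trait variance by (1 - reliability).
    """
    theta_draws = np.asarray(theta_draws, dtype=float)
    if theta_draws.ndim == 2:
        theta_draws = theta_draws[:, :, None]
    eap = theta_draws.mean(axis=0)
    sd = theta_draws.std(axis=0, ddof=1) if theta_draws.shape[0] > 1 else np.zeros_like(eap)
    rel = eap.var(axis=0, ddof=1) if eap.shape[0] > 1 else np.zeros(eap.shape[1])
    return PersonScores(eap, sd, rel, person_ids)


def dic(loglik_draws: np.ndarray) -> float:
    """Deviance information criterion,
    -2 * mean(loglik) + 2 * var(loglik), from per-iteration joint
    log-likelihood draws (sample variance with divisor n - 1)."""
    x = np.asarray(loglik_draws, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 log-likelihood draws")
    return float(-2.0 * x.mean() + 2.0 * x.var(ddof=1))


def cpo(likelihood_draws: np.ndarray) -> np.ndarray:
    """Conditional predictive ordinate: harmonic mean of per-draw cell
    likelihoods.  ``likelihood_draws`` is draws x cells; zero likelihoods
    are clamped to 1e-300 before inverting."""
    L = np.asarray(likelihood_draws, dtype=float)
    if L.ndim == 1:
        L = L[:, None]
    L = np.clip(L, 1e-300, None)
    return 1.0 / (1.0 / L).mean(axis=0)


def cpo_table(data: ResponseMatrix, spec: ModelSpec, draws: PosteriorDraws,
              ratio_cpo: float = 1.0) -> pd.DataFrame:
    """Item-level and total log-CPO from stored posterior draws.

    Cell likelihoods are recomputed on the fly from the second-half item and
    person draws (memory stays O(draws x parameters)); ``ratio_cpo`` in
    (0, 1] subsamples that fraction of the second-half iterations.  Missing
    cells are skipped.  The table has one row per item (n, logCPO) and a
    TOTAL row whose logCPO is the log pseudo-marginal likelihood (LPML).
    """
    if not 0.0 < ratio_cpo <= 1.0:
        raise ValueError("ratio_cpo must be in (0, 1]")
    if draws.theta is None:
        raise ValueError("person draws were not stored; cannot compute CPO")
    half_n = draws.n_kept // 2
    idx = np.arange(half_n, draws.n_kept)
    if ratio_cpo < 1.0:
        step = max(int(round(1.0 / ratio_cpo)), 1)
        idx = idx[::step]
    J, F = spec.n_items, spec.n_factors
    y = np.nan_to_num(data.values)
    mask = data.mask
    inv_sum = np.zeros((data.n_persons, J))
    names = draws.parameters
    if spec.model == "1PL":
        a_cols = [names.index(f"a_dim{f + 1}") for f in range(F)]
    d_cols = [names.index(f"d_{item}") for item in spec.item_names]
    for t in idx:
        if spec.model == "1PL":
            a = np.where(spec.loading_pattern, draws.matrix[t, a_cols], 0.0)
        else:
            a = np.zeros((J, F))
            k = 0
            for j, item in enumerate(spec.item_names):
                for f in range(F):
                    if spec.loading_pattern[j, f]:
                        a[j, f] = draws.matrix[t, k]
                        k += 1
        d = draws.matrix[t, d_cols]
        theta = draws.theta[t]
        p = inverse_link(theta @ a.T - d, spec.link)
        lik = np.where(mask, y * p + (1.0 - y) * (1.0 - p), 1.0)
        inv_sum += 1.0 / np.clip(lik, 1e-300, None)
    cpo_cells = idx.size / inv_sum
    log_cpo = np.where(mask, np.log(cpo_cells), 0.0)
    rows = []
    for j, item in enumerate(spec.item_names):
        rows.append({"item": item, "n": int(mask[:, j].sum()),
                     "logCPO": float(log_cpo[:, j].sum())})
    rows.append({"item": "TOTAL", "n": int(mask.sum()),
                 "logCPO": float(log_cpo.sum())})
    return pd.DataFrame(rows)
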