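"""Posterior simulation for the M2PL family.

Blocked random-walk Metropolis (RWM) with normal proposals:

* one block per person for the latent traits theta_i (all person blocks are
  conditionally independent given the item parameters, so they are proposed
  and accepted in parallel),
* one block per item for (a_j., d_j), likewise updated in parallel,
* scalar blocks for each hyperparameter and each free correlation
  regression, with an exact conjugate draw for the intercept-prior variance
  when its hyperprior is inverse gamma.

Positivity constraints are enforced through the prior (zero density below
zero, i.e. such proposals are rejected), matching a truncated-normal prior.
Proposal scales are tuned multiplicatively toward a target acceptance band
before burn-in; the chain then runs in chunks, with the stopping rule
evaluated on the second half of the total kept chain after every chunk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .data import ResponseMatrix
from .diagnostics import ConvergenceConfig, ConvergenceReport, stopping_decision
from .factors import correlation_from_regressions, regressions_from_target, theta_logpdf_rows
from .model import ModelSpec, ParameterState, PriorConfig, inverse_link

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "initialize_state",
    "two_stage_start",
    "run_chunked",
]

_ACC_TARGET = 0.35
_ACC_BAND = (0.25, 0.50)
_ADAPT_C = 1.0


@dataclass
class SamplerConfig:
    """Iteration counts and tuning limits.

    ``nbi`` burn-in iterations precede the first chunk; the chain then runs
    in chunks of ``iterationsteps`` kept (pre-thinning) iterations up to
    ``maxnmc`` post-burn-in iterations.  ``maxtune`` / ``ntu`` control
    proposal tuning for user-constant priors, ``hmaxtune`` / ``hntu`` for
    hierarchical priors.
    """

    nbi: int = 5000
    maxnmc: int = 100_000
    iterationsteps: int = 5000
    thin: int = 1
    maxtune: int = 100
    hmaxtune: int = 100
    ntu: int = 500
    hntu: int = 500
    seed: int | None = None

    def __post_init__(self):
        for name in ("nbi", "maxnmc", "maxtune", "hmaxtune", "ntu", "hntu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.thin < 1 or self.iterationsteps < 1:
            raise ValueError("thin and iterationsteps must be >= 1")

    def replace(self, **kw) -> "SamplerConfig":
        return replace(self, **kw)


@dataclass
class PosteriorDraws:
    """Kept draws of all monitored parameters, chunk-wise bookkeeping, and
    the per-iteration joint log-likelihood and person-parameter draws."""

    parameters: list
    matrix: np.ndarray  # kept iterations x parameters
    nbi: int
    thin: int = 1
    chunk_bounds: list = field(default_factory=list)
    acceptance: dict = field(default_factory=dict)
    constr: list = field(default_factory=list)
    hprior: list = field(default_factory=list)
    loglik: np.ndarray | None = None
    theta: np.ndarray | None = None  # kept iterations x persons x factors

    @property
    def n_kept(self) -> int:
        return self.matrix.shape[0]

    def second_half(self) -> np.ndarray:
        return self.matrix[self.n_kept // 2:]

    def second_half_loglik(self) -> np.ndarray:
        return self.loglik[self.n_kept // 2:]

    def second_half_theta(self) -> np.ndarray:
        return self.theta[self.n_kept // 2:]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.parameters.index(name)]

    def concat(self, other: "PosteriorDraws") -> "PosteriorDraws":
        """Stack the draws of a warm-restarted continuation run."""
        if other.parameters != self.parameters:
            raise ValueError("parameter sets differ; cannot concatenate")
        return PosteriorDraws(
            parameters=self.parameters,
            matrix=np.vstack([self.matrix, other.matrix]),
            nbi=self.nbi,
            thin=self.thin,
            chunk_bounds=self.chunk_bounds
            + [b + self.n_kept for b in other.chunk_bounds],
            acceptance=other.acceptance,
            constr=self.constr,
            hprior=self.hprior,
            loglik=None if self.loglik is None else np.concatenate([self.loglik, other.loglik]),
            theta=None if self.theta is None else np.concatenate([self.theta, other.theta]),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.parameters)
        if self.loglik is not None:
            df["loglik"] = self.loglik
        return df


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------


def _initial_beta(spec: ModelSpec) -> np.ndarray:
    F = spec.n_factors
    free = spec.covar.free_mask(F)
    beta = np.zeros((F, F))
    if spec.covar.starts:
        R0 = spec.covar.start_correlation(F)
        zero = np.zeros((F, F), dtype=bool)
        zero[np.tril_indices(F, k=-1)] = True
        zero &= ~free
        beta = regressions_from_target(R0, zero_pattern=zero)
    return beta


def parameter_names(spec: ModelSpec, priors: PriorConfig) -> tuple[list, list, list]:
    """Monitored parameter names with constraint / hierarchical markers."""
    names, constr, hprior = [], [], []
    if spec.model == "1PL":
        for f in range(spec.n_factors):
            names.append(f"a_dim{f + 1}")
            constr.append(">")
            hprior.append("")
    else:
        for j, item in enumerate(spec.item_names):
            for f in range(spec.n_factors):
                if spec.loading_pattern[j, f]:
                    names.append(f"a_{item}_dim{f + 1}")
                    constr.append(">" if spec.positivity[j, f] else "")
                    hp = priors.priors == "hierarchical" and spec.slope_set[j, f] > 0
                    hprior.append("y" if hp else "")
    for j, item in enumerate(spec.item_names):
        names.append(f"d_{item}")
        constr.append("")
        hprior.append("y" if priors.priors == "hierarchical" and spec.intercept_hier[j] else "")
    if priors.priors == "hierarchical" and spec.model == "2PL":
        for s in range(1, spec.n_slope_sets + 1):
            names += [f"mua{s}", f"vara{s}"]
            constr += ["", ""]
            hprior += ["", ""]
        if spec.intercept_hier.any():
            names += ["mud", "vard"]
            constr += ["", ""]
            hprior += ["", ""]
    free = spec.covar.free_mask(spec.n_factors)
    for f in range(spec.n_factors):
        for g in range(f):
            if free[f, g]:
                names.append(f"r{g + 1}_{f + 1}")
                constr.append("")
                hprior.append("")
    return names, constr, hprior


def initialize_state(spec: ModelSpec, priors: PriorConfig, n_persons: int,
                     overrides: dict | None = None) -> ParameterState:
    """Default starting values: a = 1 on loading positions, d = 0, theta = 0,
    correlations at their declared starting values (otherwise 0), and
    hyperparameters at deterministic points of their hyperpriors (mean of the
    support for uniforms, mode for the inverse gamma).  ``overrides`` is a
    name -> value table that wins over the defaults."""
    J, F = spec.n_items, spec.n_factors
    a = np.where(spec.loading_pattern, 1.0, 0.0)
    d = np.zeros(J)
    theta = np.zeros((n_persons, F))
    S = spec.n_slope_sets
    all_constr = bool(np.all(spec.positivity[spec.loading_pattern]))
    mu_a = np.array(
        [priors.mu_a_hyperprior(all_constr).initial_value() for _ in range(max(S, 1))]
    )
    var_a = np.array(
        [max(priors.hyperprior_var_a.initial_value(), 1e-3) for _ in range(max(S, 1))]
    )
    mu_d = priors.hyperprior_mu_d.initial_value()
    var_d = max(priors.hyperprior_var_d.initial_value(), 1e-3)
    beta = _initial_beta(spec)
    state = ParameterState(a, d, theta, mu_a, var_a, mu_d, var_d, beta)
    if overrides:
        names, _, _ = parameter_names(spec, priors)
        free = spec.covar.free_mask(F)
        r_over = {}
        slope_index = {}
        for j, item in enumerate(spec.item_names):
            for f in range(F):
                if spec.loading_pattern[j, f]:
                    slope_index[f"a_{item}_dim{f + 1}"] = (j, f)
        for name, value in overrides.items():
            value = float(value)
            if name in slope_index:
                j, f = slope_index[name]
                if spec.positivity[j, f] and value < 0:
                    raise ValueError(
                        f"override {name}={value} violates the positivity constraint"
                    )
                state.a[j, f] = value
            elif name.startswith("d_") and name[2:] in spec.item_names:
                state.d[spec.item_names.index(name[2:])] = value
            elif name == "mud":
                state.mu_d = value
            elif name == "vard":
                if value <= 0:
                    raise ValueError("vard must be positive")
                state.var_d = value
            elif name.startswith("mua") and name[3:].isdigit():
                state.mu_a[int(name[3:]) - 1] = value
            elif name.startswith("vara") and name[4:].isdigit():
                if value <= 0:
                    raise ValueError(f"{name} must be positive")
                state.var_a[int(name[4:]) - 1] = value
            elif name.startswith("r") and name in names:
                g, f = (int(t) - 1 for t in name[1:].split("_"))
                r_over[(f, g)] = value
            elif name not in names:
                raise ValueError(f"override for unknown parameter {name!r}")
        if r_over:
            R0 = spec.covar.start_correlation(F)
            for (f, g), r in r_over.items():
                R0[f, g] = R0[g, f] = r
            zero = np.zeros((F, F), dtype=bool)
            zero[np.tril_indices(F, k=-1)] = True
            zero &= ~free
            state.beta = regressions_from_target(R0, zero_pattern=zero)
        state.validate(spec)
    return state


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class _Sampler:
    """Mutable sampling machinery for one chain."""

    def __init__(self, data: ResponseMatrix, spec: ModelSpec, priors: PriorConfig,
                 state: ParameterState, rng: np.random.Generator):
        self.spec = spec
        self.priors = priors
        self.rng = rng
        self.y = np.nan_to_num(data.values)
        self.mask = data.mask.astype(float)
        self.state = state.copy()
        J, F = spec.n_items, spec.n_factors
        self.J, self.F, self.N = J, F, data.n_persons
        self.load = spec.loading_pattern
        self.pos = spec.positivity
        self.sets = spec.slope_set
        self.S = spec.n_slope_sets
        self.hier = priors.priors == "hierarchical" and spec.model == "2PL"
        self.hier_d = self.hier and spec.intercept_hier.any()
        self.all_constr = bool(np.all(self.pos[self.load]))
        free = spec.covar.free_mask(F)
        self.beta_free = [(f, g) for f in range(F) for g in range(f) if free[f, g]]
        # conjugate sampling for var_d only with an inverse-gamma hyperprior
        self.conj_vard = self.hier_d and priors.hyperprior_var_d.family == "invgamma"
        self.scales = self._default_scales()
        self.reset_counters()
        self.eta = self.state.theta @ self.state.a.T - self.state.d

    # -- bookkeeping --------------------------------------------------------

    def _default_scales(self) -> dict:
        sc = {"theta": np.full(self.N, 0.5), "item": np.full(self.J, 0.3)}
        if self.spec.model == "1PL":
            sc["slope"] = np.full(self.F, 0.2)
        if self.hier:
            sc["mu_a"] = np.full(self.S, 0.2)
            sc["var_a"] = np.full(self.S, 0.1)
            if self.hier_d:
                sc["mu_d"] = np.full(1, 0.2)
                if not self.conj_vard:
                    sc["var_d"] = np.full(1, 0.1)
        if self.beta_free:
            sc["beta"] = np.full(len(self.beta_free), 0.2)
        return sc

    def reset_counters(self):
        self.acc = {k: np.zeros_like(v) for k, v in self.scales.items()}
        self.n_sweeps = 0

    def acceptance_rates(self) -> dict:
        n = max(self.n_sweeps, 1)
        return {k: v / n for k, v in self.acc.items()}

    # -- densities ----------------------------------------------------------

    def _cell_loglik_cols(self, eta: np.ndarray) -> np.ndarray:
        """Per-item column sums of the observed-cell log-likelihood."""
        p = inverse_link(eta, self.spec.link)
        ll = self.mask * (self.y * np.log(p) + (1.0 - self.y) * np.log1p(-p))
        return ll.sum(axis=0)

    def _cell_loglik_rows(self, eta: np.ndarray) -> np.ndarray:
        p = inverse_link(eta, self.spec.link)
        ll = self.mask * (self.y * np.log(p) + (1.0 - self.y) * np.log1p(-p))
        return ll.sum(axis=1)

    def _slope_prior_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Current prior mean/variance for each slope position (J x F)."""
        pr = self.priors
        M = np.full((self.J, self.F), pr.prior_mean_a)
        V = np.full((self.J, self.F), pr.prior_var_a)
        if self.hier:
            hier_pos = self.sets > 0
            idx = np.clip(self.sets - 1, 0, None)
            M = np.where(hier_pos, self.state.mu_a[idx], M)
            V = np.where(hier_pos, self.state.var_a[idx], V)
        return M, V

    def _intercept_prior_moments(self) -> tuple[np.ndarray, np.ndarray]:
        pr = self.priors
        m = np.full(self.J, pr.prior_mean_d)
        v = np.full(self.J, pr.prior_var_d)
        if self.hier_d:
            m = np.where(self.spec.intercept_hier, self.state.mu_d, m)
            v = np.where(self.spec.intercept_hier, self.state.var_d, v)
        return m, v

    def _item_log_prior(self, a: np.ndarray, d: np.ndarray) -> np.ndarray:
        """Per-item log prior (truncation normalizer omitted: constant in the
        item block).  -inf where a positivity constraint is violated."""
        M, V = self._slope_prior_moments()
        lp_a = np.where(self.load, -0.5 * ((a - M) ** 2 / V + np.log(V)), 0.0)
        lp = lp_a.sum(axis=1)
        md, vd = self._intercept_prior_moments()
        lp = lp - 0.5 * ((d - md) ** 2 / vd + np.log(vd))
        bad = (self.pos & (a < 0)).any(axis=1)
        return np.where(bad, -np.inf, lp)

    def _theta_log_prior(self, theta: np.ndarray) -> np.ndarray:
        return theta_logpdf_rows(theta, self.state.beta)

    def _slope_set_loglik(self, s: int, mu: float, var: float) -> float:
        """log p(slopes in set s | mu, var) including the truncated-normal
        normalizer at constrained positions (it depends on mu, var)."""
        if var <= 0:
            return -np.inf
        in_set = self.sets == s
        vals = self.state.a[in_set]
        n = vals.size
        ll = -0.5 * (((vals - mu) ** 2).sum() / var + n * math.log(var))
        n_constr = int((in_set & self.pos).sum())
        if n_constr:
            ll -= n_constr * log_ndtr(mu / math.sqrt(var))
        return float(ll)

    def _intercept_set_loglik(self, mu: float, var: float) -> float:
        if var <= 0:
            return -np.inf
        vals = self.state.d[self.spec.intercept_hier]
        return float(-0.5 * (((vals - mu) ** 2).sum() / var + vals.size * math.log(var)))

    # -- sweep --------------------------------------------------------------

    def sweep(self):
        st = self.state
        rng = self.rng

        # (i) person blocks, in parallel
        prop = st.theta + self.scales["theta"][:, None] * rng.standard_normal((self.N, self.F))
        eta_prop = prop @ st.a.T - st.d
        logr = (
            self._cell_loglik_rows(eta_prop) + self._theta_log_prior(prop)
            - self._cell_loglik_rows(self.eta) - self._theta_log_prior(st.theta)
        )
        acc = np.log(rng.random(self.N)) < logr
        st.theta[acc] = prop[acc]
        self.eta[acc] = eta_prop[acc]
        self.acc["theta"] += acc

        # (ii) item blocks, in parallel
        if self.spec.model == "2PL":
            sc = self.scales["item"]
            a_prop = st.a + np.where(self.load, sc[:, None] * rng.standard_normal((self.J, self.F)), 0.0)
            d_prop = st.d + sc * rng.standard_normal(self.J)
            eta_prop = st.theta @ a_prop.T - d_prop
            col_cur = self._cell_loglik_cols(self.eta)
            col_prop = self._cell_loglik_cols(eta_prop)
            logr = (col_prop + self._item_log_prior(a_prop, d_prop)
                    - col_cur - self._item_log_prior(st.a, st.d))
            acc = np.log(rng.random(self.J)) < logr
            st.a[acc] = a_prop[acc]
            st.d[acc] = d_prop[acc]
            self.eta = np.where(acc, eta_prop, self.eta)
            self.acc["item"] += acc
            self._loglik = float(np.where(acc, col_prop, col_cur).sum())
        else:
            # 1PL: intercept-only item blocks, then one shared slope per factor
            sc = self.scales["item"]
            d_prop = st.d + sc * rng.standard_normal(self.J)
            eta_prop = self.eta - (d_prop - st.d)
            col_cur = self._cell_loglik_cols(self.eta)
            col_prop = self._cell_loglik_cols(eta_prop)
            logr = (col_prop + self._item_log_prior(st.a, d_prop)
                    - col_cur - self._item_log_prior(st.a, st.d))
            acc = np.log(rng.random(self.J)) < logr
            st.d[acc] = d_prop[acc]
            self.eta = np.where(acc, eta_prop, self.eta)
            self.acc["item"] += acc
            cur_total = float(np.where(acc, col_prop, col_cur).sum())
            for f in range(self.F):
                a_f = st.a[self.load[:, f], f][0] if self.load[:, f].any() else 1.0
                a_f_prop = a_f + self.scales["slope"][f] * rng.standard_normal()
                if a_f_prop < 0:  # truncated normal prior: N+(mu*, var*)
                    continue
                a_new = st.a.copy()
                a_new[self.load[:, f], f] = a_f_prop
                eta_prop = st.theta @ a_new.T - st.d
                prop_total = float(self._cell_loglik_cols(eta_prop).sum())
                pr = self.priors
                lp = -0.5 * (a_f_prop - pr.prior_mean_a) ** 2 / pr.prior_var_a
                lp_cur = -0.5 * (a_f - pr.prior_mean_a) ** 2 / pr.prior_var_a
                if math.log(rng.random()) < prop_total + lp - cur_total - lp_cur:
                    st.a = a_new
                    self.eta = eta_prop
                    cur_total = prop_total
                    self.acc["slope"][f] += 1
            self._loglik = cur_total

        # (iii) hyperparameters
        if self.hier:
            for s in range(1, self.S + 1):
                k = s - 1
                set_constr = self.all_constr
                hp_mu = self.priors.mu_a_hyperprior(set_constr)
                mu, var = float(st.mu_a[k]), float(st.var_a[k])
                cur = self._slope_set_loglik(s, mu, var) + hp_mu.logpdf(mu)
                mu_p = mu + self.scales["mu_a"][k] * rng.standard_normal()
                lp = hp_mu.logpdf(mu_p)
                if lp > -np.inf:
                    prop_t = self._slope_set_loglik(s, mu_p, var) + lp
                    if math.log(rng.random()) < prop_t - cur:
                        st.mu_a[k] = mu_p
                        mu = mu_p
                        cur = prop_t
                        self.acc["mu_a"][k] += 1
                hp_var = self.priors.hyperprior_var_a
                cur = self._slope_set_loglik(s, mu, var) + hp_var.logpdf(var)
                var_p = var + self.scales["var_a"][k] * rng.standard_normal()
                lp = hp_var.logpdf(var_p) if var_p > 0 else -np.inf
                if lp > -np.inf:
                    prop_t = self._slope_set_loglik(s, mu, var_p) + lp
                    if math.log(rng.random()) < prop_t - cur:
                        st.var_a[k] = var_p
                        self.acc["var_a"][k] += 1
            if self.hier_d:
                hp = self.priors.hyperprior_mu_d
                mu, var = float(st.mu_d), float(st.var_d)
                cur = self._intercept_set_loglik(mu, var) + hp.logpdf(mu)
                mu_p = mu + self.scales["mu_d"][0] * rng.standard_normal()
                lp = hp.logpdf(mu_p)
                if lp > -np.inf:
                    prop_t = self._intercept_set_loglik(mu_p, var) + lp
                    if math.log(rng.random()) < prop_t - cur:
                        st.mu_d = mu_p
                        self.acc["mu_d"][0] += 1
                if self.conj_vard:
                    st.var_d = self._draw_var_d_conjugate()
                else:
                    hp_v = self.priors.hyperprior_var_d
                    var = float(st.var_d)
                    cur = self._intercept_set_loglik(st.mu_d, var) + hp_v.logpdf(var)
                    var_p = var + self.scales["var_d"][0] * rng.standard_normal()
                    lp = hp_v.logpdf(var_p) if var_p > 0 else -np.inf
                    if lp > -np.inf:
                        prop_t = self._intercept_set_loglik(st.mu_d, var_p) + lp
                        if math.log(rng.random()) < prop_t - cur:
                            st.var_d = var_p
                            self.acc["var_d"][0] += 1

        # (iv) correlation regressions
        if self.beta_free:
            cur_rows = self._theta_log_prior(st.theta).sum()
            for k, (f, g) in enumerate(self.beta_free):
                b = st.beta[f, g]
                b_p = b + self.scales["beta"][k] * rng.standard_normal()
                beta_old = st.beta[f, g]
                st.beta[f, g] = b_p
                prop_rows = self._theta_log_prior(st.theta).sum()
                if self.priors.rdist:
                    vb = self.priors.var_beta
                    logr = (prop_rows - 0.5 * b_p**2 / vb) - (cur_rows - 0.5 * b**2 / vb)
                else:
                    logr = prop_rows - cur_rows
                if math.log(rng.random()) < logr:
                    cur_rows = prop_rows
                    self.acc["beta"][k] += 1
                else:
                    st.beta[f, g] = beta_old

        self.n_sweeps += 1

    def _draw_var_d_conjugate(self) -> float:
        """Exact inverse-gamma full-conditional draw for the intercept-prior
        variance: IG(alpha + J_h/2, beta + 0.5 * sum (d_j - mu_d)^2)."""
        alpha, beta = self.priors.hyperprior_var_d.params
        vals = self.state.d[self.spec.intercept_hier]
        a_post = alpha + 0.5 * vals.size
        b_post = beta + 0.5 * float(((vals - self.state.mu_d) ** 2).sum())
        g = self.rng.gamma(a_post)
        # tiny shapes (e.g. IG(0.01, 0.01) with no items) can underflow to 0
        return float(b_post / max(g, 1e-300))

    # -- tuning -------------------------------------------------------------

    def tune(self, max_loops: int, ntu: int) -> int:
        """Adapt proposal scales toward the target acceptance band.

        Runs up to ``max_loops`` loops of ``ntu`` sweeps; after each loop
        every scale is multiplied by exp(c * (acc - target)); stops early
        once all acceptance rates sit inside the band.  Draws are discarded
        and the scales are frozen afterwards.  Returns loops used.
        """
        loops = 0
        for loop in range(max_loops):
            self.reset_counters()
            for _ in range(ntu):
                self.sweep()
            rates = self.acceptance_rates()
            loops = loop + 1
            inside = all(
                np.all((r >= _ACC_BAND[0]) & (r <= _ACC_BAND[1]))
                for r in rates.values()
            )
            if inside:
                break
            for k, r in rates.items():
                self.scales[k] = self.scales[k] * np.exp(_ADAPT_C * (r - _ACC_TARGET))
        self.reset_counters()
        return loops

    # -- recording ----------------------------------------------------------

    def monitored_values(self) -> np.ndarray:
        st = self.state
        out = []
        if self.spec.model == "1PL":
            for f in range(self.F):
                out.append(st.a[self.load[:, f], f][0])
        else:
            out.extend(st.a[self.load].ravel())
        out.extend(st.d)
        if self.hier:
            for k in range(self.S):
                out += [st.mu_a[k], st.var_a[k]]
            if self.hier_d:
                out += [st.mu_d, st.var_d]
        if self.beta_free:
            R = correlation_from_regressions(st.beta)
            for (f, g) in self.beta_free:
                out.append(R[f, g])
        return np.array(out)


# ---------------------------------------------------------------------------
# driver operations
# ---------------------------------------------------------------------------


def two_stage_start(data: ResponseMatrix, spec: ModelSpec, priors: PriorConfig,
                    config: SamplerConfig, rng: np.random.Generator) -> ParameterState:
    """Starting values for hierarchical models via a stage-one fit.

    A short chain (``nbi`` burn-in plus one ``iterationsteps`` chunk) is run
    with the user-constant priors; its final state seeds the main chain and
    the hyperparameters are initialized at the empirical mean/variance of the
    stage-one item-parameter posterior means.
    """
    if priors.priors != "hierarchical":
        raise ValueError("two-stage start applies to hierarchical priors")
    stage1_priors = priors.replace(priors="user")
    state0 = initialize_state(spec, stage1_priors, data.n_persons)
    smp = _Sampler(data, spec, stage1_priors, state0, rng)
    smp.tune(config.maxtune, config.ntu)
    for _ in range(config.nbi):
        smp.sweep()
    keep = []
    smp.reset_counters()
    for _ in range(config.iterationsteps):
        smp.sweep()
        keep.append(smp.monitored_values())
    if np.all(smp.acc["item"] == 0):
        raise RuntimeError("stage-one chain degenerate: all item proposals rejected")
    keep = np.asarray(keep)
    names, _, _ = parameter_names(spec, stage1_priors)
    means = dict(zip(names, keep.mean(axis=0)))
    state = smp.state.copy()
    # hyperparameter starts from the stage-one item-parameter estimates
    for s in range(1, spec.n_slope_sets + 1):
        vals = [
            means[f"a_{item}_dim{f + 1}"]
            for j, item in enumerate(spec.item_names)
            for f in range(spec.n_factors)
            if spec.loading_pattern[j, f] and spec.slope_set[j, f] == s
        ]
        state.mu_a[s - 1] = float(np.mean(vals))
        state.var_a[s - 1] = max(float(np.var(vals, ddof=1)) if len(vals) > 1 else 0.1, 1e-3)
    if spec.intercept_hier.any():
        vals = [means[f"d_{item}"] for j, item in enumerate(spec.item_names)
                if spec.intercept_hier[j]]
        state.mu_d = float(np.mean(vals))
        state.var_d = max(float(np.var(vals, ddof=1)) if len(vals) > 1 else 0.1, 1e-3)
    return state


def tune_proposals(data: ResponseMatrix, spec: ModelSpec, priors: PriorConfig,
                   state: ParameterState, config: SamplerConfig,
                   rng: np.random.Generator) -> dict:
    """Stand-alone proposal tuning; returns the tuned per-block scales."""
    smp = _Sampler(data, spec, priors, state, rng)
    max_loops = config.hmaxtune if priors.priors == "hierarchical" else config.maxtune
    ntu = config.hntu if priors.priors == "hierarchical" else config.ntu
    smp.tune(max_loops, ntu)
    return smp.scales


def run_chunked(
    data: ResponseMatrix,
    spec: ModelSpec,
    priors: PriorConfig,
    config: SamplerConfig | None = None,
    convergence: ConvergenceConfig | None = None,
    seed=None,
    start_state: ParameterState | None = None,
    overrides: dict | None = None,
    keep_theta: bool = True,
) -> tuple[PosteriorDraws, ConvergenceReport, ParameterState]:
    """Run the chunked chain with automated convergence control.

    Burn-in (``nbi`` sweeps) precedes the first chunk.  After every chunk of
    ``iterationsteps`` sweeps the stopping rule is evaluated on the second
    half of the total kept chain; the run stops on convergence or once
    ``maxnmc`` post-burn-in sweeps are reached (then flagged
    ``converged=False``).  With both criteria disabled exactly one chunk is
    run.  The final state is returned for warm restarts; draws of successive
    runs can be stacked with :meth:`PosteriorDraws.concat`.
    """
    config = config or SamplerConfig()
    convergence = convergence or ConvergenceConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else config.seed
    )
    const = data.constant_items()
    if const:
        raise ValueError(
            f"items without variability are inestimable: {const}; drop them explicitly"
        )
    if start_state is not None:
        state = start_state.copy()
    elif priors.priors == "hierarchical" and spec.model == "2PL" and not (
        overrides and _covers_all(overrides, spec, priors)
    ):
        state = two_stage_start(data, spec, priors, config, rng)
        if overrides:
            state = _apply_overrides(state, spec, priors, overrides)
    else:
        state = initialize_state(spec, priors, data.n_persons, overrides)

    smp = _Sampler(data, spec, priors, state, rng)
    hier = priors.priors == "hierarchical"
    smp.tune(config.hmaxtune if hier else config.maxtune,
             config.hntu if hier else config.ntu)
    for _ in range(config.nbi):
        smp.sweep()
    smp.reset_counters()

    names, constr, hprior = parameter_names(spec, priors)
    rows, logliks, thetas = [], [], []
    chunk_bounds = []
    report = None
    post_iters = 0
    while True:
        n_this = min(config.iterationsteps, max(config.maxnmc - post_iters, 0))
        if n_this == 0:
            break
        for it in range(n_this):
            smp.sweep()
            post_iters += 1
            if post_iters % config.thin == 0:
                rows.append(smp.monitored_values())
                logliks.append(smp._loglik)
                if keep_theta:
                    thetas.append(smp.state.theta.copy())
        chunk_bounds.append(len(rows))
        matrix = np.asarray(rows)
        if convergence.any_enabled:
            report = stopping_decision(matrix, names, convergence)
            if report.converged:
                break
            if post_iters >= config.maxnmc:
                break
        else:
            # fixed-length run: one chunk, no stopping evaluation
            report = stopping_decision(matrix, names, convergence)
            break

    matrix = np.asarray(rows)
    draws = PosteriorDraws(
        parameters=names,
        matrix=matrix,
        nbi=config.nbi,
        thin=config.thin,
        chunk_bounds=chunk_bounds,
        acceptance=smp.acceptance_rates(),
        constr=constr,
        hprior=hprior,
        loglik=np.asarray(logliks),
        theta=np.asarray(thetas) if keep_theta else None,
    )
    return draws, report, smp.state.copy()


def _covers_all(overrides: dict, spec: ModelSpec, priors: PriorConfig) -> bool:
    names, _, _ = parameter_names(spec, priors)
    r_names = [n for n in names if n.startswith("r")]
    needed = set(names) - set(r_names)
    return needed.issubset(set(overrides))


def _apply_overrides(state: ParameterState, spec: ModelSpec, priors: PriorConfig,
                     overrides: dict) -> ParameterState:
    base = initialize_state(spec, priors, state.theta.shape[0], overrides)
    out = state.copy()
    names = set(overrides)
    for j, item in enumerate(spec.item_names):
        for f in range(spec.n_factors):
            if f"a_{item}_dim{f + 1}" in names:
                out.a[j, f] = base.a[j, f]
        if f"d_{item}" in names:
            out.d[j] = base.d[j]
    for s in range(1, spec.n_slope_sets + 1):
        if f"mua{s}" in names:
            out.mu_a[s - 1] = base.mu_a[s - 1]
        if f"vara{s}" in names:
            out.var_a[s - 1] = base.var_a[s - 1]
    if "mud" in names:
        out.mu_d = base.mu_d
    if "vard" in names:
        out.var_d = base.var_d
    return out
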