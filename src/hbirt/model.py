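"""Model core for the multidimensional two-parameter logistic (M2PL) family.

The item response function is parameterized on the intercept/slope scale,

    p(y_ij = 1) = link^{-1}( -d_j + sum_f a_jf * theta_if ),

so that with a positive slope a larger intercept d_j lowers the probability
of a correct response.  The classical difficulty of item j in unidimensional
models is recovered as b_j = d_j / a_j.

This module holds the in-memory model types (:class:`ModelSpec`,
:class:`PriorConfig`, :class:`ParameterState`), the link functions, the joint
log-likelihood over a :class:`~hbirt.data.ResponseMatrix` (missing cells
skipped, MAR), and the logit<->probit prior rescaling helper.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, ndtr

from .data import ResponseMatrix
from .factors import CovarSpec

__all__ = [
    "LOGISTIC_VARIANCE",
    "DistSpec",
    "ModelSpec",
    "PriorConfig",
    "ParameterState",
    "inverse_link",
    "response_probability",
    "joint_log_likelihood",
    "loglik_matrix",
    "rescale_priors_logit_to_probit",
    "difficulty_from_intercept",
]

#: Variance of the standard logistic distribution, pi^2 / 3.
LOGISTIC_VARIANCE = math.pi**2 / 3.0

# Probabilities are clamped away from {0, 1} before taking logs: random-walk
# proposals are unbounded and would otherwise produce -inf log-likelihoods.
_P_EPS = 1e-12


# ---------------------------------------------------------------------------
# hyperprior distribution mini-specs
# ---------------------------------------------------------------------------

_DIST_RE = re.compile(r"^\s*([a-zA-Z_\-]+)\s*\((.*)\)\s*$")


@dataclass(frozen=True)
class DistSpec:
    """A univariate hyperprior distribution.

    Supported families: ``uniform(a, b)``, ``invgamma(shape, scale)``,
    ``exponential(iscale)`` (rate parameterization) and
    ``half-cauchy(loc, scale)``.
    """

    family: str
    params: tuple

    @classmethod
    def parse(cls, text: str) -> "DistSpec":
        m = _DIST_RE.match(text)
        if not m:
            raise ValueError(f"cannot parse distribution spec {text!r}")
        fam = m.group(1).lower().replace("_", "-")
        raw = [p.strip() for p in m.group(2).split(",") if p.strip()]
        kw = {}
        pos = []
        for p in raw:
            if "=" in p:
                k, v = p.split("=", 1)
                kw[k.strip().lower()] = float(v)
            else:
                pos.append(float(p))
        if fam in ("uniform", "unif", "u"):
            a, b = pos
            if not b > a:
                raise ValueError("uniform needs upper > lower")
            return cls("uniform", (a, b))
        if fam in ("invgamma", "igamma", "ig", "inverse-gamma"):
            shape, scale = pos
            if shape <= 0 or scale <= 0:
                raise ValueError("invgamma needs positive shape and scale")
            return cls("invgamma", (shape, scale))
        if fam in ("exponential", "expon", "exp"):
            iscale = kw.get("iscale", pos[0] if pos else None)
            if iscale is None or iscale <= 0:
                raise ValueError("exponential needs a positive inverse scale")
            return cls("exponential", (iscale,))
        if fam in ("half-cauchy", "halfcauchy", "cauchy"):
            loc = pos[0] if pos else 0.0
            scale = pos[1] if len(pos) > 1 else 1.0
            lower = kw.get("lower", 0.0)
            if scale <= 0:
                raise ValueError("half-cauchy needs positive scale")
            return cls("half-cauchy", (loc, scale, lower))
        raise ValueError(f"unknown distribution family {fam!r}")

    @property
    def support(self) -> tuple[float, float]:
        if self.family == "uniform":
            return self.params
        if self.family == "half-cauchy":
            return (self.params[2], np.inf)
        return (0.0, np.inf)

    def logpdf(self, x: float) -> float:
        lo, hi = self.support
        if x <= lo or x >= hi:
            # uniform includes endpoints; treat open at both ends for safety
            if not (lo < x < hi):
                return -np.inf
        if self.family == "uniform":
            a, b = self.params
            return -math.log(b - a)
        if self.family == "invgamma":
            shape, scale = self.params
            return (
                shape * math.log(scale)
                - math.lgamma(shape)
                - (shape + 1) * math.log(x)
                - scale / x
            )
        if self.family == "exponential":
            (rate,) = self.params
            return math.log(rate) - rate * x
        if self.family == "half-cauchy":
            loc, scale, _ = self.params
            z = (x - loc) / scale
            return math.log(2.0 / (math.pi * scale)) - math.log1p(z * z)
        raise AssertionError(self.family)

    def initial_value(self) -> float:
        """Deterministic starting value: mean of the support for uniforms,
        mode for the inverse gamma, mean for the exponential, and the scale
        for the half-Cauchy (whose mean does not exist)."""
        if self.family == "uniform":
            a, b = self.params
            return 0.5 * (a + b)
        if self.family == "invgamma":
            shape, scale = self.params
            return scale / (shape + 1.0)
        if self.family == "exponential":
            return 1.0 / self.params[0]
        if self.family == "half-cauchy":
            return self.params[0] + self.params[1]
        raise AssertionError(self.family)

    def __str__(self) -> str:  # round-trippable through parse()
        return f"{self.family}({', '.join(repr(p) for p in self.params)})"


def _as_dist(x) -> DistSpec:
    return x if isinstance(x, DistSpec) else DistSpec.parse(x)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Factor structure, loading pattern, constraints, and prior-set labels.

    Attributes
    ----------
    item_names : list of str, length J.
    n_factors : int
    loading_pattern : (J, F) bool; item j loads on factor f.
    slope_set : (J, F) int
        Hierarchical slope-prior set label (1..S) at loading positions,
        0 for an item-specific (non-hierarchical) prior, -1 off-pattern.
    positivity : (J, F) bool; slope constrained positive.
    intercept_hier : (J,) bool; item intercept under the hierarchical prior.
    model : "1PL" or "2PL"; under 1PL all slopes on a factor are equal.
    link : "logit" or "probit".
    covar : CovarSpec for the factor correlation structure.
    """

    item_names: list
    n_factors: int = 1
    loading_pattern: np.ndarray = None
    slope_set: np.ndarray = None
    positivity: np.ndarray = None
    intercept_hier: np.ndarray = None
    model: str = "2PL"
    link: str = "logit"
    covar: CovarSpec = field(default_factory=CovarSpec)

    def __post_init__(self):
        J, F = len(self.item_names), self.n_factors
        if J < 1 or F < 1:
            raise ValueError("need at least one item and one factor")
        if self.loading_pattern is None:
            self.loading_pattern = np.ones((J, F), dtype=bool)
        self.loading_pattern = np.asarray(self.loading_pattern, dtype=bool)
        if self.loading_pattern.shape != (J, F):
            raise ValueError("loading_pattern must be J x F")
        if self.slope_set is None:
            self.slope_set = np.where(self.loading_pattern, 1, -1)
        self.slope_set = np.asarray(self.slope_set, dtype=int)
        if self.positivity is None:
            self.positivity = np.zeros((J, F), dtype=bool)
            for f in range(F):
                loaders = np.nonzero(self.loading_pattern[:, f])[0]
                if loaders.size:
                    self.positivity[loaders[0], f] = True
        self.positivity = np.asarray(self.positivity, dtype=bool)
        if self.intercept_hier is None:
            self.intercept_hier = np.ones(J, dtype=bool)
        self.intercept_hier = np.asarray(self.intercept_hier, dtype=bool)
        if self.model not in ("1PL", "2PL"):
            raise ValueError("model must be 1PL or 2PL")
        if self.link not in ("logit", "probit"):
            raise ValueError("link must be logit or probit")
        for f in range(F):
            if not self.loading_pattern[:, f].any():
                raise ValueError(f"factor {f + 1} has no loading item")
            if self.model == "2PL" and not (
                self.positivity[:, f] & self.loading_pattern[:, f]
            ).any():
                raise ValueError(
                    f"factor {f + 1} needs at least one positivity-constrained loading"
                )
        if (self.positivity & ~self.loading_pattern).any():
            raise ValueError("positivity constraint at a non-loading position")
        if ((self.slope_set >= 0) != self.loading_pattern).any():
            raise ValueError("slope_set labels must cover exactly the loading pattern")
        self.covar.validate(F)

    @property
    def n_items(self) -> int:
        return len(self.item_names)

    @property
    def n_slope_sets(self) -> int:
        """Number of hierarchical slope-prior sets S."""
        m = int(self.slope_set.max(initial=0))
        return max(m, 0)

    def slope_names(self) -> list[str]:
        out = []
        for j, name in enumerate(self.item_names):
            for f in range(self.n_factors):
                if self.loading_pattern[j, f]:
                    out.append(f"a_{name}_dim{f + 1}")
        return out

    def replace(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


@dataclass
class PriorConfig:
    """Priors and hyperpriors for item parameters.

    With ``priors="hierarchical"`` the normal priors for slopes and
    intercepts get hyperparameters with their own hyperpriors; with
    ``priors="user"`` the constants ``prior_mean_*`` / ``prior_var_*`` are
    used directly.  Excluded items (slope_set 0 / intercept_hier False) use
    the constants in either case.
    """

    priors: str = "hierarchical"
    prior_mean_a: float = 0.0
    prior_var_a: float = 4.0
    prior_mean_d: float = 0.0
    prior_var_d: float = 4.0
    hyperprior_mu_a: DistSpec = "uniform(-6, 6)"
    hyperprior_mu_a_ge0: DistSpec = "uniform(0, 6)"
    hyperprior_mu_d: DistSpec = "uniform(-6, 6)"
    hyperprior_var_a: DistSpec = "invgamma(0.01, 0.01)"
    hyperprior_var_d: DistSpec = "invgamma(0.01, 0.01)"
    muaconstr: bool = False
    var_beta: float = 1.0
    rdist: bool = True  # False: improper flat priors on the correlation regressions

    def __post_init__(self):
        if self.priors not in ("hierarchical", "user"):
            raise ValueError("priors must be 'hierarchical' or 'user'")
        for v in (self.prior_var_a, self.prior_var_d, self.var_beta):
            if v <= 0:
                raise ValueError("variances must be positive")
        for f in ("hyperprior_mu_a", "hyperprior_mu_a_ge0", "hyperprior_mu_d",
                  "hyperprior_var_a", "hyperprior_var_d"):
            setattr(self, f, _as_dist(getattr(self, f)))
        if self.hyperprior_mu_a_ge0.support[0] < 0:
            raise ValueError("hyperprior_mu_a_ge0 must exclude negative values")

    def mu_a_hyperprior(self, constrained: bool) -> DistSpec:
        """Hyperprior for a slope-set mean; the positive-support variant is
        used when the mean itself or all slopes are constrained positive."""
        return self.hyperprior_mu_a_ge0 if (constrained or self.muaconstr) else self.hyperprior_mu_a

    def replace(self, **kw) -> "PriorConfig":
        return replace(self, **kw)


@dataclass
class ParameterState:
    """One point in parameter space: all sampled quantities.

    ``a`` is J x F with zeros off the loading pattern; ``beta`` holds the
    strictly-lower-triangular regression coefficients that generate the
    factor correlation matrix.
    """

    a: np.ndarray
    d: np.ndarray
    theta: np.ndarray
    mu_a: np.ndarray
    var_a: np.ndarray
    mu_d: float
    var_d: float
    beta: np.ndarray

    def copy(self) -> "ParameterState":
        return ParameterState(
            self.a.copy(), self.d.copy(), self.theta.copy(),
            self.mu_a.copy(), self.var_a.copy(),
            float(self.mu_d), float(self.var_d), self.beta.copy(),
        )

    def validate(self, spec: ModelSpec) -> None:
        J, F = spec.n_items, spec.n_factors
        if self.a.shape != (J, F) or self.d.shape != (J,):
            raise ValueError("item-parameter dimensions do not match the spec")
        if self.theta.shape[1] != F:
            raise ValueError("theta has wrong number of factors")
        if np.any(self.a[spec.positivity] < 0):
            raise ValueError("positivity constraint violated")
        if np.any(self.var_a <= 0) or self.var_d <= 0:
            raise ValueError("hyper-variances must be positive")


# ---------------------------------------------------------------------------
# link functions and likelihood
# ---------------------------------------------------------------------------


def inverse_link(eta, link: str = "logit"):
    """Map the linear predictor to a probability, clamped inside (0, 1)."""
    eta = np.asarray(eta, dtype=float)
    if link == "logit":
        p = expit(eta)
    elif link == "probit":
        p = ndtr(eta)
    else:
        raise ValueError(f"unknown link {link!r}")
    return np.clip(p, _P_EPS, 1.0 - _P_EPS)


def response_probability(theta_row, a_row, d, link: str = "logit"):
    """p(y = 1 | theta) = link^{-1}(-d + a . theta)."""
    theta_row = np.asarray(theta_row, dtype=float)
    a_row = np.asarray(a_row, dtype=float)
    return inverse_link(-float(d) + a_row @ theta_row, link)


def loglik_matrix(data: ResponseMatrix, state: ParameterState, spec: ModelSpec) -> np.ndarray:
    """Per-cell log-likelihood, 0 at missing cells."""
    eta = state.theta @ state.a.T - state.d
    p = inverse_link(eta, spec.link)
    y = data.values
    out = np.where(data.mask, np.nan_to_num(y) * np.log(p) + np.nan_to_num(1.0 - y) * np.log1p(-p), 0.0)
    return out


def joint_log_likelihood(data: ResponseMatrix, state: ParameterState, spec: ModelSpec) -> float:
    """Sum of y log p + (1 - y) log(1 - p) over all observed cells."""
    if state.theta.shape[0] != data.n_persons or state.a.shape[0] != data.n_items:
        raise ValueError("state dimensions do not match the data")
    return float(loglik_matrix(data, state, spec).sum())


def rescale_priors_logit_to_probit(mean: float, var: float) -> tuple[float, float]:
    """Rescale a logit-metric normal prior to the probit metric.

    The logistic distribution has variance pi^2/3, the standard normal 1, so
    means divide by sqrt(pi^2/3) and variances by pi^2/3.
    """
    if var <= 0:
        raise ValueError("variance must be positive")
    return mean / math.sqrt(LOGISTIC_VARIANCE), var / LOGISTIC_VARIANCE


def difficulty_from_intercept(d, a, convention: str = "d/a"):
    """Convert intercepts to classical difficulties, b = d / a.

    Some of the IRT literature defines b = -d / a instead; pass
    ``convention="-d/a"`` for that sign.  Apply per posterior draw: the
    posterior mean of b is the mean of per-draw ratios, not the ratio of the
    posterior means.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a == 0):
        raise ValueError("difficulty undefined for zero slope")
    b = np.asarray(d, dtype=float) / a
    if convention == "-d/a":
        return -b
    if convention != "d/a":
        raise ValueError("convention must be 'd/a' or '-d/a'")
    return b
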