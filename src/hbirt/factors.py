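"""Latent-factor correlation structure via a regression parameterization.

Correlation matrices for the person parameters are generated from
strictly-lower-triangular regression coefficients ``beta``:

    theta_1 = e_1,
    theta_f = sum_{g<f} beta_fg * theta_g + e_f,   e_f ~ N(0, 1) independent,

with every theta_f rescaled to unit variance.  Any real-valued ``beta``
therefore maps to a positive-definite correlation matrix with unit diagonal,
which is what makes the construction convenient for random-walk sampling.
Free coefficients get independent N(0, var_beta) priors; coefficients of
pairs constrained to zero are fixed at 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "CovarSpec",
    "correlation_from_regressions",
    "regressions_from_target",
    "theta_logpdf_rows",
]

_PAIR_RE = re.compile(r"^(\d+)#(\d+)(?:\[(-?[0-9.]+)\])?$")


@dataclass
class CovarSpec:
    """Which factor correlations are free, with optional starting values.

    ``mode`` is one of ``"free"`` (all pairs estimated), ``"diagonal"``
    (identity correlation matrix), or ``"pairs"`` (only the listed pairs
    free).  Pairs are stored 0-based as (low, high); optional starting
    correlations come from the ``"1#2[0.5]"`` syntax.
    """

    mode: str = "free"
    pairs: list = field(default_factory=list)
    starts: dict = field(default_factory=dict)

    @classmethod
    def parse(cls, text: str) -> "CovarSpec":
        text = text.strip()
        if text in ("free", ""):
            return cls("free")
        if text == "diagonal":
            return cls("diagonal")
        pairs, starts = [], {}
        for tok in text.split():
            m = _PAIR_RE.match(tok)
            if not m:
                raise ValueError(f"malformed covar pair {tok!r}")
            f, g = int(m.group(1)) - 1, int(m.group(2)) - 1
            if f == g or f < 0 or g < 0:
                raise ValueError(f"covar pair must reference distinct factors: {tok!r}")
            lo, hi = min(f, g), max(f, g)
            if (lo, hi) in pairs:
                raise ValueError(f"duplicate covar pair {tok!r}")
            pairs.append((lo, hi))
            if m.group(3) is not None:
                r = float(m.group(3))
                if not -1.0 < r < 1.0:
                    raise ValueError("starting correlation must be in (-1, 1)")
                starts[(lo, hi)] = r
        return cls("pairs", pairs, starts)

    def __str__(self) -> str:
        if self.mode != "pairs":
            return self.mode
        toks = []
        for (lo, hi) in self.pairs:
            s = f"{lo + 1}#{hi + 1}"
            if (lo, hi) in self.starts:
                s += f"[{self.starts[(lo, hi)]}]"
            toks.append(s)
        return " ".join(toks)

    def validate(self, n_factors: int) -> None:
        if self.mode not in ("free", "diagonal", "pairs"):
            raise ValueError(f"unknown covar mode {self.mode!r}")
        for (lo, hi) in self.pairs:
            if hi >= n_factors:
                raise ValueError(f"covar pair references factor {hi + 1} > {n_factors}")
        if self.mode == "pairs" or self.starts:
            R = self.start_correlation(n_factors)
            if np.linalg.eigvalsh(R).min() <= 0:
                raise ValueError("starting correlation matrix is not positive definite")

    def free_mask(self, n_factors: int) -> np.ndarray:
        """Strictly-lower-triangular bool mask of free beta coefficients."""
        mask = np.zeros((n_factors, n_factors), dtype=bool)
        if self.mode == "free":
            mask[np.tril_indices(n_factors, k=-1)] = True
        elif self.mode == "pairs":
            for (lo, hi) in self.pairs:
                mask[hi, lo] = True
        return mask

    def start_correlation(self, n_factors: int) -> np.ndarray:
        """Correlation matrix implied by the starting values (zeros elsewhere)."""
        R = np.eye(n_factors)
        for (lo, hi), r in self.starts.items():
            R[lo, hi] = R[hi, lo] = r
        return R


def correlation_from_regressions(beta: np.ndarray) -> np.ndarray:
    """Map strictly-lower-triangular regressions to a correlation matrix.

    Positive definite with unit diagonal for every finite ``beta``.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    F = beta.shape[0]
    if beta.shape != (F, F):
        raise ValueError("beta must be square")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta entries must be finite")
    R = np.eye(F)
    for f in range(1, F):
        b = beta[f, :f]
        sub = R[:f, :f]
        cov = sub @ b
        var = b @ cov + 1.0
        R[f, :f] = R[:f, f] = cov / np.sqrt(var)
    return R


def regressions_from_target(R_target: np.ndarray, zero_pattern: np.ndarray | None = None) -> np.ndarray:
    """Invert :func:`correlation_from_regressions` for a target matrix.

    Solved row by row: with the first f factors already reproducing the
    target, the correlations of factor f+1 are linear in its regression row,
    up to the unit-variance rescaling.  Positions flagged in ``zero_pattern``
    (strictly-lower bool) are held at beta = 0 and only the free positions
    are matched.

    Raises if the target is not positive definite or the zero pattern makes
    the requested correlations unattainable.
    """
    R_target = np.asarray(R_target, dtype=float)
    F = R_target.shape[0]
    if R_target.shape != (F, F) or not np.allclose(R_target, R_target.T):
        raise ValueError("target must be a symmetric correlation matrix")
    if not np.allclose(np.diag(R_target), 1.0):
        raise ValueError("target must have unit diagonal")
    if np.linalg.eigvalsh(R_target).min() <= 0:
        raise ValueError("target correlation matrix is not positive definite")
    if zero_pattern is None:
        zero_pattern = np.zeros((F, F), dtype=bool)
    beta = np.zeros((F, F))
    R = np.eye(F)  # correlations realized so far
    for f in range(1, F):
        free = np.nonzero(~zero_pattern[f, :f])[0]
        if free.size:
            sub = R[np.ix_(free, free)]
            c = R_target[f, free]
            u = np.linalg.solve(sub, c)
            quad = float(u @ sub @ u)
            if quad >= 1.0:
                raise ValueError(
                    "requested correlations unattainable under the zero pattern"
                )
            beta[f, free] = u / np.sqrt(1.0 - quad)
        # realized correlations for this row (zero-pattern positions may be
        # non-zero only through indirect paths; exact for fully-fixed rows)
        b = beta[f, :f]
        cov = R[:f, :f] @ b
        var = b @ cov + 1.0
        R[f, :f] = R[:f, f] = cov / np.sqrt(var)
    return beta


def theta_logpdf_rows(theta: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Per-person log-density of theta rows under N(0, R(beta)).

    One F x F Cholesky per call; the per-person work is a triangular solve.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    F = theta.shape[1]
    if F == 1:
        return -0.5 * (np.log(2.0 * np.pi) + theta[:, 0] ** 2)
    R = correlation_from_regressions(beta)
    L = np.linalg.cholesky(R)
    z = solve_triangular(L, theta.T, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (F * np.log(2.0 * np.pi) + logdet + (z**2).sum(axis=0))
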