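"""Single-chain convergence diagnostics: PSR, ESS, and the stopping rule.

The potential scale reduction (PSR) is computed from a single
chain: the second half of the total chain is split into contiguous
pseudo-chains and the between/within variance ratio is formed as
PSR = sqrt((W + B) / W).  The effective sample size (ESS) uses the
initial-positive-sequence truncation of the autocorrelation sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConvergenceConfig", "ConvergenceReport", "psr", "ess", "stopping_decision"]


@dataclass
class ConvergenceConfig:
    """Stopping rule: all monitored PSR < ``psr_conv`` (when > 0) and all
    monitored ESS >= ``ess_conv`` (when > 0).  Setting a cutoff to 0 disables
    that criterion; with both at 0 the sampler runs a fixed length."""

    psr_conv: float = 1.1
    ess_conv: float = 0.0
    n_pseudo_chains: int = 2

    def __post_init__(self):
        if self.psr_conv < 0 or self.ess_conv < 0:
            raise ValueError("cutoffs must be >= 0")
        if self.n_pseudo_chains < 2:
            raise ValueError("need at least 2 pseudo-chains")

    @property
    def any_enabled(self) -> bool:
        return self.psr_conv > 0 or self.ess_conv > 0


@dataclass
class ConvergenceReport:
    parameters: list
    psr: np.ndarray
    ess: np.ndarray | None
    converged: bool
    iterations: int
    degenerate: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"Parameter": self.parameters, "PSR": self.psr})
        if self.ess is not None:
            df["ESS"] = self.ess
        df["converged"] = int(self.converged)
        return df


def psr(draws: np.ndarray, n_chains: int = 2) -> float:
    """Potential scale reduction from one chain split into pseudo-chains.

    ``draws`` should already be the portion of the chain to diagnose (the
    caller passes the second half of the total chain).  A constant chain has
    zero within-variance and is reported as 1 by convention.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 draws")
    n = (x.size // n_chains) * n_chains
    chains = x[x.size - n:].reshape(n_chains, -1)
    W = chains.var(axis=1, ddof=1).mean()
    B = chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0
    return float(np.sqrt((W + B) / W))


def ess(draws: np.ndarray, max_lag: int | None = None) -> float:
    """Effective sample size n / (1 + 2 * sum of autocorrelations).

    The autocorrelation sum is truncated by Geyer's initial-positive-sequence
    rule: consecutive lag pairs are summed and the sum stops at the first
    non-positive pair.  Anticorrelated chains can yield ESS > n.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws")
    x = x - x.mean()
    var = x @ x / n
    if var == 0.0:
        return float(n)
    if max_lag is None:
        max_lag = n - 1
    # FFT autocovariance
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence on pairs (rho_{2m-1} + rho_{2m})
    s = 0.0
    m = 1
    while m + 1 <= max_lag:
        pair = rho[m] + rho[m + 1]
        if pair <= 0.0:
            break
        s += pair
        m += 2
    denom = 1.0 + 2.0 * s
    if denom <= 0.0:
        denom = 1.0 / n  # pathological anticorrelation; cap at n^2 scale
    return float(n / denom)


def second_half(x: np.ndarray) -> np.ndarray:
    """The second half of a chain (along axis 0)."""
    n = x.shape[0]
    return x[n // 2:]


def stopping_decision(draw_matrix: np.ndarray, parameters: list,
                      config: ConvergenceConfig) -> ConvergenceReport:
    """Evaluate the stopping rule on the second half of the supplied chain.

    ``draw_matrix`` is iterations x parameters (the full kept chain); the
    diagnostics are computed from its second half.  Deterministic.
    """
    draw_matrix = np.atleast_2d(np.asarray(draw_matrix, dtype=float))
    if draw_matrix.size == 0:
        raise ValueError("empty draw matrix")
    half = second_half(draw_matrix)
    P = draw_matrix.shape[1]
    psr_vals = np.empty(P)
    degenerate = np.zeros(P, dtype=bool)
    for p in range(P):
        col = half[:, p]
        if np.all(col == col[0]):
            degenerate[p] = True
        psr_vals[p] = psr(col, config.n_pseudo_chains)
    ess_vals = None
    ok = True
    if config.psr_conv > 0:
        ok = ok and bool(np.all(psr_vals < config.psr_conv))
    if config.ess_conv > 0:
        ess_vals = np.array([ess(half[:, p]) for p in range(P)])
        ok = ok and bool(np.all(ess_vals >= config.ess_conv))
    if not config.any_enabled:
        ok = False  # fixed-length run: never report early convergence
    return ConvergenceReport(
        parameters=list(parameters),
        psr=psr_vals,
        ess=ess_vals,
        converged=ok,
        iterations=draw_matrix.shape[0],
        degenerate=degenerate,
    )
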