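"""CSV input/output.

Responses are read from wide rectangular CSV files (one row per person, an
ID column, 0/1/blank item columns).  Output tables copy the estimation
output's column naming (Parameter, Estimate, constr, hprior, alpha,
ETI/HPD bounds, PSR, converged) so results can be compared side by side.
A warm-restart state table is a two-column CSV (Parameter, Value).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .data import ResponseMatrix
from .model import ModelSpec, ParameterState, PriorConfig
from .sampler import PosteriorDraws

__all__ = [
    "read_responses",
    "write_outputs",
    "write_state",
    "read_state",
]


def read_responses(path, id_column: str | None = "id") -> ResponseMatrix:
    """Read a wide response CSV; blank/NA cells become missing.

    ``id_column=None`` treats every column as an item.
    """
    df = pd.read_csv(path)
    if id_column is not None and id_column not in df.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    return ResponseMatrix.from_dataframe(df, id_column=id_column)


def write_outputs(prefix, summary: pd.DataFrame | None = None,
                  draws: PosteriorDraws | None = None,
                  eap: pd.DataFrame | None = None,
                  cpo: pd.DataFrame | None = None,
                  convergence_log: str | None = None) -> dict:
    """Write the output tables under a common path prefix; returns the map
    of written files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = {}
    if summary is not None:
        p = prefix.with_name(prefix.name + "_summary.csv")
        summary.to_csv(p, index=False)
        written["summary"] = p
    if draws is not None:
        p = prefix.with_name(prefix.name + "_outpost.csv")
        draws.to_frame().to_csv(p, index=False)
        written["outpost"] = p
    if eap is not None:
        p = prefix.with_name(prefix.name + "_eap.csv")
        eap.to_csv(p, index=False)
        written["eap"] = p
    if cpo is not None:
        p = prefix.with_name(prefix.name + "_cpo.csv")
        cpo.to_csv(p, index=False)
        written["cpo"] = p
    if convergence_log is not None:
        p = prefix.with_name(prefix.name + "_convergence.log")
        p.write_text(convergence_log)
        written["log"] = p
    return written


def write_state(path, state: ParameterState, spec: ModelSpec,
                priors: PriorConfig) -> None:
    """Export the final sampler state for warm restarts (Parameter, Value)."""
    from .factors import correlation_from_regressions

    rows = []
    if spec.model == "1PL":
        for f in range(spec.n_factors):
            col = spec.loading_pattern[:, f]
            rows.append((f"a_dim{f + 1}", float(state.a[col, f][0])))
    else:
        for j, item in enumerate(spec.item_names):
            for f in range(spec.n_factors):
                if spec.loading_pattern[j, f]:
                    rows.append((f"a_{item}_dim{f + 1}", float(state.a[j, f])))
    for j, item in enumerate(spec.item_names):
        rows.append((f"d_{item}", float(state.d[j])))
    if priors.priors == "hierarchical" and spec.model == "2PL":
        for s in range(1, spec.n_slope_sets + 1):
            rows.append((f"mua{s}", float(state.mu_a[s - 1])))
            rows.append((f"vara{s}", float(state.var_a[s - 1])))
        if spec.intercept_hier.any():
            rows.append(("mud", float(state.mu_d)))
            rows.append(("vard", float(state.var_d)))
    free = spec.covar.free_mask(spec.n_factors)
    if free.any():
        R = correlation_from_regressions(state.beta)
        for f in range(spec.n_factors):
            for g in range(f):
                if free[f, g]:
                    rows.append((f"r{g + 1}_{f + 1}", float(R[f, g])))
    pd.DataFrame(rows, columns=["Parameter", "Value"]).to_csv(path, index=False)


def read_state(path) -> dict:
    """Read a warm-restart state table back into an override dict."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["Parameter", "Value"]:
        raise ValueError("state table must have Parameter and Value columns")
    return dict(zip(df["Parameter"], df["Value"].astype(float)))
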