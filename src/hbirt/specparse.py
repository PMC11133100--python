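"""Model-specification mini-language.

A model is declared with factor lines and ``key = value`` option lines::

    #1 y1-y30 [1]
    model = 2PL
    priors = hierarchical
    covar = free

A factor line starts with ``#<f>``; its items follow in data-column order,
ranges like ``y1-y30`` expand along the data columns, a ``>`` suffix marks
a positivity constraint (``y1>``), and a trailing ``[s]`` assigns every
item listed since the previous label to hierarchical slope-prior set ``s``.
Items on a factor without any set label get item-specific (non-hierarchical)
slope priors.  Unknown option keys are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .diagnostics import ConvergenceConfig
from .factors import CovarSpec
from .model import ModelSpec, PriorConfig
from .sampler import SamplerConfig

__all__ = ["ParsedModel", "parse_spec", "unparse_spec"]

_FACTOR_RE = re.compile(r"^#(\d+)\s+(.*)$")
_RANGE_RE = re.compile(r"^(.*?)-(.+)$")

_BOOL = {"yes": True, "no": False, "true": True, "false": False}


@dataclass
class ParsedModel:
    model_spec: ModelSpec
    priors: PriorConfig
    sampler: SamplerConfig
    convergence: ConvergenceConfig
    alpha: float = 0.05
    ratio_cpo: float = 0.0

    def __iter__(self):
        return iter((self.model_spec, self.priors, self.sampler, self.convergence))


def _expand_items(tokens: list[str], columns: list[str]) -> list[tuple[str, bool]]:
    """Expand item tokens (with ranges and '>' markers) against the data
    columns; returns (item, constrained) pairs."""
    out = []
    col_index = {c: i for i, c in enumerate(columns)}
    for tok in tokens:
        constrained = tok.endswith(">")
        if constrained:
            tok = tok[:-1]
        m = _RANGE_RE.match(tok)
        if m and tok not in col_index and m.group(1) in col_index and m.group(2) in col_index:
            i0, i1 = col_index[m.group(1)], col_index[m.group(2)]
            if i1 < i0:
                raise ValueError(f"range {tok!r} runs backwards in data-column order")
            for c in columns[i0:i1 + 1]:
                out.append((c, constrained))
        else:
            if tok not in col_index:
                raise ValueError(f"item {tok!r} not found in the data columns")
            out.append((tok, constrained))
    return out


_OPTION_KEYS = {
    "model", "link", "priors", "aconstr", "muaconstr", "duninf", "covar",
    "alpha", "rdist", "var_beta", "ratiocpo",
    "prior_mean_a", "prior_var_a", "prior_mean_d", "prior_var_d",
    "prior_mua", "prior_mua_ge0", "prior_mud", "prior_vara", "prior_vard",
    "nbi", "maxnmc", "iterationsteps", "thin",
    "maxtune", "hmaxtune", "ntu", "hntu", "seed",
    "psr_conv", "ess_conv",
}


def parse_spec(text: str, columns: list[str]) -> ParsedModel:
    """Parse a model-specification text against the data's item columns.

    Returns a :class:`ParsedModel`, iterable as (ModelSpec, PriorConfig,
    SamplerConfig, ConvergenceConfig).
    """
    if not text.strip():
        raise ValueError("empty specification")
    factor_items: dict[int, list] = {}
    options: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("!", 1)[0].strip()  # '!' starts a comment
        if not line:
            continue
        m = _FACTOR_RE.match(line)
        if m:
            f = int(m.group(1))
            if f < 1:
                raise ValueError("factor numbers start at 1")
            factor_items.setdefault(f, [])
            # scan tokens; a [s] label applies to items since the last label
            pending = []
            for tok in m.group(2).split():
                lm = re.match(r"^\[(\d+)\]$", tok)
                if lm:
                    s = int(lm.group(1))
                    if s < 1:
                        raise ValueError("set labels start at 1")
                    factor_items[f] += [(t, s) for t in pending]
                    pending = []
                else:
                    pending.append(tok)
            factor_items[f] += [(t, 0) for t in pending]  # unlabeled: item-specific
            continue
        if "=" in line:
            key, val = (s.strip() for s in line.split("=", 1))
            key = key.lower()
            if key not in _OPTION_KEYS:
                raise ValueError(f"unknown option {key!r}")
            options[key] = val
            continue
        raise ValueError(f"cannot parse line {raw!r}")
    if not factor_items:
        raise ValueError("no factor lines found")
    factors = sorted(factor_items)
    if factors != list(range(1, len(factors) + 1)):
        raise ValueError("factor numbers must be consecutive starting at 1")
    F = len(factors)

    J = len(columns)
    col_index = {c: i for i, c in enumerate(columns)}
    loading = np.zeros((J, F), dtype=bool)
    slope_set = np.full((J, F), -1, dtype=int)
    positivity = np.zeros((J, F), dtype=bool)
    explicit_constr = np.zeros(F, dtype=bool)
    for f in factors:
        fi = f - 1
        for token, s in factor_items[f]:
            for item, item_constr in _expand_items([token], columns):
                j = col_index[item]
                if loading[j, fi]:
                    raise ValueError(f"item {item!r} listed twice on factor {f}")
                loading[j, fi] = True
                slope_set[j, fi] = s
                if item_constr:
                    positivity[j, fi] = True
                    explicit_constr[fi] = True

    aconstr = options.pop("aconstr", "auto").lower()
    if aconstr == "all":
        positivity = loading.copy()
    elif aconstr == "auto":
        for fi in range(F):
            if not explicit_constr[fi]:
                loaders = np.nonzero(loading[:, fi])[0]
                if loaders.size:
                    positivity[loaders[0], fi] = True
    else:
        raise ValueError("aconstr must be auto or all")

    intercept_hier = np.ones(J, dtype=bool)
    for item, _ in _expand_items(options.pop("duninf", "").split(), columns):
        intercept_hier[col_index[item]] = False

    covar = CovarSpec.parse(options.pop("covar", "free"))
    model = options.pop("model", "2PL").upper()
    link = options.pop("link", "logit").lower()
    spec = ModelSpec(
        item_names=list(columns), n_factors=F, loading_pattern=loading,
        slope_set=slope_set, positivity=positivity,
        intercept_hier=intercept_hier, model=model, link=link, covar=covar,
    )

    pkw = {}
    if "priors" in options:
        pkw["priors"] = options.pop("priors").lower()
    for key, attr in (("prior_mua", "hyperprior_mu_a"),
                      ("prior_mua_ge0", "hyperprior_mu_a_ge0"),
                      ("prior_mud", "hyperprior_mu_d"),
                      ("prior_vara", "hyperprior_var_a"),
                      ("prior_vard", "hyperprior_var_d")):
        if key in options:
            pkw[attr] = options.pop(key)
    for key in ("prior_mean_a", "prior_var_a", "prior_mean_d", "prior_var_d",
                "var_beta"):
        if key in options:
            pkw[key] = float(options.pop(key))
    for key in ("muaconstr", "rdist"):
        if key in options:
            pkw[key] = _BOOL[options.pop(key).lower()]
    priors = PriorConfig(**pkw)

    skw = {}
    for key in ("nbi", "maxnmc", "iterationsteps", "thin", "maxtune",
                "hmaxtune", "ntu", "hntu", "seed"):
        if key in options:
            skw[key] = int(float(options.pop(key)))
    sampler = SamplerConfig(**skw)

    ckw = {}
    if "psr_conv" in options:
        ckw["psr_conv"] = float(options.pop("psr_conv"))
    if "ess_conv" in options:
        ckw["ess_conv"] = float(options.pop("ess_conv"))
    convergence = ConvergenceConfig(**ckw)

    alpha = float(options.pop("alpha", 0.05))
    ratio_cpo = float(options.pop("ratiocpo", 0.0))
    assert not options
    return ParsedModel(spec, priors, sampler, convergence, alpha, ratio_cpo)


def unparse_spec(parsed: ParsedModel) -> str:
    """Render a parsed model back to specification text that re-parses to an
    equivalent model (item lists are written explicitly, not as ranges)."""
    spec = parsed.model_spec
    lines = []
    for fi in range(spec.n_factors):
        toks = []
        for j, item in enumerate(spec.item_names):
            if not spec.loading_pattern[j, fi]:
                continue
            toks.append(item + (">" if spec.positivity[j, fi] else ""))
            s = int(spec.slope_set[j, fi])
            if s > 0:
                toks.append(f"[{s}]")
        lines.append(f"#{fi + 1} " + " ".join(toks))
    lines.append(f"model = {spec.model}")
    lines.append(f"link = {spec.link}")
    lines.append(f"covar = {spec.covar}")
    duninf = [it for j, it in enumerate(spec.item_names) if not spec.intercept_hier[j]]
    if duninf:
        lines.append("duninf = " + " ".join(duninf))
    pr = parsed.priors
    lines.append(f"priors = {pr.priors}")
    lines.append(f"prior_mean_a = {pr.prior_mean_a}")
    lines.append(f"prior_var_a = {pr.prior_var_a}")
    lines.append(f"prior_mean_d = {pr.prior_mean_d}")
    lines.append(f"prior_var_d = {pr.prior_var_d}")
    lines.append(f"muaconstr = {'yes' if pr.muaconstr else 'no'}")
    lines.append(f"rdist = {'yes' if pr.rdist else 'no'}")
    lines.append(f"var_beta = {pr.var_beta}")
    lines.append(f"prior_mua = {pr.hyperprior_mu_a}")
    lines.append(f"prior_mua_ge0 = {pr.hyperprior_mu_a_ge0}")
    lines.append(f"prior_mud = {pr.hyperprior_mu_d}")
    lines.append(f"prior_vara = {pr.hyperprior_var_a}")
    lines.append(f"prior_vard = {pr.hyperprior_var_d}")
    sc = parsed.sampler
    for key in ("nbi", "maxnmc", "iterationsteps", "thin", "maxtune",
                "hmaxtune", "ntu", "hntu"):
        lines.append(f"{key} = {getattr(sc, key)}")
    if sc.seed is not None:
        lines.append(f"seed = {sc.seed}")
    cv = parsed.convergence
    lines.append(f"psr_conv = {cv.psr_conv}")
    lines.append(f"ess_conv = {cv.ess_conv}")
    lines.append(f"alpha = {parsed.alpha}")
    lines.append(f"ratiocpo = {parsed.ratio_cpo}")
    return "\n".join(lines) + "\n"
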