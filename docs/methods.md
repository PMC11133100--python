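# Methods

## Model

`hbirt` estimates multidimensional two-parameter logistic (M2PL) models —
and their 1PL and probit variants — for dichotomous items. The response of
person *i* to item *j* is Bernoulli with

    p(y_ij = 1) = g^{-1}( -d_j + Σ_f a_jf θ_if ),

where `g` is the logit (default) or probit link, `d_j` is the item
intercept, `a_jf` the slope (loading) of item *j* on factor *f*, and
`θ_if` the person parameter on factor *f*, with `θ_i ~ N(0, R)` for a
correlation matrix `R`. With a positive slope, larger intercepts lower the
success probability; in unidimensional models the classical difficulty is
`b_j = d_j / a_j` (some of the literature defines `b = -d/a`; both sign
conventions are available, `d/a` being the default). Missing responses are
assumed missing at random and contribute nothing to the likelihood.

### Priors

Item parameters carry normal priors. Under the *hierarchical* (adaptive
informative) specification the prior means and variances are themselves
parameters:

    a_jf ~ N(μ_a(s), σ²_a(s)),   d_j ~ N(μ_d, σ²_d),
    μ_a(s), μ_d ~ U(-6, 6),      σ²_a(s), σ²_d ~ IG(0.01, 0.01),

where `s` indexes user-defined slope-prior sets (e.g. one per content
facet), so information is pooled across the items of a set. Individual
items can be excluded from the pooling (they then receive user-constant
normal priors, defaults N(0, 4)), and all hyperpriors can be replaced
(uniform, inverse gamma, exponential, half-Cauchy are understood). Under
`priors = "user"` all items use the constant priors. Prior variances are
stated on the scale of the link: logistic residuals have variance π²/3, so
a logit-metric prior (m, v) corresponds approximately to the probit-metric
prior (m/√(π²/3), v/(π²/3)); `rescale_priors_logit_to_probit` performs
this conversion.

To break the sign non-identifiability of factor models (the likelihood is
invariant to flipping all loadings on a factor together with that factor's
person parameters), at least one loading per factor gets a positivity
constraint, realized by truncating its normal prior at zero. By default
the first listed item of each factor is constrained; `>` markers or
`aconstr = all` override this. The constraint can be extended to the
hyper-mean (`muaconstr`), which switches its hyperprior to U(0, 6). No
post-hoc relabeling is applied: the constraint is the remedy for label
switching.

### Factor correlations

Correlation matrices for the person parameters are generated by a
regression construction:

    θ_1 = e_1,   θ_f = Σ_{g<f} β_fg θ_g + e_f,   e_f ~ N(0, 1),

with each θ_f rescaled to unit variance. Every finite `β` maps to a
positive-definite correlation matrix with unit diagonal, so random-walk
updates on `β` can never leave the valid set. Free coefficients carry
N(0, var_beta) priors (default var_beta = 1; smaller values concentrate
the induced correlation prior around zero; `rdist = no` drops the prior,
i.e. an improper flat prior on β). Pairs constrained to zero have their
β fixed at 0. One consequence of this parameterization: when a factor's
row contains both free and fixed coefficients, a fixed β of 0 constrains
the *partial* association, and the marginal correlation of that pair can
be slightly non-zero through indirect paths; it is exactly zero whenever
the factor's entire row is fixed (e.g. `covar = diagonal`, or a single
free pair). Starting correlations (`covar = 1#2[0.5]`) are converted to
starting β by inverting the construction row by row (a deterministic
least-squares solve; infeasible combinations are reported, not silently
adjusted).

## Sampling

Posterior simulation is blocked random-walk Metropolis with normal
proposals:

* one block per person (all person blocks are conditionally independent
  given the item parameters, so they are proposed and accepted in
  parallel);
* one block per item, jointly proposing (a_j·, d_j) — likewise parallel;
* scalar blocks for each hyperparameter and each free β;
* the intercept-prior variance σ²_d is drawn exactly from its conjugate
  inverse-gamma full conditional, IG(α + J_h/2, β + ½Σ(d_j − μ_d)²),
  whenever its hyperprior is inverse gamma (otherwise it falls back to
  random-walk Metropolis).

Constraint handling goes through the prior: a proposal below zero at a
constrained position has prior density zero and is rejected, which is
equivalent to a truncated-normal prior. The truncation normalizer
Φ(μ_a/σ_a) is constant within an item block but is included in the
hyperparameter updates, where it varies. Probabilities are clamped to
[1e-12, 1 − 1e-12] before logs so that extreme proposals yield finite
log-posteriors. For 1PL models the slopes on a factor collapse to a single
parameter with a truncated-normal prior built from the user constants.

**Proposal tuning.** Before burn-in, up to `maxtune` (user priors) or
`hmaxtune` (hierarchical priors) loops of `ntu`/`hntu` sweeps adapt each
proposal scale multiplicatively, `scale ← scale · exp(c · (acc − 0.35))`
with c = 1, until every block's acceptance rate sits in the 0.25–0.50
band; tuning draws are discarded and scales frozen afterwards. Default
starting scales are 0.5 (persons), 0.3 (items), 0.2 (means and β) and 0.1
(variances).

**Starting values.** Defaults are a = 1 on loading positions, d = 0,
θ = 0, correlations at their declared starting values (else 0), and
hyperparameters at deterministic points of their hyperpriors (mean of the
support for uniforms, mode for the inverse gamma). Hierarchical fits use a
two-stage start: a short chain with the user-constant priors (burn-in plus
one chunk) supplies the item-parameter state, and the hyperparameters are
initialized at the empirical mean and variance of the stage-one posterior
means. A complete override table (warm restart) skips the stage-one fit;
the final state of every run is exportable, and the draws of a
continuation run can be stacked onto the original.

**Chunked runs and stopping.** After `nbi` burn-in sweeps the chain runs
in chunks of `iterationsteps` sweeps (default 5,000; `thin` keeps every
n-th draw). After each chunk the stopping rule is evaluated on the second
half of the total kept chain — the first half is always treated as
additional burn-in for every computed quantity. The monitored set is the
item parameters, hyperparameters, and free correlations; person parameters
are summarized but not monitored. Convergence requires all potential scale
reductions below `psr_conv` (default 1.1) and, if enabled, all effective
sample sizes at least `ess_conv` (default 0 = off). With both criteria
disabled, exactly one chunk is run (fixed-length mode, e.g. for multi-chain
checks with different seeds). Reaching `maxnmc` post-burn-in sweeps
(default 100,000) without convergence returns the draws flagged
non-converged rather than raising.

## Diagnostics

*PSR* is computed from a single chain: the supplied segment is split into
two contiguous pseudo-chains and PSR = √((W + B)/W), with W the mean
within-chain variance and B the variance of the pseudo-chain means. A
constant chain is reported as PSR = 1 and flagged degenerate. Small-sample
correction terms are omitted; the 1.1 cutoff is coarse. *ESS* is
n / (1 + 2Σρ_k) with the autocorrelation sum truncated by the
initial-positive-sequence rule on consecutive lag pairs (FFT-based
autocovariances); anticorrelated chains are capped at n. The ESS criterion
is applied per parameter (equivalent to comparing the minimum).

## Outputs

The summary table reports, per parameter: posterior mean, SD, constraint
and hierarchical-prior markers, equal-tail interval (linear interpolation
of order statistics at α/2 and 1 − α/2) and HPD interval at level α
(default .05), PSR and the converged flag. The HPD interval is the
shortest [Q(t), Q(t + 1 − α)] over a grid of lower-tail probabilities
t ∈ [0, α] that includes t = α/2, so it is never longer than the
equal-tail interval by construction. (Quantile conventions differ across
software; bit-exact parity with any particular program is a non-goal.)

Person parameters are reported as EAP estimates with posterior SDs from
the second-half θ draws. EAP reliability per factor is the between-person
variance of the EAP scores (the population trait variance is fixed at 1);
it understates the trait variance by one minus the reliability. DIC is
−2·mean + 2·var of the per-iteration joint log-likelihood (sample
variance, divisor n − 1). CPO per cell is the harmonic mean of per-draw
cell likelihoods, recomputed on the fly from the stored parameter draws so
memory stays O(draws × parameters); `ratio_cpo` ∈ (0, 1] subsamples that
fraction of the second-half iterations. Log-CPOs are summed per item and
in total (the log pseudo-marginal likelihood).

## Marginal ML comparator

The frequentist reference fits the unidimensional 2PL, in the same
intercept/slope parameterization, by marginal maximum likelihood:
Bock–Aitkin EM with Gauss–Hermite quadrature (41 nodes transformed to the
N(0, 1) measure; 21 vs 41 nodes changes estimates by less than 1e-3 at
N=500). The M-step is a per-item weighted logistic regression on the node
grid, solved by a few damped Newton steps; the marginal log-likelihood is
non-decreasing across iterations up to the 1e-8 stopping tolerance.
Standard errors come from the observed information, obtained by central
finite differences of the analytic score; Wald intervals are
estimate ± z·SE. A fit is flagged non-converged when the iteration cap is
reached or a slope exceeds 10 in absolute value — for quasi-separated
items the marginal likelihood has no interior maximum and the slope drifts
without bound, so no ML estimate exists; this is common in very small
samples. ML slopes are not sign-constrained; the solution is flipped to a
positive mean slope for comparability.

## Simulation harness and what it does (not) show

`hbirt.simulation` generates unidimensional 2PL data with item and person
parameters redrawn *per replicate*: a ~ N(1, 0.04), d ~ N(0, 1),
θ ~ N(0, 1), k = 25 items, N ∈ {50, 100, 500}. These are the study
conditions; the implied difficulty d/a has mean 0 and variance ≈ 1.15. A
replicate containing an item with no observed variability is inestimable
and is by default regenerated under a fresh sub-seed (and counted);
dropping instead is available. Five arms analyze each replicate: marginal
ML, and Bayesian fits with uninformative (a ~ N(1, 100), d ~ N(0, 100)),
informative (a ~ N(1, 4), d ~ N(0, 4)), hierarchical (default
hyperpriors), or correct (a ~ N(1, 0.04), d ~ N(0, 1)) priors. The
Bayesian arms use the default single positivity constraint and PSR < 1.1
stopping, with proposal tuning only for the hierarchical arm and
convergence checks every 2,500 iterations — the study configuration, not
the general-purpose defaults. Non-converged replicates are excluded from a
cell's metrics (this mainly affects ML at N = 50, where roughly a tenth of
replicates contain a quasi-separated item).

Metrics pool items × replicates: bias, mean estimation variance (squared
SE or posterior variance), RMSE, interval coverage (Wald for ML, HPD and
equal-tail for Bayes) and interval-length mean and 5th/50th/95th
percentiles; 95% bootstrap intervals resample replicates (10,000 draws by
default). Coverage is pooled over items × replicates (identical to the
mean of per-replicate coverages here, since every replicate contributes k
items). The shrinkage regression fits estimation error on the centered
generating parameter by OLS with CR1 cluster-robust standard errors,
replicates as clusters; a negative slope is the signature of shrinkage
toward the prior mean. EAP metrics report the coverage of
estimate ± 1.96 · posterior SD, the estimated reliability (variance of the
EAP scores, averaged over replicates), and the true reliability (squared
correlation of EAP scores with the generating traits).

The generator draws cleanly from the assumed model: unidimensional,
normal traits, independent items given the trait, MAR missingness only
when explicitly imposed. Passing tests therefore demonstrate correct
estimation *under the model*; they say nothing about robustness to
multidimensional contamination, guessing (no 3PL), local dependence, or
informative missingness. A synthetic three-facet "numeracy-style" fixture
(140 persons, 3 × 10 items, loading means 1, 1.5, 2, inter-facet
correlation 0.5 as a documented default) exercises the multidimensional
code paths.

## Problem sizes used in the checked runs

The packaged checks run reduced versions of the study: 12–20 replicates
per condition instead of 100, with comparison bands widened by
√(100/R) relative to the study's printed bootstrap intervals, and
moderately shortened chains for the fixed-length diagnostic fits. The full
grid (all arms × all N at R = 100) is available through
`hbirt simulate --replicates 100 ...` and runs unattended in hours.

## Known limitations

* Polytomous items, 3PL guessing parameters, and multidimensional
  difficulty indices are out of scope.
* WAIC and PSIS-LOO are not computed; model comparison is DIC and
  CPO/LPML.
* Multi-chain Gelman–Rubin across independently seeded runs is supported
  only by exporting draws and stacking them externally.
* The sampler is plain random-walk Metropolis; for very high-dimensional
  models gradient-based samplers would mix faster.
* ESS uses direct Geyer truncation without rank-normalization; heavy-tailed
  posteriors may be diagnosed optimistically.
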