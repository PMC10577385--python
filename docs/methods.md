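# Methods

## Scope and data model

The package analyses multi-site tree provenance trials laid out as
randomized complete block designs (RCBD) with single-tree plots: at each
site, each block contains one planted position per provenance (and per
family replicate, when families are replicated within blocks). The unit
of analysis is the individual live tree with its DBH (cm, breast height
1.3 m) and total height (m). Dead positions keep their rows so that block
survival can be computed against the planted design; blocks with survival
below a threshold (default 60 %) are discarded before any modelling, so
that mortality differences do not distort the height–diameter (H–D)
relationship. The survival denominator is the planted positions per block
supplied as design metadata; when absent it falls back to the maximum
observed row count per block within the site, which is exact for a full
RCBD layout.

Two conventions worth flagging:

* **H–D ratio** is height in metres divided by DBH in centimetres
  (values ≈ 0.8–1.1 for the trials emulated here), not the dimensionless
  m/m slenderness. It is reported this way throughout.
* **Per-provenance volumes** are means of per-tree volumes
  (0.45/4 · π · DBH² · H, DBH in m), never the volume of the mean tree;
  with the trials' diameter spread the two differ materially.

## Candidate curves and base-model choice

Ten standard H–D forms are fitted: linear, reciprocal-linear (fitted on
1/H vs 1/DBH and back-transformed for all fit statistics), quadratic,
Chapman–Richards, power, Wykoff, hyperbolic, Weibull, and the
Chapman–Richards/Weibull variants without the breast-height intercept.
The linear forms use exact OLS; the rest use bounded trust-region
nonlinear least squares from deterministic starting heuristics (asymptote
≈ 1.1 × max H, rate solved through the median point, shape 1; Wykoff from
an exact log-scale OLS). Positivity bounds keep the asymptotic forms on
their increasing branch; Wykoff's parameters are naturally unbounded (its
rate parameter is negative for an increasing curve, and its DBH → 0 limit
is 1.3 + exp(a + b), near but not exactly breast height — it is therefore
excluded from the exact breast-height and positive-parameter monotonicity
checks).

Models are compared on the observed height scale by MAE, AIC
(2k − 2 LL with the profile Gaussian log-likelihood
LL = −n/2 (ln 2π + ln(SSE/n) + 1)), plain and adjusted R², and a paired
*t*-test of predicted vs observed heights as a bias screen: biased models
(p < 0.05) are excluded, the rest ranked by AIC, ties broken by MAE then
R². By default k is the true per-model mean-parameter count; a
fixed-k compatibility mode sets k = 3 for every model, the convention some
published comparison tables follow. Both R² variants are always emitted
because published tables are frequently ambiguous about which they print.

## Dummy-variable NLME model

The selected base (the Weibull) is extended on its asymptote with
reference-coded dummies — sites against a reference site, provenances
against a reference provenance (offsets of the reference are identically
zero) — and with Gaussian block random effects u0 on the asymptote and u1
on the DBH exponent. Residuals follow the power variance function
σ²·(fitted)^{2γ} with "fitted" the full predicted height including the
1.3 m intercept and the block effects. The within-block error correlation
is fixed to the identity: each tree is measured once, so serial
correlation cannot arise; u0 and u1 are taken independent (the minimal
assumption absent evidence of correlation).

Estimation alternates two steps until every parameter changes by less
than 1e-6 relative (or 200 iterations; a criterion-stability fallback
absorbs the terminal jitter of the derivative-free inner optimizer):

1. **Penalized NLS** in all fixed effects and block effects under the
   current weights, with analytic Jacobians, plus a Gauss–Newton polish
   so that equivalent reparameterizations (reference-level swaps) land on
   identical fitted values to machine precision;
2. **Linearized mixed-model step**: the working response at the current
   linearization point is fitted by profiling the fixed effects (GLS) and
   σ² out of the ML or REML criterion and optimizing the two relative
   variance components and γ (Nelder–Mead over log-variances); block
   effects are refreshed by BLUP. Per-block Woodbury identities keep the
   cost linear in trees.

Variance components may legitimately sit on the boundary zero (published
fits of the emulated trials report several zero block variances); this is
reported as converged with a boundary flag, never as failure. Fixed-effect
standard errors come from the GLS information matrix at the optimum.

The implementation was cross-validated against R's `nlme`
(`varPower` on fitted values, REML) on a deterministic simulated fixture:
fixed effects, γ, σ, standard errors and the REML log-likelihood agree to
three–four significant digits, and both push the block variance to the
same boundary (frozen oracle values in `tests/test_nlme.py`).

Likelihood-ratio tests between nested fixed-effect structures use ML
criteria (REML likelihoods are not comparable across fixed-effect
structures; a compatibility path accepts externally supplied
log-likelihoods as-is). The df for the provenance extension of the base
Weibull is 24 dummies + 2 variance components + γ = 27. A negative
statistic is returned with a warning, never clamped. In the pipeline the
NLME always extends the Weibull form, so its LRT is nested against the
Weibull base fit even when the candidate ranking narrowly favours another
form on a particular draw.

## Clustering and selection

Provenance asymptote offsets k_j are scalars, so provenances are grouped
by 1-D agglomerative hierarchical clustering (Euclidean distance), the
tree cut at the requested group count, groups ordered by descending mean
offset. The default linkage is between-groups average (UPGMA): it is the
default of the classical "system clustering" routines in legacy
statistical packages and it is the linkage that exactly reproduces the
published three-group partition of the Mengla offsets (Ward and complete
linkage move two provenances across the second boundary). Ward, complete
and single remain available; on scalars all of them produce groups that
are contiguous intervals of the sorted offsets.

The selection rule: among provenances whose mean DBH strictly exceeds the
site's overall (tree-weighted) mean, rank by k_j ascending and keep
ceil(rate × provenances present), default rate 20 %. The reported
selected/total trait means average the per-provenance means unweighted —
the convention that reproduces the published gain tables. The reference
provenance (k ≡ 0) competes by default; an option excludes it, which is
required to reproduce the published Hua'an set. Gains are reported both
with the signed total-mean denominator and with |total mean|, because the
sign convention is ambiguous when the total mean k is negative. At two of
the four emulated sites (Pingxiang, Changning) the stated rule applied to
the published inputs does **not** return the published selected sets; the
exact eligibility screen used there is under-determined, so the package
exposes criterion options (`dbh_above_mean`, `dbh_and_height_above_mean`)
and the tests assert the discrepancy rather than guessing.

## Synthetic trial generator

The generator emulates the four-site, 25-provenance trial structure the
analysis assumes: per site, blocks receive Gaussian u0/u1 effects, each
(block, provenance, replicate) position survives with probability 0.65
(the emulated trials report ~63–67 %), live trees draw DBH from a gamma
distribution with the published per-site means (20.58 / 15.57 / 21.12 /
7.74 cm) and CV 0.35 (chosen once to span the observed diameter ranges;
DBH is a regressor, not a modelled response, so only its marginal spread
matters), and heights follow the Weibull NLME equation with
power-variance noise, floored at 1.31 m (physically impossible heights
below breast height; affects a negligible fraction of draws under the
defaults). Site designs (12–19 blocks, 5–12 family replicates per
provenance per block) are sized so expected live-tree counts land near
the published per-site totals; an exact-counts mode reproduces them
exactly (7,724 trees) for fixture work. Everything is reproducible from a
single integer seed.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: spatial autocorrelation between
neighbouring trees, family structure within provenances, non-Gaussian or
asymmetric height errors, measurement rounding correlated with size, and
genotype-specific DBH distributions. Parameter-recovery results therefore
demonstrate correctness of the estimator under its own assumptions, not
robustness to their violation.

## Problem sizes and numerical choices

The simulate-and-refit checks use ~3,000 live trees in 15 blocks at the
provenance level and ~7,700 across four sites at the site level — the
scale of the emulated trials. At that size the asymptote is recovered
within ~2 %, shape/rate within a few percent, and γ within ~0.03; the
rate parameter φ2 has the widest relative sampling uncertainty (its ±10 %
recovery band is ≈1.3 sampling SDs, so occasional draws fall outside it).
The null-size calibration of the provenance LRT runs 200 replicates of
the fixed-effects dummy LRT at n = 500: at n = 250 the χ²₂₄ reference
inflates the size to ~11 % — a finite-sample property of the LRT, not an
estimation defect — while n = 500 yields ~4–5 % at nominal 5 %.

Degenerate inputs are handled explicitly: flat heights are a starting-
value error; SSE = 0 makes the profile likelihood diverge (overflow
error); a constant observed vector has no R²; all-zero paired differences
return t = 0, p = 1 while zero-variance non-zero differences are a
degenerate error; duplicate offsets at a cluster-cut boundary resolve by
stable label order; an all-blocks-discarded filter result warns instead
of silently succeeding.

## Known limitations

* The NLME likelihood is the standard linearized approximation; for
  strongly nonlinear random-effect influence it can differ from adaptive
  quadrature likelihoods.
* `fit_nlme` implements the Weibull mean function (the base model of the
  analysis); the dummy fixed-effects extension supports all ten forms.
* No provenance random effects, site × provenance joint model, spatial or
  AR error structures, multi-trait index selection, or breeding-value
  estimation — these are outside the analysis this package reproduces.
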