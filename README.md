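# hdtrial

Height–diameter (H–D) allometry and provenance selection for multi-site
tree provenance trials.

Tree height H (m) and stem diameter at breast height DBH (cm) are the core
growth traits of forest genetic trials. Their allometric relationship —
the H–D curve — carries information that neither trait does alone: at a
given diameter, a *lower* curve asymptote means a stockier, more
wind-stable stem and more diameter-directed growth, which matters for
large-sized timber breeding of species such as *Betula alnoides*. This
package is for tree breeders and forest biometricians who want to

1. fit and compare the standard candidate H–D equations,
2. quantify **site** and **provenance** effects on the curve asymptote with
   dummy-variable nonlinear mixed-effects (NLME) models, and
3. select superior provenances by combining above-average DBH with a low
   asymptote, with selection gains for every trait.

## The model

The base curve is the Weibull H–D equation, selected among ten candidates
by AIC/MAE/R² and a paired *t*-test bias screen:

    H = 1.3 + a · (1 − exp(−b · DBH^c))

Site and provenance enter as reference-coded dummy offsets on the
asymptote, and blocks of the randomized complete block design contribute
Gaussian random effects on the asymptote and on the DBH exponent:

    H_ilm = 1.3 + (φ0 + Σ_i x_i S_i + Σ_j k_j P_j + μ0_l)
                  · (1 − exp(−φ2 · DBH^(φ1 + μ1_l))) + ε_ilm

    μ0_l ~ N(0, σ²_0block),  μ1_l ~ N(0, σ²_1block),
    var(ε) = σ² · (fitted)^(2γ)          (power variance function)

Estimation is by the classical alternating scheme for nonlinear mixed
models (penalized NLS step + linearized mixed-model step with profiled
fixed effects), ML or REML. Nested fixed-effect structures are compared
with likelihood-ratio tests on ML criteria. Provenances are then
clustered on their asymptote offsets k_j (1-D hierarchical clustering)
and the selection rule keeps, among provenances with above-average DBH,
the 20 % with the lowest k_j; gains are
(selected mean − total mean)/total mean × 100 %.

Because the per-tree field data of the motivating trials are not publicly
deposited, the package ships a synthetic-trial generator
(`hdtrial.synthetic`) whose defaults are the *published* model estimates
and site summaries (`hdtrial.reference`), so the full analysis is
exercisable and testable end to end.

## Worked example

Simulate a single-site provenance trial from the published Mengla
estimates and run the full pipeline:

```sh
hdtrial simulate --level provenance --site Mengla --seed 1 --out mengla.csv
hdtrial all --input mengla.csv --seed 1 --out run1
```

or in Python:

```python
import hdtrial as ht

table = ht.generate_trial(ht.default_config("provenance", "Mengla", seed=1))
fit = ht.fit_nlme(table, "provenance", method="REML")
print(fit.phi0, fit.phi1, fit.phi2, fit.gamma)
# 21.958  1.579  0.0140  -0.101
```

The generating values were φ0 = 22.404, φ1 = 1.556, φ2 = 0.015,
γ = −0.106: the fitter recovers the asymptote within 2 %, the shape and
rate parameters within a few percent, and the variance-power exponent
within 0.01 on ~2,900 trees in 15 blocks. The pipeline's `nlme.csv` for
this run reports the likelihood-ratio test of the 24 provenance dummies
against the plain Weibull fit (statistic 244.1, χ²₂₇, p ≈ 8e-37): the
provenance effect on the asymptote is unambiguous in data simulated with
the published offsets. `selection.csv` then lists the five selected
provenances with their trait means and gains.

Applying the selection rule directly to the published per-provenance
summaries reproduces the published outcome at Mengla:

```python
report = ht.select(ht.reference.growth_summaries("Mengla"),
                   ht.reference.PROVENANCE_MODELS["Mengla"]["k"],
                   rate=0.20, site_mean_dbh=20.58)
print(report.selected)          # ['W', 'B', 'P', 'J', 'N']
print(round(report.gains["dbh"], 2))  # 1.3  (DBH gain in %)
```

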