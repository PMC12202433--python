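# bifactorlab

Bifactor structural equation modeling of anxiety dimensions and
working-memory components in children.

## The problem

Working memory is not one thing: a domain-general *central executive*
operates on material held in *phonological* and *visuospatial* short-term
stores. Anxiety is not one thing either: *cognitive worry* and
*physiological arousal* are separable symptom dimensions riding on a shared
*common anxiety* core. Whether — and where — anxiety relates to working
memory in children (and whether the answer changes with co-occurring ADHD)
depends on fractionating both constructs at the latent level, which is what
this package does.

The measurement workhorse is the reference-facet bifactor model. Every
indicator loads on a general factor; subsets load on orthogonal specific
factors; and one or more *reference facets* load on the general factor only,
anchoring its meaning:

- **Working memory, bifactor-(S·I-1)**: 8 span indicators (two tasks ×
  set sizes 3–6, scored as mean stimuli-correct per trial). All load on the
  central executive; set sizes 4–6 of each task load on the matching
  short-term-memory factor; both set-size-3 conditions are reference facets.
- **Anxiety, bifactor-(S-1)**: 22 four-point items (11 worry, 11 arousal)
  plus the sum of 17 items judged to reflect neither dimension, which is the
  reference facet defining common anxiety.

For indicators **y**, loadings Λ, orthonormal-within-construct factors η
(cov Φ), and diagonal residuals Θ, the model-implied moments are
Σ = ΛΦΛ′ + Θ, estimated by normal-theory maximum likelihood

F(θ) = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p,  χ² = N·F(θ̂),

single- or multi-group with equality ties (configural → metric → scalar →
covariance-constrained), MIMIC-style covariates (age, sex, SES), Wald tests
from the inverse expected information, and the usual index battery: CFI,
TLI, RMSEA (90% CI), SRMR, the ω family, explained common variance (ECV),
percentage of uncontaminated correlations (PUC), and construct
replicability (H).

Around the estimator sits the full study workflow:

| module | what it does |
| --- | --- |
| `simulate` | population bifactor models; latent + indicator simulation; Likert discretization; trial-level span records; MCAR holes and planted outliers; rating matrices |
| `preprocess` | partial-credit scoring, composite scoring, 3-SD within-group winsorization, Little's MCAR test, EM (conditional-mean) imputation |
| `agreement` | Fleiss' κ and consensus classification of items by multiple raters |
| `specs` / `engine` | model declaration and the ML fitting machinery |
| `indices` | fit, reliability and dimensionality indices |
| `pipeline` | measurement → structural → multigroup → sensitivity stages |
| `power` | Monte Carlo power (convergence, bias, per-loading Wald power) and analytic required-N for a cross-construct correlation |

No real data ship with the package; every analysis is exercised on
synthetic data whose generating process is explicit and seeded.

## Worked example

```python
import bifactorlab as bl
from bifactorlab.power import power_report

wm = bl.monte_carlo_power(bl.wm_population(), bl.wm_spec(),
                          n=340, reps=200, seed=1, label="working_memory")
anx = bl.monte_carlo_power(bl.anxiety_population(), bl.anxiety_spec(),
                           n=340, reps=200, seed=1, label="anxiety")
print(power_report([wm, anx]).to_string(index=False))

apc = bl.analytic_power_corr(r=0.30, alpha=0.05, target_power=0.80)
print(apc.required_n, round(apc.F0, 5))
```

prints

```
         model   n  reps  convergence_%  max_|rel_bias|  min_power  alpha
working_memory 340   200           99.0          0.0138     0.9798   0.05
       anxiety 340   200          100.0          0.0383     0.9900   0.05
453 0.01734
```

Reading it: simulating 200 samples of n=340 from the hypothesized
working-memory population (standardized general loadings .60, specific
loadings .40) and refitting the bifactor model, 99% of replicates converge
to an admissible solution, the worst mean estimate is within 1.4% of its
true value, and the least-powered loading still rejects in 98% of
replicates at α=.05. The final line sizes a separate question: under the
joint model for both constructs, a true correlation of .30 between the two
general factors produces a population discrepancy F₀ = 0.01734 when forced
to zero, so N = 453 subjects push the df=1 likelihood-ratio test to 80%
power at α=.05.

The `examples/` directory has one short script per capability: simulation +
preprocessing, rater agreement, measurement models, the structural and
multigroup stages, and power analysis.

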