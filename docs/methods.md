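# Methods

This note documents the models, algorithms and design choices behind
`bifactorlab`, and what its synthetic-data experiments do and do not show
about real data.

## Measurement models and identification

Both measurement models are reference-facet bifactor models: every
indicator loads on one general factor, at most one orthogonal specific
factor, and reference facets load on the general factor alone, fixing its
interpretation. Within a construct all factor covariances are zero; when
two constructs are modeled jointly, the nine cross-construct factor
covariances are free.

Identification defaults to the variance-standardized convention — all
loadings free, factor (disturbance) variances fixed to 1 — which the
reference-facet structure requires no marker assumptions for. A marker
convention (one loading per factor fixed to 1, factor variance free;
the reference indicator is chosen as marker where one exists) is also
implemented; the two describe the same model and agree in the standardized
solution at any proper optimum.

Covariates (age in years, sex as 0/1, Hollingshead SES) enter MIMIC-style:
latent factors regressed on observed exogenous covariates whose own
moments are fixed at their sample values ("fixed-x"), so the covariate
block of the implied moments is saturated. With disturbance variances
fixed at 1, the free cross-construct disturbance covariances are directly
the disturbance correlations the structural stage reports. One consequence
worth knowing: covariates induce small correlations among factors, so the
orthogonal variance decomposition behind the ω family is exact without
covariates and approximate with them (the reliability report applies the
same formulas either way and skips the strict orthogonality check in the
covariate case).

## Estimation

The discrepancy is the normal-theory ML fit function, with a mean term
when intercepts/latent means are modeled. Residual variances are
optimized on the log scale so the search stays interior; a residual whose
standardized value collapses below 1e-6 flags the solution inadmissible
(Heywood) rather than being bounded away. χ² = N·F̂ (normal likelihood
scaling, matching mainstream SEM defaults; N−1 Wishart scaling is a
switch). Degrees of freedom count sample moments minus free parameters,
with the fixed-x covariate block treated as saturated on both sides.

The default optimizer is Fisher scoring: Newton-type steps under the
expected information with Levenberg damping, a step-norm cap and an
Armijo backtracking line search, started from deterministic values
(general loadings .5 and specific loadings .3 on the indicator-SD scale,
residuals at half the sample variance, everything else at zero). If
scoring stalls short of the gradient tolerance — typically when a
specific factor is empirically vanishing — an L-BFGS-B polish continues
from the stall point. Fits are therefore bit-reproducible functions of
(data, structure, options). Standard errors come from the inverse
expected information; multigroup equality ties (loadings, intercepts,
residuals, factor covariances, covariate paths) share one parameter across
groups, and in scalar models latent means are freed in all groups but the
reference, which anchors them at zero.

Admissibility of a converged solution requires: no Heywood residual, a
positive-definite factor covariance block, and a numerically invertible
expected information (relative condition above 1e-12). The last criterion
mirrors what practitioners see as "standard errors could not be computed";
without it the Wald machinery downstream would run on a singular
information matrix.

## Indices

CFI/TLI follow the noncentrality formulation; RMSEA uses the same N as the
χ² scaling, multiplies by √G in G-group models, and gets its 90% CI by
root-finding the noncentral-χ² CDF in the noncentrality parameter (the CDF
at the returned bounds equals .95/.05 to 1e-6). SRMR averages squared
correlation-metric residuals over the unique indicator-moment cells
(diagonal included, covariate rows excluded). The ω family, ECV, PUC and H
use their standard bifactor formulas; PUC is purely structural —
(C − Σₛ Cₛ)/C over indicator pairs — and for the anxiety specification
(p=23, two 11-item specifics) equals (253−110)/253 = .565, printed as .57.
The paper-facing WM value of .68 is *not* reproduced by the stated 3+3
specific structure, which gives (28−6)/28 = .786; the structural formula is
authoritative here and the anxiety value confirms it.

The nested χ²-difference guard: if a "restricted" fit lands below its
nesting model by more than tolerance, the comparison raises and the
pipeline refits the restricted model along the global quasi-Newton route
before testing.

## Synthetic data: what it emulates

The generator draws latent factors from the population bifactor model
(unit variances, within-construct orthogonality, configurable
cross-construct correlations), shifts group latent means (defaults mirror
the reported pattern: the clinical group ~1.0 SD lower on the central
executive, 0.7/0.66 SD lower on the short-term stores, no anxiety
differences), adds covariate effects, and emits indicators as
Λη + Γ-mediated covariate effects + normal residual, with residual
variances 1 − λ_g² − λ_s² so indicators are standardized in the
population.

Hypothesized populations: working memory λ_g = .60 and λ_s = .40 over 8
indicators; anxiety item loadings λ_g = .60 and λ_s = .30 over the
23-indicator structure. The reference composite is not an item but the sum
of 17 items; under the item-level hypothesis its standardized loading is
17·(.6)/√(17 + 272·.36) ≈ .95, and that is the population default
(`aggregate_reference_loading`). This matters: with the composite treated
as just another .60 indicator, the (S-1) general factor is so weakly
anchored at n=340 that roughly one replicate in eight has its maximum-
likelihood solution in a collapsed/sign-mixed mode (the data's
within-specific signal never vanishes — the modes are an extreme-value
effect over the 2^22 sign configurations — but they genuinely fit better
by several χ² units), which wrecks convergence, bias and power summaries.
With the aggregate-strength anchor the estimator behaves essentially
asymptotically, reproducing the benchmark Monte Carlo profile
(convergence ≈ 99–100%, bias < .03, per-loading power > .93). The literal
.60-composite population remains available through `lambda_general`
overrides.

Realism layers, used for end-to-end pipeline tests but off for
parameter-recovery baselines: four-point Likert discretization by
thresholds (default (−0.8, 0.2, 1.2), giving category rates
.21/.37/.31/.12); span indicators mapped onto the stimuli-correct metric
(locations/scales consistent with the printed descriptives) and expanded
into six integer trials per task × set size, whose attainable means lie on
the 1/6 grid; MCAR blanking at a configurable rate (default 0.2% of item
cells); planted outliers at 5 within-group SDs. Covariates: age ~
U(8.1, 13.5), sex ~ Bernoulli(.5), SES ~ N(47, 11) truncated to [11, 66].
Covariate effects default to zero (none are stated for the study
populations); power populations exclude covariates entirely.

What passing tests therefore do *not* show: real item responses are
ordinal, skewed and ceiling-afflicted, and treating them as continuous
normal attenuates loadings and perturbs scalar invariance (visible in the
end-to-end demo as inflated latent-mean contrasts when the span ceiling
binds). Normal-theory ML on Likert data is the convention mirrored here;
robust/categorical estimators are out of scope.

## Preprocessing

Pipeline order: score (partial-credit span means; composite = sum of the
17 "neither" items, missing if any constituent is) → winsorize (within
group × variable, |value − mean| > 3 SD with the candidate included in the
statistics, replaced by the most extreme non-flagged value on that side;
single pass) → Little's MCAR test on the incomplete matrix → EM
imputation. Note the inclusive 3-SD screen has a finite-sample floor: with
n values the largest attainable |z| is (n−1)/√n, so tiny groups cannot
flag anything — irrelevant at the study's group sizes (~197/143).

EM for the multivariate-normal mean/covariance iterates pattern-wise
conditional moments until the largest parameter change drops below 1e-6
(observed-data log-likelihood is verified non-decreasing); imputation is
the deterministic conditional mean under the converged parameters — no
residual draws, so repeated runs agree bit-for-bit and observed cells are
untouched. Little's statistic sums
n_j (ȳ_obs,j − μ̂_j)′ Σ̂_j⁻¹ (ȳ_obs,j − μ̂_j) over missingness patterns,
df = Σ p_j − p; complete data return χ²=0, df=0, p=1 with a warning.

## Rater agreement

Fleiss' κ with the textbook estimator; undefined when all ratings share
one category (returned as 1 only under perfect agreement). Consensus
classification takes the modal category per item: agreement ≥ 6/7 accepts,
[5/7, 6/7) flags for adjudication (modal category provisional; a manual
override map resolves it, matching how borderline items are settled by
senior raters), below 5/7 — or any modal tie — forces neither/unclear.
Items judged "both" are excluded from the specific factors and the
composite, preserving the 11/11/17 structure.

## Power machinery

Monte Carlo: per replicate, simulate continuous indicators, fit, and
record convergence/admissibility, estimates, and two-sided Wald p per free
loading plus the general-factor ECV of the standardized solution.
Non-admissible replicates count against the convergence rate and leave the
bias/power denominators. Replicate seeds spawn deterministically from the
run seed. The shipped designs use 500 replicates — enough to put binomial
Monte Carlo error on a 98% power estimate at ~0.6 points — and run in
well under a minute each.

Analytic required-N: build the joint population correlation matrix with
the tested cross-construct correlation at its alternative value (default
.30 between the two general factors, all other cross correlations zero),
fit the model with that correlation fixed to zero and everything else
free, and take F₀ as the minimized discrepancy. The required N is the
smallest integer with noncentral-χ²(df=1, λ=N·F₀) power ≥ the target at
level α (λ ≈ 7.849 for α=.05, power .80). Under the hypothesized
loadings this yields N = 453. Freedoms of the null model matter a great
deal here: fixing the other eight cross correlations instead of freeing
them would give F₀ ≈ .061 (N = 129), and freeing only the
general-to-specific ones F₀ ≈ .021 (N = 367); the all-else-free
convention is the one implemented because the hypothesized joint model
leaves all nine correlations free.

## Known limitations

- Normal-theory ML only: no FIML (missingness is handled upstream by EM
  imputation), no robust corrections, no categorical-indicator estimation.
- The ω/ECV decomposition is approximate in MIMIC models (see above).
- No multiple-testing correction is applied to the nine structural
  correlations, matching the analysis convention; a Holm-adjusted column
  is easy to add from the returned table but deliberately not default.
- Bootstrap confidence intervals for reliability indices are out of scope.
- With weakly anchored general factors and weak specific loadings, ML at
  n in the low hundreds is multimodal; the package reports what the
  likelihood supports (and flags underidentified solutions) rather than
  hiding the phenomenon.
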