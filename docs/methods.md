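# Methods

## The model family

`mixirt` implements adjacent-category logit models for ordered polytomous
items — the partial credit model (PCM) and the generalized partial credit
model (GPCM) — together with their finite-mixture extensions. For item
*i* with categories `0..m_i`, class *g*, and latent trait θ,

    P(X = x | θ, g) ∝ exp( Σ_{s≤x} δ_ig (θ − τ_isg) ),      s = 1..m_i,

with the `s = 0` term identically zero, so category 0 is the reference.
The thresholds τ_isg are the trait locations where the characteristic
curves of categories x−1 and x intersect; δ_ig > 0 is the discrimination.
The mixture marginal sums over classes with weights π_g and integrates the
trait over a class-specific normal distribution N(0, σ²_g); class means
are fixed at 0 as an identification constraint.

Variants differ only in how discriminations are tied:

| variant | discriminations                    |
|---------|------------------------------------|
| PCM / mPCM   | all fixed at 1                |
| GPCM / rmGPCM | per item, shared across classes; item 1 fixed at 1 |
| mGPCM   | per item and class; item 1 of class 1 fixed at 1 |

This identification (free thresholds and one free variance per class,
G − 1 mixing weights, discriminations as above) gives free-parameter
counts of 55/107/159/211/263 for the restricted mixture GPCM with 1–5
classes on five 11-category items, and 155/169 for the 3-class mPCM and
mGPCM — matching the published accounting for this family.

## Estimation

The marginal likelihood is maximized in two phases:

1. **EM.** The E-step computes responsibilities over (class, quadrature
   node) pairs. The M-step updates mixing weights in closed form and
   improves the expected complete-data log-likelihood over the remaining
   parameters with a bounded quasi-Newton step (default 20 inner
   iterations) — a generalized EM step, so the observed log-likelihood is
   non-decreasing by construction; a step-halving guard backs off toward
   the previous iterate in the (never observed in practice) event of a
   numerical decrease.
2. **Newton refinement.** Direct quasi-Newton (L-BFGS) maximization of the
   observed log-likelihood on unconstrained transforms: raw thresholds,
   log discriminations, log latent standard deviations, multinomial-logit
   mixing weights. The exact gradient comes from the Fisher identity (the
   observed score equals the expected complete-data score at the current
   parameters), so no finite differences are involved in fitting.

Latent-trait integration uses Gauss–Hermite quadrature on the standard
normal scale (21 nodes by default, configurable), rescaled per class by
σ_g. Node-doubling changes small-pattern marginal probabilities by less
than 1e-6 in the parameter ranges of interest.

**Multi-start.** Each random start runs a short EM burn-in (40 iterations
by default); the best start by likelihood is refined with the full EM
budget (default cap 8000) and then the Newton phase (default cap 600).
Starting values: per-item thresholds sorted uniform(−2, 2) with N(0, 0.1)
jitter; free discriminations log-uniform(0.5, 2); mixing weights from a
flat Dirichlet; **latent variances log-uniform(0.01, 2.25)**. The variance
draw matters: the latent scale is only weakly identified early in EM, and
starts pinned at σ² = 1 reliably converge to an inferior basin when the
true scale is small (as it is under the calibrated survey preset, σ ≈
0.22). With variance-randomized starts, 10 starts recover the best known
basin on every seed we examined.

Classes are always reported in order of decreasing mixing proportion,
which also resolves label switching between runs. One integer seed drives
all starts through a `numpy.random.SeedSequence` split; fits are
bit-reproducible.

**Standard errors** are square roots of the inverse observed-information
diagonal, with the information matrix obtained by central finite
differences of the exact analytic score (step 1e-5, symmetrized); a
sandwich ("robust") variant uses per-person analytic scores. Estimates on
the log/logit scales are mapped to natural-scale SEs by the delta method.
Fixed reference parameters carry no SE. A singular information matrix
falls back to the pseudo-inverse and is flagged.

## Model selection

Candidates are compared by AIC, BIC and the consistent AIC
(CAIC = −2LL + p(ln n + 1)); CAIC is the primary criterion and ties break
toward fewer classes. Absolute fit uses parametric-bootstrap p-values of
the Pearson and Cressie–Read (λ = 2/3) statistics with the add-one
convention p = (1 + #{boot ≥ obs})/(B + 1). Because the full response-
pattern space of five 11-category items (11⁵ cells) is hopelessly sparse,
the goodness-of-fit cell set is the observed unique patterns plus one
pooled remainder cell; software packages differ in their internal pooling
dialect, so absolute-fit p-values are comparable only within this
package. Nested variants (mPCM ⊂ rmGPCM ⊂ mGPCM) are compared by a
bootstrapped likelihood-ratio difference test: the null distribution of
2ΔLL is simulated from the restricted fit, and on each replicate the
general model is additionally seeded from the restricted solution so the
statistic cannot go negative through start failures. Bootstrap refits use
10 starts by default (not the full 100) for tractability.

## Scale-usage diagnostics

Threshold inversions (τ_s > τ_{s+1}; ties count as ordered), avoided
categories (never the strict arg-max of the characteristic curves on a
θ ∈ [−6, 6] grid with step 0.01; near-ties within 1e-9 count as covered),
signed adjacent-threshold distances (latent category widths), and
model-implied expected category frequencies per class (item probabilities
averaged over the class's latent distribution and over items). The
class-level width summary reports min/max over ordered adjacent pairs
across items; the exact cell set behind such summaries is a reporting
convention, so it is descriptive only.

Marginal reliability is EAP-based: person-level expected-a-posteriori
trait scores are computed across classes and nodes, and reliability is
var(EAP)/(var(EAP) + mean posterior variance). This is compared with
Cronbach's α on the raw scores, which absorbs scale-usage variance and
therefore overstates the precision of the trait measurement.

## Class-membership regression

The bias-adjusted three-step method: (1) fit the measurement model,
(2) assign modal classes and estimate the classification-error matrix
D[s, t] = P(assigned s | true t) from the posteriors, (3) maximize the
ML-corrected multinomial-logit likelihood Σ_v log Σ_t P(t | x_v; B)
D[s_v, t]. The ML correction (rather than weighting-based alternatives)
is the canonical choice for this workflow. With D = I the estimator
reduces exactly to an ordinary multinomial logit on the labels (verified
against `statsmodels` in the test suite). Wald SEs come from the observed
information (central differences of the analytic score); odds ratios are
e^B with 95% intervals exp(B ± 1.96 SE); the reported pseudo-R² is
McFadden's on the corrected likelihood, in percent — other pseudo-R²
definitions give different values, so it should not be compared across
software. Any pairwise class contrast is a coefficient difference
(B_{2v3} = B_{2v1} − B_{3v1}, exactly).

## The synthetic-data generator

`scenario_preset("hilda_like")` carries the class-specific thresholds and
item discriminations of a published three-class restricted mixture GPCM
solution for the five HILDA wave-1 job-satisfaction items (11-point
scale, n = 7036), with class proportions (0.40, 0.33, 0.27). The
published tables do not report the class latent variances; we calibrated
σ_g = (0.225, 0.237, 0.191) so that the model-implied marginal item means,
SDs and category frequencies reproduce the published descriptive table
(discrepancy RMSE < 0.005 on the mean/SD pairs; frequencies within 0.1
percentage points). In other words, the missing scale of the latent
distributions is recovered from printed information, and the generator's
marginals reproduce the survey's left-skewed distributions essentially
exactly.

A few published thresholds are extreme with very large standard errors
(attributed to near-empty categories); `"hilda_like_stable"` clips
|τ| ≤ 4 and is the preset used in recovery experiments. Archetype presets
`"ordered_11"` (ordered equidistant thresholds −2.25..2.25, slope 1.5),
`"avoided_mid"` (same with thresholds 7 and 8 reversed, burying
category 7) and `"ers_dichotomous"` (wide extreme categories) cover
ordinary usage, category avoidance and extreme-response-style patterns.

Covariates are generated by rejection: proposals from declared baseline
families (normal or categorical) are accepted with the class probability
of a user-set multinomial logit, so class-conditional covariate densities
are exactly proportional to baseline × logit. Slope coefficients of the
generating logit are therefore recoverable by class-membership
regression; intercepts absorb the mismatch between the class prior and
the logit's implied marginal. The default battery is schematic (age,
gender, education, income, tenure, job position, part-time status,
organization size, four job-characteristics subscales, job importance)
with effect sizes of the order reported for such analyses; only the
class–covariate association structure matters for testing, not
distributional realism.

**What the generator does not emulate:** survey design effects (weights,
household clustering), item-level missingness patterns, and covariate
missingness (the regression stage rejects missing covariates; multiple
imputation is out of scope). Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not robustness
to real-survey complications.

## Problem sizes used in the checks

Recovery experiments use n = 4000 (10 starts); at that size the mixing
proportions are recovered within ±0.02–0.04, while the aligned threshold
root-mean-square error is dominated by the handful of thresholds living
in near-empty categories — the published standard errors themselves imply
an RMSE floor near 1.0 at n = 7036 (0.28 after excluding the six largest),
so threshold RMSE well below ~0.3 is not achievable at these sample
sizes and the package reports it honestly rather than trimming the cell
set. The class-enumeration consistency experiment runs at the study's
sample size n = 7036: the published model-comparison table implies a
per-observation log-likelihood gain of 347/7036 ≈ 0.049 for the third
class, which crosses the CAIC penalty only above n ≈ 5000 — below that,
CAIC correctly-by-design prefers two classes, so smaller sample sizes
cannot exhibit selection consistency. Bootstrap calibration checks use a
small single-class model (two 3-category items, n = 200, B = 99, 20
replications) so the null distribution can be simulated quickly.

## Numerical choices and degenerate inputs

Pattern probabilities are evaluated with log-sum-exp throughout and
floored at 1e-300 before logging (with a warning counter). Duplicate
response patterns are collapsed with weights before fitting. Missing
responses are ignorable by default (skipped likelihood factors); a strict
flag rejects them instead. Ties in modal class assignment go to the
lowest class index and are logged. Items must have at least two
categories; persons must have at least one observed response; constant
items yield zero SD in descriptives and undefined (NaN) reliability/α
where variance vanishes, with warnings rather than crashes.

## Known limitations

- Absolute-fit p-values depend on the pooled-cell dialect (above).
- The "robust" sandwich SEs and any published robust SEs need not agree;
  the robust-SE estimator behind published tables is generally
  unspecified.
- Extreme thresholds in near-empty categories are estimated with very
  large uncertainty; interpretation should lean on the ordering/avoidance
  diagnostics, which are stable, rather than on the numeric values of
  extreme thresholds.
- One-step estimation with covariates inside the measurement model, and
  Bayesian estimation, are out of scope.
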