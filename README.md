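# mixirt — mixture partial-credit IRT for diagnosing rating-scale usage

Long rating scales (say, 11 response options) are popular in panel
surveys, but many respondents cannot meaningfully distinguish that many
categories: they avoid some options, collapse the scale onto its
extremes, or otherwise use it in content-unrelated ways. Such
*inappropriate scale usage* contaminates total scores and inflates
classical reliability. `mixirt` detects and characterizes it with mixture
item response theory: it fits partial credit models (PCM) and generalized
partial credit models (GPCM) with latent scale-usage classes, selects the
number of classes, turns the fitted thresholds into interpretable
diagnostics (avoided categories, response styles, latent category
widths), and relates class membership to covariates.

The package is aimed at psychometricians and survey methodologists who
want this workflow on their own ordinal data, and it ships a synthetic
data generator that emulates the structure of a well-known application —
five job-satisfaction items from the HILDA survey rated 0–10 — so every
stage is testable without licensed microdata.

## The model

For item *i* (categories `0..m_i`), latent class *g* and trait θ, the
category probabilities follow the adjacent-category logit form

    P(X = x | θ, g) ∝ exp( Σ_{s≤x} δ_ig (θ − τ_isg) ),

where the threshold τ_isg is the trait location at which the
characteristic curves of categories x−1 and x intersect, and δ_ig > 0 is
the discrimination. Classes mix with weights π_g, and within class *g*
the trait is N(0, σ²_g) (means fixed at 0 for identification). Variants:
**mPCM** (all δ = 1), **rmGPCM** (δ_i per item, shared across classes),
**mGPCM** (δ_ig per item and class). Estimation is marginal maximum
likelihood: multi-start EM with closed-form mixing updates and
quasi-Newton item-parameter updates, followed by direct quasi-Newton
refinement with exact analytic scores; the trait is integrated out with
class-rescaled Gauss–Hermite quadrature.

Unordered thresholds are the key diagnostic: if τ_s > τ_{s+1}, the
intervening category is never the most likely response anywhere on the
trait continuum — it is *avoided*. Classes whose extreme categories own
most of the continuum exhibit an extreme response style.

## Worked example

Simulate survey-like data from the three-class preset, select the number
of classes by CAIC, and diagnose scale usage:

```python
import numpy as np
from mixirt import (FitOptions, enumerate_classes, generate_responses,
                    scenario_preset, marginal_reliability, cronbach_alpha,
                    assign_modal_classes)

params = scenario_preset("hilda_like")      # 5 items x 11 categories, 3 classes
data, truth = generate_responses(params, n=7036, seed=0)

opts = FitOptions(n_starts=10, seed=0, burn_in_iterations=15)
ic, best = enumerate_classes(data, "rmgpcm", [1, 2, 3], opts)
print(ic.table[["LL", "n_par", "CAIC"]].round(0))
print("selected classes:", ic.best_index)
print("class shares:", np.round(best.params.mixing, 3))
print("reliability:", round(marginal_reliability(best, data), 2),
      " alpha:", round(cronbach_alpha(data), 2))
```

Output (seed 0):

```
                LL  n_par      CAIC
n_classes
1         -69666.0     55  139875.0
2         -68170.0    107  137395.0
3         -67743.0    159  137053.0
selected classes: 3
class shares: [0.408 0.33  0.262]
reliability: 0.57  alpha: 0.68
```

The three-class solution wins by CAIC and recovers the generating class
shares (0.40, 0.33, 0.27). The marginal (EAP) reliability of the trait
*after* separating scale usage (0.57) is visibly lower than Cronbach's α
on the raw scores (0.68): α absorbs response-style variance and
overstates measurement precision. Threshold diagnostics
(`scale_usage_report(best, data)`) then show which categories each class
avoids and which classes behave like extreme-response styles.

A command-line interface mirrors the workflow:
`mixirt simulate / fit / select / diagnose / predict-classes / report`.

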