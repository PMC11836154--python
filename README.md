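# silicofem

Desk-scale *in silico* clinical trials of hip-fracture incidence in
virtual cohorts of postmenopausal women.

Placebo-controlled osteoporosis trials are slow, expensive and
ethically fraught. An *in silico* trial replaces the recruited cohort
with simulated patients: femur anatomies sampled from a statistical
atlas, falls arriving as a stochastic process, impact biomechanics, and
a bone-strength model deciding who fractures. `silicofem` implements
that whole pipeline at desk scale — the expensive CT-based
finite-element solves are replaced by either a fast aBMD-calibrated
strength surrogate or an exact strain-criterion evaluator applied to
externally computed strain fields.

## The model

**Virtual cohort.** A principal-component atlas is fitted to a training
matrix of pooled femur features (nodal coordinates + element
densities + DXA-style aBMD features). With *n* training femurs the
atlas holds *n − 1* stochastic variables; new patients are synthesised
by drawing each PC score from the inverse empirical CDF of the training
scores, and accept/reject thinning matches the cohort's total-hip areal
bone mineral density (aBMD) to a clinical target N(μ, σ²). Height and
weight attach through a Gaussian copula with Pearson correlation 0.4 to
femoral-neck aBMD; trochanteric soft-tissue thickness is linear in BMI.

**Falls.** Fall counts per patient-year are i.i.d. Poisson(λ) with
λ = 0.65 falls/year (literature value for community-dwelling older
women):  P_λ(n) = λⁿ e^(−λ) / n!

**Impact.** Each fall is a side fall onto the greater trochanter. The
hip free-falls from a fraction of body height, v = √(2g·0.51·h); a
single-degree-of-freedom mass–spring contact gives the peak force
F = v·√(k·m_eff); trochanteric soft tissue and flooring attenuate it
multiplicatively. The impact direction (α intra-extra rotation,
β abduction-adduction) is uniform on the 61 × 31 integer-degree grid
α ∈ [−30°, 30°], β ∈ [0°, 30°] — 1891 equiprobable directions.

**Strength.** The femur fails when, under a linearly scaled 1000 N
reference load, the sphere-averaged (r = 3 mm) surface principal
strains first reach 0.73% in tension or 1.04% in compression:

FL = 1000 N × min over surface nodes of min(0.0073/ε_t, 0.0104/ε_c)

The cohort-scale surrogate instead samples a direction-dependent
failure-load surface with median exp(c0 + c1·aBMD) and lognormal
patient residuals.

**Follow-up.** A per-patient absorbing Markov chain with 1-year steps:
active patients draw falls, each fall compares attenuated force against
the direction-specific failure load (strict inequality fractures), and
fractured patients leave the trial. Incidence is summarised over
independent realizations; convergence uses bootstrap estimates of the
relative change in the cumulative mean with a 1% threshold.

## Worked example

```bash
silicofem run-trial --out results/lift --seed 77
# 7.9 +- 1.6 fractures over 3 years (min 6, max 10; incidence 0.64%)

silicofem report --results results/lift
# cohort n=1238: 7.9 +- 1.6 fractures (min 6, max 10), incidence 0.64%
# mean fractures per year: 4.0, 2.0, 1.9
# bootstrap rel diff (last) = 7.01%; not converged
```

With no config file this builds the LIFT-like cohort (1238 patients,
total-hip aBMD 0.722 ± 0.096 g/cm²) and runs 10 realizations of the
3-year follow-up. The first line is the ensemble mean ± SD of the
fracture count with its range; the per-year profile declines because
the most fragile patients fracture early and leave the cohort; the
bootstrap relative difference is the convergence diagnostic of the
cumulative mean (small ensembles of small counts need more than 10
realizations to pass the 1% threshold). `results/lift/` holds
`summary.json`, per-realization counts, per-fracture records and a
reproducibility manifest. Every output is a deterministic function of
the seed.

Python API:

```python
import numpy as np
from silicofem import *

rng = np.random.default_rng(1)
X, meta = generate_atlas_training(FixtureSpec(), rng)
atlas = fit_atlas(X, feature_meta=meta)
cohort = build_cohort(atlas, reference_configs()["LIFT"].target, rng,
                      surrogate=SurrogateParams())
result = run_trial(cohort, reference_configs()["LIFT"].trial_config(master_seed=1))
print(result.mean, result.sd, result.incidence)
```

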