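# Methods

This note documents the models implemented in `silicofem`, their
assumptions, the defaults that matter, and what the synthetic data can
and cannot establish.

## Virtual cohort

The statistical anatomy atlas is a PCA of a training feature matrix
(one row per femur: nodal coordinates in mm, element densities in
g/cm³, and scalar aBMD features). Fitting uses a centred SVD; the
component count is at most `n_train − 1` and is reduced (with a
warning) when the matrix is numerically rank-deficient, judged against
a tolerance scaled to the data magnitude so that duplicated rows yield
zero informative components. Patient synthesis draws each PC score
independently from the inverse empirical CDF of the training scores
(linear interpolation between order statistics), reproducing the
training marginals without a Gaussianity assumption; features are
`mean + modes · scores`.

Areal BMD supports two decodings. In surrogate mode aBMD is carried as
a designated atlas feature. In projection mode it is the DXA-style
quotient of total mineral mass over the area of the coronal-plane
(x–z) projection of the region of interest, the projected area being
the convex hull of the projected nodes; for a uniform slab this reduces
exactly to density × thickness, and the measure is homogeneous of
degree 1 in density.

Cohort assembly is accept/reject: a presample of 2000 proposals gives a
Gaussian-kernel density estimate of the proposal aBMD distribution; a
patient with aBMD *x* is accepted with probability
`N(x; μ, σ) / (M · kde(x))`, where `M` is 1.2 × the supremum of the
density ratio over the presample. The target mean must lie inside the
presample support, and the build aborts if the running acceptance rate
drops below 10⁻⁴. Matching therefore enforces the full Gaussian target
shape, not just its moments.

Anthropometry uses a Gaussian copula: standardised femoral-neck aBMD
correlates 0.4 with height and weight (the height–weight mutual
correlation defaults to 0.5 and is config-exposed, since only the 0.4
link is externally specified); marginals default to postmenopausal
reference values, height 1.60 ± 0.06 m and weight 66 ± 11 kg, with
non-positive draws resampled. Soft-tissue thickness is
`−10 mm + 1.2 mm·(kg/m²)⁻¹ · BMI`, clipped below at 2 mm; all
coefficients are config-exposed.

## Falls and impact

Fall counts are i.i.d. Poisson(λ = 0.65/year) per patient-year —
homogeneous across patients, years and within years. This deliberately
ignores frailty heterogeneity (in reality ~30% of subjects account for
most falls) and fall clustering; both are known limitations of the
homogeneous-rate assumption, not of the implementation.

Each fall is treated as a side fall onto the greater trochanter. The
impact model is a single-degree-of-freedom mass–spring contact:

* impact velocity `v = √(2 g · 0.51 · height)`, multiplied by a
  unit-mean lognormal factor with CV 0.1 (the only stochastic term of
  the impact chain by default);
* peak force `F = v √(k · m_eff)` with contact stiffness
  k = 50 kN/m and effective mass 0.35 × body mass;
* transmitted force `F × flooring × max(1 − 0.02/mm · STT, 0.3)`,
  so attenuation can reduce the force by at most 70% and never
  amplifies it.

Muscle contraction is not modelled: unexpected falls complete in
300–750 ms, within elderly reaction times. Directions are uniform and
independent on the inclusive integer grid α ∈ [−30, 30]°,
β ∈ [0, 30]° (1891 cells), stored row-major in (α, β).

## Strength

The exact backend evaluates the validated strain criterion on a
precomputed nodal principal-strain field under a 1000 N reference load
(linear elasticity, so strains scale with load). Surface-node strains
are averaged over an inclusive 3 mm sphere restricted to surface nodes
(interior nodes are excluded — a deliberate choice, flagged because the
alternative is defensible), and the failure load is the reference load
times the minimum over surface nodes of
`min(0.0073/ε_t, 0.0104/ε_c)` computed after averaging; "whichever
occurs first" is exactly the smaller ratio under linear scaling. A
field with all-zero averaged strains is rejected as degenerate. The FE
solve itself is out of scope; fields come from the fixture generator or
any external solver via the plain-text node/element/strain format.

The surrogate replaces per-direction FE solves at cohort scale:
`S0 = exp(c0 + c1 · aBMD)` with a median-preserving lognormal
patient residual (CV 0.2), modulated across the direction grid by a
smooth separable cosine factor of amplitude ±20%. Defaults c0 = 6.3,
c1 = 3.4 (g/cm²)⁻¹ were calibrated once, analytically plus a
Monte-Carlo pass over simulated falls, so that a cohort at aBMD
0.722 g/cm² experiences a per-fall fracture probability of order 0.5%
— i.e. a 3-year incidence of order 1%, the clinical order of magnitude
for this population. They were not fitted to reproduce any published
fracture count. Because patient residuals are heavy-tailed, cohort
incidence is dominated by the most fragile tail and varies by roughly
a factor of two between independently built cohorts; the same
mechanism produces a declining per-year fracture profile (fragile
patients are absorbed early).

## Follow-up and diagnostics

The follow-up is an absorbing Markov chain with a fixed 1-year step:
per active patient-year a Poisson fall count is drawn; falls are
processed in draw order; a fall fractures the patient iff the
transmitted force *strictly* exceeds the direction-specific failure
load; the remaining falls of that year are discarded and the patient
is excluded from later years (hip fracture as clinical endpoint). One
strength lookup is performed per processed fall — the count reported as
the evaluation workload. The RNG is a master `SeedSequence` spawning
per-realization and per-patient substreams, so results are bit-for-bit
reproducible and edits to one patient never perturb another's draws.

Convergence: for each prefix length k ≥ 2, 10,000 paired bootstrap
resamples of the first k and first k−1 realization counts estimate
`E |M_k* − M_{k−1}*| / M_{k−1}*`; convergence is declared at the first
k at or below the 1% threshold. Plain cumulative-mean relative
differences are emitted alongside (the bootstrap/plain distinction is
ambiguous in the field's usage, so both are reported). The diagnostic
is scale-invariant and decays like 1/√k for i.i.d. counts; note that
for ensembles of ~10 realizations of small counts the bootstrap
version typically sits at a few percent, so small trials honestly
report "not converged". Cohort equivalence uses the pooled
(equal-variance) two-sample t-test with explicit zero-variance
degenerate handling.

## Synthetic data: what it does and does not show

The fixture generator supplies (i) Gaussian training matrices with a
prescribed covariance spectrum (default: geometric decay, full rank
n_train − 1 = 93) and aBMD columns affine in the latent scores with
realistic means/SDs (total hip 0.72 ± 0.13, neck 0.56 ± 0.09 g/cm²,
latent correlation 0.85); (ii) toy quadratic-tet box meshes (≤ 500
nodes, midside nodes at edge midpoints) carrying constant, hotspot or
gradient strain patterns whose failure load the generator computes
itself with an independent O(n²) brute-force pass; (iii) ready-to-run
LIFT-like (n = 1238, 0.722 ± 0.096) and FREEDOM-like (n = 1225,
0.709 ± 0.099) bundles with λ = 0.65, 3 years, 10 realizations.

Passing tests on these fixtures validates the machinery — PCA
round-trips, inverse-CDF sampling, the strain criterion, the absorbing
chain, the diagnostics — under known ground truth. It does **not**
validate anatomical realism: synthetic features are Gaussian where real
femur geometry/density features are not, the aBMD projection ROI is a
simplified proximal window, and surrogate strengths are calibrated to
literature-plausible magnitudes rather than to CT-based FE solves.
Absolute incidence predictions therefore carry the surrogate's
calibration uncertainty; relative comparisons (e.g. between aBMD
targets under common random numbers) are the more robust output.

## Numerical choices and problem sizes

* PCA rank tolerance: `max(n, p) · eps · max(σ₁, max|X|, 1)`.
* Accept/reject envelope 1.2×; presample 2000; batch 1000.
* Sphere averaging radius inclusive (≤ r); KD-tree implementation,
  checked against the generator's brute force.
* Strength lookups are exact grid indexing; off-grid queries error.
* Tie-break: force exactly equal to failure load does not fracture.
* Lognormal noises: velocity factor is mean-one; strength residual is
  median-one (so the surrogate median is exactly `exp(c0 + c1·aBMD)`).
* Default test/verification sizes: 10,000 draws for distributional
  checks, 20,000 for copula correlation recovery, 30,000 realizations
  for the enumeration-oracle check of the trial engine, 80 seeds ×
  B = 400 for the 1/√k decay of the bootstrap diagnostic — sizes chosen
  to keep each statistical assertion at ≥ 3 standard errors while the
  whole suite runs in well under a minute.
* The bootstrap convergence trace costs O(B · R²) and is skipped for
  very large ensembles (`compute_convergence=False`).

## Known limitations

* Homogeneous fall rate; no frailty, clustering, fear-of-falling or
  treatment arms.
* No osteoporosis progression: bone properties are frozen over the
  3-year follow-up.
* Every fall is a trochanteric side impact within the α/β grid; the
  calibration of the surrogate absorbs the fact that most real-world
  falls do not load the hip directly.
* The exact strength backend requires externally computed strain
  fields; mesh generation and FE solving are out of scope.
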