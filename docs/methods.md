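# Methods

This note records the models, conventions and defaults behind
`nirscal`, and what the synthetic-data tests do and do not demonstrate.

## Spectra and preprocessing

Spectra are absorbance-like log(1/R) values on a fixed grid, 400–2500 nm
in 0.5 nm steps (4201 points). The preprocessing chain is fixed in
order: SNV → detrend → gap-segment derivative.

**SNV** standardises each spectrum to mean 0, SD 1 (n−1 denominator), so
it is exactly invariant to any per-spectrum affine map a·x + b with
a > 0 — the multiplicative and additive scatter model. **Detrend**
subtracts a per-spectrum least-squares polynomial in wavelength
(degree 2 by default), removing curvilinear baseline drift, including
the wavelength-linear tilt that survives SNV. Detrend is only offered
after SNV: detrending a raw-scale spectrum would mix scatter back in.

**Gap-segment derivative.** The math treatment `d,g,s,s2` applies a
running mean over `s` points, then `d` passes of the centred gap
difference f(λ+g/2) − f(λ−g/2), then an optional second running mean
over `s2` points (`1` = none). Conventions:

* The gap `g` is in nm and must map to a positive even number of grid
  points; the smoothing segments are in points. The asymmetry is
  deliberate — it mirrors how the treatment codes are quoted in
  practice (gap in nm, segments in points).
* Even smoothing windows use the left-biased half-open window
  [i−s/2, i+s/2−1], keeping the common even segment lengths (e.g. 6)
  usable. The treatment-code field is therefore any positive integer,
  not just odd values.
* Differences are **not** divided by the gap width: the constant is
  absorbed by the downstream regression coefficients, which keeps the
  pipeline scale-equivariant and the bookkeeping simple.
* Edges are trimmed, never padded. The default `2,8,6,1` on a 0.5 nm
  grid trims 19 points on the left and 18 on the right
  (6-point smooth: 3+2; two passes of the 16-point gap: 16 per side),
  leaving 4164 of 4201 points. `trim_per_side` reports this.

Whether the original instrument software applies detrend before or
after SNV, or which even-window convention it uses, is not public; the
choices above are documented defaults, selected for their algebraic
properties, not claimed bit-compatibility.

## Modified PLS

The regression engine is NIPALS PLS1 on centred X and y (no column
scaling of X). The *modified* variant standardises the columns of the
spectral residual matrix (divides by their SDs, n−1) after each factor
is deflated, preventing a few high-variance wavelengths from dominating
late factors. Residual columns with zero SD are left unscaled. With
`residual_scaling=False` the algorithm is exactly standard PLS1 — the
test suite verifies prediction equality with scikit-learn's
`PLSRegression(scale=False)` to 1e-6 — so the modification is the only
untestable-by-oracle ingredient, and it is exercised by behaviour
(parameter recovery) instead.

Because every stage is linear, the stage-wise model collapses to one
regression vector per term count,
b_t = Σ_{a≤t} q_a·M_{a−1}w_a with M_a = M_{a−1}(I − w_a p_aᵀ)D_a⁻¹,
computed by back-substitution in O(t²·p); predictions are a dot
product, and serialized models are self-contained JSON.

**Cross-validation.** Groups are formed cyclically over the input
ordering (sample i → group i mod G, no shuffling); G defaults to 5.
SECV(t) = √(Σ(ŷ_cv − y)²/N) pooled over all held-out samples. The
selected term count is the smallest t with
SECV(t) ≤ (1 + tol)·min SECV, tol = 0 by default, with an absolute tie
floor of 1e-9·SD(y) so that exactly recoverable data select the
generating rank rather than a numerically-smaller zero. The original
software's proprietary F-test is approximated by this rule.

**SEC monotonicity.** SEC uses the df-corrected denominator
√(Σe²/(N−t−1)). It decreases monotonically while factors still remove
real variance; past the informative rank the numerator plateaus while
the df shrink, and SEC can tick up slightly. The residual sum of
squares itself is always non-increasing. Term selection by SECV keeps
fitted models inside the monotone regime.

**Global H.** GH is the squared Mahalanobis distance of a spectrum's
factor scores from the calibration-score centroid (n−1 covariance),
divided by f·(N−1)/N where f = min(selected terms, 10) factors — the
normalisation under which the calibration-set mean GH is exactly 1.
The outlier protocol is asymmetric by design: samples with GH > 3 are
removed once and the model refitted (round 1); any GH > 3 in the
refitted model is reported but kept (round 2). This prevents the
iterative chiselling-away of the calibration set.

## Validation statistics

With e = predicted − reference (the sign convention is a package
choice; printed tables constrain only magnitudes):

* bias = mean(e); SEP = √(Σe²/N);
  SEP(C) = √(N/(N−1)·(SEP² − bias²)) ≡ SD of residuals (n−1).
  This denominator pairing is the one that reproduces the published
  SEP(C) cells from their SEP/bias/N companions, and is fixed.
* SEC = √(Σe²/(N−t−1)) on fitted calibration residuals;
  SECV = √(Σe²/N) on cross-validation residuals.
* Calibration and validation R² are squared Pearson correlations of
  predicted vs measured; the validation slope is the OLS slope of
  predicted (response) on measured (predictor). Calibration R² uses
  fitted, not cross-validated, values.
* RPD = SD/SEP (or SD/SECV), reported to one decimal.

Validation outlier screening (for heterogeneous-matrix sets) flags
samples with |e − bias| > k·SEP(C), k = 2.5 by default (the choice of k
is a package default; screening is report-first and runs exactly one
removal round). Reports are invariant to sample ordering.

## AmAc single-extraction calibration

Extractable concentrations and totals are both expressed in g/L
substrate (dry-matter totals converted as g/kg DM × kg DM/L = g/L via
dry bulk density). The calibration is OLS of √(total) on
√(extractable); prediction squares the clamped-at-zero sqrt-scale value.
Squaring without a retransformation-bias correction follows standard
reporting practice for these calibrations and is a known (small,
noise-dependent) bias source. The shipped coefficient file
(`nirscal/data/amac_equations.json`, versioned) carries the published
slopes/intercepts per element: P 1.22/2.23, K 0.93/1.80, Ca 1.45/−8.60,
Mg 1.53/−4.40 — note the sqrt-scale slope ordering K < P < Ca < Mg,
i.e. extractability relative to totals decreases K > P > Ca > Mg.
Validation regresses back-transformed predictions on measured totals on
the raw scale.

## Synthetic data generator

The generator emulates two datasets: a strawberry-leaf set
(N, P, K, Mg, Ca; default 369 samples, split 294/75) and a
growing-media set (plus OM, pH, EC, C/N, C/P; default 567, split
458/109), with published means/SDs, published ranges where available
(N 0.6–3.5 %/DM, P 700–6300 and K 2000–29000 mg/kg DM), mean ± 4 SD
otherwise, and pinned correlations (leaf: corr(P,K)=0.80,
corr(Mg,Ca)=−0.22; media: corr(Mg,Ca)=0.88, corr(Mg,K)=corr(N,K)=0.49).
Unpinned off-diagonals default to 0.3 and the matrix is projected to
the nearest PSD correlation matrix.

**Concentrations** are drawn from a Gaussian copula with
range-truncated normal marginals whose latent parameters are
moment-matched so the truncated mean/SD hit the configured targets.
A joint-rejection truncated MVN was considered and rejected: when a
marginal's target SD is near or beyond what its range permits, the
inflated latent scale couples through the joint acceptance region,
biasing *other* marginals and collapsing the configured correlations.
The copula keeps marginals exact and decoupled at the cost of a ~2%
attenuation of Pearson correlations through the monotone transforms.
One limitation is inherent: the leaf potassium SD (9560 on the range
2000–29000) exceeds the SD of *any* truncated normal on that interval
(the family saturates at the uniform limit, ≈7790), so the generated K
SD sits ~19% low; the real data are evidently multi-modal across
fertiliser trials, which the single-component model does not emulate.

**Spectra.** Each constituent absorbs through 3 Gaussian bands (centres
uniform on 1100–2500 nm, widths 20–80 nm, amplitudes scaled inversely
to the constituent's mean so each contributes ~0.1 AU). On top sits a
fixed matrix-background spectrum (4 broad bands, 100–300 nm wide,
~1 AU total) representing the dominant cellulose/water absorbance of a
dried, ground sample. This background matters: it is what makes each
spectrum's wavelength-SD nearly composition-independent, which in turn
is why SNV behaves as an affine correction rather than a nonlinear
distortion — on a pure constituent mixture the same pipeline degrades
badly. Each replicate scan (2 by default, averaged) receives
α·A + β₀ + β₁·(λ−1450)/1050 + ε with α ~ LogNormal(0, 0.05),
β₀, β₁ ~ N(0, 0.02) and ε ~ N(0, 1e-4) per point (~100 µAU, a typical
bench-instrument noise floor). No published noise/scatter magnitudes
exist for these instruments; the defaults are realism-based choices,
documented here, and tunable.

**AmAc pairs** follow √(total) = a·√(amac) + b + ε with the shipped
coefficients, extractable concentrations uniform on element-specific
default ranges (P, K 0.5–8; Mg 10–100; Ca 40–400 g/L — the wider Ca/Mg
ranges keep the negative-intercept equations out of the clamped
region), and sqrt-scale noise defaulting to 0.1, the level at which the
synthetic potassium calibration reproduces the published calibration
R² ≈ 0.97.

**What the synthetic tests show — and don't.** Passing parameter
recovery (validation R² ≥ 0.95, |slope−1| ≤ 0.1 on the leaf preset)
shows the pipeline is internally correct and statistically efficient
under a Beer–Lambert world with the configured scatter and noise. It
does not certify performance on real spectra, which add moisture and
particle-size effects, band overlap with the matrix, instrument drift
and reference-method error; no physically meaningful band assignments
are attempted, and fresh-versus-dried effects are out of scope.

## Numerical choices and degenerate inputs

* Determinism everywhere: every stochastic function takes an explicit
  seed; identical config + seed reproduce outputs bitwise. CV group
  assignment and the outlier protocol are fully deterministic.
* Constant (zero-SD) spectra are rejected by SNV with the offending
  sample id; zero-variance y and zero-variance sqrt-extractables are
  rejected by the fitters.
* Constituent-wise missing reference values are dropped pairwise
  (reports carry per-constituent N); never imputed.
* If round-1 outlier removal would leave ≤ max_terms+1 samples, the
  round-1 model is kept and a warning issued instead of refitting.
* Negative sqrt-scale extraction predictions clamp to 0 before
  squaring.
* Problem sizes in the test suite: the full leaf preset (369 × 4201)
  runs in seconds; unit tests use smaller matrices (tens × hundreds)
  chosen as the smallest sizes that still separate signal from noise.
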