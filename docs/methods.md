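# Methods

## The profile and its parameterization

`voigtkit` works in reduced coordinates.  A physical component is
`VoigtShape(center x0, gauss_width w, xi, area A)` where `w` is the
Gaussian **1/e half-width** (so the Gaussian factor is `exp(-((x-x0)/w)²)`,
HWHM `sqrt(ln 2)·w`), and `xi = omega_L / w` with `omega_L` the Lorentzian
HWHM.  The density in reduced units is

    V(v, xi) = (1/pi) ∫₀^∞ exp(-xi·y - y²/4) cos(v·y) dy ,

normalized to unit area; the physical density is `A·V((x-x0)/w, xi)/w`.
This cosine-transform form is the package's single normalization anchor:
the equivalent convolution form carries the prefactor `xi/pi^{3/2}`, and
the Faddeeva-type function satisfies `Re W(v + i·xi) = sqrt(pi)·V(v, xi)`
(the package calibrated this constant against the integral rather than
assuming it; `faddeeva_like` returns the unnormalized complex `W`, whose
imaginary part is exposed for dispersive-lineshape work).

## Exact series evaluator

`voigt_series` evaluates

    V(v, xi) = (2·xi/pi^{3/2}) Σ_{n∈ℤ} exp(-(v - n/2)²) / (n² + 4·xi²)
             - (2/sqrt(pi)) · exp(xi² - v²) · cos(2·xi·v) / expm1(4·pi·xi)

The first piece is a shifted-Gaussian comb over half-integers (the
analytically recombined form of `e^{-v²} e^{-n²/4} cosh(n·v)`; the naive
cosh factorization overflows for |n·v| ≳ 700).  The second is the
closed-form pole correction, written through `expm1` because
`1 - coth(2·pi·xi) = -2/expm1(4·pi·xi)` exactly — this removes the
catastrophic small-`xi` cancellation between the coth term and the `n = 0`
comb term.

Numerical branching, each switch point chosen where the two branches agree
to better than the target accuracy:

* **`xi < 1e-8`** — return the Gaussian limit `e^{-v²}/sqrt(pi)`.  The
  grouped correction-plus-`n=0` evaluation loses about `eps/xi` absolute
  accuracy, while the Gaussian limit is wrong by at most `(2/pi)·xi`; the
  two error curves cross near `1e-8`, where both are ~6e-9.
* **`xi ≥ 6`** — drop the pole correction.  Its true magnitude is
  `~exp(xi² - 4·pi·xi)` (≈1e-39 at the threshold, utterly negligible), but
  the closed form is the analytic continuation of the *small-xi* residue
  correction and becomes spurious as `xi` approaches `4·pi`, where it
  diverges; the comb alone is machine-exact there because the trapezoid
  error of the underlying convolution saturates at `~e^{-4·pi²}` once the
  integrand's poles leave the optimal summation strip.
* **comb truncation** — only terms with `|v - n/2| ≤ sqrt(-ln tol) + 2`
  contribute above `tol`; the window slides with `v`, making the cost per
  point O(1) even for Cauchy-tailed sample arrays reaching |v| ~ 1e5.
* evaluation at `|v|` makes the even symmetry bit-exact.

Measured against adaptive quadrature of the defining integral (and,
independently, scipy's Faddeeva function), the series is accurate to
better than 1e-10 absolute for every `xi ≥ 0` and |v| ≤ 8; the tests pin
1e-8 on the acceptance grid with wide margin.

`voigt_oracle` integrates any of the three defining integral forms with
SciPy's adaptive quadrature, cutting the range from the `e^{-y²/4}`
envelope and subdividing at cosine half-periods for |v| > 5.  In the far
tail the oscillatory integral cancels almost completely; results are
accepted when the absolute error estimate is at the 1e-12 noise level even
if the relative target is unreachable there.

## Limiting approximations and their validated regimes

Four closed approximations are exposed (they are *evaluable* anywhere;
`regime_ok` reports whether a point lies in the validated region, and the
CLI flags out-of-regime use):

| form | expression sketch | regime | measured max rel. error |
| --- | --- | --- | --- |
| near-peak Gaussian dominance | `e^{-v²}[erfcx(xi)cos(2 xi v) + 2 sin²(xi v)/(sqrt(pi) xi) · poly(v, xi)]/sqrt(pi)` | \|v\| ≤ 0.5, xi ≤ 0.3 | 1e-3 |
| small-xi two-cosine form | `e^{-v²}[1/(pi·xi) + b(xi) cos(2 xi v)]` | \|v\| ≤ 0.5, xi ≤ 0.1 | 2e-3 |
| Lorentzian-dominance comb | the shifted-Gaussian comb alone | xi ≥ 1 | 1e-4 |
| far-tail Lorentzian | `xi/(pi(xi²+v²)) · [1 + v²/(xi²+v²)²]` | xi ≥ 10 | 5e-3 |

The two-cosine form's constant pair is fixed by internal consistency: its
peak value `a + b` must reproduce the exact peak law
`V(0, xi) = erfcx(xi)/sqrt(pi)`, which forces `a = 1/(pi·xi)` and
`b = [erfcx(xi) - 1/(sqrt(pi)·xi)]/sqrt(pi)`; the same pair falls out of
the near-peak form via `2 sin² = 1 - cos`.  The bounds in the table were
established by sweeping each form against the quadrature oracle and are
re-verified by the test suite on every run.

The production evaluator and both fitting pipelines always use the exact
series — routing 1e-3-accurate approximations into an optimizer would bias
the recovered `xi` — so the approximations serve analysis and
cross-checking, not fitting.

## Variance

The full profile's second moment reduces to a series whose terms tend to
1: the variance is *undefined* for every `xi > 0` (the Lorentzian `1/v²`
tail).  `variance_full` returns an explicit infinite sentinel with
`finite=False` — divergence is a mathematical statement, never a float
overflow.  Two closed forms exist for Gaussian dominance:

    Var_a = (1/2)(1-2 xi²) erfc(xi)
          + (1-e^{-xi²})/(sqrt(pi)·xi) · (0.6259 + 0.0814 xi²)
          + e^{-xi²}/pi · (1.5486 xi + 0.2605 xi³ - 0.3136 xi⁵ + 0.0434 xi⁷)

    Var_b = (1/2)(1-2 xi²) erfc(xi)
          + [1 - (1-2 xi²) e^{-xi²}] / (2 sqrt(pi)·xi)

Both tend to 1/2 (the Gaussian value) as `xi -> 0` and agree to ≤2e-6 for
`xi ≤ 0.01`; near zero they are evaluated through `expm1` to avoid 0/0.
`Var_a` is flat (<2%) over [0, 0.01], dips through the
Gaussian-to-Lorentzian transition, and rises again past `xi ≈ 3`; `Var_b`
is meaningful only for `xi ≪ 1` — its large-`xi` decay is an artifact of
using the small-`xi` form outside its regime.  `variance_numeric_truncated`
is the quadrature oracle for the truncated second moment; it grows like
`(2·xi/pi)·vmax`, so comparisons with the closed forms are meaningful only
where that tail term is small (at `xi = 0.01` it already contributes ~7%
by `vmax = 6`; the cross-validation test therefore uses `xi = 0.001`).

## Lévy connection

`levy_pdf` evaluates the symmetric stable density
`(1/pi)∫₀^∞ e^{-gamma·y^alpha} cos(v·y) dy` with SciPy's Fourier-weight
quadrature (QAWF: half-period subdivision with series acceleration), which
reproduces the Gaussian (`alpha = 2`) and Lorentzian (`alpha = 1`) closed
forms to ≤1e-10 and matches SciPy's independent stable-law implementation
to ≤1e-8 for intermediate indices.  In this parameterization `gamma`
corresponds to SciPy's `scale**alpha`.

The truncated Lévy flight hard-cuts the density at `±l` and renormalizes
(`norm_c = 1/mass ≥ 1`); the cutoff is kept literal — discontinuous at
`±l` — because the Voigt profile itself is the smooth alternative, with
`1/xi` playing the cutoff role (`cutoff_from_xi`).  Sampling is exact
(inverse-CDF) for `alpha = 1`, exact-resampled for `alpha = 2`, and
rejection from a truncated Cauchy envelope otherwise, with the envelope
constant measured on a setup grid with a 10% safety margin.  All samplers
are driven by a `numpy` Generator and bit-reproducible under a seed.

## Fitting

Mixture model: `Σ_j A_j · V((x - c_j)/w_j, xi_j) / w_j`, 1 or 2
components, bounded trust-region least squares with three seeded starts
(initials from mode detection: peak location, half-width at half-maximum,
`xi` start 0.5).  `xi` is fitted as `log10 xi` on [-4, 3] — its relevant
dynamic range spans 1e-2…1e1 and more — and its standard error is
propagated back to the linear scale from the Jacobian-based covariance
with reduced-chi-square scaling.  Convergence is reported honestly: a
max-iteration exit sets `converged=False`.

Loss functions, in order of preference:

* **histogram data** (counts available): variance-stabilized Poisson
  residuals `2(sqrt(counts + 3/8) - sqrt(mu + 3/8))` on bin-integrated
  expected counts (Simpson average over each bin).  Weighting density
  values by observed-count sigmas collapses under heavy tails — near-empty
  bins get enormous weight and drag `xi` down by tens of percent — while
  model-variance (Pearson) weights over-reward isolated tail counts and
  bias `xi` up; the square-root transform has neither pathology.
* **tabulated densities**: weighted least squares on the values, weights
  from supplied uncertainties, else uniform.
* **raw samples** (`method="mle"`): direct mixture likelihood, useful when
  Lorentzian tails make any histogram inefficient; very large inputs are
  strided down to 2e5 points for tractable likelihood evaluations.

Histograms default to 250 bins over `median ± 12·IQR/1.349`: a robust
range is essential because with Cauchy tails both the sample extremes and
extreme quantiles put the entire Gaussian core into one bin; the density
is conditional on the range and the free component area absorbs the
clipped tail mass.  Measured recovery under the package's own generator
(10⁵ Normal+Cauchy draws, 20 replicates): median relative error of fitted
`xi` between 1.8% and 4.6% across `xi_true ∈ {0.1, 0.5, 1, 2}`, with a
residual −3…−4% bias at `xi = 2` (the Gaussian core carries little signal
once the profile is Lorentzian-dominated); 95%-interval coverage ≈90%.
Bimodal mixtures are fitted jointly — overlapping tails bias
mode-by-mode fits — with per-mode masked fits available via `mask`.

### QENS

The incoherent scattering model at one momentum transfer is an elastic
delta plus `n` quasielastic Lorentzians, attenuated by the
Debye–Waller-type factor `exp(-Q²⟨u²⟩/3)`.  Convolution with the Gaussian
instrument resolution (1/e half-width `w_res`, fixed during fits) is
closed-form: the delta becomes the unit-area resolution Gaussian and each
Lorentzian of HWHM `Gamma_i` a Voigt profile with `xi_i = Gamma_i/w_res`.
`fit_qens` parameterizes the weights on the simplex (stick-breaking, so
`A0 + ΣA_i = 1` holds by construction), fits `Gamma_i` in log space, and
optionally a flat background (off by default; the ideal model has none).
The overall scale absorbs the Debye–Waller factor, which is not separable
from detector normalization at a single Q.  Widths pinned at the fit
bounds are flagged as non-identifiable rather than returned silently.
A `window` argument restricts the fit to `lo ≤ |omega| ≤ hi`, mirroring
the two fitting modes used for real spectra (whole-spectrum vs
high-energy-only); fitting a free single Voigt to the high-energy wings of
a Gaussian-dominated spectrum returns a small `xi`, while whole-spectrum
fits of a temperature ladder with broadening lines give strictly
increasing `xi`.

## Synthetic generators: what they emulate, and what they do not

* `gen_voigt_samples` is **exact** (the defining convolution:
  Normal(sd `w/sqrt(2)`) + Cauchy(HWHM `xi·w`)), so recovery tests carry a
  true ground-truth `xi`.
* `gen_two_state` emulates folding/unfolding switching of an
  order-parameter trajectory: a two-state Markov chain (geometric
  residence times, drawn segment-wise) with per-state Voigt observation
  noise.  Per-state noise is Voigt *by construction* so that a per-mode
  ground truth exists; real folding PDFs motivate but do not guarantee
  that shape.  No kinetic coupling between noise and switching, no
  intermediate states, no autocorrelation within a state — passing
  recovery tests shows the pipeline extracts `xi` from data of this
  statistical shape, not that real trajectories are two-state.
* `gen_dihedral` integrates overdamped Langevin dynamics on the circle
  (Euler–Maruyama; stability guard `curvature·D·dt/kT < 0.1`, burn-in of
  ten relaxation times from a potential minimum) in flat, harmonic, or
  periodic multi-well potentials and returns wrapped lag increments.  It
  emulates the statistics of backbone-dihedral rotation — harmonic wells
  give near-Gaussian increments, deep multi-well hopping gives
  heavy-tailed ones — not any specific force field.
* `gen_qens` adds relative-Gaussian noise (sigma = noise·I + floor, the
  floor at 1% of the peak sigma so weights stay finite) or Poisson
  counting noise to the closed-form spectrum, with the per-point sigma
  reported honestly in the error column.  Real spectrometer artifacts
  (asymmetric resolution, detector balance, multiple scattering) are out
  of scope.

Problem sizes used by the test suite and the acceptance script — 10⁵
draws per recovery replicate, 2×10⁵-step switching trajectories, 801-point
spectra — are the package's chosen study conditions: large enough that
Monte-Carlo error sits well below the tolerances being asserted, small
enough that the whole suite runs in minutes on one CPU.

## Known limitations

* The series' closed-form correction is invalid for `xi` between ~11 and
  `4·pi`; the implementation sidesteps this via the `xi ≥ 6` branch, but
  anyone re-deriving the formula should be aware the printed correction is
  a small-`xi` residue form.
* Fitted `xi` carries a small negative bias (few %) in strongly
  Lorentzian-dominated samples, where the Gaussian width is weakly
  identified from histogram data; the MLE mode reduces but does not
  remove it.
* The `1/xi` cutoff reading is an interpretation, not a quantitative
  equivalence between Voigt tails and hard-truncated Lévy tails; the
  package exposes both objects but asserts no mapping between them.
* Single-Q QENS fits only; no global multi-Q analysis, no elastic
  incoherent structure factor extraction, no model selection over the
  number of Lorentzians (the user chooses `n`).
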