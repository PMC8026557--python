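# voigtkit

The Voigt profile — the convolution of a Gaussian and a Lorentzian — is
the universal lineshape interpolating between the two, and it turns out to
be just as useful away from spectroscopy: probability distributions of
protein-folding order parameters (radius of gyration, backbone dihedral
increments) and quasielastic neutron-scattering (QENS) spectra all live on
the Gaussian–Lorentzian continuum.  `voigtkit` evaluates the profile
exactly, exposes its limiting approximations and variance formulas,
connects it to Lévy-stable and truncated-Lévy-flight statistics, and fits
it to data to extract the single number that locates a distribution on
that continuum: the **line-damping parameter**

```
xi = omega_L / omega_G'
```

the ratio of the Lorentzian half-width at half-maximum to the Gaussian 1/e
half-width.  In reduced coordinates `v = (x - x0)/omega_G'`,

```
V(v, xi) = (1/pi) ∫₀^∞ exp(-xi*y - y²/4) cos(v y) dy
         = Re[W(v + i*xi)] / sqrt(pi),    W(z) = e^{-z²} erfc(-iz)
```

with `xi -> 0` giving the Gaussian `e^{-v²}/sqrt(pi)` and `xi -> ∞` the
Lorentzian `xi/(pi (v² + xi²))`.  Small `xi` means near-Gaussian local
dynamics; growing `xi` signals heavy Lorentzian tails — long jumps over
folding barriers, multi-well dihedral hopping, or rising quasielastic
intensity with temperature.  The reciprocal `1/xi` acts as the effective
cutoff length of a truncated Lévy flight embedded in the profile.

## Who it is for

Researchers analysing molecular-simulation order-parameter distributions
or incoherent neutron spectra who want a principled Gaussian/Lorentzian
deconvolution: per-mode `xi` for unimodal or bimodal PDFs, and
`xi = Gamma / omega_res` per quasielastic Lorentzian for
resolution-convolved spectra.

## What is inside

| module | contents |
| --- | --- |
| `voigtkit.core` | exact rapidly-converging series evaluator, quadrature oracle for all three defining integrals, Gaussian/Lorentzian-dominance approximations, Faddeeva-type `W(z)`, Dawson function, physical-units wrapper |
| `voigtkit.moments` | variance of the profile: divergent full form (flagged, never a float overflow), two Gaussian-dominance closed forms, truncated numerical second moment |
| `voigtkit.levy` | symmetric Lévy-stable density by cosine-transform quadrature, truncated Lévy flight (normalizer, density, variance, seeded sampler), the `1/xi` cutoff reading |
| `voigtkit.fitting` | histogram densities with Poisson statistics, mode detection, 1–2-component Voigt mixture fits (least squares or maximum likelihood), QENS model evaluation and inversion, `xi`-vs-covariate trend tables |
| `voigtkit.synthetic` | seeded generators: exact Voigt sampler, two-state folding-like trajectories with per-state Voigt noise, overdamped circular diffusion of a dihedral angle, noisy QENS spectra |
| `voigtkit.cli` | `voigt-eval`, `voigt-var`, `voigt-fit`, `levy-pdf`, `tlf-sample`, `rg-sim`, `dihedral-sim`, `qens-sim`, `qens-fit`, `xi-trend` |

## Worked example

Draw 10⁵ samples from a Voigt-shaped radius-of-gyration-like density
(center 1.45 nm, Gaussian 1/e half-width 0.12 nm, true `xi = 0.4`) and fit
them back:

```python
import voigtkit as vk

shape   = vk.VoigtShape(center=1.45, gauss_width=0.12, xi=0.4)
samples = vk.gen_voigt_samples(100_000, shape, seed=1)
fit     = vk.fit_voigt(vk.histogram_pdf(samples), n_components=1, seed=0)
c = fit.components[0]
print(f"center      = {c.center:.4f} nm")
print(f"gauss width = {c.gauss_width:.4f} nm (1/e half-width)")
print(f"xi          = {c.xi:.4f} +/- {fit.xi_stderr[0]:.4f}")
print(f"lorentz HWHM= {c.lorentz_hwhm:.4f} nm")
```

prints

```
center      = 1.4497 nm
gauss width = 0.1203 nm (1/e half-width)
xi          = 0.3910 +/- 0.0070
lorentz HWHM= 0.0470 nm
```

i.e. the fitted line-damping parameter is within ~2% of the generating
value, and its 95% interval covers the truth.  `vk.cutoff_from_xi(c.xi)`
reads the same number as a truncated-Lévy cutoff length (`1/xi ≈ 2.56`
reduced units, intermediate regime), and `vk.variance_full(c.xi)` reminds
you that the untruncated profile has no finite variance — the reason the
Gaussian-dominance closed forms (`variance_gauss_a/b`) exist.

A two-state trend demonstration mirrors the folding phenomenology: make
switching trajectories whose state with more frequent long jumps carries a
larger generating `xi`, fit each mode, and `vk.xi_trend` tabulates the
monotone relation between mean residence time and fitted `xi` (see
`tests/test_fitting.py::test_xi_trend_residence_time_ladder`).

The same pipeline runs from the shell:

```sh
rg-sim --k-unfold 0.0 --n 40000 --seed 3 --out traj.tsv
qens-sim --gamma 0.1 --a0 0.6 --noise 0.02 --seed 5 --out spectrum.tsv
qens-fit --input spectrum.tsv --resolution-fwhm 0.1 --out fit.json
```

Every command writes its resolved configuration (including the seed) into
the output header or JSON envelope, so any run can be reproduced from its
own output.

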