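"""Fitting pipelines: histogram densities, mode detection, Voigt mixture
fits, QENS model evaluation and inversion, and the xi-trend table."""

import math

import numpy as np
import pytest

import voigtkit as vk

SQRT_PI = math.sqrt(math.pi)


# -------------------------------------------------------------- histogram


def test_histogram_normal_peak():
    rng = np.random.default_rng(1)
    pdf = vk.histogram_pdf(rng.normal(size=100_000), n_bins=50)
    assert pdf.density.max() == pytest.approx(1.0 / math.sqrt(2 * math.pi),
                                              rel=0.05)


def test_histogram_unit_area_rectangle_rule():
    rng = np.random.default_rng(2)
    for draw in (rng.normal(size=500), rng.standard_cauchy(size=5000)):
        pdf = vk.histogram_pdf(draw, n_bins=40)
        assert pdf.area == pytest.approx(1.0, abs=1e-9)


def test_histogram_rejects_degenerate_input():
    with pytest.raises(ValueError):
        vk.histogram_pdf(np.ones(500))
    with pytest.raises(ValueError):
        vk.histogram_pdf(np.arange(50))  # too few samples
    with pytest.raises(ValueError):
        vk.histogram_pdf(np.random.default_rng(0).normal(size=500), n_bins=5)


def test_empirical_pdf_validation():
    with pytest.raises(ValueError):
        vk.EmpiricalPDF(np.array([0.0, 0.0, 1.0]), np.zeros(3))
    with pytest.raises(ValueError):
        vk.EmpiricalPDF(np.array([0.0, 1.0]), np.array([-1.0, 0.0]))


# ------------------------------------------------------------ mode finding


def test_detect_single_mode(unit_shape):
    x = np.linspace(-6, 6, 301)
    pdf = vk.EmpiricalPDF(x, vk.voigt_pdf(x, unit_shape))
    modes = vk.detect_modes(pdf)
    assert modes.n_modes == 1
    assert modes.locations[0] == pytest.approx(0.0, abs=0.05)


def test_detect_two_separated_modes():
    # separation > 4 widths makes the mixture provably bimodal
    a = vk.VoigtShape(-3.0, 1.0, 0.3, 0.5)
    b = vk.VoigtShape(3.0, 1.0, 0.3, 0.5)
    x = np.linspace(-9, 9, 401)
    pdf = vk.EmpiricalPDF(x, vk.voigt_pdf(x, a) + vk.voigt_pdf(x, b))
    modes = vk.detect_modes(pdf)
    assert modes.n_modes == 2
    assert sorted(modes.locations) == pytest.approx([-3.0, 3.0], abs=0.1)


def test_detect_modes_flat_density_errors():
    x = np.linspace(0, 1, 50)
    with pytest.raises(vk.FitError):
        vk.detect_modes(vk.EmpiricalPDF(x, np.zeros(50)))


# ------------------------------------------------------------- Voigt fits


def test_fit_recovers_exact_model():
    """Noiseless self-consistency: parameters back to optimizer tolerance."""
    true = vk.VoigtShape(center=0.0, gauss_width=1.0, xi=0.5, area=1.0)
    x = np.linspace(-8, 8, 400)
    pdf = vk.EmpiricalPDF(x, vk.voigt_pdf(x, true))
    res = vk.fit_voigt(pdf, n_components=1, seed=0)
    c = res.components[0]
    assert res.converged
    assert c.center == pytest.approx(0.0, abs=1e-4)
    assert c.gauss_width == pytest.approx(1.0, abs=1e-4)
    assert c.xi == pytest.approx(0.5, abs=1e-4)
    assert c.area == pytest.approx(1.0, abs=1e-4)


def test_fit_recovers_xi_from_samples():
    """Normal + Cauchy draws: xi = gamma_L / (sigma sqrt(2)) within 5%."""
    sigma, gamma_l = 1.0, 0.5
    xi_true = gamma_l / (sigma * math.sqrt(2.0))
    shape = vk.VoigtShape(0.0, sigma * math.sqrt(2.0), xi_true)
    s = vk.gen_voigt_samples(100_000, shape, seed=12)
    res = vk.fit_voigt(vk.histogram_pdf(s), n_components=1, seed=0)
    assert res.converged
    assert res.xi == pytest.approx(xi_true, rel=0.05)


def test_fit_two_component_recovery():
    p = vk.TwoStateParams(
        mu_folded=1.0, mu_unfolded=1.8,
        noise_folded=vk.VoigtShape(0.0, 0.08, 0.1),
        noise_unfolded=vk.VoigtShape(0.0, 0.15, 0.5),
        k_fold=0.01, k_unfold=0.01, n_steps=200_000, seed=11)
    traj = vk.gen_two_state(p)
    res = vk.fit_voigt(vk.histogram_pdf(traj.values, n_bins=200),
                       n_components=2, seed=0)
    comps = sorted(res.components, key=lambda c: c.center)
    assert comps[0].xi == pytest.approx(0.1, rel=0.10)
    assert comps[1].xi == pytest.approx(0.5, rel=0.10)


def test_fit_reparameterization_invariance():
    """Changing abscissa units rescales x0 and width, leaves xi alone."""
    true = vk.VoigtShape(0.2, 0.9, 0.7, 1.0)
    x = np.linspace(-8, 8, 400)
    d = vk.voigt_pdf(x, true)
    r1 = vk.fit_voigt(vk.EmpiricalPDF(x, d), seed=0)
    k = 1000.0
    r2 = vk.fit_voigt(vk.EmpiricalPDF(k * x, d / k), seed=0)
    c1, c2 = r1.components[0], r2.components[0]
    assert c2.xi == pytest.approx(c1.xi, rel=1e-6)
    assert c2.center == pytest.approx(k * c1.center, rel=1e-4, abs=1e-3)
    assert c2.gauss_width == pytest.approx(k * c1.gauss_width, rel=1e-6)


def test_fit_mle_mode_on_samples():
    shape = vk.VoigtShape(0.0, math.sqrt(2.0), 0.5)
    s = vk.gen_voigt_samples(50_000, shape, seed=4)
    res = vk.fit_voigt(vk.histogram_pdf(s), method="mle", seed=0)
    assert res.method == "mle"
    assert res.xi == pytest.approx(0.5, rel=0.10)


def test_fit_rejects_bad_requests(unit_shape):
    x = np.linspace(-6, 6, 101)
    pdf = vk.EmpiricalPDF(x, vk.voigt_pdf(x, unit_shape))
    with pytest.raises(ValueError):
        vk.fit_voigt(pdf, n_components=3)
    with pytest.raises(vk.FitError):
        vk.fit_voigt(pdf, mask=np.zeros(101, dtype=bool))
    with pytest.raises(vk.FitError):
        vk.fit_voigt(pdf, method="mle")  # no raw samples attached


# ------------------------------------------------------------------ QENS


def _resolution():
    # 0.1 meV FWHM Gaussian resolution -> 1/e half-width
    return 0.1 / (2.0 * math.sqrt(math.log(2.0)))


def test_qens_model_validation():
    r = _resolution()
    with pytest.raises(ValueError):
        vk.QENSModel(1.0, 0.0, 0.5, ((0.4, 0.1),), r)  # weights != 1
    with pytest.raises(ValueError):
        vk.QENSModel(1.0, 0.0, 0.5, ((0.5, -0.1),), r)  # bad width
    m = vk.QENSModel(1.0, 0.0, 0.6, ((0.4, 0.1),), r)
    assert m.xi[0] == pytest.approx(0.1 / r)


def test_qens_elastic_only_is_resolution_gaussian():
    r = _resolution()
    m = vk.QENSModel(q=1.0, msd=0.0, elastic_fraction=1.0, components=(),
                     resolution_width=r)
    w = np.linspace(-1, 1, 201)
    expected = np.exp(-(w / r) ** 2) / (r * SQRT_PI)
    np.testing.assert_allclose(vk.qens_spectrum(w, m), expected, rtol=1e-12)


def test_qens_lorentzian_becomes_voigt():
    # Gamma = 0.1 meV over a 0.0721 meV (1/e half-width) resolution
    r = 0.0721
    m = vk.QENSModel(q=1.0, msd=0.0, elastic_fraction=0.0,
                     components=((1.0, 0.1),), resolution_width=r)
    assert m.xi[0] == pytest.approx(1.387, abs=0.01)
    w = np.linspace(-2, 2, 401)
    ref = vk.voigt_pdf(w, vk.VoigtShape(0.0, r, 0.1 / r))
    np.testing.assert_allclose(vk.qens_spectrum(w, m), ref, atol=1e-8)


def test_qens_debye_waller_scaling():
    r = _resolution()
    w = np.linspace(-2, 2, 101)
    m1 = vk.QENSModel(1.0, 0.3, 0.6, ((0.4, 0.1),), r)
    m2 = vk.QENSModel(1.0, 0.6, 0.6, ((0.4, 0.1),), r)
    ratio = vk.qens_spectrum(w, m2) / vk.qens_spectrum(w, m1)
    np.testing.assert_allclose(ratio, math.exp(-1.0 * 0.3 / 3.0), rtol=1e-12)


def test_qens_round_trip_recovers_gamma():
    r = _resolution()
    m = vk.QENSModel(1.0, 0.0, 0.6, ((0.4, 0.1),), r)
    omega = np.linspace(-2, 2, 801)
    spec = vk.gen_qens(vk.QENSGenParams(model=m, omega=omega, noise=0.02,
                                        seed=5))
    fit = vk.fit_qens(omega, spec.intensity, r, err=spec.err,
                      n_lorentzians=1)
    assert fit.converged and not fit.warnings
    assert fit.model.components[0][1] == pytest.approx(0.1, rel=0.05)
    assert fit.model.elastic_fraction == pytest.approx(0.6, abs=0.05)


def test_qens_temperature_ladder_monotone_xi():
    """Broader quasielastic lines at higher temperature => rising xi."""
    r = _resolution()
    omega = np.linspace(-2, 2, 801)
    fits = []
    for i, (temp, gamma) in enumerate(zip([300, 330, 370, 400],
                                          [0.03, 0.06, 0.12, 0.2])):
        m = vk.QENSModel(1.0, 0.0, 0.5, ((0.5, gamma),), r)
        spec = vk.gen_qens(vk.QENSGenParams(model=m, omega=omega,
                                            noise=0.02, seed=100 + i))
        fits.append((temp, vk.fit_qens(omega, spec.intensity, r,
                                       err=spec.err, n_lorentzians=1)))
    df = vk.xi_trend(fits)
    assert list(df["covariate"]) == [300, 330, 370, 400]
    assert np.all(np.diff(df["xi"]) > 0)


def test_qens_high_energy_window_gaussian_dominated():
    """A Gaussian-dominated spectrum fitted only at |omega| > 1 meV gives a
    small line-damping parameter."""
    m = vk.QENSModel(q=1.0, msd=0.0, elastic_fraction=0.0,
                     components=((1.0, 0.04),), resolution_width=0.8)
    omega = np.linspace(-2.5, 2.5, 601)
    spec = vk.gen_qens(vk.QENSGenParams(model=m, omega=omega, noise=0.02,
                                        seed=9))
    pdf = vk.EmpiricalPDF(omega, np.clip(spec.intensity, 0.0, None),
                          sigma=spec.err)
    res = vk.fit_voigt(pdf, mask=np.abs(omega) >= 1.0, seed=0)
    assert res.xi < 0.3  # Gaussian-dominant regime


def test_qens_window_too_narrow_errors():
    r = _resolution()
    m = vk.QENSModel(1.0, 0.0, 0.6, ((0.4, 0.1),), r)
    omega = np.linspace(-2, 2, 801)
    clean = vk.qens_spectrum(omega, m)
    with pytest.raises(vk.FitError):
        vk.fit_qens(omega, clean, r, window=(1.996, 2.0))


# ---------------------------------------------------------------- trends


def test_xi_trend_sorts_and_propagates():
    rows = [(330.0, (0.5, 0.02)), (300.0, (0.3, 0.01))]
    df = vk.xi_trend(rows)
    assert list(df["covariate"]) == [300.0, 330.0]
    assert list(df["xi"]) == [0.3, 0.5]
    with pytest.raises(ValueError):
        vk.xi_trend([(300.0, (0.3, 0.01))])


def test_xi_trend_residence_time_ladder():
    """Constructed ladder: longer native residence paired with smaller xi;
    the fitted trend must reproduce the monotone ordering by rank."""
    from scipy.stats import spearmanr
    entries = []
    for i, (k_unfold, xi_gen) in enumerate(zip([0.02, 0.01, 0.005],
                                               [0.6, 0.3, 0.15])):
        p = vk.TwoStateParams(
            mu_folded=1.0, mu_unfolded=2.0,
            noise_folded=vk.VoigtShape(0.0, 0.08, xi_gen),
            noise_unfolded=vk.VoigtShape(0.0, 0.15, 0.5),
            k_fold=0.02, k_unfold=k_unfold, n_steps=150_000, seed=20 + i)
        traj = vk.gen_two_state(p)
        folded = traj.values[traj.states == 0]
        res = vk.fit_voigt(vk.histogram_pdf(folded, n_bins=150), seed=0)
        mean_res = traj.residence_times(0).mean()
        entries.append((mean_res, res))
    df = vk.xi_trend(entries)
    rho = spearmanr(df["covariate"], df["xi"]).statistic
    assert rho == -1.0  # longer residence, smaller xi
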