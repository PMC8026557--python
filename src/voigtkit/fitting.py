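"""Extracting the line-damping parameter from data.

Two pipelines:

* **Empirical PDFs** (radius-of-gyration histograms, dihedral-angle
  increment distributions, …): :func:`histogram_pdf` turns raw samples into
  a unit-area density with Poisson uncertainties, :func:`detect_modes`
  locates the peaks, and :func:`fit_voigt` fits a 1- or 2-component Voigt
  mixture by bounded weighted least squares (with an optional
  maximum-likelihood mode on the raw samples, useful when the heavy
  Lorentzian tails make histogram least squares inefficient).

* **QENS spectra**: the theoretical incoherent scattering function is an
  elastic delta plus a sum of quasielastic Lorentzians, attenuated by a
  Debye–Waller-type factor.  Convolving with the Gaussian instrument
  resolution turns the delta into a Gaussian and every Lorentzian into a
  Voigt profile — :func:`qens_spectrum` evaluates that closed form, and
  :func:`fit_qens` inverts it, reporting a line-damping parameter
  ``xi_i = Gamma_i / w_res`` per quasielastic component.

The fitted ``xi`` is parameterized in log space (its physically relevant
range spans 1e-2 … 1e1 and more) and its standard error is propagated back
to the linear scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.signal import find_peaks

from .core import VoigtShape, voigt_pdf, voigt_series

__all__ = [
    "EmpiricalPDF",
    "ModeDetection",
    "VoigtFitResult",
    "QENSModel",
    "QENSFitResult",
    "FitError",
    "histogram_pdf",
    "detect_modes",
    "fit_voigt",
    "qens_spectrum",
    "fit_qens",
    "xi_trend",
]

_SQRT_PI = math.sqrt(math.pi)

LOG10_XI_BOUNDS = (-4.0, 3.0)


class FitError(RuntimeError):
    """Raised when a fit cannot be set up or returns nonsense."""


@dataclass(frozen=True)
class EmpiricalPDF:
    """A tabulated density: strictly increasing grid, non-negative values.

    ``sigma`` are optional per-point uncertainties (used as least-squares
    weights); ``samples`` optionally carries the raw draws behind a
    histogram; ``edges``/``counts``/``n_total`` the histogram provenance
    when applicable (they switch the fit to Poisson counting statistics).
    """

    x: np.ndarray
    density: np.ndarray
    sigma: np.ndarray | None = None
    samples: np.ndarray | None = None
    edges: np.ndarray | None = None
    counts: np.ndarray | None = None
    n_total: int | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "density", d)
        if x.ndim != 1 or x.size < 2 or d.shape != x.shape:
            raise ValueError("x and density must be matching 1-D arrays")
        if not np.all(np.diff(x) > 0):
            raise ValueError("abscissa grid must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(d))):
            raise ValueError("non-finite values in empirical PDF")
        if np.any(d < 0):
            raise ValueError("density values must be non-negative")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != x.shape or np.any(s <= 0):
                raise ValueError("sigma must match the grid and be positive")

    @property
    def area(self) -> float:
        """Integrated density (rectangle rule over bins if edges known)."""
        if self.edges is not None:
            return float(np.sum(self.density * np.diff(self.edges)))
        return float(np.trapezoid(self.density, self.x))


def histogram_pdf(samples, n_bins: int = 250,
                  range: tuple[float, float] | None = None,
                  range_sigmas: float = 12.0) -> EmpiricalPDF:
    """Unit-area histogram density with Poisson uncertainties.

    With heavy-tailed input neither the sample extremes nor extreme
    quantiles give a usable range (a handful of Lorentzian outliers would
    flatten the core into one bin), so the default range is robust:
    ``median ± range_sigmas * IQR/1.349`` (the IQR-calibrated Gaussian
    sigma).  The density is conditional on that range; fits leave the
    component area free, which absorbs the clipped tail mass.
    """
    s = np.asarray(samples, dtype=float)
    s = s[np.isfinite(s)]
    if s.size < 100:
        raise ValueError("need at least 100 finite samples")
    if n_bins < 10:
        raise ValueError("need at least 10 bins")
    if range is None:
        med = float(np.median(s))
        q25, q75 = np.quantile(s, [0.25, 0.75])
        robust_sd = (q75 - q25) / 1.349
        lo, hi = med - range_sigmas * robust_sd, med + range_sigmas * robust_sd
    else:
        lo, hi = range
    if not hi > lo:
        raise ValueError("degenerate sample range")
    counts, edges = np.histogram(s, bins=n_bins, range=(lo, hi))
    n_in = int(counts.sum())
    if n_in < 100:
        raise ValueError("fewer than 100 samples inside the histogram range")
    widths = np.diff(edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (n_in * widths)
    sigma = np.sqrt(np.maximum(counts, 1.0)) / (n_in * widths)
    return EmpiricalPDF(centers, density, sigma=sigma, samples=s, edges=edges,
                        counts=counts.astype(float), n_total=n_in)


@dataclass(frozen=True)
class ModeDetection:
    n_modes: int
    locations: np.ndarray
    indices: np.ndarray
    prominences: np.ndarray


def detect_modes(pdf: EmpiricalPDF, prominence_fraction: float = 0.1) -> ModeDetection:
    """Locate density peaks with prominence above a fraction of the maximum."""
    if not 0 < prominence_fraction < 1:
        raise ValueError("prominence_fraction must be in (0, 1)")
    d = pdf.density
    idx, props = find_peaks(d, prominence=prominence_fraction * float(d.max()))
    # an interior-less maximum at the boundary still counts as one mode
    if idx.size == 0:
        k = int(np.argmax(d))
        if k in (0, d.size - 1) and d[k] > 0:
            return ModeDetection(1, pdf.x[[k]], np.array([k]),
                                 np.array([float(d[k])]))
        raise FitError("no mode with sufficient prominence found")
    order = np.argsort(-props["prominences"])
    idx = idx[order]
    return ModeDetection(int(idx.size), pdf.x[idx], idx,
                         props["prominences"][order])


@dataclass(frozen=True)
class VoigtFitResult:
    """Fitted Voigt mixture with diagnostics.

    ``xi_stderr`` are per-component standard errors of xi propagated from
    the log-space covariance; ``covariance`` is over the raw parameter
    vector ``(center, width, log10 xi, area) * n_components``.
    """

    components: tuple[VoigtShape, ...]
    loss: float
    converged: bool
    iterations: int
    covariance: np.ndarray | None
    method: str
    xi_stderr: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("at least one component required")
        if self.loss < 0:
            raise ValueError("loss must be >= 0")

    @property
    def xi(self) -> float:
        """Line-damping parameter of the dominant (largest-area) component."""
        areas = [c.area for c in self.components]
        return self.components[int(np.argmax(areas))].xi


def _mixture_density(x, params, n_components):
    out = np.zeros_like(np.asarray(x, dtype=float))
    for j in range(n_components):
        c, w, lxi, a = params[4 * j:4 * j + 4]
        out = out + a * voigt_series((x - c) / w, 10.0 ** lxi) / w
    return out


def _initial_guess(pdf: EmpiricalPDF, n_components: int) -> np.ndarray:
    modes = detect_modes(pdf, prominence_fraction=0.05)
    if modes.n_modes < n_components:
        # fall back: split the support
        locs = np.quantile(pdf.x, np.linspace(0.25, 0.75, n_components))
        idxs = [int(np.argmin(np.abs(pdf.x - l))) for l in locs]
    else:
        idxs = list(modes.indices[:n_components])
        locs = list(pdf.x[idxs])
    span = pdf.x[-1] - pdf.x[0]
    p0 = []
    for loc, k in zip(locs, idxs):
        peak = max(pdf.density[k], 1e-12)
        # half-width at half-maximum from the nearest half-crossing
        half = peak / 2.0
        below = np.nonzero(pdf.density < half)[0]
        right = below[below > k]
        left = below[below < k]
        hwhm = span / 8.0
        if right.size and left.size:
            hwhm = 0.5 * (pdf.x[right[0]] - pdf.x[left[-1]])
        elif right.size:
            hwhm = pdf.x[right[0]] - loc
        elif left.size:
            hwhm = loc - pdf.x[left[-1]]
        hwhm = max(hwhm, span / 200.0)
        w0 = hwhm / _SQRT_PI  # crude: Gaussian HWHM ~ 0.83 w, Voigt wider
        area0 = min(max(peak * hwhm * 2.0, 1e-6), 2.0)
        p0.extend([loc, w0, math.log10(0.5), area0])
    return np.asarray(p0)


def fit_voigt(pdf: EmpiricalPDF, n_components: int = 1,
              init: np.ndarray | None = None,
              bounds: tuple[np.ndarray, np.ndarray] | None = None,
              mask: np.ndarray | None = None,
              method: str = "least_squares",
              n_starts: int = 3, seed: int = 0) -> VoigtFitResult:
    """Fit a Voigt mixture to an empirical density.

    Parameters per component: center, 1/e Gaussian width, log10(xi), area.

    When the PDF carries histogram counts, the loss is a variance-
    stabilized Poisson (Anscombe square-root) residual on bin-integrated
    expected counts — weighting density values by observed-count sigmas is
    badly biased by near-empty heavy-tail bins, and bin-center evaluation
    is biased by peak curvature (Simpson averaging over each bin fixes
    that).  For a plain tabulated density the loss is weighted least
    squares on the values (weights from ``pdf.sigma`` when present).
    ``method="mle"`` instead maximizes the mixture likelihood of the raw
    samples (requires ``pdf.samples``).  ``mask`` restricts the fit to a
    boolean subset of grid points (per-mode or high-energy-window fits).
    Multi-start: the initial guess plus ``n_starts - 1`` seeded jitters.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    x, d = pdf.x, pdf.density
    sig = pdf.sigma if pdf.sigma is not None else np.ones_like(d)
    poisson = pdf.counts is not None and pdf.edges is not None \
        and pdf.n_total is not None
    if poisson:
        counts, xl, xr = pdf.counts, pdf.edges[:-1], pdf.edges[1:]
        widths = np.diff(pdf.edges)
        n_tot = pdf.n_total
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != x.shape:
            raise ValueError("mask must match the grid")
        if mask.sum() < 4 * n_components + 1:
            raise FitError("mask leaves too few points to fit")
        x, d, sig = x[mask], d[mask], sig[mask]
        if poisson:
            counts, xl, xr, widths = (counts[mask], xl[mask], xr[mask],
                                      widths[mask])

    p0 = np.asarray(init, dtype=float) if init is not None \
        else _initial_guess(pdf, n_components)
    if p0.size != 4 * n_components:
        raise ValueError("init must have 4 parameters per component")

    span = pdf.x[-1] - pdf.x[0]
    if bounds is None:
        lo = np.tile([pdf.x[0] - span, span * 1e-4, LOG10_XI_BOUNDS[0], 1e-12],
                     n_components)
        hi = np.tile([pdf.x[-1] + span, 4.0 * span, LOG10_XI_BOUNDS[1], 1e6],
                     n_components)
        bounds = (lo, hi)
    p0 = np.clip(p0, bounds[0] + 1e-12, bounds[1] - 1e-12)

    if method == "mle":
        return _fit_voigt_mle(pdf, n_components, p0, bounds)
    if method != "least_squares":
        raise ValueError("method must be 'least_squares' or 'mle'")

    if poisson:
        def resid(p):
            # Simpson bin-average of the model density -> expected counts
            m = (_mixture_density(xl, p, n_components)
                 + 4.0 * _mixture_density(x, p, n_components)
                 + _mixture_density(xr, p, n_components)) / 6.0
            mu = m * n_tot * widths
            r = 2.0 * (np.sqrt(counts + 0.375) - np.sqrt(mu + 0.375))
            if not np.all(np.isfinite(r)):
                raise FitError("non-finite residuals encountered")
            return r
    else:
        def resid(p):
            r = (_mixture_density(x, p, n_components) - d) / sig
            if not np.all(np.isfinite(r)):
                raise FitError("non-finite residuals encountered")
            return r

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        p_start = p0.copy()
        if start > 0:
            jitter = rng.normal(0.0, 1.0, size=p0.size)
            # absolute jitter on centers, relative on widths/areas, 0.3 dex on xi
            scale = np.tile([span * 0.02, 0.0, 0.3, 0.0], n_components)
            rel = np.tile([0.0, 0.2, 0.0, 0.2], n_components)
            p_start = np.clip(p0 + jitter * (scale + rel * np.abs(p0)),
                              bounds[0] + 1e-12, bounds[1] - 1e-12)
        try:
            res = least_squares(resid, p_start, bounds=bounds, method="trf",
                                x_scale="jac", max_nfev=2000)
        except FitError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("all fit starts produced non-finite residuals")

    return _package_result(best, n_components, x.size, "least_squares")


def _package_result(res, n_components, n_points, tag) -> VoigtFitResult:
    p = res.x
    comps = tuple(
        VoigtShape(center=p[4 * j], gauss_width=p[4 * j + 1],
                   xi=10.0 ** p[4 * j + 2], area=p[4 * j + 3])
        for j in range(n_components)
    )
    dof = max(n_points - p.size, 1)
    s2 = 2.0 * res.cost / dof
    cov = None
    xi_err = []
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.pinv(jtj) * s2
        for j in range(n_components):
            var_lxi = max(cov[4 * j + 2, 4 * j + 2], 0.0)
            xi_err.append(comps[j].xi * math.log(10.0) * math.sqrt(var_lxi))
    except (np.linalg.LinAlgError, ValueError):
        xi_err = [math.nan] * n_components
    converged = bool(res.status > 0)
    return VoigtFitResult(components=comps, loss=2.0 * res.cost,
                          converged=converged, iterations=int(res.nfev),
                          covariance=cov, method=tag,
                          xi_stderr=tuple(xi_err))


def _fit_voigt_mle(pdf, n_components, p0, bounds) -> VoigtFitResult:
    if pdf.samples is None:
        raise FitError("maximum-likelihood fitting requires raw samples")
    s = pdf.samples
    # subsample very large inputs for tractable likelihood evaluations
    if s.size > 200_000:
        s = s[:: s.size // 200_000 + 1]

    def nll(p):
        dens = np.zeros_like(s)
        total = 0.0
        for j in range(n_components):
            c, w, lxi, a = p[4 * j:4 * j + 4]
            dens = dens + a * voigt_series((s - c) / w, 10.0 ** lxi) / w
            total += a
        dens = np.maximum(dens / total, 1e-300)
        return -np.sum(np.log(dens))

    res = minimize(nll, p0, method="L-BFGS-B",
                   bounds=list(zip(bounds[0], bounds[1])),
                   options={"maxiter": 500})
    p = res.x
    comps = tuple(
        VoigtShape(center=p[4 * j], gauss_width=p[4 * j + 1],
                   xi=10.0 ** p[4 * j + 2], area=p[4 * j + 3])
        for j in range(n_components)
    )
    cov = None
    xi_err = [math.nan] * n_components
    if hasattr(res, "hess_inv"):
        try:
            cov = res.hess_inv.todense()
            xi_err = [comps[j].xi * math.log(10.0)
                      * math.sqrt(max(cov[4 * j + 2, 4 * j + 2], 0.0))
                      for j in range(n_components)]
        except Exception:
            pass
    return VoigtFitResult(components=comps, loss=float(res.fun),
                          converged=bool(res.success),
                          iterations=int(res.nit), covariance=cov,
                          method="mle", xi_stderr=tuple(xi_err))


# --------------------------------------------------------------------------
# QENS


@dataclass(frozen=True)
class QENSModel:
    """Incoherent quasielastic scattering model at one momentum transfer.

    ``S(Q, omega) = exp(-Q^2 <u^2> / 3) * [A0 * delta(omega)
    + sum_i Ai * Lorentzian(omega; Gamma_i)]`` convolved with a Gaussian
    resolution of 1/e half-width ``resolution_width``; an optional flat
    background is added after the Debye–Waller attenuation.

    Weights satisfy ``A0 + sum Ai = 1``; ``scale`` multiplies the whole
    spectrum (detector normalization).
    """

    q: float                       # momentum transfer, 1/Angstrom
    msd: float                     # <u^2>, Angstrom^2
    elastic_fraction: float        # A0 in [0, 1]
    components: tuple[tuple[float, float], ...]  # (Ai, Gamma_i [meV])
    resolution_width: float        # Gaussian 1/e half-width, meV
    background: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.elastic_fraction <= 1.0:
            raise ValueError("elastic_fraction must lie in [0, 1]")
        if self.msd < 0 or self.q < 0:
            raise ValueError("q and msd must be >= 0")
        if not self.resolution_width > 0:
            raise ValueError("resolution_width must be > 0")
        tot = self.elastic_fraction
        for a, g in self.components:
            if a < 0 or not g > 0:
                raise ValueError("component weights must be >= 0, widths > 0")
            tot += a
        if abs(tot - 1.0) > 1e-8:
            raise ValueError("A0 + sum(Ai) must equal 1")
        if self.background < 0 or not self.scale > 0:
            raise ValueError("background >= 0 and scale > 0 required")

    @property
    def debye_waller(self) -> float:
        return math.exp(-self.q * self.q * self.msd / 3.0)

    @property
    def xi(self) -> tuple[float, ...]:
        """Line-damping parameter of each quasielastic component."""
        return tuple(g / self.resolution_width for _, g in self.components)


def qens_spectrum(omega, model: QENSModel):
    """Resolution-convolved scattering intensity on an energy-transfer grid.

    Closed form: the elastic delta becomes the unit-area resolution
    Gaussian; each Lorentzian of HWHM Gamma becomes a Voigt profile with
    ``xi = Gamma / w_res``.
    """
    w = np.asarray(omega, dtype=float)
    r = model.resolution_width
    out = model.elastic_fraction * np.exp(-(w / r) ** 2) / (r * _SQRT_PI)
    for a, g in model.components:
        out = out + a * voigt_series(w / r, g / r) / r
    out = model.scale * model.debye_waller * out + model.background
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class QENSFitResult:
    model: QENSModel
    xi: tuple[float, ...]
    xi_stderr: tuple[float, ...]
    gamma_stderr: tuple[float, ...]
    loss: float
    converged: bool
    iterations: int
    warnings: tuple[str, ...] = ()


def fit_qens(omega, intensity, resolution_width: float,
             err=None, n_lorentzians: int = 1, fit_background: bool = False,
             window: tuple[float, float] | None = None,
             q: float = 1.0, seed: int = 0) -> QENSFitResult:
    """Fit the resolution-convolved QENS model to a measured spectrum.

    The resolution width (Gaussian 1/e half-width, meV) is known from the
    instrument and held fixed.  Free parameters: overall scale (absorbing
    the Debye–Waller factor), the elastic fraction and quasielastic weights
    on the simplex (stick-breaking parameterization), one HWHM
    ``Gamma_i`` per Lorentzian (fitted in log space), and optionally a flat
    background.  ``window = (lo, hi)`` restricts the fit to grid points
    with ``lo <= |omega| <= hi`` (the high-energy-only fitting mode).

    Returns the fitted model plus ``xi_i = Gamma_i / w_res`` per component.
    Non-identifiable widths (Gamma at the bounds) are flagged in
    ``warnings``, never silently returned.
    """
    if n_lorentzians not in (1, 2, 3):
        raise ValueError("n_lorentzians must be 1, 2 or 3")
    w = np.asarray(omega, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if w.shape != y.shape or w.ndim != 1:
        raise ValueError("omega and intensity must be matching 1-D arrays")
    sig = np.asarray(err, dtype=float) if err is not None else np.ones_like(y)
    if np.any(sig <= 0):
        sig = np.where(sig > 0, sig, np.max(np.abs(sig)) + 1e-12)
    n_params = 1 + 2 * n_lorentzians + (1 if fit_background else 0)
    if window is not None:
        lo, hi = window
        keep = (np.abs(w) >= lo) & (np.abs(w) <= hi)
        if keep.sum() < n_params + 2:
            raise FitError("window leaves too few points to fit")
        w, y, sig = w[keep], y[keep], sig[keep]

    span = float(np.max(np.abs(w)))
    r = float(resolution_width)
    glo, ghi = math.log10(r * 1e-3), math.log10(4.0 * span)
    nb = 1 if fit_background else 0
    # params: scale, sticks (n_lorentzians of them), log10 gammas, [bg]
    area = float(np.trapezoid(np.abs(y), w))
    p0 = np.concatenate([[max(area, 1e-12)],
                         np.full(n_lorentzians, 0.5),
                         np.linspace(math.log10(r), math.log10(max(span / 4, 2 * r)),
                                     n_lorentzians),
                         [max(float(np.min(y)), 1e-12)] * nb])
    lo_b = np.concatenate([[1e-15], np.zeros(n_lorentzians) + 1e-6,
                           np.full(n_lorentzians, glo), [0.0] * nb])
    hi_b = np.concatenate([[1e12], np.ones(n_lorentzians) - 1e-6,
                           np.full(n_lorentzians, ghi),
                           [max(float(np.max(y)), 1e-6)] * nb])

    def unpack(p):
        scale = p[0]
        sticks = p[1:1 + n_lorentzians]
        lgs = p[1 + n_lorentzians:1 + 2 * n_lorentzians]
        bg = p[-1] if fit_background else 0.0
        # stick-breaking on the simplex: first stick is A0
        weights = []
        rem = 1.0
        for s in sticks:
            weights.append(rem * s)
            rem *= (1.0 - s)
        a0 = 1.0 - sum(weights)
        return scale, a0, list(weights), [10.0 ** g for g in lgs], bg

    def model_of(p):
        scale, a0, weights, gammas, bg = unpack(p)
        out = a0 * np.exp(-(w / r) ** 2) / (r * _SQRT_PI)
        for a, g in zip(weights, gammas):
            out = out + a * voigt_series(w / r, g / r) / r
        return scale * out + bg

    def resid(p):
        rr = (model_of(p) - y) / sig
        if not np.all(np.isfinite(rr)):
            raise FitError("non-finite residuals in QENS fit")
        return rr

    res = least_squares(resid, p0, bounds=(lo_b, hi_b), method="trf",
                        x_scale="jac", max_nfev=4000)
    scale, a0, weights, gammas, bg = unpack(res.x)

    warnings = []
    for i, g in enumerate(gammas):
        lg = math.log10(g)
        if lg < glo + 0.05 or lg > ghi - 0.05:
            warnings.append(
                f"Gamma_{i+1} = {g:.3g} meV pinned at the fit bounds; "
                "component not identifiable")

    # covariance and xi errors
    dof = max(w.size - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    gam_err = [math.nan] * n_lorentzians
    try:
        cov = np.linalg.pinv(res.jac.T @ res.jac) * s2
        for i in range(n_lorentzians):
            k = 1 + n_lorentzians + i
            gam_err[i] = gammas[i] * math.log(10.0) * math.sqrt(max(cov[k, k], 0.0))
    except (np.linalg.LinAlgError, ValueError):
        pass

    # normalize weights defensively before constructing the model
    wsum = a0 + sum(weights)
    model = QENSModel(q=q, msd=0.0, elastic_fraction=a0 / wsum,
                      components=tuple((a / wsum, g)
                                       for a, g in zip(weights, gammas)),
                      resolution_width=r, background=bg, scale=scale * wsum)
    xi = tuple(g / r for g in gammas)
    xi_err = tuple(e / r for e in gam_err)
    return QENSFitResult(model=model, xi=xi, xi_stderr=xi_err,
                         gamma_stderr=tuple(gam_err), loss=2.0 * res.cost,
                         converged=bool(res.status > 0),
                         iterations=int(res.nfev), warnings=tuple(warnings))


def xi_trend(fits) -> pd.DataFrame:
    """Tabulate the line-damping parameter against a covariate.

    ``fits`` is an iterable of ``(covariate, result)`` where ``result`` is a
    :class:`VoigtFitResult`, a :class:`QENSFitResult` (first component), or
    a bare ``(xi, stderr)`` pair.  Returns a DataFrame sorted by covariate
    with columns ``covariate``, ``xi``, ``xi_stderr``.
    """
    rows = []
    for cov, res in fits:
        if isinstance(res, VoigtFitResult):
            areas = [c.area for c in res.components]
            j = int(np.argmax(areas))
            rows.append((cov, res.components[j].xi,
                         res.xi_stderr[j] if res.xi_stderr else math.nan))
        elif isinstance(res, QENSFitResult):
            rows.append((cov, res.xi[0], res.xi_stderr[0]))
        else:
            xi, err = res
            rows.append((cov, float(xi), float(err)))
    if len(rows) < 2:
        raise ValueError("need at least two fits for a trend")
    df = pd.DataFrame(rows, columns=["covariate", "xi", "xi_stderr"])
    return df.sort_values("covariate", ignore_index=True)
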