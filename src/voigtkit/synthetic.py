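"""Seeded generators emulating the statistical structure of the study inputs.

None of these simulate molecular dynamics or a real spectrometer; they
produce data with the same *statistical shape* so every analysis stage has
a ground truth:

* :func:`gen_voigt_samples` — exact draws from a Voigt density via its
  defining convolution, ``X = x0 + Normal(sd = w/sqrt(2)) + Cauchy(HWHM =
  xi*w)``.
* :func:`gen_two_state` — a two-state Markov chain (folded/unfolded levels
  of a radius-of-gyration-like order parameter) with per-state Voigt
  observation noise, returning the trajectory, state labels, and residence
  times.  Depending on the switching rates the resulting PDF is unimodal or
  bimodal.
* :func:`gen_dihedral` — overdamped Langevin (Euler–Maruyama) diffusion of
  an angle on the circle in a flat, harmonic, or periodic multi-well
  potential; returns wrapped angle increments at a chosen lag, emulating
  backbone-dihedral rotation statistics.
* :func:`gen_qens` — the closed-form resolution-convolved QENS model plus
  relative-Gaussian or Poisson counting noise.

Every generator takes a seed (or Generator) and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import VoigtShape
from .fitting import QENSModel, qens_spectrum

__all__ = [
    "TwoStateParams",
    "TwoStateTrajectory",
    "CircularDiffusionParams",
    "DihedralResult",
    "QENSGenParams",
    "SpectrumData",
    "gen_voigt_samples",
    "gen_two_state",
    "gen_dihedral",
    "gen_qens",
]


def _rng_of(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_voigt_samples(n: int, shape: VoigtShape, seed=None) -> np.ndarray:
    """Exact Voigt-distributed draws by the Gaussian + Cauchy convolution.

    The Gaussian factor ``exp(-((x-x0)/w)**2)`` has standard deviation
    ``w/sqrt(2)``; the Cauchy factor carries HWHM ``xi*w`` (inverse-CDF
    ``tan`` method through the generator's standard Cauchy).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng_of(seed)
    out = shape.center + rng.normal(0.0, shape.gauss_width / math.sqrt(2.0), size=n)
    if shape.xi > 0:
        out = out + shape.lorentz_hwhm * rng.standard_cauchy(size=n)
    return out


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state switching trajectory of an order parameter.

    ``k_fold`` is the per-step probability of an unfolded -> folded switch,
    ``k_unfold`` the reverse.  Observation noise around each state level is
    Voigt with the given shapes (their centers are ignored; the state level
    is used).
    """

    mu_folded: float
    mu_unfolded: float
    noise_folded: VoigtShape
    noise_unfolded: VoigtShape
    k_fold: float
    k_unfold: float
    n_steps: int
    seed: int = 0
    start: str = "folded"

    def __post_init__(self) -> None:
        if not (0 <= self.k_fold < 1 and 0 <= self.k_unfold < 1):
            raise ValueError("switch rates must lie in [0, 1)")
        if self.mu_folded == self.mu_unfolded:
            raise ValueError("state levels must be distinct")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.start not in ("folded", "unfolded"):
            raise ValueError("start must be 'folded' or 'unfolded'")


@dataclass(frozen=True)
class TwoStateTrajectory:
    values: np.ndarray      # observed order parameter
    states: np.ndarray      # 0 = folded, 1 = unfolded
    residence: tuple        # list of (state, duration in steps)

    def residence_times(self, state: int) -> np.ndarray:
        return np.array([d for s, d in self.residence if s == state], dtype=float)


def gen_two_state(params: TwoStateParams) -> TwoStateTrajectory:
    """Simulate the switching chain and add per-state Voigt noise.

    Residence durations are geometric with mean ``1/k_leave``; they are
    drawn directly segment by segment (fast even for 1e6 steps) and the
    final, censored segment is excluded from the residence list.
    """
    rng = _rng_of(params.seed)
    n = params.n_steps
    states = np.empty(n, dtype=np.int8)
    segments = []
    pos = 0
    state = 0 if params.start == "folded" else 1
    leave = (params.k_unfold, params.k_fold)  # leave prob of state 0 / 1
    while pos < n:
        k = leave[state]
        dur = n - pos if k == 0 else int(rng.geometric(k))
        dur = min(dur, n - pos)
        states[pos:pos + dur] = state
        segments.append((state, dur))
        pos += dur
        state = 1 - state
    if len(segments) > 1:
        segments = segments[:-1]  # last segment is censored by the run end

    levels = np.where(states == 0, params.mu_folded, params.mu_unfolded)
    noise = np.empty(n)
    for s, shp in ((0, params.noise_folded), (1, params.noise_unfolded)):
        m = states == s
        cnt = int(m.sum())
        if cnt:
            centered = VoigtShape(0.0, shp.gauss_width, shp.xi, shp.area)
            noise[m] = gen_voigt_samples(cnt, centered, seed=rng)
    return TwoStateTrajectory(values=levels + noise, states=states,
                              residence=tuple(segments))


@dataclass(frozen=True)
class CircularDiffusionParams:
    """Overdamped diffusion of an angle on (-pi, pi].

    ``potential`` is one of ``"free"``, ``"harmonic"`` (``U = k/2 * g**2``,
    stiffness ``k``), or ``"multiwell"`` (``U = depth/2 * (1 - cos(n_wells
    * g))``).  ``diffusion`` is in rad^2 per unit time, ``dt`` the
    integration step.  Stability requires the drift per step to stay small
    relative to the well curvature: ``curvature * diffusion * dt / kT <
    0.1``.
    """

    potential: str = "free"
    stiffness: float = 1.0
    well_depth: float = 4.0
    n_wells: int = 2
    diffusion: float = 0.1
    kT: float = 1.0
    dt: float = 1.0
    n_steps: int = 100_000
    lag: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.potential not in ("free", "harmonic", "multiwell"):
            raise ValueError("potential must be free, harmonic or multiwell")
        if not (self.diffusion > 0 and self.kT > 0 and self.dt > 0):
            raise ValueError("diffusion, kT and dt must be > 0")
        if self.n_steps <= self.lag or self.lag < 1:
            raise ValueError("need n_steps > lag >= 1")
        if self.curvature * self.diffusion * self.dt / self.kT >= 0.1:
            raise ValueError("unstable step size: curvature*D*dt/kT must be < 0.1")

    @property
    def curvature(self) -> float:
        if self.potential == "harmonic":
            return self.stiffness
        if self.potential == "multiwell":
            return 0.5 * self.well_depth * self.n_wells ** 2
        return 0.0

    def force(self, g: np.ndarray) -> np.ndarray:
        if self.potential == "harmonic":
            return -self.stiffness * g
        if self.potential == "multiwell":
            return -0.5 * self.well_depth * self.n_wells * np.sin(self.n_wells * g)
        return np.zeros_like(g)


@dataclass(frozen=True)
class DihedralResult:
    angles: np.ndarray       # wrapped trajectory after burn-in
    increments: np.ndarray   # wrapped increments at the requested lag
    lag_time: float


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def gen_dihedral(params: CircularDiffusionParams) -> DihedralResult:
    """Euler–Maruyama trajectory on the circle; returns lag increments.

    The walk starts at a potential minimum and is equilibrated for ten
    relaxation times (``kT / (curvature * D)``, capped at the trajectory
    length) before increments are collected; a free walk needs no burn-in.
    """
    rng = _rng_of(params.seed)
    D, dt, kT = params.diffusion, params.dt, params.kT
    if params.curvature > 0:
        tau = kT / (params.curvature * D)
        burn = min(int(10.0 * tau / dt), 10 * params.n_steps)
    else:
        burn = 0
    n_tot = params.n_steps + burn
    step_sd = math.sqrt(2.0 * D * dt)
    kicks = rng.normal(0.0, step_sd, size=n_tot)
    g = np.empty(n_tot + 1)
    g[0] = 0.0
    mob = D * dt / kT
    for i in range(n_tot):
        g[i + 1] = g[i] + mob * params.force(np.asarray(g[i])) + kicks[i]
    g = _wrap(g[burn:])
    inc = _wrap(g[params.lag:] - g[:-params.lag])
    return DihedralResult(angles=g, increments=inc,
                          lag_time=params.lag * dt)


@dataclass(frozen=True)
class QENSGenParams:
    """Synthetic spectrum: closed-form model plus counting noise.

    ``noise`` is the relative Gaussian noise level (sigma = noise *
    intensity + floor, floor = noise * peak / 100); ``count_scale``, if
    set, switches to Poisson counting statistics with that many counts per
    unit intensity.
    """

    model: QENSModel
    omega: np.ndarray
    noise: float = 0.02
    count_scale: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "omega", w)
        if self.noise < 0:
            raise ValueError("noise level must be >= 0")
        if w.min() > -self.model.resolution_width or w.max() < self.model.resolution_width:
            raise ValueError("omega grid must cover the elastic peak")


@dataclass(frozen=True)
class SpectrumData:
    omega: np.ndarray
    intensity: np.ndarray
    err: np.ndarray


def gen_qens(params: QENSGenParams) -> SpectrumData:
    """Noisy synthetic QENS spectrum with honest per-point error column."""
    rng = _rng_of(params.seed)
    clean = qens_spectrum(params.omega, params.model)
    if params.count_scale is not None:
        lam = np.maximum(clean * params.count_scale, 0.0)
        counts = rng.poisson(lam)
        intensity = counts / params.count_scale
        err = np.sqrt(np.maximum(lam, 1.0)) / params.count_scale
    elif params.noise > 0:
        floor = params.noise * float(np.max(clean)) / 100.0
        err = params.noise * clean + floor
        intensity = clean + rng.normal(0.0, 1.0, size=clean.shape) * err
    else:
        intensity = clean.copy()
        err = np.full_like(clean, 1e-12)
    return SpectrumData(omega=params.omega, intensity=intensity, err=err)
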