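"""Kubo-model machinery for vibrational lineshapes.

The frequency-frequency correlation function (FFCF) used throughout this
package has the form

    C(t) = (homogeneous, delta-correlated term of Lorentzian FWHM Γ_h)
           + Δ₁² e^{−t/τ₁} + Δ_s²

i.e. a motionally narrowed homogeneous contribution plus one exponentially
sampled inhomogeneous term and one static inhomogeneous term.  Amplitudes
Δ are stored in cm⁻¹ and converted to angular frequency (rad/ps) only
inside the second-cumulant lineshape integral.

``gamma_h`` is interpreted as the *total* homogeneous Lorentzian FWHM —
pure dephasing and lifetime broadening merged — so linear-spectrum
synthesis applies no separate 1/(2T₁) coherence decay.  Population
relaxation (T₁) enters only through waiting-time dynamics in the 2D
simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "C_CM_PER_PS",
    "FFCFParams",
    "SpectralComponent",
    "LinearSpectrum",
    "ffcf_inhomogeneous",
    "lineshape_g",
    "synth_linear",
    "voigt_fwhm",
    "fwhm_of",
    "GAUSSIAN_FWHM_FACTOR",
]

#: speed of light in cm/ps
C_CM_PER_PS = 2.99792458e-2

#: FWHM of a unit-σ Gaussian
GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class MotionalNarrowingWarning(UserWarning):
    """Δ₁·τ₁ in the fast-modulation regime: amplitude and timescale inseparable."""


@dataclass(frozen=True)
class FFCFParams:
    """Kubo FFCF parameter set for one vibrational state.

    Parameters
    ----------
    gamma_h:
        Total homogeneous Lorentzian FWHM Γ_h = 1/(π c T₂*), cm⁻¹.
    delta_1:
        Amplitude of the exponentially sampled inhomogeneous term, cm⁻¹.
    tau_1:
        Sampling timescale of that term, ps.  Ignored when ``delta_1 == 0``.
    delta_s:
        Static inhomogeneous amplitude (sampled more slowly than the
        experimental window), cm⁻¹.  May be zero.
    t1_lifetime:
        Vibrational (population) lifetime T₁, ps.
    """

    gamma_h: float
    delta_1: float
    tau_1: float
    delta_s: float
    t1_lifetime: float = 16.0

    def __post_init__(self) -> None:
        if not self.gamma_h > 0:
            raise ValueError(f"gamma_h must be > 0, got {self.gamma_h}")
        if self.delta_1 < 0 or self.delta_s < 0:
            raise ValueError("inhomogeneous amplitudes must be >= 0")
        if self.delta_1 > 0 and not self.tau_1 > 0:
            raise ValueError("tau_1 must be > 0 when delta_1 > 0")
        if not self.t1_lifetime > 0:
            raise ValueError("t1_lifetime must be > 0")
        if 0 < self.motional_narrowing_parameter < 1:
            warnings.warn(
                "2πc·Δ₁·τ₁ < 1: Δ₁ and τ₁ are not separately identifiable "
                "(fast-modulation limit); values reported but degenerate",
                MotionalNarrowingWarning,
                stacklevel=2,
            )

    @property
    def t2_star(self) -> float:
        """Homogeneous dephasing time T₂* = 1/(π c Γ_h), ps."""
        return 1.0 / (np.pi * C_CM_PER_PS * self.gamma_h)

    @property
    def motional_narrowing_parameter(self) -> float:
        """Diagnostic 2πc·Δ₁·τ₁; ≫1 means quasi-static, ≪1 motionally narrowed."""
        return 2.0 * np.pi * C_CM_PER_PS * self.delta_1 * self.tau_1

    @property
    def inhomogeneous_width(self) -> float:
        """Quadrature inhomogeneous standard deviation √(Δ₁²+Δ_s²), cm⁻¹."""
        return float(np.hypot(self.delta_1, self.delta_s))


@dataclass(frozen=True)
class SpectralComponent:
    """One conformational state's CO-stretch band.

    ``dipole`` is the relative transition dipole magnitude |μ| with the
    reference component at 1; linear-band area scales as population·μ² and
    2D-band amplitude as population·μ⁴ (enforced by the simulator).
    """

    nu_0: float
    ffcf: FFCFParams
    dipole: float = 1.0
    population: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.population <= 1.0):
            raise ValueError("population must lie in [0, 1]")
        if not self.dipole > 0:
            raise ValueError("dipole must be > 0")

    def with_population(self, p: float) -> "SpectralComponent":
        return replace(self, population=p)


@dataclass(frozen=True)
class LinearSpectrum:
    """A linear absorption spectrum on a uniform, strictly increasing axis."""

    frequency: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequency, dtype=float)
        absb = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "frequency", freq)
        object.__setattr__(self, "absorbance", absb)
        if freq.ndim != 1 or freq.size < 16 or absb.shape != freq.shape:
            raise ValueError("axis and values must be equal-length 1D arrays, length >= 16")
        steps = np.diff(freq)
        if np.any(steps <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        if np.ptp(steps) > 1e-6 * steps.mean():
            raise ValueError("frequency axis must be uniform to 1 part in 1e6")

    @property
    def step(self) -> float:
        return float(self.frequency[1] - self.frequency[0])

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.absorbance, self.frequency))


def ffcf_inhomogeneous(params: FFCFParams, t: float | np.ndarray) -> float | np.ndarray:
    """Inhomogeneous part of the FFCF, Δ₁²·e^{−t/τ₁} + Δ_s², in cm⁻².

    Monotone non-increasing in ``t``; bounded by [Δ_s², Δ₁²+Δ_s²].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if params.delta_1 == 0:
        out = np.full_like(t, params.delta_s**2)
    else:
        out = params.delta_1**2 * np.exp(-t / params.tau_1) + params.delta_s**2
    return out if out.ndim else float(out)


def _g_of(params: FFCFParams, t: np.ndarray) -> np.ndarray:
    """Second-cumulant lineshape function g(t) for any non-negative t array."""
    t = np.asarray(t, dtype=float)
    d1 = 2.0 * np.pi * C_CM_PER_PS * params.delta_1  # rad/ps
    ds = 2.0 * np.pi * C_CM_PER_PS * params.delta_s
    g = (np.pi * C_CM_PER_PS * params.gamma_h) * t + 0.5 * ds**2 * t**2
    if params.delta_1 > 0:
        tau = params.tau_1
        g = g + d1**2 * tau**2 * (np.exp(-t / tau) + t / tau - 1.0)
    return g


def lineshape_g(params: FFCFParams, t_grid: np.ndarray) -> np.ndarray:
    """Evaluate g(t) on an increasing grid of non-negative times (ps).

    g(t) = Δ₁²τ₁²(e^{−t/τ₁} + t/τ₁ − 1) + Δ_s²t²/2 + (πcΓ_h)t with the Δ's
    in rad/ps.  The FFCF here is real (no Stokes-shift imaginary part), so
    g is real; it is returned as a float array with g(0) = 0 and a convex,
    increasing profile.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1D array")
    if t_grid[0] < 0:
        raise ValueError("t_grid must be non-negative")
    if t_grid.size > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    return _g_of(params, t_grid)


def _coherence_time_span(params: FFCFParams, decay_target: float = 30.0) -> float:
    """Time at which g(t) reaches ``decay_target`` (amplitude e^{-target})."""
    from scipy.optimize import brentq

    hi = 1.0
    while _g_of(params, np.array([hi]))[0] < decay_target and hi < 1e6:
        hi *= 2.0
    return float(brentq(lambda t: _g_of(params, np.array([t]))[0] - decay_target, 0.0, hi))


def _halfcos_apodization(n: int, fraction: float = 0.1) -> np.ndarray:
    """Unit window with a cosine half-taper over the final ``fraction``."""
    window = np.ones(n)
    ntap = max(int(round(fraction * n)), 2)
    x = np.linspace(0.0, np.pi / 2.0, ntap)
    window[-ntap:] = np.cos(x) ** 2
    return window


def synth_linear(
    component: SpectralComponent,
    axis: np.ndarray,
    *,
    dt: float = 0.02,
) -> LinearSpectrum:
    """Synthesize the linear absorption band of one component.

    Absorbance ∝ Re ∫₀^∞ dt e^{i(ω−ω₀)t} e^{−g(t)}, evaluated by FFT of the
    coherence decay on a fine time grid (step ``dt`` ps, extent set by the
    decay of e^{−g}, cosine half-apodization over the last 10%, zero-padded
    to ≥4× the sample count).  The integrated area is scaled to
    population·dipole².
    """
    axis = np.asarray(axis, dtype=float)
    params = component.ffcf
    fwhm_est = voigt_fwhm(
        GAUSSIAN_FWHM_FACTOR * params.inhomogeneous_width, params.gamma_h
    )
    if axis[0] > component.nu_0 - 2 * fwhm_est or axis[-1] < component.nu_0 + 2 * fwhm_est:
        raise ValueError(
            f"axis [{axis[0]:.1f}, {axis[-1]:.1f}] too narrow for a band at "
            f"{component.nu_0:.1f} cm⁻¹ with FWHM ≈ {fwhm_est:.1f} cm⁻¹"
        )

    t_max = _coherence_time_span(params)
    n = int(np.ceil(t_max / dt)) + 1
    t = np.arange(n) * dt
    signal = np.exp(-_g_of(params, t)) * _halfcos_apodization(n)
    signal[0] *= 0.5  # trapezoid endpoint for the one-sided transform

    npad = 1 << int(np.ceil(np.log2(4 * n)))
    spec = np.fft.fft(signal, npad).real * dt
    freq = np.fft.fftfreq(npad, d=dt) / C_CM_PER_PS  # cm⁻¹ offsets from ν₀

    order = np.argsort(freq)
    freq, spec = freq[order], spec[order]
    spec = np.clip(spec, 0.0, None)
    area = np.trapezoid(spec, freq)
    scale = component.population * component.dipole**2 / area
    absorbance = np.interp(axis - component.nu_0, freq, spec) * scale
    return LinearSpectrum(axis, absorbance)


def voigt_fwhm(gaussian_fwhm: float, lorentzian_fwhm: float) -> float:
    """FWHM of a Voigt profile from its Gaussian and Lorentzian FWHMs.

    Olivero–Longbothum approximation, accurate to ~0.02% of the exact
    convolution width.
    """
    if gaussian_fwhm < 0 or lorentzian_fwhm < 0:
        raise ValueError("widths must be non-negative")
    if gaussian_fwhm == 0 and lorentzian_fwhm == 0:
        raise ValueError("at least one width must be positive")
    fl, fg = lorentzian_fwhm, gaussian_fwhm
    return float(0.5346 * fl + np.sqrt(0.2166 * fl**2 + fg**2))


def fwhm_of(spectrum: LinearSpectrum) -> float:
    """Full width at half maximum by linear interpolation of the crossings."""
    y = spectrum.absorbance
    x = spectrum.frequency
    imax = int(np.argmax(y))
    if imax in (0, y.size - 1):
        raise ValueError("global maximum lies at an axis edge")
    half = y[imax] / 2.0

    left = np.nonzero(y[: imax + 1] < half)[0]
    right = np.nonzero(y[imax:] < half)[0]
    if left.size == 0 or right.size == 0:
        raise ValueError("half maximum not crossed on both sides of the peak")

    i = left[-1]
    x_lo = x[i] + (half - y[i]) / (y[i + 1] - y[i]) * (x[i + 1] - x[i])
    j = imax + right[0]
    x_hi = x[j - 1] + (half - y[j - 1]) / (y[j] - y[j - 1]) * (x[j] - x[j - 1])
    return float(x_hi - x_lo)
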