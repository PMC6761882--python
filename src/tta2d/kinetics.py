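"""Kinetic models for two-dimensional diffusion-controlled triplet-triplet
annihilation (TTA).

Two excited triplets that meet annihilate, ``T1 + T1 -> S1 + S0``, so the
triplet surface population ``T*(t)`` decays with second-order kinetics,

    dT*/dt = -k T*^2 .

In a strictly two-dimensional medium the bimolecular "constant" is not a
constant: solving the Smoluchowski problem in cylindrical coordinates
(an absorbing disk of radius ``R`` in an infinite plane, Razi-Naqvi / Owen)
gives a time-dependent rate coefficient

    k(t) = N_A * (8 D / pi) * Integral_0^inf  exp(-D u^2 t)
              / ( u * [J0(uR)^2 + Y0(uR)^2] )  du ,

where ``D`` is the lateral diffusion coefficient, ``J0``/``Y0`` are the
zero-order Bessel functions of the first and second kind and ``u`` a dummy
integration variable.  ``k(t)`` decays forever (logarithmically slowly) and
never reaches an asymptote -- the hallmark of compact exploration in 2D.

When crowding makes the motion subdiffusive the kinetics follow the
phenomenological fractal rate law

    dT*/dt = -k_frac * t^(-h) * T*^2 ,   0 <= h < 1,

whose closed form is ``1/T(t) = 1/T0 + k_frac t^(1-h) / (1-h)``.

All public interfaces are SI: time in s, surface concentration in mol m^-2,
D in m^2 s^-1, bimolecular coefficients in m^2 mol^-1 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate
from scipy.constants import Avogadro as N_A
from scipy.interpolate import PchipInterpolator
from scipy.special import j0, y0

__all__ = [
    "KineticTrace",
    "SecondOrderParams",
    "DiffusionKineticsParams",
    "FractalParams",
    "RateCoefficientCurve",
    "NumericalError",
    "DEFAULT_REACTION_RADIUS",
    "DEFAULT_T_MIN",
    "second_order_solution",
    "half_life_second_order",
    "rate_coefficient_2d",
    "dimensionless_rate_integral",
    "solve_tta_2d",
    "fractal_solution",
]

#: Center-to-center contact distance of two porphyrin cores, m.
DEFAULT_REACTION_RADIUS = 1.5e-9

#: Earliest model time for the diffusion model, s.  The 2D coefficient
#: diverges as t -> 0+; events faster than the ~20 ns instrument resolution
#: are not probed, so the model trace starts here by default.
DEFAULT_T_MIN = 2e-8


class NumericalError(RuntimeError):
    """Quadrature or ODE integration failed to converge."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticTrace:
    """Triplet surface concentration T*(t) versus time.

    times : s, strictly increasing, times[0] >= 0
    conc  : mol m^-2, non-negative
    """

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and conc must be 1-D arrays of equal length")
        if t.size and t[0] < 0:
            raise ValueError("times must start at >= 0")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)

    def __len__(self):
        return self.times.size


@dataclass(frozen=True)
class SecondOrderParams:
    """Classical second-order TTA: rate constant k (m^2 mol^-1 s^-1) and
    initial triplet surface concentration T0 (mol m^-2)."""

    k: float
    T0: float

    def __post_init__(self):
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (self.T0 > 0):
            raise ValueError(f"T0 must be > 0, got {self.T0}")


@dataclass(frozen=True)
class DiffusionKineticsParams:
    """2D diffusion-controlled TTA: lateral diffusion coefficient D
    (m^2 s^-1), reaction radius R (m, default 1.5 nm) and T0 (mol m^-2)."""

    D: float
    T0: float
    R: float = DEFAULT_REACTION_RADIUS

    def __post_init__(self):
        if not (self.D > 0):
            raise ValueError(f"D must be > 0, got {self.D}")
        if not (self.R > 0):
            raise ValueError(f"R must be > 0, got {self.R}")
        if not (self.T0 > 0):
            raise ValueError(f"T0 must be > 0, got {self.T0}")


@dataclass(frozen=True)
class FractalParams:
    """Fractal-kinetics TTA: coefficient k_frac (m^2 mol^-1 s^(h-1)),
    exponent h in [0, 1), and T0 (mol m^-2).

    h = 0 recovers classical second-order kinetics with k = k_frac.
    """

    k_frac: float
    h: float
    T0: float

    def __post_init__(self):
        if not (0.0 <= self.h < 1.0):
            raise ValueError(f"h must be in [0, 1), got {self.h}")
        if not (self.k_frac > 0):
            raise ValueError(f"k_frac must be > 0, got {self.k_frac}")
        if not (self.T0 > 0):
            raise ValueError(f"T0 must be > 0, got {self.T0}")


@dataclass(frozen=True)
class RateCoefficientCurve:
    """The time-dependent 2D rate coefficient k(t) on a time grid.

    times  : s, strictly increasing, all > 0
    k_of_t : m^2 mol^-1 s^-1, positive and strictly decreasing
    """

    times: np.ndarray
    k_of_t: np.ndarray
    D: float = field(default=np.nan)
    R: float = field(default=np.nan)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        k = np.asarray(self.k_of_t, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "k_of_t", k)


# ---------------------------------------------------------------------------
# Classical second-order kinetics
# ---------------------------------------------------------------------------

def second_order_solution(params: SecondOrderParams, times) -> KineticTrace:
    """Closed-form solution T(t) = T0 / (1 + k*T0*t) of dT/dt = -k T^2."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    conc = params.T0 / (1.0 + params.k * params.T0 * t)
    return KineticTrace(times=t, conc=conc)


def half_life_second_order(params: SecondOrderParams) -> float:
    """Half-life t1/2 = 1/(k*T0); inversely proportional to the initial
    triplet concentration, the diagnostic signature of second-order decay."""
    return 1.0 / (params.k * params.T0)


# ---------------------------------------------------------------------------
# 2D time-dependent rate coefficient (cylindrical Smoluchowski)
# ---------------------------------------------------------------------------

_EULER_GAMMA = float(np.euler_gamma)
# below x = exp(-_S_CUT) the Bessel modulus is replaced by its exact
# logarithmic limit (relative error < 1e-30 there)
_S_CUT = 40.0


def dimensionless_rate_integral(tau: float) -> float:
    """Master integral I(tau) = Int_0^inf exp(-tau x^2) / (x [J0(x)^2 + Y0(x)^2]) dx.

    The molar rate coefficient is k(t) = N_A * (8 D / pi) * I(D t / R^2):
    k depends on (t, D, R) only through the dimensionless group tau = Dt/R^2.

    Evaluated in the log variable s = ln x, where the integrand is smooth:
    the (integrable) small-x singularity 1/(x ln^2 x) becomes the exact
    analytic Lorentzian-like piece handled in closed form below s = -40, and
    the large-x Gaussian tail uses J0^2 + Y0^2 -> 2/(pi x) and erfc.
    """
    if not (tau > 0):
        raise ValueError("tau must be > 0 (the 2D coefficient diverges at t=0)")
    c = _EULER_GAMMA - np.log(2.0)

    # exact limit piece: integrand -> 1 / (1 + (2/pi)^2 (s + c)^2) as s -> -inf
    head = (np.pi / 2.0) * (np.arctan(2.0 * (-_S_CUT + c) / np.pi) + np.pi / 2.0)

    x_max = max(6.0 / np.sqrt(tau), 30.0)
    s_max = np.log(x_max)

    def integrand(s):
        x = np.exp(s)
        return np.exp(-tau * x * x) / (j0(x) ** 2 + y0(x) ** 2)

    body, err = integrate.quad(
        integrand, -_S_CUT, s_max, limit=400, epsabs=1e-13, epsrel=1e-11
    )
    # Gaussian tail with the large-x Bessel modulus 2/(pi x)
    from scipy.special import erfc

    tail = (np.pi / 2.0) * 0.5 * np.sqrt(np.pi / tau) * erfc(np.sqrt(tau) * x_max)

    total = head + body + tail
    if not np.isfinite(total) or total <= 0:
        raise NumericalError(
            f"rate-coefficient quadrature failed at tau={tau!r}: "
            f"head={head!r} body={body!r} tail={tail!r} quad_err={err!r}"
        )
    if err > 1e-6 * abs(body):
        raise NumericalError(
            f"rate-coefficient quadrature did not converge at tau={tau!r} "
            f"(estimated error {err:.3e} on {body:.6e})"
        )
    return float(total)


@lru_cache(maxsize=8)
def _master_curve(log10_tau_min: float = -9.0, log10_tau_max: float = 12.0,
                  points_per_decade: int = 32) -> PchipInterpolator:
    """Monotone interpolant of ln I(tau) vs ln tau on a log-spaced grid.

    Fitting evaluates k(t) thousands of times; a single master curve in the
    scale-invariant variable tau = Dt/R^2 makes every (D, R) cheap.
    """
    n = int((log10_tau_max - log10_tau_min) * points_per_decade) + 1
    log_tau = np.linspace(log10_tau_min * np.log(10), log10_tau_max * np.log(10), n)
    vals = np.array([dimensionless_rate_integral(np.exp(lt)) for lt in log_tau])
    return PchipInterpolator(log_tau, np.log(vals), extrapolate=True)


def _rate_values(times: np.ndarray, D: float, R: float, exact: bool) -> np.ndarray:
    tau = D * times / (R * R)
    if exact:
        return (8.0 * D / np.pi) * N_A * np.array(
            [dimensionless_rate_integral(x) for x in tau]
        )
    curve = _master_curve()
    return (8.0 * D / np.pi) * N_A * np.exp(curve(np.log(tau)))


def rate_coefficient_2d(params: DiffusionKineticsParams, times,
                        exact: bool = True) -> RateCoefficientCurve:
    """Time-dependent molar 2D rate coefficient on a time grid (all t > 0).

    Parameters
    ----------
    exact : evaluate the quadrature at every point (default).  With
        ``exact=False`` a cached monotone log-log interpolant of the
        dimensionless master curve is used (relative error < 1e-5), the mode
        used inside fitting.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("the 2D rate coefficient requires t > 0 (diverges at t=0)")
    k = _rate_values(t, params.D, params.R, exact)
    return RateCoefficientCurve(times=t, k_of_t=k, D=params.D, R=params.R)


# ---------------------------------------------------------------------------
# Decay with the time-dependent coefficient
# ---------------------------------------------------------------------------

def _inverse_conc_increment(times: np.ndarray, D: float, R: float,
                            points_per_decade: int = 64) -> np.ndarray:
    """K(t) - K(times[0]) where K' = k(t), by cumulative trapezoid of the
    master-curve k on a dense log grid.  The decay ODE is separable:
    1/T(t) = 1/T0 + Int_{t0}^{t} k(s) ds."""
    t0, t1 = times[0], times[-1]
    if t1 == t0:
        return np.zeros_like(times)
    n = max(int(np.log10(t1 / t0) * points_per_decade), 16) + 1
    grid = np.geomspace(t0, t1, n)
    kg = _rate_values(grid, D, R, exact=False)
    K = np.concatenate([[0.0], integrate.cumulative_trapezoid(kg, grid)])
    return np.interp(times, grid, K)


def solve_tta_2d(params: DiffusionKineticsParams, times,
                 rtol: float = 1e-8, exact_rate: bool = False) -> KineticTrace:
    """Numerical solution of dT*/dt = -k(t) T*^2 with the 2D coefficient.

    The trace starts at times[0] (> 0, typically DEFAULT_T_MIN = 20 ns) with
    T*(times[0]) = T0.  Uses an adaptive stiff-capable integrator (LSODA) at
    relative tolerance ``rtol``; k(t) comes from the cached master curve
    unless ``exact_rate`` forces full quadrature at each solver step.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 time points")
    if t[0] <= 0:
        raise ValueError("times must start at t_min > 0 for the 2D model")
    D, R, T0 = params.D, params.R, params.T0
    curve = None if exact_rate else _master_curve()
    RR = R * R

    def k_of(t_):
        if exact_rate:
            return (8.0 * D / np.pi) * N_A * dimensionless_rate_integral(D * t_ / RR)
        return (8.0 * D / np.pi) * N_A * np.exp(curve(np.log(D * t_ / RR)))

    def rhs(t_, y):
        return [-k_of(t_) * y[0] * y[0]]

    sol = integrate.solve_ivp(
        rhs, (t[0], t[-1]), [T0], t_eval=t, method="LSODA",
        rtol=rtol, atol=T0 * rtol * 1e-3,
    )
    if not sol.success:
        raise NumericalError(f"TTA ODE integration failed: {sol.message}")
    conc = np.clip(sol.y[0], 0.0, T0)
    return KineticTrace(times=t, conc=conc)


def tta_2d_closed(params: DiffusionKineticsParams, times) -> KineticTrace:
    """Fast equivalent of :func:`solve_tta_2d` via the separable closed form
    1/T(t) = 1/T0 + Int k(s) ds (used inside least-squares fitting)."""
    t = np.asarray(times, dtype=float)
    if t[0] <= 0:
        raise ValueError("times must start at t_min > 0 for the 2D model")
    K = _inverse_conc_increment(t, params.D, params.R)
    conc = 1.0 / (1.0 / params.T0 + K)
    return KineticTrace(times=t, conc=conc)


# ---------------------------------------------------------------------------
# Fractal kinetics
# ---------------------------------------------------------------------------

def fractal_solution(params: FractalParams, times) -> KineticTrace:
    """Closed form of the fractal rate law dT/dt = -k_frac t^(-h) T^2:

        1/T(t) = 1/T0 + k_frac * t^(1-h) / (1-h).

    1/T is affine in t^(1-h); h = 0 reduces to the classical second-order
    solution with k = k_frac.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    growth = params.k_frac * np.power(t, 1.0 - params.h) / (1.0 - params.h)
    conc = 1.0 / (1.0 / params.T0 + growth)
    return KineticTrace(times=t, conc=conc)


def fractal_half_life(params: FractalParams) -> float:
    """Analytic half-life of the fractal decay:
    t1/2 = [(1-h) / (k_frac * T0)]^(1/(1-h))."""
    e = 1.0 - params.h
    return float((e / (params.k_frac * params.T0)) ** (1.0 / e))
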