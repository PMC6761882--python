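"""Least-squares estimation of TTA kinetic parameters from decay traces.

Estimates the second-order rate constant k, the lateral diffusion
coefficient D (with the reaction radius R held fixed), and the fractal
pair (k_frac, h) from triplet decay traces, plus half-life extraction.

Fits minimise unweighted least squares on concentration by default
(optional 1/sigma^2 weighting).  Positive parameters are log-parameterised
so bounds are implicit; internally traces are normalised by T0 to condition
the Jacobian, and parameters are reported back in SI units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    DEFAULT_REACTION_RADIUS,
    DiffusionKineticsParams,
    FractalParams,
    KineticTrace,
    SecondOrderParams,
    second_order_solution,
    fractal_solution,
    tta_2d_closed,
)

__all__ = [
    "SHGTrace",
    "FitResult",
    "depletion_to_concentration",
    "fit_second_order",
    "fit_diffusion_2d",
    "fit_fractal",
    "extract_half_life",
]


@dataclass(frozen=True)
class SHGTrace:
    """Normalised ground-state depletion versus pump-probe delay.

    The SHG-probed ground-state depletion is directly proportional to the
    triplet concentration, so a depletion trace is a linear image of the
    triplet decay.

    delays    : s, strictly increasing
    depletion : dimensionless (0 at full ground-state recovery)
    sigma     : optional noise-scale estimate, same shape
    """

    delays: np.ndarray
    depletion: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        d = np.asarray(self.delays, dtype=float)
        y = np.asarray(self.depletion, dtype=float)
        if d.shape != y.shape or d.ndim != 1:
            raise ValueError("delays and depletion must be 1-D of equal length")
        if d.size > 1 and not np.all(np.diff(d) > 0):
            raise ValueError("delays must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("depletion must be finite")
        object.__setattr__(self, "delays", d)
        object.__setattr__(self, "depletion", y)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != d.shape:
                raise ValueError("sigma must match trace shape")
            object.__setattr__(self, "sigma", s)


@dataclass
class FitResult:
    """Parameter estimates from a trace fit.

    params     : point estimates, SI units
    stderr     : asymptotic standard errors (same keys; >= 0)
    residuals  : data - model, trace-length
    residual_norm : ||residuals||_2
    converged  : optimiser success AND the data constrain the parameters
    model      : model identifier
    message    : diagnostic (e.g. ill-conditioning)
    """

    params: dict
    stderr: dict
    residuals: np.ndarray
    residual_norm: float
    converged: bool
    model: str
    message: str = ""
    extra: dict = field(default_factory=dict)


def depletion_to_concentration(trace: SHGTrace, T0: float) -> KineticTrace:
    """Convert a depletion trace to a triplet concentration trace.

    Depletion is proportional to triplet concentration, so
    conc = T0 * depletion / depletion[0]; the first delay maps to T0.
    """
    if not (T0 > 0):
        raise ValueError("T0 must be > 0")
    d0 = trace.depletion[0]
    if not (d0 > 0):
        raise ValueError("initial depletion must be > 0 to normalise")
    conc = T0 * trace.depletion / d0
    return KineticTrace(times=trace.delays, conc=np.clip(conc, 0.0, None))


def _stderr_from_jac(res, n_data: int) -> np.ndarray:
    """Asymptotic standard errors from the least-squares Jacobian."""
    _, s, VT = np.linalg.svd(res.jac, full_matrices=False)
    thresh = np.finfo(float).eps * max(res.jac.shape) * s[0]
    s = s[s > thresh]
    VT = VT[: s.size]
    dof = max(n_data - res.x.size, 1)
    sigma2 = 2.0 * res.cost / dof
    cov = (VT.T / s**2) @ VT * sigma2
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def fit_second_order(trace: KineticTrace, fit_T0: bool = False,
                     weights: np.ndarray | None = None) -> FitResult:
    """Fit the classical second-order model T(t) = T0/(1 + k T0 t).

    By default T0 is pinned to the first data point and only k is free;
    ``fit_T0=True`` frees both.  Flags ill-conditioning when the trace
    carries no curvature (k*T0*t << 1 throughout).
    """
    t, y = trace.times, trace.conc
    if t.size < 8:
        raise ValueError("need at least 8 points to fit")
    if np.any(y <= 0):
        raise ValueError("concentrations must be positive for fitting")
    T0_obs = y[0]
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)

    # starting k from the two-point inverse-concentration slope
    slope = (1.0 / y[-1] - 1.0 / y[0]) / (t[-1] - t[0])
    k0 = slope if slope > 0 else 1.0 / (T0_obs * (t[-1] - t[0]))

    yn = y / T0_obs  # dimensionless residuals condition the Jacobian

    if fit_T0:
        def resid(p):
            k, T0 = np.exp(p)
            m = T0 / (1.0 + k * T0 * (t - t[0]))
            return w * (yn - m / T0_obs)
        x0 = np.log([k0, T0_obs])
    else:
        def resid(p):
            k = np.exp(p[0])
            m = T0_obs / (1.0 + k * T0_obs * (t - t[0]))
            return w * (yn - m / T0_obs)
        x0 = np.log([k0])

    res = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    est = np.exp(res.x)
    k_hat = est[0]
    T0_hat = est[1] if fit_T0 else T0_obs

    se_log = _stderr_from_jac(res, t.size)
    stderr = {"k": k_hat * se_log[0]}
    params = {"k": k_hat, "T0": T0_hat}
    if fit_T0:
        stderr["T0"] = T0_hat * se_log[1]

    residuals = resid(res.x) * T0_obs

    # degenerate: essentially no second-order curvature over the window
    extent = k_hat * T0_hat * (t[-1] - t[0])
    ill = extent < 0.05
    msg = "" if not ill else (
        f"ill-conditioned: k*T0*t_max = {extent:.3g} << 1, "
        "the trace shows no second-order curvature"
    )
    return FitResult(
        params=params, stderr=stderr, residuals=residuals,
        residual_norm=float(np.linalg.norm(residuals)),
        converged=bool(res.success and not ill),
        model="second_order", message=msg or res.message,
    )


def fit_diffusion_2d(trace: KineticTrace, R: float = DEFAULT_REACTION_RADIUS,
                     weights: np.ndarray | None = None) -> FitResult:
    """Fit the 2D diffusion-controlled model (time-dependent coefficient,
    R fixed) for the lateral diffusion coefficient D.

    The decay with time-dependent k(t) is separable, so each candidate D is
    evaluated through the cached dimensionless master curve rather than by
    re-integrating the ODE.
    """
    t, y = trace.times, trace.conc
    if not (R > 0):
        raise ValueError("R must be > 0")
    if t[0] <= 0:
        raise ValueError("the 2D model requires the trace to start at t > 0")
    if t.size < 8:
        raise ValueError("need at least 8 points to fit")
    if np.any(y <= 0):
        raise ValueError("concentrations must be positive for fitting")
    T0_obs = y[0]
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    yn = y / T0_obs

    # Brownian-order starting guess: treat the half-life scale with an
    # effective k ~ 4 pi D N_A, i.e. D0 ~ k_eff / (4 pi N_A)
    from scipy.constants import Avogadro as N_A
    t_half = t[np.searchsorted(-yn, -0.5)] if yn[-1] < 0.5 else t[-1]
    k_eff = 1.0 / (T0_obs * t_half)
    D0 = max(k_eff / (4.0 * np.pi * N_A), 1e-16)

    def resid(p):
        D = np.exp(p[0])
        m = tta_2d_closed(
            DiffusionKineticsParams(D=D, R=R, T0=T0_obs), t
        ).conc
        return w * (yn - m / T0_obs)

    res = least_squares(resid, [np.log(D0)], method="lm",
                        xtol=1e-13, ftol=1e-13)
    D_hat = float(np.exp(res.x[0]))
    se_log = _stderr_from_jac(res, t.size)
    residuals = resid(res.x) * T0_obs
    rel_decay = 1.0 - yn[-1]
    ill = rel_decay < 0.02
    return FitResult(
        params={"D": D_hat, "R": R, "T0": T0_obs},
        stderr={"D": D_hat * se_log[0]},
        residuals=residuals,
        residual_norm=float(np.linalg.norm(residuals)),
        converged=bool(res.success and not ill),
        model="diffusion_2d",
        message="" if not ill else "ill-conditioned: trace barely decays",
    )


def fit_fractal(trace: KineticTrace, h0: float = 0.1,
                weights: np.ndarray | None = None) -> FitResult:
    """Fit the fractal rate law dT/dt = -k_frac t^(-h) T^2 for (k_frac, h).

    h is bounded to [0, 0.99]; a fit pinned at the upper bound is flagged
    as not converged.  Requires >= 10 points spanning >= 1.5 decades of
    time (the power-law exponent is unidentifiable on a narrow window).

    The fractal law is non-autonomous (the clock enters through t^-h), so
    T0 -- the concentration at t = 0, not at the first sample -- is fitted
    as a third free parameter, started at the first observed value.
    """
    t, y = trace.times, trace.conc
    if t.size < 10:
        raise ValueError("need at least 10 points to fit the fractal law")
    tpos = t[t > 0]
    if tpos.size < 10 or np.log10(tpos[-1] / tpos[0]) < 1.5:
        raise ValueError("trace must span at least 1.5 decades of time")
    if np.any(y <= 0):
        raise ValueError("concentrations must be positive for fitting")
    mask = t > 0
    tf, yf = t[mask], y[mask]
    T0_obs = y[0]
    w = (np.ones_like(yf) if weights is None
         else np.asarray(weights, float)[mask])
    yn = yf / T0_obs

    slope = (1.0 / yf[-1] - 1.0 / yf[0]) / (tf[-1] - tf[0])
    k0 = slope if slope > 0 else 1.0 / (T0_obs * (tf[-1] - tf[0]))

    def resid(p):
        k_frac, h, T0 = np.exp(p[0]), p[1], np.exp(p[2])
        m = fractal_solution(
            FractalParams(k_frac=k_frac, h=h, T0=T0), tf
        ).conc
        return w * (yn - m / T0_obs)

    res = least_squares(
        resid, [np.log(k0), h0, np.log(T0_obs)],
        bounds=([-np.inf, 0.0, -np.inf], [np.inf, 0.99, np.inf]),
        xtol=1e-14, ftol=1e-14,
    )
    k_hat, h_hat = float(np.exp(res.x[0])), float(res.x[1])
    T0_hat = float(np.exp(res.x[2]))
    se = _stderr_from_jac(res, tf.size)
    residuals = resid(res.x) * T0_obs
    pinned = h_hat >= 0.99 - 1e-9
    return FitResult(
        params={"k_frac": k_hat, "h": h_hat, "T0": T0_hat},
        stderr={"k_frac": k_hat * se[0], "h": float(se[1]),
                "T0": T0_hat * se[2]},
        residuals=residuals,
        residual_norm=float(np.linalg.norm(residuals)),
        converged=bool(res.success and not pinned),
        model="fractal",
        message="h pinned at upper bound" if pinned else res.message,
    )


def extract_half_life(trace: KineticTrace) -> float:
    """Time of the first crossing of conc = conc[0]/2, by linear
    interpolation between the bracketing samples."""
    y = trace.conc
    target = y[0] / 2.0
    below = np.nonzero(y <= target)[0]
    if below.size == 0:
        raise ValueError("trace never reaches half of its initial value")
    i = below[0]
    if i == 0:
        return float(trace.times[0])
    t0, t1 = trace.times[i - 1], trace.times[i]
    y0_, y1_ = y[i - 1], y[i]
    return float(t0 + (y0_ - target) / (y0_ - y1_) * (t1 - t0))
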