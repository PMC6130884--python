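"""Closed-form learning kernels for a pre/post spike pair with alpha traces.

Spikes are idealised Dirac deltas; each spike leaves an eligibility trace
shaped as an alpha function,

    eps(t) = kappa * (t/tau) * exp(1 - t/tau)   for t >= 0, else 0,

normalised so the trace peaks at value kappa at t = tau.  With the
pre-synaptic spike at time 0 (trace time constant tau1) and the
post-synaptic spike at time dt (tau2), every G-DHL component integral

    Dw_k(dt) = integral component_k(eps1(t), eps2(t - dt)) dt

has an exact closed form: each factor (the trace, or the positive/negative
part of its derivative) is a linear polynomial times a decaying exponential
supported on a single interval, so the integrand is a quadratic polynomial
times exp(-alpha*t) on the intersection of the two supports, and the
antiderivative is elementary.  Because the two exponential rates *add*
(alpha = 1/tau1 + 1/tau2), the formulas are well conditioned for every
tau1, tau2 combination, including tau1 = tau2 — no separate equal-tau
branch is needed.

Support bookkeeping gives the piecewise structure in dt directly: e.g. the
positive derivative part of a trace lives on [spike, spike + tau] and the
negative part on [spike + tau, inf), which is why the 'np' component is
exactly zero for dt <= 0 when tau1 = tau2, and 'pn' for dt >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .kernels import KernelCurve
from .rule import COMPONENTS, GDHLCoefficients

__all__ = [
    "TraceParams",
    "alpha_trace",
    "alpha_trace_derivative",
    "analytic_component_dw",
    "analytic_kernel",
    "kernel_peak",
    "PeakResult",
]


@dataclass(frozen=True)
class TraceParams:
    """Alpha-function eligibility-trace parameters.

    kappa: peak trace amplitude (dimensionless); tau1/tau2: pre-/post-trace
    time constants (ms).  All strictly positive.
    """

    kappa: float = 1.0
    tau1: float = 20.0
    tau2: float = 20.0

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("kappa, tau1 and tau2 must all be > 0")


def alpha_trace(t, kappa: float, tau: float):
    """eps(t) = kappa*(t/tau)*exp(1 - t/tau) for t >= 0, else 0 (peak kappa at tau)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, kappa * (t / tau) * np.exp(1.0 - t / tau), 0.0)
    return float(out) if out.ndim == 0 else out


def alpha_trace_derivative(t, kappa: float, tau: float):
    """d/dt of the alpha trace: positive before t = tau, negative after."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, (kappa / tau) * (1.0 - t / tau) * np.exp(1.0 - t / tau), 0.0)
    return float(out) if out.ndim == 0 else out


def _factor(kind: str, tau, kappa: float, shift):
    """One multiplication factor as (lo, hi, c0, c1, rate, log_pref).

    The factor equals (c0 + c1*t) * exp(log_pref - t/tau) on [lo, hi] and is
    zero outside.  *shift* is the spike time; shift and tau may be arrays
    (everything broadcasts).

    kind 's': the trace itself, support [shift, inf)
    kind 'p': positive part of the trace derivative, support [shift, shift+tau]
    kind 'n': negative part of the trace derivative, support [shift+tau, inf)
    """
    shift = np.asarray(shift, dtype=float)
    tau = np.asarray(tau, dtype=float)
    r = 1.0 / tau
    log_pref = 1.0 + shift * r
    inf = np.inf * np.ones(np.broadcast_shapes(shift.shape, tau.shape))
    if kind == "s":
        c1 = kappa * r + 0.0 * shift
        c0 = -shift * kappa * r
        lo, hi = shift + 0.0 * tau, inf
    elif kind == "p":
        c0 = kappa * r * (1.0 + shift * r)
        c1 = -kappa * r**2 + 0.0 * shift
        lo, hi = shift + 0.0 * tau, shift + tau
    elif kind == "n":
        c0 = -kappa * r * (1.0 + shift * r)
        c1 = kappa * r**2 + 0.0 * shift
        lo, hi = shift + tau, inf
    else:  # pragma: no cover - guarded by COMPONENTS
        raise KeyError(f"unknown factor kind {kind!r}")
    return lo, hi, c0, c1, r + 0.0 * shift, log_pref


def _integral_poly2_exp(p0, p1, p2, alpha, length):
    """integral_0^L (p0 + p1 s + p2 s^2) exp(-alpha s) ds, L possibly inf."""
    a = p2 / alpha
    b = (p1 + 2.0 * a) / alpha
    c = (p0 + b) / alpha
    length = np.asarray(length, dtype=float)
    finite = np.isfinite(length)
    lf = np.where(finite, length, 0.0)
    tail = np.where(finite, np.exp(-alpha * lf) * (a * lf**2 + b * lf + c), 0.0)
    return c - tail


def _component_dw_core(component: str, delta_t, tau1, tau2, kappa: float):
    """Broadcasting core of the closed form (delta_t/tau1/tau2 arrays OK)."""
    pre_kind, post_kind = component
    zero = 0.0 * np.asarray(delta_t, dtype=float)
    lo1, hi1, a0, a1, r1, e1 = _factor(pre_kind, tau1, kappa, zero)
    lo2, hi2, b0, b1, r2, e2 = _factor(post_kind, tau2, kappa, delta_t)
    lo = np.maximum(lo1, lo2)
    # clamping the length at zero makes empty overlaps integrate to exactly 0
    length = np.maximum(np.minimum(hi1, hi2) - lo, 0.0)
    alpha = r1 + r2
    # product polynomial in t, recentred at t = lo for conditioning
    q0 = a0 * b0
    q1 = a0 * b1 + a1 * b0
    q2 = a1 * b1
    p0 = q0 + q1 * lo + q2 * lo**2
    p1 = q1 + 2.0 * q2 * lo
    p2 = q2
    core = _integral_poly2_exp(p0, p1, p2, alpha, length)
    # exp(e1 + e2 - alpha*lo) <= e^2: lo lies at or past both spike times
    return np.exp(e1 + e2 - alpha * lo) * core


def analytic_component_dw(component: str, delta_t, p: TraceParams):
    """Closed-form total weight change of one unit-coefficient component.

    Pre-synaptic spike at 0, post-synaptic spike at *delta_t* (scalar or
    array; ms).  Both factors carry the trace amplitude, so the value scales
    as kappa**2.
    """
    if component not in COMPONENTS:
        raise KeyError(f"unknown component {component!r}")
    delta_t = np.asarray(delta_t, dtype=float)
    out = _component_dw_core(component, delta_t, p.tau1, p.tau2, p.kappa)
    return float(out) if out.ndim == 0 else out


def analytic_kernel(
    c: GDHLCoefficients, p: TraceParams, delta_ts
) -> KernelCurve:
    """Coefficient-weighted sum of the eight component kernels at each delay."""
    delta_ts = np.asarray(delta_ts, dtype=float)
    total = np.zeros_like(delta_ts)
    for k in COMPONENTS:
        w = c.coefficient(k)
        if w != 0.0:
            total = total + w * analytic_component_dw(k, delta_ts, p)
    return KernelCurve(delta_ts, c.rate * total)


@dataclass(frozen=True)
class PeakResult:
    """Argmax and max of a component kernel, with the method used."""

    delta_t: float
    dw: float
    method: str = "grid+bounded-refine"


def kernel_peak(
    component: str, p: TraceParams, span: float | None = None, n_grid: int = 4001
) -> PeakResult:
    """Location and height of the maximum of a unit-coefficient component kernel.

    A symmetric grid scan over [-span, span] (span defaults to 8 times the
    slower time constant, which safely covers the kernel support) brackets
    the maximum, which is then refined by bounded scalar minimisation.
    """
    if span is None:
        span = 8.0 * max(p.tau1, p.tau2)
    grid = np.linspace(-span, span, n_grid)
    vals = analytic_component_dw(component, grid, p)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda d: -analytic_component_dw(component, d, p),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    d_star, v_star = float(res.x), float(-res.fun)
    if vals[i] >= v_star:  # grid point at least as good (e.g. peak at a kink)
        d_star, v_star = float(grid[i]), float(vals[i])
    return PeakResult(delta_t=d_star, dw=v_star)
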