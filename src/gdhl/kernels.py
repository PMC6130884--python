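"""Numerical learning kernels: total weight change as a function of delay.

A learning kernel K(dt) is obtained by placing one event on the pre-synaptic
signal and one on the post-synaptic signal separated by an inter-event delay
dt (convention: dt = t_post - t_pre, positive means the pre-synaptic event
leads), running the rule over the pair, and recording the accumulated weight
change.  Sweeping dt yields the familiar STDP-style curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rule import COMPONENTS, GDHLCoefficients, component_update, instantaneous_update
from .signals import (
    EventSpec,
    Signal,
    SkewedEventSpec,
    TimeGrid,
    cosine_event,
    derivative,
    skewed_cosine_event,
)

__all__ = [
    "KernelCurve",
    "numerical_kernel",
    "component_kernels",
    "default_delta_ts",
]

Event = EventSpec | SkewedEventSpec


@dataclass(frozen=True)
class KernelCurve:
    """Sampled learning kernel: strictly increasing delays and their dw."""

    delta_ts: np.ndarray = field(repr=False)
    dws: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dts = np.asarray(self.delta_ts, dtype=float)
        dws = np.asarray(self.dws, dtype=float)
        object.__setattr__(self, "delta_ts", dts)
        object.__setattr__(self, "dws", dws)
        if dts.shape != dws.shape or dts.ndim != 1:
            raise ValueError("delta_ts and dws must be 1-D arrays of equal length")
        if dts.size >= 2 and not np.all(np.diff(dts) > 0):
            raise ValueError("delta_ts must be strictly increasing")

    def to_csv(self, path, comments: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in comments or []:
                fh.write(f"# {line}\n")
            fh.write("delta_t,dw\n")
            for dt_, dw in zip(self.delta_ts, self.dws):
                fh.write(f"{dt_:.12g},{dw:.12g}\n")

    @classmethod
    def from_csv(cls, path) -> "KernelCurve":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        return cls(df["delta_t"].to_numpy(float), df["dw"].to_numpy(float))


def default_delta_ts(lo: float = -1.0, hi: float = 1.0, step: float = 0.01) -> np.ndarray:
    """Default delay grid for dimensionless event demos: [-1, 1] step 0.01."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _event_halfwidths(event: Event) -> tuple[float, float]:
    if isinstance(event, SkewedEventSpec):
        return event.rise_half_width, event.fall_half_width
    return event.half_width, event.half_width


def _place_event(event: Event, center: float, grid: TimeGrid) -> Signal:
    if isinstance(event, SkewedEventSpec):
        spec = SkewedEventSpec(
            center, event.rise_half_width, event.fall_half_width, event.amplitude
        )
        return skewed_cosine_event(spec, grid)
    spec = EventSpec(center, event.half_width, event.amplitude)
    return cosine_event(spec, grid)


def _pair_grid(event: Event, delta_ts: np.ndarray, dt: float) -> TimeGrid:
    """One grid covering both events at every delay, padded by a full width."""
    hw_l, hw_r = _event_halfwidths(event)
    width = hw_l + hw_r
    lo = min(0.0, float(np.min(delta_ts))) - hw_l - width
    hi = max(0.0, float(np.max(delta_ts))) + hw_r + width
    return TimeGrid.from_span(lo, hi, dt)


def numerical_kernel(
    event: Event,
    c: GDHLCoefficients,
    delta_ts: np.ndarray | None = None,
    dt: float = 0.001,
) -> KernelCurve:
    """Learning kernel of a coefficient set for a given event waveform.

    The pre-synaptic event is centred at 0 and the post-synaptic one at each
    delay in *delta_ts*; the rule is integrated over a window covering both
    events padded by one event width, so the (formally infinite) kernel
    integral is truncated only where the integrand is exactly zero.
    """
    if delta_ts is None:
        delta_ts = default_delta_ts()
    delta_ts = np.asarray(delta_ts, dtype=float)
    grid = _pair_grid(event, delta_ts, dt)
    pre = _place_event(event, 0.0, grid)
    u1 = pre.values
    du1 = derivative(pre).values
    dws = np.empty(delta_ts.size)
    for i, d in enumerate(delta_ts):
        post = _place_event(event, float(d), grid)
        wdot = instantaneous_update(u1, du1, post.values, derivative(post).values, c)
        dws[i] = np.sum(wdot) * dt
    return KernelCurve(delta_ts, dws)


def component_kernels(
    event: Event,
    delta_ts: np.ndarray | None = None,
    dt: float = 0.001,
) -> dict[str, KernelCurve]:
    """One unit-coefficient kernel per G-DHL component.

    Any preset/coefficient kernel is the coefficient-weighted sum of these
    (the rule is linear in its coefficients).
    """
    if delta_ts is None:
        delta_ts = default_delta_ts()
    delta_ts = np.asarray(delta_ts, dtype=float)
    grid = _pair_grid(event, delta_ts, dt)
    pre = _place_event(event, 0.0, grid)
    u1 = pre.values
    du1 = derivative(pre).values
    out = {k: np.empty(delta_ts.size) for k in COMPONENTS}
    for i, d in enumerate(delta_ts):
        post = _place_event(event, float(d), grid)
        u2 = post.values
        du2 = derivative(post).values
        for k in COMPONENTS:
            out[k][i] = np.sum(component_update(k, u1, du1, u2, du2)) * dt
    return {k: KernelCurve(delta_ts, v) for k, v in out.items()}
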