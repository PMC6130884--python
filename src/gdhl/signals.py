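"""Uniformly sampled neural signals and the operators that feed DHL rules.

A differential Hebbian rule consumes a pre- and a post-synaptic *signal*
(firing rate, membrane potential, neurotransmitter concentration, ...) on a
shared uniform time grid.  The rule itself only ever sees the signal values,
their first derivative, and the positive/negative parts of that derivative,
so those operators live here, together with event generators (raised-cosine
bumps, random cosine mixtures) and the leaky-accumulator trace filter used
to bridge time gaps between events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "TimeGrid",
    "Signal",
    "EventSpec",
    "SkewedEventSpec",
    "positive_part",
    "negative_part",
    "derivative",
    "cosine_event",
    "skewed_cosine_event",
    "random_cosine_mixture",
    "leaky_trace",
    "shift_nonnegative",
    "read_signal_csv",
    "write_signal_csv",
]


@dataclass(frozen=True)
class TimeGrid:
    """A uniform time grid: ``t_k = t0 + k*dt`` for ``k = 0..n-1``."""

    t0: float
    dt: float
    n: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t0) and np.isfinite(self.dt)):
            raise ValueError("grid t0/dt must be finite")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.n < 2:
            raise ValueError(f"grid needs at least 2 samples, got {self.n}")

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.n - 1)

    @classmethod
    def from_span(cls, t0: float, t_end: float, dt: float) -> "TimeGrid":
        n = int(round((t_end - t0) / dt)) + 1
        return cls(t0, dt, n)

    def matches(self, other: "TimeGrid", rtol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and abs(self.t0 - other.t0) <= rtol * max(1.0, abs(self.t0))
            and abs(self.dt - other.dt) <= rtol * self.dt
        )


@dataclass(frozen=True)
class Signal:
    """A real-valued signal sampled on a uniform grid.

    Invariants: ``dt > 0``, all samples finite, at least 2 samples.
    """

    t0: float
    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("signal must be a 1-D array with length >= 2")
        if not np.all(np.isfinite(vals)):
            raise ValueError("signal values must all be finite")
        if not (np.isfinite(self.t0) and np.isfinite(self.dt)) or self.dt <= 0:
            raise ValueError("t0 must be finite and dt > 0")

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(self.t0, self.dt, self.values.size)

    def times(self) -> np.ndarray:
        return self.grid.times()

    @classmethod
    def on_grid(cls, grid: TimeGrid, values: np.ndarray) -> "Signal":
        values = np.asarray(values, dtype=float)
        if values.size != grid.n:
            raise ValueError("values length does not match grid size")
        return cls(grid.t0, grid.dt, values)

    def with_values(self, values: np.ndarray) -> "Signal":
        return Signal(self.t0, self.dt, values)


@dataclass(frozen=True)
class EventSpec:
    """A symmetric raised-cosine event: smooth rise then fall around *center*."""

    center: float
    half_width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class SkewedEventSpec:
    """An asymmetric raised-cosine event: rise and fall half-widths differ."""

    center: float
    rise_half_width: float
    fall_half_width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.rise_half_width <= 0 or self.fall_half_width <= 0:
            raise ValueError("half-widths must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


def positive_part(x):
    """[x]+ : x where x >= 0, else 0.  Accepts scalars or arrays."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("positive_part: input must be finite")
    out = np.maximum(x, 0.0)
    return float(out) if out.ndim == 0 else out


def negative_part(x):
    """[x]- : -x where x <= 0, else 0 (a magnitude, never negative)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("negative_part: input must be finite")
    out = np.maximum(-x, 0.0)
    return float(out) if out.ndim == 0 else out


def derivative(s: Signal) -> Signal:
    """First time derivative: central differences inside, one-sided at edges."""
    if s.values.size < 3:
        raise ValueError("derivative needs at least 3 samples")
    return s.with_values(np.gradient(s.values, s.dt))


def _raised_cosine(t, center, hw_left, hw_right, amplitude):
    x = np.asarray(t, dtype=float) - center
    out = np.zeros_like(x)
    left = (x >= -hw_left) & (x < 0)
    right = (x >= 0) & (x <= hw_right)
    out[left] = 0.5 * (1.0 + np.cos(np.pi * x[left] / hw_left))
    out[right] = 0.5 * (1.0 + np.cos(np.pi * x[right] / hw_right))
    return amplitude * out


def _check_support(grid: TimeGrid, lo: float, hi: float) -> None:
    if lo < grid.t0 or hi > grid.t_end:
        warnings.warn(
            "event support [%g, %g] not fully covered by grid [%g, %g]; "
            "event will be truncated" % (lo, hi, grid.t0, grid.t_end),
            stacklevel=3,
        )


def cosine_event(spec: EventSpec, grid: TimeGrid) -> Signal:
    """Sample a symmetric raised-cosine bump on *grid*.

    u(t) = A/2 * (1 + cos(pi*(t - c)/h)) on |t - c| <= h, zero outside; the
    value and the first derivative both vanish at the edges, so the event is
    a smooth monotonic rise followed by a smooth fall.
    """
    _check_support(grid, spec.center - spec.half_width, spec.center + spec.half_width)
    vals = _raised_cosine(
        grid.times(), spec.center, spec.half_width, spec.half_width, spec.amplitude
    )
    return Signal.on_grid(grid, vals)


def skewed_cosine_event(spec: SkewedEventSpec, grid: TimeGrid) -> Signal:
    """Asymmetric bump: raised-cosine rise over ``rise_half_width`` and fall
    over ``fall_half_width``.  Used to break the left/right symmetry of the
    component kernels."""
    _check_support(
        grid, spec.center - spec.rise_half_width, spec.center + spec.fall_half_width
    )
    vals = _raised_cosine(
        grid.times(),
        spec.center,
        spec.rise_half_width,
        spec.fall_half_width,
        spec.amplitude,
    )
    return Signal.on_grid(grid, vals)


def random_cosine_mixture(
    n_components: int,
    grid: TimeGrid,
    freq_range: tuple[float, float] = (0.1, 3.0),
    seed: int | np.random.Generator | None = None,
) -> Signal:
    """Average of *n_components* cosines with random frequency and amplitude.

    Each cosine ``cos(f*t)`` (frequency uniform in *freq_range*, radians per
    time unit) is first rescaled to (0, 1) and then multiplied by an
    amplitude uniform in (0, 1); the components are averaged, so the result
    lies in [0, 1].  All components share phase zero at t = 0.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = grid.times()
    freqs = rng.uniform(freq_range[0], freq_range[1], size=n_components)
    amps = rng.uniform(0.0, 1.0, size=n_components)
    comps = 0.5 * (1.0 + np.cos(freqs[:, None] * t[None, :]))
    vals = np.mean(amps[:, None] * comps, axis=0)
    return Signal.on_grid(grid, vals)


def leaky_trace(s: Signal, tau: float, init: float = 0.0) -> Signal:
    """Leaky-accumulator (discrete leaky-integrator) trace of a signal.

    m_t = m_{t-1} + (dt/tau) * (-m_{t-1} + u_{t-1}), with m_0 = *init*.
    The trace decays towards zero with time constant *tau* and accumulates
    the input, letting events separated by a gap interact in learning.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    a = s.dt / tau
    # y[k] = (1-a)*y[k-1] + a*x[k-1]  ==  IIR filter with one-sample input lag
    b = [0.0, a]
    den = [1.0, -(1.0 - a)]
    out, _ = lfilter(b, den, s.values, zi=[float(init)])
    return s.with_values(out)


def shift_nonnegative(s: Signal) -> Signal:
    """Shift a signal so its minimum is zero; identity if already nonnegative.

    DHL assumes nonnegative activations; shifting leaves the derivative (and
    hence every differential component) unchanged.
    """
    lo = float(np.min(s.values))
    if lo >= 0:
        return s
    return s.with_values(s.values - lo)


def write_signal_csv(s: Signal, path, comments: list[str] | None = None) -> None:
    """Write a signal as two-column CSV (``time,value``; '#' comments)."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write("time,value\n")
        for t, v in zip(s.times(), s.values):
            fh.write(f"{t:.12g},{v:.12g}\n")


def read_signal_csv(path) -> Signal:
    """Read a two-column ``time,value`` CSV into a Signal (grid must be uniform)."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    t = df["time"].to_numpy(float)
    v = df["value"].to_numpy(float)
    if t.size < 2:
        raise ValueError("signal CSV needs at least 2 rows")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-12 * max(1.0, dt)):
        raise ValueError("signal CSV must be sampled on a uniform time grid")
    return Signal(float(t[0]), dt, v)
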