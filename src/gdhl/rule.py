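"""The general differential Hebbian learning (G-DHL) rule.

The rule updates a synapse from the step-by-step interaction of the pre- and
post-synaptic signals u1, u2 and their derivatives.  Writing [x]+ and [x]-
for the positive/negative parts of x, the instantaneous weight change is a
linear combination of eight components:

    dw/dt = rate * ( sigma_pp [du1]+ [du2]+  +  sigma_pn [du1]+ [du2]-
                   + sigma_np [du1]- [du2]+  +  sigma_nn [du1]- [du2]-
                   + eta_sp   u1    [du2]+   +  eta_sn   u1    [du2]-
                   + eta_ps  [du1]+  u2      +  eta_ns  [du1]-  u2 )

Component ids are two letters (pre factor, post factor) drawn from
{s: signal, p: positive derivative part, n: negative derivative part}; the
signal-by-signal combination "ss" is excluded because plain Hebbian
correlation is already generated by the pp + nn pair.  Classic rules are
special cases: Kosko's du1*du2 (sigma = +1,-1,-1,+1) and the
Porr-Wörgötter u1*du2 (eta_sp = +1, eta_sn = -1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .signals import Signal, TimeGrid, derivative, negative_part, positive_part

__all__ = [
    "COMPONENTS",
    "GDHLCoefficients",
    "WeightTrajectory",
    "component_update",
    "instantaneous_update",
    "integrate",
    "preset",
    "PRESET_NAMES",
]

#: Canonical component order: the four differential (sigma) components, then
#: the four mixed (eta) components.
COMPONENTS: tuple[str, ...] = ("pp", "pn", "np", "nn", "sp", "sn", "ps", "ns")

_COEFF_FIELD = {
    "pp": "sigma_pp",
    "pn": "sigma_pn",
    "np": "sigma_np",
    "nn": "sigma_nn",
    "sp": "eta_sp",
    "sn": "eta_sn",
    "ps": "eta_ps",
    "ns": "eta_ns",
}


@dataclass(frozen=True)
class GDHLCoefficients:
    """The eight component weights plus a global learning rate.

    ``sigma_*`` weight derivative-by-derivative (differential) components,
    ``eta_*`` weight signal-by-derivative (mixed) components.  The sign of a
    coefficient decides whether its component potentiates (LTP) or
    depresses (LTD) the synapse; ``rate`` is the 1/tau global multiplier of
    the classic rules, applied after the sum (default 1).
    """

    sigma_pp: float = 0.0
    sigma_pn: float = 0.0
    sigma_np: float = 0.0
    sigma_nn: float = 0.0
    eta_sp: float = 0.0
    eta_sn: float = 0.0
    eta_ps: float = 0.0
    eta_ns: float = 0.0
    rate: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    def coefficient(self, component: str) -> float:
        """The coefficient attached to a two-letter component id."""
        try:
            return getattr(self, _COEFF_FIELD[component])
        except KeyError:
            raise KeyError(f"unknown component {component!r}") from None

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "GDHLCoefficients":
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GDHLCoefficients":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_components(
        cls, weights: dict[str, float], rate: float = 1.0
    ) -> "GDHLCoefficients":
        """Build from a ``{component_id: weight}`` mapping (others zero)."""
        kwargs = {_COEFF_FIELD[k]: float(v) for k, v in weights.items()}
        return cls(rate=rate, **kwargs)

    def scaled(self, factor: float) -> "GDHLCoefficients":
        """Scale every component coefficient (rate untouched)."""
        kwargs = {
            f.name: getattr(self, f.name) * factor
            for f in fields(self)
            if f.name != "rate"
        }
        return replace(self, **kwargs)


@dataclass(frozen=True)
class WeightTrajectory:
    """Step-by-step weight evolution under a DHL rule.

    ``wdot`` holds the instantaneous change at each sample and ``w`` the
    explicit-Euler running weight w[k] = w0 + sum_{j<=k} wdot[j]*dt.
    """

    grid: TimeGrid
    wdot: np.ndarray = field(repr=False)
    w: np.ndarray = field(repr=False)
    w0: float = 0.0

    @property
    def total_dw(self) -> float:
        return float(self.w[-1] - self.w0)


def component_update(component: str, u1, du1, u2, du2):
    """Unsigned single-component product (coefficient excluded).

    Vectorised: scalars or same-shape arrays are accepted.
    """
    if component not in _COEFF_FIELD:
        raise KeyError(f"unknown component {component!r}")
    pre, post = component
    f1 = {"s": lambda: np.asarray(u1, dtype=float),
          "p": lambda: positive_part(du1),
          "n": lambda: negative_part(du1)}[pre]()
    f2 = {"s": lambda: np.asarray(u2, dtype=float),
          "p": lambda: positive_part(du2),
          "n": lambda: negative_part(du2)}[post]()
    out = f1 * f2
    return float(out) if np.ndim(out) == 0 else out


def instantaneous_update(u1, du1, u2, du2, c: GDHLCoefficients):
    """Instantaneous weight change dw/dt for given signal samples.

    Requires nonnegative activations u1, u2 (pre-process with
    :func:`gdhl.signals.shift_nonnegative` if needed).
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if np.any(u1 < 0) or np.any(u2 < 0):
        raise ValueError(
            "u1 and u2 must be nonnegative; shift the signals first "
            "(signals.shift_nonnegative)"
        )
    p1, n1 = positive_part(du1), negative_part(du1)
    p2, n2 = positive_part(du2), negative_part(du2)
    total = (
        c.sigma_pp * p1 * p2
        + c.sigma_pn * p1 * n2
        + c.sigma_np * n1 * p2
        + c.sigma_nn * n1 * n2
        + c.eta_sp * u1 * p2
        + c.eta_sn * u1 * n2
        + c.eta_ps * p1 * u2
        + c.eta_ns * n1 * u2
    )
    out = c.rate * total
    return float(out) if np.ndim(out) == 0 else out


def integrate(
    s1: Signal, s2: Signal, c: GDHLCoefficients, w0: float = 0.0
) -> WeightTrajectory:
    """Run the rule over a pair of signals and accumulate the weight.

    The two signals must share the same grid.  The weight is accumulated by
    explicit Euler (the Riemann-sum reading of the kernel integral):
    w[k] = w0 + sum(wdot[:k+1]) * dt.
    """
    if not s1.grid.matches(s2.grid):
        raise ValueError("pre- and post-synaptic signals must share the same grid")
    du1 = derivative(s1).values
    du2 = derivative(s2).values
    wdot = instantaneous_update(s1.values, du1, s2.values, du2, c)
    w = w0 + np.cumsum(wdot) * s1.dt
    return WeightTrajectory(grid=s1.grid, wdot=wdot, w=w, w0=w0)


_PRESETS: dict[str, dict[str, float]] = {
    # symmetric Hebb-like rule from the two same-sign differential components
    "hebb": {"pp": 1.0, "nn": 1.0},
    # Kosko: du1 * du2
    "kosko": {"pp": 1.0, "pn": -1.0, "np": -1.0, "nn": 1.0},
    # Porr-Wörgötter: u1 * du2 (lambda absorbed into the etas, default 1)
    "porr_worgotter": {"sp": 1.0, "sn": -1.0},
    "causal": {"sp": 1.0, "sn": -1.0},
    "anticausal": {"sn": 1.0, "ns": -1.0},
    "coincidence": {"pp": 1.0, "nn": 1.0, "pn": -1.0, "np": -1.0},
    "flat_at_zero": {"pn": -1.0, "np": 1.0},
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESETS)


def preset(name: str, rate: float = 1.0) -> GDHLCoefficients:
    """Named coefficient sets for the classic and example rules.

    hebb, kosko, porr_worgotter, causal, anticausal, coincidence,
    flat_at_zero.
    """
    try:
        weights = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {', '.join(_PRESETS)}"
        ) from None
    return GDHLCoefficients.from_components(weights, rate=rate)
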