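"""Reference simulations: pre-filtering and eligibility traces.

Two self-contained demonstrations used by the CLI and the test suite:

* the *filter demo* runs the Porr-Wörgötter rule on a pair of random
  cosine-mixture signals after pre-filtering each with the positive or
  negative part of its derivative, showing that the choice of event filter
  decides the learning outcome — with the same rule, filtering the
  post-synaptic signal for increases versus decreases drives the weight in
  opposite directions within a run;
* the *trace demo* shows that events separated by a time gap cannot change
  the synapse, while their leaky-accumulator traces can.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rule import GDHLCoefficients, WeightTrajectory, integrate, preset
from .signals import (
    EventSpec,
    Signal,
    TimeGrid,
    cosine_event,
    derivative,
    leaky_trace,
    negative_part,
    positive_part,
    random_cosine_mixture,
)

__all__ = ["FilterDemoResult", "filter_demo", "trace_demo", "TraceDemoResult"]


def _derivative_part_filter(s: Signal, which: str) -> Signal:
    du = derivative(s).values
    if which == "p":
        return s.with_values(positive_part(du))
    if which == "n":
        return s.with_values(negative_part(du))
    raise ValueError("filter must be 'p' (increases) or 'n' (decreases)")


@dataclass(frozen=True)
class FilterDemoResult:
    """Weight trajectories of the two differently filtered simulations."""

    up_up: WeightTrajectory    # both signals filtered for increases
    up_down: WeightTrajectory  # pre for increases, post for decreases
    seed: int


def filter_demo(
    seed: int = 0,
    duration: float = 20.0,
    dt: float = 0.005,
    n_components: int = 4,
    freq_range: tuple[float, float] = (0.1, 3.0),
    rule: GDHLCoefficients | None = None,
) -> FilterDemoResult:
    """Run the two pre-filtering simulations on one random signal pair.

    Both simulations start from the same two signals (averages of
    *n_components* cosines with random frequency and amplitude).  The first
    filters both signals for increase events ([du]+ / [du]+), the second
    filters the post-synaptic signal for decrease events ([du]+ / [du]-);
    both then apply the same causal (Porr-Wörgötter) rule.  Because an
    increase of the post-synaptic signal is systematically followed by a
    decrease, the two runs drift in opposite directions.
    """
    rule = rule if rule is not None else preset("porr_worgotter")
    grid = TimeGrid(0.0, dt, int(round(duration / dt)) + 1)
    rng = np.random.default_rng(seed)
    u1 = random_cosine_mixture(n_components, grid, freq_range=freq_range, seed=rng)
    u2 = random_cosine_mixture(n_components, grid, freq_range=freq_range, seed=rng)
    v1 = _derivative_part_filter(u1, "p")
    up_up = integrate(v1, _derivative_part_filter(u2, "p"), rule)
    up_down = integrate(v1, _derivative_part_filter(u2, "n"), rule)
    return FilterDemoResult(up_up=up_up, up_down=up_down, seed=seed)


@dataclass(frozen=True)
class TraceDemoResult:
    """Weight change for gapped events, raw versus leaky-trace-filtered."""

    without_traces: WeightTrajectory
    with_traces: WeightTrajectory
    gap: float
    tau: float


def trace_demo(
    gap: float = 1.0,
    tau: float = 1.0,
    dt: float = 0.001,
    half_width: float = 0.25,
    rule: GDHLCoefficients | None = None,
) -> TraceDemoResult:
    """Events separated by *gap* cannot interact unless traced.

    Two unit raised-cosine events with disjoint supports (edge-to-edge
    separation *gap*) are fed to the u1*[du2]+ rule component directly and
    after leaky-accumulator filtering with time constant *tau*.  Without
    traces the instantaneous product is identically zero; the traces outlast
    the first event and overlap the second.
    """
    if gap <= 0:
        raise ValueError("gap must be > 0 (disjoint events)")
    rule = rule if rule is not None else GDHLCoefficients(eta_sp=1.0)
    c1 = 2.0 * half_width
    c2 = c1 + half_width + gap + half_width
    grid = TimeGrid.from_span(0.0, c2 + half_width + 6.0 * tau, dt)
    u1 = cosine_event(EventSpec(c1, half_width, 1.0), grid)
    u2 = cosine_event(EventSpec(c2, half_width, 1.0), grid)
    raw = integrate(u1, u2, rule)
    traced = integrate(leaky_trace(u1, tau), leaky_trace(u2, tau), rule)
    return TraceDemoResult(
        without_traces=raw, with_traces=traced, gap=gap, tau=tau
    )
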