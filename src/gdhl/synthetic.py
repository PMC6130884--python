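"""Synthetic STDP datasets with known ground truth.

The generator draws inter-spike intervals over a window spanning both signs
of dt, evaluates the closed-form kernel of a known component combination,
and adds Gaussian noise scaled to the kernel's peak amplitude.  It is the
controlled counterpart of a pairing experiment: the fitting engine can be
scored against the exact generating truth.  Named fixtures mirror the four
qualitative kernel classes seen across real STDP datasets (causal,
anticausal, Mexican-hat and flat-at-zero), with coefficient magnitudes
borrowed from published fits purely as plausible generator values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .fitting import STDPDataset, predict_kernel
from .spike_pair import TraceParams

__all__ = ["SyntheticSpec", "generate", "fixture", "FIXTURE_NAMES", "write_truth_json"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic STDP dataset.

    weights: generating {component: coefficient} map; trace: alpha-trace
    parameters of the generating kernel; noise_sd is the Gaussian noise
    standard deviation as a fraction of the peak |dw| of the noiseless
    kernel over the sampled delays.
    """

    weights: dict[str, float]
    trace: TraceParams = TraceParams(1.0, 20.0, 20.0)
    n_points: int = 60
    delta_t_range: tuple[float, float] = (-100.0, 100.0)
    sampling: str = "dense_near_zero"
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 6:
            raise ValueError("n_points must be >= 6")
        lo, hi = self.delta_t_range
        if not (lo < 0 < hi):
            raise ValueError("delta_t_range must span both signs of delta_t")
        if self.sampling not in ("uniform", "dense_near_zero"):
            raise ValueError("sampling must be 'uniform' or 'dense_near_zero'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.weights:
            raise ValueError("weights must name at least one component")


def _sample_delta_ts(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.delta_t_range
    if spec.sampling == "uniform":
        dts = rng.uniform(lo, hi, size=spec.n_points)
    else:
        # half the points concentrated near zero, as real pairing designs do
        n_near = spec.n_points // 2
        near_lo, near_hi = max(lo, -20.0), min(hi, 20.0)
        dts = np.concatenate(
            [
                rng.uniform(near_lo, near_hi, size=n_near),
                rng.uniform(lo, hi, size=spec.n_points - n_near),
            ]
        )
    return np.sort(dts)


def generate(spec: SyntheticSpec) -> STDPDataset:
    """Draw a reproducible dataset from a known kernel plus Gaussian noise.

    The generating truth (weights, trace, noise level, seed) is stored in
    the dataset's ``meta`` and reproduces the noiseless kernel exactly.
    """
    rng = np.random.default_rng(spec.seed)
    dts = _sample_delta_ts(spec, rng)
    clean = predict_kernel(dts, spec.weights, spec.trace)
    peak = float(np.max(np.abs(clean)))
    if spec.noise_sd > 0 and peak == 0.0:
        raise ValueError("generating kernel is identically zero; relative noise undefined")
    noise = rng.normal(0.0, spec.noise_sd * peak, size=dts.size)
    meta = {
        "truth": {
            "weights": dict(spec.weights),
            "kappa": spec.trace.kappa,
            "tau1": spec.trace.tau1,
            "tau2": spec.trace.tau2,
        },
        "noise_sd": spec.noise_sd,
        "noise_scale": spec.noise_sd * peak,
        "seed": spec.seed,
        "sampling": spec.sampling,
        "delta_t_range": list(spec.delta_t_range),
    }
    return STDPDataset(dts, clean + noise, label="synthetic", meta=meta)


# Coefficient magnitudes for the four qualitative kernel classes; the tau
# values put the kernels on the tens-of-milliseconds scale of cortical STDP.
_FIXTURES: dict[str, SyntheticSpec] = {
    "causal_like": SyntheticSpec(
        weights={"sp": 0.66, "ns": -0.60}, trace=TraceParams(1.0, 20.0, 20.0), seed=11
    ),
    "anticausal_like": SyntheticSpec(
        weights={"sp": -0.65, "ns": 0.61}, trace=TraceParams(1.0, 20.0, 20.0), seed=12
    ),
    "mexican_hat_like": SyntheticSpec(
        weights={"np": -0.52, "pn": -0.48, "nn": 0.77},
        trace=TraceParams(1.0, 20.0, 20.0),
        seed=13,
    ),
    "flat_at_zero_like": SyntheticSpec(
        weights={"np": 0.78, "pn": -0.56}, trace=TraceParams(1.0, 20.0, 20.0), seed=14
    ),
}

FIXTURE_NAMES: tuple[str, ...] = tuple(_FIXTURES)


def fixture(name: str) -> STDPDataset:
    """A fixed-seed dataset shaped like one of the qualitative STDP classes.

    causal_like (LTD for dt<0, LTP for dt>0), anticausal_like (mirrored),
    mexican_hat_like (LTP centre, LTD lobes), flat_at_zero_like (no change
    near dt = 0).
    """
    try:
        spec = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {', '.join(_FIXTURES)}"
        ) from None
    d = generate(spec)
    return STDPDataset(d.delta_t, d.dw, label=name, meta=d.meta)


def write_truth_json(d: STDPDataset, path) -> None:
    """Write a dataset's generating truth metadata as a sibling JSON file."""
    with open(path, "w") as fh:
        json.dump(d.meta, fh, indent=2)
        fh.write("\n")
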