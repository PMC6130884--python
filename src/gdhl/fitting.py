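"""Fitting STDP datasets with sparse combinations of G-DHL components.

An STDP dataset is a cloud of (dt, dw) points: inter-spike interval in ms
(dt = t_post - t_pre) against measured synaptic change.  Every non-empty
subset of the eight rule components is treated as a separate model: its
predicted kernel is the coefficient-weighted sum of the closed-form
component kernels for trace time constants (tau1, tau2), and the model is
scored by the fraction of variance unexplained (FVU).  Model selection
compares the best fit of each subset with the Bayesian information
criterion (BIC), penalising parameter count, and returns the minimum-BIC
model.

Optimisation exploits the structure of the rule: for fixed (tau1, tau2) the
kernel is *linear* in the coefficients, so they are profiled out exactly by
least squares and a real-coded genetic algorithm only has to search the
two-dimensional (tau1, tau2) space, followed by a Nelder-Mead polish.  The
trace amplitude kappa is fixed at 1: every component scales as kappa**2, so
kappa is exactly degenerate with the coefficient scale and fixing it makes
the coefficients identifiable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .rule import COMPONENTS, GDHLCoefficients
from .spike_pair import TraceParams, _component_dw_core, analytic_component_dw

__all__ = [
    "STDPDataset",
    "GAConfig",
    "FitResult",
    "fvu",
    "exp_baseline",
    "bic",
    "fit_subset",
    "model_select",
]

DELTA_T_CONVENTION = "post_minus_pre"


@dataclass(frozen=True)
class STDPDataset:
    """Observed (dt, dw) points from a pairing experiment.

    delta_t: inter-spike intervals in ms, convention dt = t_post - t_pre
    (positive = pre leads post).  dw: synaptic change (percent or any
    consistent normalised unit; FVU is invariant to its affine scale).
    """

    delta_t: np.ndarray = field(repr=False)
    dw: np.ndarray = field(repr=False)
    label: str = ""
    convention: str = DELTA_T_CONVENTION
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        dts = np.asarray(self.delta_t, dtype=float)
        dws = np.asarray(self.dw, dtype=float)
        object.__setattr__(self, "delta_t", dts)
        object.__setattr__(self, "dw", dws)
        if dts.shape != dws.shape or dts.ndim != 1:
            raise ValueError("delta_t and dw must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(dts)) and np.all(np.isfinite(dws))):
            raise ValueError("dataset values must be finite")
        if self.convention != DELTA_T_CONVENTION:
            raise ValueError(
                f"delta_t convention must be {DELTA_T_CONVENTION!r} "
                "(positive = pre-synaptic spike first)"
            )

    @property
    def n(self) -> int:
        return int(self.delta_t.size)

    def to_csv(self, path, comments: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"# delta_t convention: {self.convention}\n")
            if self.label:
                fh.write(f"# label: {self.label}\n")
            for line in comments or []:
                fh.write(f"# {line}\n")
            fh.write("delta_t_ms,dw_percent\n")
            for d, w in zip(self.delta_t, self.dw):
                fh.write(f"{d:.12g},{w:.12g}\n")

    @classmethod
    def from_csv(cls, path, label: str = "") -> "STDPDataset":
        df = pd.read_csv(path, comment="#")
        missing = {"delta_t_ms", "dw_percent"} - set(df.columns)
        if missing:
            raise ValueError(
                f"STDP CSV must have columns delta_t_ms,dw_percent; missing {missing}"
            )
        return cls(
            df["delta_t_ms"].to_numpy(float),
            df["dw_percent"].to_numpy(float),
            label=label or str(path),
        )


@dataclass(frozen=True)
class GAConfig:
    """Real-coded genetic-algorithm settings for the (tau1, tau2) search.

    Coefficients are solved exactly per individual (linear least squares),
    so the genome is only the two trace time constants.  mutation_scale is
    the Gaussian mutation standard deviation as a fraction of the tau range.
    """

    population: int = 40
    generations: int = 60
    mutation_scale: float = 0.1
    crossover_rate: float = 0.7
    restarts: int = 3
    seed: int = 0
    tournament: int = 3
    elitism: int = 1
    sigma_bounds: tuple[float, float] = (-5.0, 5.0)
    eta_bounds: tuple[float, float] = (-5.0, 5.0)
    tau_bounds: tuple[float, float] = (1.0, 100.0)

    def __post_init__(self) -> None:
        if self.population < 10:
            raise ValueError("population must be >= 10")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.tau_bounds[0] <= 0 or self.tau_bounds[1] <= self.tau_bounds[0]:
            raise ValueError("tau bounds must be positive and increasing")

    @classmethod
    def reduced(cls, seed: int = 0) -> "GAConfig":
        """Small search budget for full 255-subset model selection runs."""
        return cls(population=16, generations=25, restarts=2, seed=seed)


@dataclass(frozen=True)
class FitResult:
    """Selected component subset with fitted parameters and scores."""

    subset: tuple[str, ...]
    coefficients: GDHLCoefficients
    trace: TraceParams
    fvu: float
    bic: float
    n_params: int
    bic_table: tuple[dict, ...] = ()
    seed: int = 0

    def predict(self, delta_t: np.ndarray) -> np.ndarray:
        return predict_kernel(
            delta_t,
            {k: self.coefficients.coefficient(k) for k in self.subset},
            self.trace,
        )

    def to_json(self, path) -> None:
        payload = {
            "subset": list(self.subset),
            "coefficients": self.coefficients.as_dict(),
            "tau1": self.trace.tau1,
            "tau2": self.trace.tau2,
            "kappa": self.trace.kappa,
            "fvu": self.fvu,
            "bic": self.bic,
            "n_params": self.n_params,
            "seed": self.seed,
            "delta_t_convention": DELTA_T_CONVENTION,
            "bic_table": list(self.bic_table),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            subset=tuple(d["subset"]),
            coefficients=GDHLCoefficients.from_dict(d["coefficients"]),
            trace=TraceParams(d["kappa"], d["tau1"], d["tau2"]),
            fvu=d["fvu"],
            bic=d["bic"],
            n_params=d["n_params"],
            bic_table=tuple(d["bic_table"]),
            seed=d["seed"],
        )


def fvu(observed, predicted) -> float:
    """Fraction of variance unexplained: sum((y-yhat)^2) / sum((y-ybar)^2)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values are all equal: FVU undefined")
    return float(np.sum((y - yhat) ** 2) / sst)


def exp_baseline(delta_t, tau: float, a_plus: float = 1.0, a_minus: float = 1.0):
    """Phenomenological exponential STDP window.

    a_plus * exp(-dt/tau) for dt > 0, -a_minus * exp(dt/tau) for dt <= 0.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    dt = np.asarray(delta_t, dtype=float)
    out = np.where(dt > 0, a_plus, -a_minus) * np.exp(-np.abs(dt) / tau)
    return float(out) if out.ndim == 0 else out


def bic(n: int, rss: float, k: int) -> float:
    """Gaussian-error BIC: n*ln(rss/n) + k*ln(n)."""
    if n <= k:
        raise ValueError("BIC needs more observations than parameters")
    if rss < 0:
        raise ValueError("rss must be nonnegative")
    rss = max(rss, 1e-300)  # numerically-perfect fits
    return float(n * np.log(rss / n) + k * np.log(n))


def predict_kernel(
    delta_t: np.ndarray, weights: dict[str, float], trace: TraceParams
) -> np.ndarray:
    """Weighted sum of closed-form component kernels at the data delays."""
    dt = np.asarray(delta_t, dtype=float)
    out = np.zeros_like(dt)
    for k, w in weights.items():
        if w != 0.0:
            out = out + w * analytic_component_dw(k, dt, trace)
    return out


def _design_matrix(
    delta_t: np.ndarray, subset: tuple[str, ...], tau1: float, tau2: float
) -> np.ndarray:
    p = TraceParams(1.0, tau1, tau2)
    return np.column_stack(
        [analytic_component_dw(k, delta_t, p) for k in subset]
    )


def _profiled_rss(
    delta_t: np.ndarray,
    dw: np.ndarray,
    subset: tuple[str, ...],
    tau1: float,
    tau2: float,
    coef_bounds: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Best coefficients (exact least squares, clipped to bounds) and RSS."""
    X = _design_matrix(delta_t, subset, tau1, tau2)
    coef, *_ = np.linalg.lstsq(X, dw, rcond=None)
    clipped = np.clip(coef, coef_bounds[:, 0], coef_bounds[:, 1])
    resid = dw - X @ clipped
    return float(resid @ resid), clipped


def _coef_bounds(subset: tuple[str, ...], g: GAConfig) -> np.ndarray:
    return np.array(
        [g.sigma_bounds if k[0] in "pn" and k[1] in "pn" else g.eta_bounds
         for k in subset]
    )


def _batch_rss(
    delta_t: np.ndarray,
    dw: np.ndarray,
    subset: tuple[str, ...],
    taus: np.ndarray,
    coef_bounds: np.ndarray,
) -> np.ndarray:
    """Profiled RSS for a whole population of (tau1, tau2) genomes at once."""
    t1 = taus[:, 0:1]
    t2 = taus[:, 1:2]
    X = np.stack(
        [_component_dw_core(k, delta_t[None, :], t1, t2, 1.0) for k in subset],
        axis=-1,
    )  # (m, n, k)
    coef = np.einsum("mkn,n->mk", np.linalg.pinv(X), dw)
    coef = np.clip(coef, coef_bounds[:, 0], coef_bounds[:, 1])
    resid = dw[None, :] - np.einsum("mnk,mk->mn", X, coef)
    return np.einsum("mn,mn->m", resid, resid)


def _run_ga(
    d: STDPDataset,
    subset: tuple[str, ...],
    g: GAConfig,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """One GA run over (tau1, tau2); returns (best rss, best genome)."""
    lo, hi = g.tau_bounds
    span = hi - lo
    bounds = _coef_bounds(subset, g)
    pop = rng.uniform(lo, hi, size=(g.population, 2))
    fit = _batch_rss(d.delta_t, d.dw, subset, pop, bounds)
    best_i = int(np.argmin(fit))
    best_rss, best = fit[best_i], pop[best_i].copy()
    for _ in range(g.generations):
        order = np.argsort(fit)
        elite = pop[order[: g.elitism]]
        # tournament selection
        idx = rng.integers(0, g.population, size=(g.population, g.tournament))
        winners = idx[np.arange(g.population), np.argmin(fit[idx], axis=1)]
        parents = pop[winners]
        # arithmetic (blend) crossover between consecutive parents
        partners = parents[rng.permutation(g.population)]
        mix = rng.uniform(0.0, 1.0, size=(g.population, 1))
        cross = rng.uniform(size=g.population) < g.crossover_rate
        children = np.where(
            cross[:, None], mix * parents + (1 - mix) * partners, parents
        )
        # Gaussian mutation
        children = children + rng.normal(
            0.0, g.mutation_scale * span, size=children.shape
        )
        children = np.clip(children, lo, hi)
        children[: g.elitism] = elite
        pop = children
        fit = _batch_rss(d.delta_t, d.dw, subset, pop, bounds)
        i = int(np.argmin(fit))
        if fit[i] < best_rss:
            best_rss, best = fit[i], pop[i].copy()
    return best_rss, best


def fit_subset(
    d: STDPDataset, subset, g: GAConfig
) -> tuple[GDHLCoefficients, TraceParams, float]:
    """Best fit of one component subset: coefficients, trace params, FVU.

    The GA (with restarts) searches (tau1, tau2); coefficients are profiled
    out by least squares at every evaluation and the best genome gets a
    final Nelder-Mead polish.  Deterministic given ``g.seed`` and the
    subset.
    """
    subset = tuple(sorted(set(subset), key=COMPONENTS.index))
    if len(subset) < 1:
        raise ValueError("subset must contain at least one component")
    k_params = len(subset) + 2
    if d.n <= k_params:
        raise ValueError(
            f"dataset has {d.n} points but the model needs > {k_params}"
        )
    mask = sum(1 << COMPONENTS.index(k) for k in subset)
    bounds = _coef_bounds(subset, g)
    best_rss, best = np.inf, None
    for restart in range(max(1, g.restarts)):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=g.seed, spawn_key=(mask, restart))
        )
        rss, genome = _run_ga(d, subset, g, rng)
        if rss < best_rss:
            best_rss, best = rss, genome
    lo, hi = g.tau_bounds

    def objective(x):
        t1, t2 = np.clip(x, lo, hi)
        return _profiled_rss(d.delta_t, d.dw, subset, t1, t2, bounds)[0]

    res = minimize(
        objective, best, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 200},
    )
    if res.fun < best_rss:
        best = np.clip(res.x, lo, hi)
    tau1, tau2 = float(best[0]), float(best[1])
    rss, coef = _profiled_rss(d.delta_t, d.dw, subset, tau1, tau2, bounds)
    coefficients = GDHLCoefficients.from_components(dict(zip(subset, coef)))
    trace = TraceParams(1.0, tau1, tau2)
    sst = float(np.sum((d.dw - d.dw.mean()) ** 2))
    return coefficients, trace, rss / sst


def model_select(
    d: STDPDataset, g: GAConfig, max_components: int = 8
) -> FitResult:
    """Exhaustive subset enumeration with BIC model comparison.

    Fits every non-empty subset of up to *max_components* components
    (255 models at the default), scores each with BIC at
    k = len(subset) + 2 (the two tau parameters), and returns the
    minimum-BIC model; ties break towards fewer components, then
    lexicographic order in the canonical component sequence.
    """
    n = d.n
    sst = float(np.sum((d.dw - d.dw.mean()) ** 2))
    if sst == 0:
        raise ValueError("dataset has zero variance; nothing to fit")
    # Gaussian BIC diverges as rss -> 0; numerically-perfect fits are floored
    # at a precision scale so they tie and the fewer-components rule decides.
    rss_floor = n * (1e-8 * float(np.max(np.abs(d.dw)))) ** 2
    table: list[dict] = []
    best_key = None
    best_entry = None
    for size in range(1, max_components + 1):
        for subset in itertools.combinations(COMPONENTS, size):
            k_params = size + 2
            if n <= k_params:
                continue
            coefficients, trace, f = fit_subset(d, subset, g)
            score = bic(n, max(f * sst, rss_floor), k_params)
            entry = {
                "subset": list(subset),
                "fvu": f,
                "bic": score,
                "n_params": k_params,
            }
            table.append(entry)
            key = (score, size, tuple(COMPONENTS.index(c) for c in subset))
            if best_key is None or key < best_key:
                best_key = key
                best_entry = (subset, coefficients, trace, f, score, k_params)
    if best_entry is None:
        raise ValueError("dataset too small for any candidate model")
    subset, coefficients, trace, f, score, k_params = best_entry
    return FitResult(
        subset=subset,
        coefficients=coefficients,
        trace=trace,
        fvu=f,
        bic=score,
        n_params=k_params,
        bic_table=tuple(table),
        seed=g.seed,
    )
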