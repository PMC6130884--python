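# gdhl — general differential Hebbian learning

Tools for studying synaptic plasticity rules that use *signal derivatives*
to capture the timing of neural events, and for fitting spike-timing-
dependent plasticity (STDP) data with sparse combinations of such rules.

Classic Hebbian learning strengthens a synapse when pre- and post-synaptic
activity *co-occur*; it is blind to which neuron fired first. Differential
Hebbian learning (DHL) rules instead multiply *derivatives* of the
activations, so the rising and falling phases of neural events interact and
the sign and size of the weight change depend on the inter-event delay.
The general rule implemented here spans the whole family. Writing
$[x]^+ = \max(x, 0)$ and $[x]^- = \max(-x, 0)$ for the positive/negative
parts, and $u_1, u_2$ for the pre-/post-synaptic signals:

$$
\dot w \;=\; \sigma_{pp}[\dot u_1]^+[\dot u_2]^+ + \sigma_{pn}[\dot u_1]^+[\dot u_2]^-
           + \sigma_{np}[\dot u_1]^-[\dot u_2]^+ + \sigma_{nn}[\dot u_1]^-[\dot u_2]^-
$$
$$
\qquad\;\; + \eta_{sp}\,u_1[\dot u_2]^+ + \eta_{sn}\,u_1[\dot u_2]^-
           + \eta_{ps}[\dot u_1]^+u_2 + \eta_{ns}[\dot u_1]^-u_2 .
$$

Eight components, indexed by two letters (pre factor, post factor) from
{`s` signal, `p` positive derivative part, `n` negative derivative part}.
Setting $\sigma = (1,-1,-1,1)$ recovers Kosko's rule
$\dot w = \dot u_1\dot u_2$; setting $\eta_{sp} = -\eta_{sn} = \lambda$
recovers the Porr–Wörgötter rule $\dot w = \lambda\, u_1\dot u_2$.

The package provides:

* **signals** — sampled signals, raised-cosine events, random cosine
  mixtures, derivative/part operators, leaky-accumulator eligibility traces,
  `time,value` CSV I/O;
* **rule** — the coefficients, instantaneous update, step-by-step weight
  trajectories, and named presets (`hebb`, `kosko`, `porr_worgotter`,
  `causal`, `anticausal`, `coincidence`, `flat_at_zero`);
* **kernels** — numerical learning kernels $\Delta w(\Delta t)$ for
  arbitrary event waveforms (convention: $\Delta t = t_{post} - t_{pre}$);
* **spike_pair** — exact closed-form kernels for a pre/post spike pair
  whose Dirac-δ spikes leave α-function eligibility traces
  $\varepsilon(t) = \kappa\,(t/\tau)\,e^{1-t/\tau}$;
* **fitting** — STDP dataset fitting: FVU objective, per-subset genetic
  algorithm with exactly profiled (least-squares) coefficients, exhaustive
  enumeration of all 255 component subsets, BIC model selection, and the
  phenomenological exponential window as a baseline;
* **synthetic** — STDP point clouds with known ground truth plus fixtures
  for the four qualitative kernel classes (causal, anticausal, Mexican-hat,
  flat-at-zero);
* a `gdhl` command-line interface (`kernel`, `simulate`, `fit`, `generate`,
  `presets`).

## Worked example

Closed-form STDP kernel of a causal-class rule
($\eta_{sp} = 0.66$, $\eta_{ns} = -0.60$, $\tau_1 = \tau_2 = 20$ ms):

```python
import numpy as np
from gdhl import GDHLCoefficients, TraceParams, analytic_kernel, kernel_peak

rule = GDHLCoefficients(eta_sp=0.66, eta_ns=-0.60)   # causal-class STDP fit
trace = TraceParams(kappa=1.0, tau1=20.0, tau2=20.0)
curve = analytic_kernel(rule, trace, np.arange(-80, 81, 20))
for dt, dw in zip(curve.delta_ts, curve.dws):
    print(f"dt = {dt:+6.1f} ms   dw = {dw:+.4f}")
peak = kernel_peak("pp", trace)
print(f"pp component peaks at dt = {peak.delta_t:.3f} ms, dw_max = {peak.dw:.4f}")
```

```
dt =  -80.0 ms   dw = -0.0165
dt =  -60.0 ms   dw = -0.0373
dt =  -40.0 ms   dw = -0.0812
dt =  -20.0 ms   dw = -0.1655
dt =   +0.0 ms   dw = +0.0300
dt =  +20.0 ms   dw = +0.2229
dt =  +40.0 ms   dw = +0.1193
dt =  +60.0 ms   dw = +0.0576
dt =  +80.0 ms   dw = +0.0263
pp component peaks at dt = 0.000 ms, dw_max = 0.0799
```

Depression for post-before-pre delays, potentiation peaking near
$\Delta t \approx +20$ ms: the classic causal STDP window. The
positive-derivative × positive-derivative (`pp`) component by itself is a
sharp coincidence detector that always peaks at $\Delta t = 0$.

Fitting a synthetic dataset from the shell:

```sh
gdhl generate --weights '{"sp": 0.66, "ns": -0.60}' --seed 1 --out data.csv
gdhl fit data.csv --reduced --seed 1 --out fit.json --bic-table bic.csv
```

`fit.json` records the selected component subset, its coefficients, the
trace time constants, FVU and BIC, and the full 255-row BIC table.

## Further reading

`docs/methods.md` documents the model conventions, the closed-form
derivation, the fitting procedure, its parameters and known limitations
(including the mirror-image identifiability degeneracy of component subsets
at equal trace time constants).
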