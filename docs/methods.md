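# Methods

## Model and conventions

The rule operates on nonnegative sampled signals $u_1(t)$ (pre-synaptic)
and $u_2(t)$ (post-synaptic) on a shared uniform grid. An *event* is a
portion of a signal that rises monotonically and then falls; the positive
part of the derivative marks the rising phase, the negative part (taken as
a magnitude) the falling phase. The instantaneous weight change is the
linear combination of the eight products of
$\{u_i, [\dot u_i]^+, [\dot u_i]^-\}$ across the two neurons, excluding the
signal×signal term (plain Hebbian correlation is already generated by the
`pp` + `nn` pair). A single global `rate` multiplier (the $1/\tau$ of the
classic rules, default 1) is applied after the sum, so the rule stays
linear in its coefficient vector.

Negative signals are never clipped silently: `instantaneous_update` rejects
them and the caller shifts them explicitly (`shift_nonnegative`), which
leaves every derivative-based component untouched.

Delay convention, used everywhere and stamped into every output file:
$\Delta t = t_{post} - t_{pre}$, positive when the pre-synaptic event
leads. Learning-kernel curves $\Delta w(\Delta t)$ are computed by placing
one event per signal separated by $\Delta t$ and accumulating the rule by
explicit Euler ($w_{k+1} = w_k + \dot w_k \, \Delta$), the Riemann-sum
reading of the kernel integral; no stiffness is present, so no
higher-order integrator is warranted.

Numerical defaults: sampling step 0.001 time units for dimensionless event
demos (0.002 in the bulk kernel sweeps, where the discretisation error is
well below the asserted tolerances), delay grid $[-1, 1]$ in steps of 0.01
for cosine-event kernels. Events are raised-cosine bumps
$u(t) = \tfrac{A}{2}(1 + \cos(\pi (t-c)/h))$ on $|t-c| \le h$: value *and*
slope vanish at the edges, so the event is smooth and its derivative parts
are well defined; a skewed variant with different rise/fall half-widths is
provided to break left/right symmetry. The kernel integration window is
the union of the two event supports padded by one full event width, which
truncates the formally infinite integral only where the integrand is
exactly zero.

## Closed-form spike-pair kernels

For STDP work, spikes are idealised Dirac deltas and each spike leaves an
eligibility trace shaped as an α-function
$\varepsilon(t) = \kappa (t/\tau) e^{1 - t/\tau}$ ($t \ge 0$), normalised
to peak at value $\kappa$ at $t = \tau$. Any constant-factor difference
from other α-function normalisations is absorbed by the fitted
coefficients. The trace of a spike at $t_0$ is simply
$\varepsilon(t - t_0)$ (convolution with the delta), so no numerical delta
is ever represented.

Each component integral is evaluated exactly. Every factor — the trace,
or the positive/negative part of its derivative — is a *linear polynomial
times a decaying exponential* supported on one interval:
$[\dot\varepsilon]^+$ lives on $[t_0, t_0 + \tau]$ and
$[\dot\varepsilon]^-$ on $[t_0 + \tau, \infty)$, with the sign change of
$\dot\varepsilon$ at the trace peak providing the breakpoints. The product
of two factors is a quadratic polynomial times $e^{-\alpha t}$ with
$\alpha = 1/\tau_1 + 1/\tau_2$ on the *intersection* of the supports, and
the antiderivative is elementary. Because the rates add rather than
subtract, the formulas are well conditioned for every
$(\tau_1, \tau_2)$ — including $\tau_1 = \tau_2$, which needs no special
branch. Two numerical safeguards: the integration length is clamped at
zero (an empty overlap then integrates to exactly 0, which is what makes
the `np` kernel identically zero for $\Delta t \le 0$ at equal $\tau$, and
`pn` for $\Delta t \ge 0$), and the polynomial is re-centred at the lower
limit so the combined exponent never exceeds $e^2$.

The closed forms are guarded by a test suite comparing them against
adaptive quadrature of the raw integrand (8 components × 3 $\tau$ regimes
× 41 delays, relative tolerance 1e-8; observed agreement ~1e-13).
Component kernel maxima (`kernel_peak`) are located by a symmetric grid
scan over $\pm 8\max(\tau_1,\tau_2)$ — safely past any kernel support —
refined by bounded scalar minimisation; the grid value is kept when the
refinement cannot improve it (peaks can sit on kinks).

## Fitting STDP datasets

A dataset is a cloud of $(\Delta t, \Delta w)$ points (ms, percent or any
consistent unit — the objective is scale-invariant). Each non-empty subset
of the eight components is one candidate model; its prediction is the
coefficient-weighted sum of closed-form component kernels with trace
constants $(\tau_1, \tau_2)$ and $\kappa \equiv 1$. Fit quality is the
fraction of variance unexplained,
$\mathrm{FVU} = \sum (y - \hat y)^2 / \sum (y - \bar y)^2$.

$\kappa$ is fixed at 1 because every component carries both traces and
hence scales as $\kappa^2$: $\kappa$ is exactly degenerate with the
coefficient scale, and fixing it makes the coefficients identifiable.

Optimisation exploits the rule's linearity: for fixed $(\tau_1, \tau_2)$
the optimal coefficients are an exact linear least-squares solve (clipped
to the coefficient bounds), so the genetic algorithm only searches the
two-dimensional $(\tau_1, \tau_2)$ box. The GA is real-coded with
tournament selection (size 3), arithmetic crossover (rate 0.7), Gaussian
mutation (σ = 0.1 × range), one elite, and independent restarts; the best
genome receives a final Nelder–Mead polish. Defaults: population 40,
60 generations, 3 restarts; `GAConfig.reduced()` (population 16,
25 generations, 2 restarts) is sized for full 255-subset scans and is
ample for the smooth 2-D profiled landscape. Bounds: $\sigma, \eta \in
[-5, 5]$, $\tau_{1,2} \in [1, 100]$ ms. Every GA draw derives
deterministically from the run seed and the subset, so fits are exactly
reproducible.

Model comparison uses the Gaussian-error BIC,
$n \ln(\mathrm{RSS}/n) + k \ln n$ with $k = |\text{subset}| + 2$ (the two
$\tau$'s). Ties break towards fewer components, then lexicographic
component order. Because $\ln \mathrm{RSS}$ diverges as perfect fits
approach machine precision — where the Gaussian likelihood model is
meaningless — the RSS is floored at $n (10^{-8} \max|\Delta w|)^2$;
numerically-perfect fits then tie and the parsimony tie-break selects the
smallest generating subset.

The exponential window $\Delta w = a_+ e^{-\Delta t/\tau}$
($\Delta t > 0$), $-a_- e^{\Delta t/\tau}$ ($\Delta t \le 0$) is provided
as the standard phenomenological baseline.

## Synthetic data

The generator draws delays either uniformly over the configured range
(default $[-100, 100]$ ms) or with half the points concentrated in
$[-20, 20]$ ms (`dense_near_zero`, mimicking real pairing designs),
evaluates the closed-form kernel of a known component combination, and
adds Gaussian noise with standard deviation expressed as a fraction
(default 5%) of the peak $|\Delta w|$. Defaults — 60 points, $\tau_1 =
\tau_2 = 20$ ms, coefficient magnitudes around 0.5–0.8 — match the sample
sizes, time scales and effect sizes typical of published pairing
experiments. The generating truth is stored in the dataset metadata and
reproduces the noiseless kernel bit-identically.

What the generator does *not* emulate: pairing-frequency effects, outliers,
heteroscedastic measurement error, or delay jitter. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
assumed noise model, not robustness to every artefact of real recordings.

## Pre-filtering and traces

Two reference simulations document the signal-processing layer. The
*filter demo* draws a pair of signals (averages of four cosines with random
frequency in $[0.1, 3]$ rad per time unit and random amplitude, each
rescaled to $(0,1)$; all components share phase zero), filters the pre
signal for increases ($[\dot u_1]^+$) and the post signal for increases or
for decreases, and applies the causal rule to both filtered pairs.
Within a run the two drifts go in opposite directions in the large
majority of seeds (sign correlation ≈ −0.86 over 50 runs at the default
duration of 20 time units): a rise of the post-synaptic signal
systematically *precedes* its own fall, so whichever temporal order holds
between the pre events and the post rises, the opposite order holds with
the post falls. Which of the two runs is the positive one depends on the
particular signal pair; it is the *opposition* that is systematic.

The *trace demo* feeds two events with disjoint supports to the
$u_1 [\dot u_2]^+$ component: the raw signals give exactly zero total
change (the product is identically zero), while leaky-accumulator traces
($m_t = m_{t-1} + (\Delta/\tau)(-m_{t-1} + u_{t-1})$, $\tau = 1$,
$\Delta = 0.001$) outlast the first event, overlap the second, and produce
a change more than half the size of the coincident-event reference.

## Known limitations

* **Mirror degeneracy of subset selection.** At $\tau_1 = \tau_2$ the
  component kernels mirror under pre/post exchange:
  $K_{ps}(\Delta t) = K_{sp}(-\Delta t)$ and
  $K_{sn}(\Delta t) = K_{ns}(-\Delta t)$. For a nearly odd target kernel —
  e.g. the causal class generated by $\{sp, ns\}$ — the mirrored subset
  $\{sn, ps\}$ reproduces the data almost exactly (noiseless FVU ~1e-4,
  well below a 5%-noise floor of ~5e-3), so exact-subset identification
  from 60 noisy points succeeds in only roughly 60–80% of datasets, with
  the misses selecting the mirror subset or a small superset. The selected
  kernel *shape* and the recovered coefficients on hits (within a few
  percent at 5% noise) are robust; the component labels are not, and
  distinguishing mirror pairs requires asymmetric trace constants or more
  data.
* Spike-pair analytics cover pairs only; triplet/quadruplet interactions
  would need three-factor components.
* The numerical kernel assumes complete, isolated events inside the
  integration window; overlapping event trains are integrated faithfully
  but are not summarised by a single $\Delta w(\Delta t)$ curve.
* BIC model counts assume independent Gaussian residuals; strongly
  correlated measurement error would mis-calibrate the parsimony penalty.
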