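# Methods

`snnloop` trains spiking neural networks (SNNs) *through* a simulated analog
neuromorphic substrate: the forward pass runs on the emulated device, the
backward pass runs in software on recorded observables, and updated weights
are written back. This note documents the model, the emulation, the
synthetic tasks, and the numerical and design choices, in enough detail to
re-derive every computation the package performs.

## 1. Neuron model and training graph

Hidden units are leaky integrate-and-fire (LIF) neurons with exponential
current synapses, in the dimensionless convention `V_leak = 0`, `C = 1`,
threshold `theta = 1`:

    dV/dt = -V / tau_m + I / dt_unit,      dI/dt = -I / tau_s  (+ spike input)

Current units are chosen so that a unit model current integrates one
threshold unit per sampling interval `dt` on a non-leaky membrane; weights
are therefore directly comparable between the graph and the substrate.

The training graph discretises these dynamics on the sampling grid (step
`dt`):

    I[t+1] = I[t] * exp(-dt/tau_s) + W_in x[t] + W_rec S[t]
    V[t+1] = (1 - S[t]) * (V[t] * exp(-dt/tau_m) + I[t])
    S[t+1] = Heaviside(V[t+1] - theta)

Defaults: `tau_m = 20 dt`, `tau_s = 10 dt` (configurable; the temporal-task
experiments use `6 dt / 3 dt`, section 6). The output layer follows the same
recursion without threshold or reset; classification reads its membrane
traces. Conventions:

* **Reset** is a multiplicative gate on the previous step's spike,
  reset-to-0 one step after the crossing. The gate is *detached* from
  gradient flow by default (`detach_reset=False` reinstates the
  `-(V[t]*lam_m + I[t])` term in the spike adjoint).
* **Recurrence** uses spikes from the previous grid step (one-bin delay).
* Input spikes are assigned to grid bins by `floor(t/dt)`.
* The `max`-over-time readout routes its subgradient to the argmax step
  only, ties broken toward the earliest step. A consequence worth knowing:
  a *fully quiescent* network under the max-over-time loss has its
  subgradient at `t = 0` where no weight can receive it; training from a
  quiescent hidden layer works with the sum-over-time loss (or any nonzero
  output activity).

## 2. In-the-loop differentiation

Measured quantities replace model estimates in the forward direction through
the identity `f(x, x_tilde) = x` with derivatives `df/dx = 0`,
`df/dx_tilde = 1`: injected are the sampled hidden and output membranes and
the binned spikes; synaptic currents are never measured and remain model
estimates. The spike nonlinearity's derivative is replaced by the
SuperSpike-family pseudo-derivative

    dS/dV := (1 + beta * |V - theta|)^-2        (default, beta = 10)

evaluated at the *sampled* membrane values. The literal inverse-square form
`(beta * |V - theta|)^-2` is selectable (`surrogate_form="literal"`); it
diverges at threshold, so it is floored at `|V - theta| >= 1e-6` and meant
to be combined with gradient clipping. Forward values never depend on
`beta`.

Because the unrolled graph is a fixed two-layer recurrent structure, BPTT is
implemented directly as the adjoint recursions of the forward equations
(hand-derived, numba-compiled), not through an autodiff framework. Two
oracles pin its correctness: (i) on an ideal substrate, ITL gradients equal
pure-simulation gradients to machine precision; (ii) on the spike-free
readout pathway, gradients match central finite differences to <1e-4
relative error.

## 3. The simulated substrate

`AnalogSubstrate` emulates `n_hidden` spiking and `n_out` non-spiking LIF
circuits with:

* **Integration.** Default `integration="exact"`: the exact exponential
  propagator of the 2-state ODE at fine step `delta = dt/substeps`
  (default 10). Spike detection and reset happen at fine resolution; input
  and recurrent events are routed at grid-bin boundaries. Subthreshold and
  between events, the trajectory is exact at all fine points regardless of
  `delta`. The alternative `integration="grid"` integrates the *training
  graph's* discrete recursion at step `dt`; with mismatch, noise and
  quantization off this reproduces the graph bit for bit and is the
  reference configuration for validating trace injection
  (`AnalogSubstrate.ideal`). A single integrator cannot both match the
  continuous closed forms and the discrete graph — the discrete recursion is
  itself an O(dt) approximation of the ODE — hence the two modes; in the
  default mode the substrate deviates from the graph's model by a few
  percent, which is precisely the regime ITL training is designed for.
* **Fixed-pattern mismatch** (`MismatchSpec`): per-neuron time constants
  and/or thresholds drawn once per substrate instance from
  `Normal(target, sigma_d * target)`; time constants are redrawn until
  positive (an error is raised after 1000 failed redraws). Thresholds may
  fall below the leak — such "leak-over-threshold" neurons fire without
  input and are reported by `leak_over_threshold()`, not repaired. The
  output layer's time constants are decalibrated as well (it shares the
  analog circuitry).
* **Trial noise** (`NoiseSpec`): `membrane_noise_sd` is the *stationary* SD
  of the membrane's noise component (default 0.01, i.e. 1% of threshold),
  realised as per-bin Gaussian injections with variance
  `sd^2 * (1 - exp(-2 dt/tau_m))` so the accumulated process has the stated
  SD regardless of the integration step; `sample_jitter_sd` (default 0.01)
  is white measurement noise on the sampled traces. Fixed-pattern mismatch
  is frozen per instance; noise is redrawn per trial.
* **Quantized weights.** Deployed weights are
  `clip(round(w * scale), -63, +63)` (7-bit signed). Hidden-side matrices
  use a fixed scale (default 100, i.e. range ±0.63, step 0.01); the output
  layer — whose traces may be scaled arbitrarily — uses the dynamic rule
  `scale = 63 / max|w_out|` (fallback 1 for an all-zero matrix).
* **Readout.** Membranes are sampled at bin starts; spikes are timestamped
  at fine resolution and binned (binary per bin) onto the grid. A constant
  per-neuron current `i_bias` is available for characterisation (f-I
  curves); it uses the exact constant-input propagator.
* Refractory period: none by default; configurable in fine steps.

Closed-form checks in the default mode: the single-spike PSP peak matches
`(w/dt) * tau_m tau_s/(tau_m - tau_s) * (r^(tau_s/(tau_m-tau_s)) -
r^(tau_m/(tau_m-tau_s)))`, `r = tau_s/tau_m`, to ~1e-8 relative at
`substeps=100`, and the constant-drive inter-spike interval matches
`tau_m ln(J tau_m / (J tau_m - theta))` to within one fine step after
subtracting the one-step reset hold.

## 4. Training loop

Each batch: (1) quantize the float master weights and deploy; (2) emulate
the forward pass, recording traces and spikes; (3) unroll the graph with the
*idealized* (calibration-target) parameters, injecting the recordings —
the graph never learns about mismatch; (4) evaluate the loss; (5) BPTT;
(6) Adam step on the float master copy. Losses: max- or sum-over-time
softmax NLL on the output traces; optional amplitude penalty
`rho_a * mean_i (max_t V_i)^2`; spike-count sparsity penalty
`rho_b/N_H * sum_i (sum_t S_i)^2` (can only reduce activity); homeostatic
penalty `rho_r * max(0, sum_{i,t} S_i - theta_r)^2`. Batch-averaged.

Initialization is Kaiming-style: entries `Normal(0, sigma_w / sqrt(fan_in))`
per layer (`sigma_w = 1` default). Library defaults: Adam `lr = 1e-3`,
optional per-epoch exponential decay, batch 32, 100 epochs. The experiment
configs shipped under `configs/` use `lr = 3e-3` and smaller batches (16 for
the self-calibration sweep, 32 for the sparsity sweep) with fewer epochs
(section 6): at larger batches a noticeable fraction of 30-epoch runs on
decalibrated substrates stalls in "class-capture" minima of the
max-over-time loss (a handful of class pairs stay confused while the rest of
the task is solved); more optimizer updates per epoch largely avoid this.

**Dropout** is per-training-batch: a Bernoulli(1 − rate) mask over hidden
units, realised by silencing the dropped units on the deployed weights (they
receive no input, hence never spike) and masking their spikes in the graph;
surviving units' outgoing weights are rescaled by 1/keep (inverted dropout
adapted to binary spikes) so evaluation-time drive statistics match
training. Dropout is per batch rather than per sample because it models a
per-deployment reconfiguration of the substrate; it consequently needs long
training runs to average over masks. Disabled at evaluation.

**Ablation** (`ablate_hidden`) silences `floor(fraction * N_H)` randomly
chosen hidden units (inputs, recurrent connections and outputs zeroed),
modelling post-deployment circuit failure. **Weight transfer** deploys a
software-trained network's quantized weights on a substrate and evaluates
without fine-tuning. The **frozen-recurrent control** permutes a trained
network's recurrent matrix (preserving the weight multiset), freezes it, and
retrains input and readout weights only.

## 5. Synthetic tasks

Both generators are pure functions of `(spec, seed)`.

* **Latency images**: per class a smooth random blob prototype (Gaussian
  field, sigma = min(h,w)/8, min-max normalised; prototypes redrawn until
  pairwise L2 distance >= 1) plus i.i.d. pixel noise (SD 0.12), clipped to
  [0, 1]; optional rotation augmentation. Defaults: 10 classes x 100
  samples; the experiment configs use 70 pixels (7x10), matching the
  self-calibration network's 70 inputs. Pixels are encoded by the latency
  code `t_i = tau_in ln(x_i / (x_i - theta_in))` for `x_i > theta_in`
  (defaults `tau_in = 20`, `theta_in = 0.2`, cutoff 60), one spike per
  sufficiently bright pixel, brighter = earlier. A linear classifier reaches
  >95% on raw pixels (tested), so failures of the SNN pipeline are not
  attributable to inseparable data.
* **Temporal patterns**: each class is a set of anchor events (default 24)
  on 70 channels inside the central 80% of a 100-step window; classes come
  in *time-reversed pairs* sharing channels and per-channel counts, so
  rate-only readouts cannot separate them and temporal order must be
  resolved. Samples add timing jitter (SD 2 steps), channel jitter (SD 0.5),
  deletions (p = 0.1) and uniform background events (Poisson, mean 4).
  Defaults: 6 classes x 60 samples.
* `train_test_split` partitions at random; the `disjoint_variant` adds extra
  noise (pixel SD 0.1 / timing SD 3 by default) to the held-out samples,
  emulating evaluation on a shifted regime such as held-out speakers.

What the generators do *not* emulate: the visual statistics of handwritten
digits, real speech spectro-temporal structure, class imbalance, and
session-level nonstationarity. Passing experiments therefore demonstrate
properties of the training method under controlled statistical structure,
not benchmark-level performance on natural data.

## 6. Experiments and problem sizes

All experiment runners derive per-cell seeds by hashing (config seed, cell
coordinates, replicate), write CSV + the resolved config, and are resumable
cell by cell. Sizes were chosen so the full set runs in well under an hour
on one CPU core:

| experiment | conditions | size |
|---|---|---|
| self-calibration | ITL vs. weight transfer, sigma_d in {0, 0.3, 0.5}, substrate backend | 70-64-10 net, 30 epochs, 3 seeds |
| sparsity | rho_b in {0, 1e-3, 1e-2, 1e-1}, substrate backend | 70-64-10, 20 epochs, 3 seeds |
| robustness | dropout {0, 0.4} x ablation {0, 0.05, 0.15, 0.3} (3 draws each) | software backend, 80 epochs, 3 seeds |
| recurrence | trained vs. shuffled-frozen recurrent | software backend, tau = 6/3 dt, 80 epochs, 3 seeds |

Backend choices: self-calibration and sparsity are substrate properties and
run in the loop. The robustness and recurrence contrasts are properties of
the trained connectivity; they run on the software backend because per-batch
dropout and recurrent credit assignment need ~80 epochs to converge, and
because through the noisy substrate at this desk scale both recurrence
conditions saturate near the accuracy ceiling, leaving the contrast without
statistical power. The recurrence experiment also shortens the time
constants to `6 dt / 3 dt`: with the default `20 dt` the feed-forward PSPs
alone span most of the pattern window and recurrence is unnecessary to solve
the task, which would make the control comparison vacuous.

Robustness reports *absolute* test-error inflation (error at ablation
fraction f minus baseline error): the no-dropout networks reach zero
baseline test error on this task, making relative inflation ill-defined.
The sparsity "accuracy plateau" is defined as the set of sweep cells whose
median accuracy is within 2 percentage points of the best cell; its extent
is measured as the ratio of the largest to the smallest median spike count
within the plateau.

## 7. Numerical choices and limitations

* Decay factors `exp(-dt/tau)` are required to lie strictly in (0, 1).
* Quantization rounds half-to-even (`np.rint`); saturation at ±63 is the
  defined out-of-range behaviour. Jittered channels round half away from
  zero and clip at the range edges.
* Degenerate `tau_m ≈ tau_s` in the exact propagator switches to the
  analytic limit `delta * exp(-delta/tau) / dt`.
* Gradient clipping (global norm) is available and recommended with the
  literal surrogate form; off by default.
* Determinism: every run is reproducible byte-for-byte from (config, seed);
  substrate trial noise, shuffling, dropout masks and initialization all
  derive from the estimator's `random_state` and the substrate seeds.
* Limitations: no adaptation currents or exponential spiking nonlinearity;
  no modelling of ADC transfer functions or event-router bandwidth; no
  energy/latency modelling; binary per-bin spike routing (a neuron spiking
  twice within one sampling interval contributes one routed event, though
  both raw spike times are recorded); BPTT memory grows linearly in T (no
  online approximation).
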