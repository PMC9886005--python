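# Methods

## Models

**Continuous reference.** The subthreshold LIF dynamics with exponential
postsynaptic currents form a linear, upper-triangular 2-state system in
(V, I_syn). The reference simulator advances it on a fixed grid of step `h`
with the closed-form matrix exponential: diagonal factors `e^(−h/τ_v)`,
`e^(−h/τ_syn)`, coupling `(e^(−h/τ_v) − e^(−h/τ_syn)) / (C·(1/τ_syn − 1/τ_v))`,
and a constant drive pulling V toward `E_L + R·I_bias`. On-grid values are
therefore exact samples of the analytic solution for *any* `h`; the tests
pin this at 1e-10 relative against the closed form and 1e-12 against an
independent scaling-and-squaring matrix exponential. When
`τ_syn = τ_v` the coupling degenerates; the simulator switches to the
analytic alpha-function limit `(h/C)·e^(−h/τ)` (relative gap below 1e-9)
rather than perturbing a parameter, so the degenerate case is also exact.
There is no refractory period; the threshold test is strict (`V > Θ`), and
the recorded post-spike sample is the reset value.

**Fixed-point compartment.** The emulator is a bit-faithful software model
of a digital neuromorphic compartment: signed 23-bit integer states, per-step
decay by multiply-and-arithmetic-right-shift (`(x·(4096 − δ)) >> 12`, i.e.
floor), current updated before voltage so the voltage update uses the
current of the same step, strict integer threshold, reset to zero. Floor is
the hardware-natural rounding; it is exact for non-negative products and
biases negative states downward, and it is the dominant error source at
small `dt` (about half a level per step, amplified by `4096/δ` at the fixed
point). A unit-test oracle transcribes the update rule independently with
unbounded Python integers and must match bit-for-bit over randomized
configurations. With rounding and quantization switched off (`run_euler`)
the same update is plain forward Euler on the hardware scale and converges
to the reference at first order in `dt`, which separates discretization
from quantization error.

## Parameter translation

Voltage: `v = (V − V_r)/V_s` and back `V = v·V_s + V_r` (exact mutual
inverses). Decays: `δ = (dt/τ)·2¹²`, rounded to the **nearest** integer in
[1, 4096] — nearest minimizes the effective-τ error; τ is representable iff
`dt ≤ τ ≤ 4096·dt`. Threshold: `(Θ − V_r)/V_s` rounded to the nearest
multiple of 64 (a 17-bit mantissa in the high bits of the 23-bit word).
Bias: `b = [I_bias/(C·V_s) + (E_L − V_r)/(τ_v·V_s)]·dt`, encoded as
`mantissa·2^exponent` with mantissa in [−4096, 4096] and exponent in [0, 7]
by exhaustive minimization of the absolute error, ties to the smallest
exponent; the error is at most `2^(e−1)`. The reference-drive term
`(E_L − V_r)/τ_v` is folded into the bias; it vanishes whenever resting and
reset potentials coincide (as in both worked parameter sets). Synaptic
weights map like the bias current: `w_hw = round(w_syn·dt/(C·V_s))` levels
per spike. All quantizers are idempotent.

## Stimuli and defaults

Three drive modes: constant bias current (a mapped parameter), frozen
external spike trains (the packaged five-source, eleven-event fixture), and
seeded homogeneous Poisson generators (`rate` in Hz; the frozen fixture was
originally drawn at 5 Hz per source over 500 ms). Defaults chosen once and
exposed in config: `τ_syn = 5 ms`, and `w_syn` defaulting to the weight
whose single-spike postsynaptic potential peaks at 1 mV (52.57 pA for the
spike-driven worked set, from the closed-form double-exponential peak).

## Event timing and trace pairing

Two conventions interact and were fixed deliberately:

* **Reference**: a spike at time `t` is a current delta at the first grid
  point ≥ `t`; the recorded `I_syn` at that grid point includes the jump and
  the voltage integrates it from the next step on (the standard convention
  of exact-integration point-neuron simulators).
* **Emulator**: every event — external stimulus and network spike alike —
  scheduled at step `s` reaches the postsynaptic current at step `s + 1`
  (uniform one-step synaptic latency). Within a step the current updates
  first, so the voltage responds in the same step the current jumps.

Consequently the emulator's `u[k]` is the *left-endpoint* current driving
step `k` in the Euler scheme, while `v[k]` is the end-of-step potential.
Validation therefore pairs `v[k] ↔ V(t_k)` but `u[k] ↔ I_syn(t_{k−1})`.
Pairing both states index-by-index instead would put a spurious one-step
phase error into exactly one of the two comparisons (measured: the current
correlation drops from 0.998 to 0.79 at dt = 1). The pairing starts at step
1; the shared initial condition is excluded, so 500 ms at dt = 1 yields 500
paired samples. For `dt ≠ 1` the reference grid is `h = min(1, dt)` ms and
the comparison subsamples onto the emulator grid — exactness makes the
reference `h` immaterial at shared grid points.

## Validation metrics and protocol

RMSE and the Pearson product-moment correlation are computed on the
physical scale after inverse mapping (`V = v·V_s + V_r`;
`I = u·C·V_s/dt`); correlation is affine-invariant, so raw-level and mV
correlations coincide. RMSE is taken over all time points (an option to
mask windows around spikes exists but is off by default). Diagnostics
return plot-ready data: Gaussian-KDE densities (Silverman bandwidth) of
each series, per-step raster arrays, and the scatter pairs with the
least-squares trend line. A correlation on a constant pair (e.g. the
synaptic current under pure bias drive) is undefined and reported as None
rather than a number.

**Single-neuron protocol.** 500 ms, dt = 1 ms/step, V_s = 1e-4 mV/level,
initial state at rest. The protocol records *subthreshold* dynamics by
default: for the bias-driven worked set the steady state (−40.6 mV) sits
slightly above the −43 mV threshold, and in the spiking regime the two
backends' effective time constants — 25 ms vs `−dt/ln(1 − 164/4096)` ≈
24.5 ms — produce 63- vs 62-step firing periods that drift out of phase, so
a thresholded comparison measures spike-timing drift rather than mapping
quality (spike *counts* still agree to within one). Both regimes are
available; the spiking one is reported separately in the examples.

**Precision sweeps.** dt ∈ {0.1, 1, 10} ms at V_s = 1e-4, and V_s ∈
{1e-3, 1e-4, 1e-5} at dt = 1, spike-driven. At dt = 10 the synaptic time
constant (5 ms) is outside the representable window; the sweep clamps that
decay to 4096 (full per-step decay) and flags the row instead of dropping
it, because the degraded dynamics are part of the result. The observed
pattern — both states' RMSE minimized at dt = 1, voltage RMSE improving
from V_s = 1e-3 to 1e-4, current RMSE flat between 1e-4 and 1e-5 — follows
from the error budget: floor-rounding grows as dt shrinks (more steps, and
the inverse current map divides by dt), while the decay-quantization error
is independent of V_s.

**Ensemble and networks.** The ensemble harness runs a table of independent
neurons on both backends and aggregates per-class metrics. The packaged
20-class table is *synthetic* (`make_ensemble_table`): measured per-class
parameter sets live outside this package, so the generator draws
physiologically plausible ranges (τ_v 10–40 ms, C 40–300 pF, bias-driven
deflections 5–25 mV, half excitatory / half inhibitory), seeded and
reproducible. Random networks are directed Erdős–Rényi graphs (default
p = 0.1, 1:1 E/I split, excitatory edges positive, inhibitory negative,
no self-loops) of identical bias-driven compartments. The scaling harness
reports wall-clock runtimes for connected vs unconnected populations; these
are host-dependent and explicitly informational — they are never asserted
quantitatively, and overflowing compartments saturate instead of aborting.

## What the synthetic inputs do and do not show

The frozen fixture and Poisson generators emulate sparse cortical afferent
drive at the statistics used in the validation studies; they do not emulate
rate-modulated or correlated input, and the ensemble table mimics parameter
*ranges*, not any measured cell-type distribution. Passing tests therefore
certify the numerics of the mapping and the two engines — they do not
certify that any particular biological dataset maps well, which always
depends on whether its time constants fit the `[dt, 4096·dt]` window.

## Numerical choices and edge cases

Nearest-integer rounding throughout the quantizers (ties: threshold rounds
half up; bias ties take the smallest exponent). Spike times are binned to
steps by `round(t/dt)`; coincident arrivals sum. State overflow (|x| ≥ 2²³)
raises by default, naming the state and step; saturation mode clips.
Initial emulator state is `round((V_0 − V_r)/V_s)` with `V_0 = E_L` by
default. Determinism: identical configs and stimuli produce bit-identical
emulator traces, and all randomness (Poisson stimuli, ensemble tables,
networks) flows from explicit integer seeds.

## Known limitations

* Only the plain LIF compartment is modeled: no dendritic trees, learning
  rules, axonal delay programming, or mantissa/exponent weight compression.
* The emulator models arithmetic, not hardware timing or core/chip
  partitioning; its runtimes say nothing about silicon.
* The spiking-regime comparison is sample-wise and is expected to degrade
  with duration through phase drift; spike-train distance metrics are out
  of scope.
* Subthreshold exactness of the reference holds on grid points only;
  between-grid behavior is never compared.
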