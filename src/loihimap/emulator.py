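"""Bit-faithful software model of the fixed-point neuromorphic compartment.

State is a pair of signed 23-bit integers per compartment: membrane
potential ``v`` and synaptic current ``u``, both in hardware levels.  Each
algorithmic time step applies, in order,

    u <- (u * (4096 - delta_u)) >> 12  + incoming weighted spikes
    v <- (v * (4096 - delta_v)) >> 12  + b + u
    if v > theta (strict):  emit spike, v <- 0

The decay multiply uses an arithmetic right shift, i.e. floor division by
2**12 — the hardware-natural rounding, exact for non-negative states and
floor-biased for negative ones.  The current update precedes the voltage
update, so the ``u`` entering ``v`` is the current already updated for the
step.  Every event (external stimulus or network spike) scheduled at step
``t`` reaches the postsynaptic current at step ``t + 1`` — a uniform
one-step synaptic latency.

State words exceeding the ±2**23 range raise :class:`StateOverflowError` by
default; a saturation mode clips instead (useful for scaling studies where a
hard failure of one compartment should not abort the run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import STATE_MAX, DECAY_MAX, LoihiNeuronConfig

__all__ = [
    "StateOverflowError",
    "EmulatorState",
    "EmulatorTrace",
    "NetworkSpec",
    "decay_multiply",
    "step",
    "schedule_spikes",
    "run",
    "run_euler",
    "run_network",
]


class StateOverflowError(OverflowError):
    """A state variable left the signed 23-bit range."""


@dataclass
class EmulatorState:
    v: int = 0
    u: int = 0
    t: int = 0


@dataclass
class EmulatorTrace:
    """Per-step state recording in integer levels.

    ``v[k]``, ``u[k]`` are the states after step ``k``; index 0 holds the
    initial condition, so the arrays have ``n_steps + 1`` entries.
    ``spike_steps`` are the step indices at which the compartment fired.
    """

    v: np.ndarray
    u: np.ndarray
    spike_steps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if len(self.v) != len(self.u):
            raise ValueError("v and u must have equal length")
        if np.any(np.diff(self.spike_steps) <= 0):
            raise ValueError("spike steps must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.v) - 1


@dataclass
class NetworkSpec:
    """A network of compartments with directed weighted synapses.

    ``configs`` holds one hardware config per compartment; ``edges`` is a
    list of ``(pre, post, weight_levels)``; ``external`` optionally maps a
    compartment index to its per-step external increment schedule.
    """

    configs: list[LoihiNeuronConfig]
    edges: list[tuple[int, int, int]] = field(default_factory=list)
    external: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.configs)
        for pre, post, w in self.edges:
            if not (0 <= pre < n and 0 <= post < n):
                raise ValueError(f"edge ({pre}, {post}) out of range for {n} compartments")
            if abs(int(w)) >= STATE_MAX:
                raise ValueError(f"edge weight {w} exceeds the 23-bit range")

    @property
    def n_compartments(self) -> int:
        return len(self.configs)


def decay_multiply(x: int, delta: int) -> int:
    """``(x * (4096 - delta)) >> 12`` with arithmetic-shift (floor) semantics.

    Exact integer arithmetic; by the 23-bit state precondition the
    intermediate product fits comfortably in a 64-bit word.
    """
    if not 1 <= delta <= DECAY_MAX:
        raise ValueError(f"delta must be in [1, {DECAY_MAX}]")
    return (int(x) * (DECAY_MAX - delta)) >> 12


def _check_range(value: int, name: str, t: int, saturate: bool) -> int:
    if -STATE_MAX < value < STATE_MAX:
        return value
    if saturate:
        return STATE_MAX - 1 if value > 0 else -(STATE_MAX - 1)
    raise StateOverflowError(
        f"state overflow: |{name}| = {abs(value)} >= 2**23 at step {t}"
    )


def step(
    state: EmulatorState,
    cfg: LoihiNeuronConfig,
    spike_increment: int = 0,
    apply_threshold: bool = True,
    saturate: bool = False,
) -> tuple[EmulatorState, bool]:
    """Advance one compartment by one algorithmic step."""
    t = state.t + 1
    u = decay_multiply(state.u, cfg.delta_u) + int(spike_increment)
    u = _check_range(u, "u", t, saturate)
    v = decay_multiply(state.v, cfg.delta_v) + cfg.bias + u
    v = _check_range(v, "v", t, saturate)
    spiked = False
    if apply_threshold and v > cfg.theta_hw:
        v = 0
        spiked = True
    return EmulatorState(v=v, u=u, t=t), spiked


def schedule_spikes(
    spike_times,
    dt: float,
    n_steps: int | None = None,
    weight: int = 1,
) -> np.ndarray:
    """Bin spike times (ms) onto the step grid: time ``t`` lands on step
    ``round(t / dt)``; coincident arrivals sum their weights.

    Returns an integer array of per-step increments of length
    ``n_steps + 1`` (index = scheduled step).
    """
    times = np.asarray(list(spike_times), dtype=float)
    if times.size and times.min() < 0:
        raise ValueError("spike times must be non-negative")
    steps = np.rint(times / dt).astype(int)
    if n_steps is None:
        n_steps = int(steps.max()) if steps.size else 0
    if steps.size and steps.max() > n_steps:
        raise ValueError(
            f"spike at step {steps.max()} beyond the simulation horizon {n_steps}"
        )
    out = np.zeros(n_steps + 1, dtype=np.int64)
    np.add.at(out, steps, int(weight))
    return out


def _external_schedule(cfg, stimulus, params, mapping_cfg, n_steps):
    """Build the per-step external increment array for one compartment from a
    SpikeTrainSet, using the mapped per-source weights."""
    from .mapping import map_weight

    increments = np.zeros(n_steps + 1, dtype=np.int64)
    for source in stimulus.sources:
        w_pa = stimulus.weight_of(source)
        w_hw = cfg.w_hw if w_pa is None else map_weight(w_pa, params, mapping_cfg)
        increments += schedule_spikes(
            stimulus.times_of(source), mapping_cfg.dt, n_steps=n_steps, weight=w_hw
        )
    return increments


def run(
    cfg: LoihiNeuronConfig,
    increments: np.ndarray | None = None,
    n_steps: int = 500,
    v0: int = 0,
    u0: int = 0,
    apply_threshold: bool = True,
    saturate: bool = False,
) -> EmulatorTrace:
    """Run a single compartment for ``n_steps`` algorithmic steps.

    ``increments[k]`` is the weighted external input scheduled at step ``k``;
    it reaches the current at step ``k + 1`` (one-step synaptic latency).
    """
    if increments is None:
        increments = np.zeros(n_steps + 1, dtype=np.int64)
    if len(increments) < n_steps + 1:
        increments = np.pad(increments, (0, n_steps + 1 - len(increments)))

    v_rec = np.empty(n_steps + 1, dtype=np.int64)
    u_rec = np.empty(n_steps + 1, dtype=np.int64)
    v_rec[0], u_rec[0] = v0, u0
    spikes: list[int] = []
    state = EmulatorState(v=int(v0), u=int(u0), t=0)
    for k in range(1, n_steps + 1):
        state, spiked = step(
            state,
            cfg,
            spike_increment=int(increments[k - 1]),
            apply_threshold=apply_threshold,
            saturate=saturate,
        )
        v_rec[k], u_rec[k] = state.v, state.u
        if spiked:
            spikes.append(k)
    return EmulatorTrace(v=v_rec, u=u_rec, spike_steps=np.asarray(spikes, dtype=int))


def run_euler(
    params,
    mapping_cfg,
    increments: np.ndarray | None = None,
    n_steps: int = 500,
    v0: float = 0.0,
    u0: float = 0.0,
    apply_threshold: bool = False,
) -> EmulatorTrace:
    """Unquantized twin of the integer compartment: the same update with
    real-valued states, the exact (unrounded) decay factors
    ``dt/tau * 4096 / 4096 = dt/tau`` and the exact real-valued bias.

    This is plain forward Euler for the scaled subthreshold ODE on the
    hardware level/step scale.  Comparing it with :func:`run` separates the
    emulator's discretization error (present here) from its quantization and
    integer-rounding error (absent here).  ``increments`` are real-valued
    level jumps with the same one-step delivery convention as :func:`run`.
    """
    from .mapping import compute_bias, to_levels

    if increments is None:
        increments = np.zeros(n_steps + 1)
    if len(increments) < n_steps + 1:
        increments = np.pad(np.asarray(increments, dtype=float),
                            (0, n_steps + 1 - len(increments)))
    dv = mapping_cfg.dt / params.tau_v
    du = mapping_cfg.dt / params.tau_syn
    b = compute_bias(params, mapping_cfg)
    theta = to_levels(params.Theta, params.V_r, mapping_cfg.V_s)
    v_rec = np.empty(n_steps + 1)
    u_rec = np.empty(n_steps + 1)
    v_rec[0], u_rec[0] = float(v0), float(u0)
    spikes: list[int] = []
    v, u = float(v0), float(u0)
    for k in range(1, n_steps + 1):
        u = u * (1.0 - du) + float(increments[k - 1])
        v = v * (1.0 - dv) + b + u
        if apply_threshold and v > theta:
            v = 0.0
            spikes.append(k)
        v_rec[k], u_rec[k] = v, u
    return EmulatorTrace(v=v_rec, u=u_rec, spike_steps=np.asarray(spikes, dtype=int))


def run_network(
    spec: NetworkSpec,
    n_steps: int,
    v0: np.ndarray | None = None,
    apply_threshold: bool = True,
    saturate: bool = False,
    record: bool = True,
) -> list[EmulatorTrace]:
    """Advance all compartments synchronously.

    A spike emitted at step ``t`` is delivered to the postsynaptic current at
    step ``t + 1``, exactly like external events.  Vectorized over
    compartments with 64-bit integers (the 23-bit range keeps every
    intermediate product exact).
    """
    n = spec.n_compartments
    delta_v = np.array([c.delta_v for c in spec.configs], dtype=np.int64)
    delta_u = np.array([c.delta_u for c in spec.configs], dtype=np.int64)
    bias = np.array([c.bias for c in spec.configs], dtype=np.int64)
    theta = np.array([c.theta_hw for c in spec.configs], dtype=np.int64)

    # adjacency as index arrays for fast scatter-add of emitted spikes
    if spec.edges:
        pre = np.array([e[0] for e in spec.edges], dtype=np.int64)
        post = np.array([e[1] for e in spec.edges], dtype=np.int64)
        w = np.array([e[2] for e in spec.edges], dtype=np.int64)
    else:
        pre = post = w = np.empty(0, dtype=np.int64)

    v = np.zeros(n, dtype=np.int64) if v0 is None else np.asarray(v0, dtype=np.int64).copy()
    u = np.zeros(n, dtype=np.int64)
    pending = np.zeros(n, dtype=np.int64)  # synaptic input due this step

    if record:
        v_rec = np.empty((n_steps + 1, n), dtype=np.int64)
        u_rec = np.empty((n_steps + 1, n), dtype=np.int64)
        v_rec[0], u_rec[0] = v, u
    spike_lists: list[list[int]] = [[] for _ in range(n)]

    limit = STATE_MAX
    for k in range(1, n_steps + 1):
        incoming = pending
        for idx, sched in spec.external.items():
            if k - 1 < len(sched):
                incoming[idx] += sched[k - 1]
        u = ((u * (DECAY_MAX - delta_u)) >> 12) + incoming
        _check_range_array(u, "u", k, saturate, limit)
        v = ((v * (DECAY_MAX - delta_v)) >> 12) + bias + u
        _check_range_array(v, "v", k, saturate, limit)
        if apply_threshold:
            fired = v > theta
            if fired.any():
                v = np.where(fired, 0, v)
                for idx in np.flatnonzero(fired):
                    spike_lists[idx].append(k)
                pending = np.zeros(n, dtype=np.int64)
                if len(pre):
                    mask = fired[pre]
                    np.add.at(pending, post[mask], w[mask])
            else:
                pending = np.zeros(n, dtype=np.int64)
        else:
            pending = np.zeros(n, dtype=np.int64)
        if record:
            v_rec[k], u_rec[k] = v, u

    if not record:
        return [
            EmulatorTrace(
                v=np.array([v[i]]),
                u=np.array([u[i]]),
                spike_steps=np.asarray(spike_lists[i], dtype=int),
            )
            for i in range(n)
        ]
    return [
        EmulatorTrace(
            v=v_rec[:, i].copy(),
            u=u_rec[:, i].copy(),
            spike_steps=np.asarray(spike_lists[i], dtype=int),
        )
        for i in range(n)
    ]


def _check_range_array(x: np.ndarray, name: str, t: int, saturate: bool, limit: int) -> None:
    bad = np.abs(x) >= limit
    if not bad.any():
        return
    if saturate:
        np.clip(x, -(limit - 1), limit - 1, out=x)
        return
    idx = int(np.flatnonzero(bad)[0])
    raise StateOverflowError(
        f"state overflow: |{name}[{idx}]| >= 2**23 at step {t}"
    )
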