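"""Exact-integration reference simulator for the continuous LIF model.

The subthreshold dynamics

    V'(t) = -(V - E_L)/tau_v + (I_bias + I_syn(t)) / C
    I_syn'(t) = -I_syn / tau_syn   (+ w_syn at each afferent spike)

form a linear system, so on a fixed grid of step ``h`` the solution is
advanced by the matrix exponential of the system matrix — "exact
integration".  On-grid values are machine-precision samples of the analytic
solution regardless of ``h``, which is what distinguishes this reference
from the forward-Euler-like update of the fixed-point hardware model and
makes it a valid ground truth at any comparison grid.

Conventions
-----------
* An afferent spike at time ``s`` is a Dirac delta in the synaptic current
  at the first grid point ``t_k >= s``: the recorded ``I_syn[k]`` includes
  the jump, and the voltage integrates it from the following step on.
* Threshold test is strict (``V > Theta``); on a spike the recorded value is
  the post-reset ``V_r``.  No refractory period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import PhysicalLIFParams

__all__ = [
    "Propagator",
    "SimulationGrid",
    "NeuronState",
    "Trace",
    "build_propagator",
    "step",
    "run",
]


@dataclass(frozen=True)
class Propagator:
    """Per-step linear update coefficients.

    V <- P_vv * V + P_vi * I_syn + drive ;  I_syn <- P_ii * I_syn
    """

    P_vv: float
    P_vi: float
    P_ii: float
    drive: float
    h: float


@dataclass(frozen=True)
class SimulationGrid:
    duration: float  # ms
    h: float = 1.0   # ms per grid step

    def __post_init__(self) -> None:
        if self.h <= 0 or self.duration <= 0:
            raise ValueError("duration and h must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.h))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.h


@dataclass
class NeuronState:
    V: float      # mV
    I_syn: float  # pA


@dataclass
class Trace:
    """Time-indexed recording of one reference simulation.

    ``times[k] = k*h`` includes the initial condition at t = 0, so the
    arrays have ``n_steps + 1`` entries.
    """

    times: np.ndarray
    V: np.ndarray
    I_syn: np.ndarray
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.V) == len(self.I_syn)):
            raise ValueError("times, V and I_syn must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    @property
    def h(self) -> float:
        return float(self.times[1] - self.times[0])


def build_propagator(params: PhysicalLIFParams, h: float) -> Propagator:
    """Closed-form matrix exponential of the 2-state subthreshold system.

    The system matrix is upper triangular,

        A = [[-1/tau_v, 1/C], [0, -1/tau_syn]],

    so exp(A h) has diagonal ``exp(-h/tau_v)``, ``exp(-h/tau_syn)`` and
    coupling term ``(1/C)(e^{-h/tau_v} - e^{-h/tau_syn})/(1/tau_syn - 1/tau_v)``.
    When the two time constants coincide the coupling degenerates to the
    analytic alpha-function limit ``(h/C) e^{-h/tau}`` (no perturbation, no
    NaN).  The constant drive moves V toward ``E_L + R*I_bias``.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    P_vv = math.exp(-h / params.tau_v)
    P_ii = math.exp(-h / params.tau_syn)
    if math.isclose(params.tau_v, params.tau_syn, rel_tol=1e-9):
        P_vi = h / params.C * math.exp(-h / params.tau_v)
    else:
        rate_gap = 1.0 / params.tau_syn - 1.0 / params.tau_v
        P_vi = (P_vv - P_ii) / (params.C * rate_gap)
    drive = params.V_inf * (1.0 - P_vv)
    return Propagator(P_vv=P_vv, P_vi=P_vi, P_ii=P_ii, drive=drive, h=h)


def step(
    state: NeuronState,
    propagator: Propagator,
    params: PhysicalLIFParams,
    spike_input: float = 0.0,
    apply_threshold: bool = True,
) -> tuple[NeuronState, bool]:
    """Advance one grid step: linear update, then add the afferent-spike
    current jump, then the strict threshold/reset test."""
    V = propagator.P_vv * state.V + propagator.P_vi * state.I_syn + propagator.drive
    I_syn = propagator.P_ii * state.I_syn + spike_input
    spiked = False
    if apply_threshold and V > params.Theta:
        V = params.V_r
        spiked = True
    return NeuronState(V=V, I_syn=I_syn), spiked


def run(
    params: PhysicalLIFParams,
    stimulus=None,
    grid: SimulationGrid | None = None,
    V0: float | None = None,
    apply_threshold: bool = True,
) -> Trace:
    """Simulate one neuron on a fixed grid and record the full trace.

    Parameters
    ----------
    stimulus : SpikeTrainSet or None
        Afferent spike trains; each event adds its source weight (default
        ``params.w_syn``) to the synaptic current.  ``None`` means
        bias-current drive only.
    grid : simulation window; default 500 ms at h = 1 ms.
    V0 : initial potential, default the resting potential E_L.
    apply_threshold : set False to record the pure subthreshold dynamics.
    """
    if grid is None:
        grid = SimulationGrid(duration=500.0, h=1.0)
    n = grid.n_steps
    prop = build_propagator(params, grid.h)

    increments = np.zeros(n + 1)
    if stimulus is not None:
        for source in stimulus.sources:
            w = stimulus.weight_of(source)
            w = params.w_syn if w is None else w
            for s in stimulus.times_of(source):
                if s < 0 or s > grid.duration:
                    raise ValueError(
                        f"spike at t = {s} ms outside [0, {grid.duration}] ms"
                    )
                k = int(math.ceil(s / grid.h - 1e-9))
                increments[k] += w

    V = np.empty(n + 1)
    I = np.empty(n + 1)
    V[0] = params.E_L if V0 is None else V0
    I[0] = increments[0]
    spike_times: list[float] = []
    state = NeuronState(V=V[0], I_syn=I[0])
    for k in range(1, n + 1):
        state, spiked = step(
            state, prop, params, spike_input=increments[k], apply_threshold=apply_threshold
        )
        V[k] = state.V
        I[k] = state.I_syn
        if spiked:
            spike_times.append(k * grid.h)
    return Trace(times=grid.times, V=V, I_syn=I, spike_times=np.asarray(spike_times))
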