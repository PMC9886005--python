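"""Scripted validation studies.

Four study harnesses built on the lower-level modules:

* :func:`run_single_neuron` — the worked single-neuron protocol: 500 ms on
  both backends, inverse-map, report RMSE / correlation for both states.
* :func:`sweep_dt` / :func:`sweep_vs` — temporal and voltage precision
  sweeps over the two mapping knobs.
* :func:`run_ensemble` — a table of independent neuron classes simulated on
  both backends, with per-class and aggregate metrics.
* :func:`build_random_network` / :func:`scaling_study` — random E/I networks
  and a wall-clock scaling harness (informational only; runtimes are
  host-dependent and are never part of the validation surface).

The single-neuron protocol records the *subthreshold* dynamics by default
(threshold and reset disabled on both backends): the worked bias-driven
parameter set has a mapped steady state a few mV above threshold, and the
two backends' slightly different effective time constants would phase-drift
the spike trains, turning a numerics comparison into a spike-timing
comparison.  Pass ``subthreshold=False`` for the spiking regime.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import emulator as emu_mod
from . import reference as ref_mod
from .mapping import MappingError, map_neuron, to_levels
from .params import LoihiNeuronConfig, MappingConfig, PhysicalLIFParams
from .stimulus import SpikeTrainSet
from .validation import ComparisonReport, compare

__all__ = [
    "run_single_neuron",
    "SweepResult",
    "sweep_dt",
    "sweep_vs",
    "EnsembleResult",
    "make_ensemble_table",
    "run_ensemble",
    "RandomNetworkSpec",
    "build_random_network",
    "scaling_study",
]

DEFAULT_DURATION_MS = 500.0


def _run_pair(
    params: PhysicalLIFParams,
    stimulus: SpikeTrainSet | None,
    cfg: MappingConfig,
    duration_ms: float,
    subthreshold: bool,
    clamp_decay: bool = False,
):
    """Run both backends for one neuron and return (ref_trace, emu_trace, cfg_hw)."""
    cfg_hw = map_neuron(params, cfg, clamp_decay=clamp_decay)
    h = min(1.0, cfg.dt)
    grid = ref_mod.SimulationGrid(duration=duration_ms, h=h)
    ref_trace = ref_mod.run(
        params, stimulus=stimulus, grid=grid, apply_threshold=not subthreshold
    )
    n_steps = cfg.n_steps(duration_ms)
    increments = None
    if stimulus is not None:
        increments = emu_mod._external_schedule(cfg_hw, stimulus, params, cfg, n_steps)
    v0 = int(round(to_levels(params.E_L, params.V_r, cfg.V_s)))
    emu_trace = emu_mod.run(
        cfg_hw,
        increments=increments,
        n_steps=n_steps,
        v0=v0,
        apply_threshold=not subthreshold,
    )
    return ref_trace, emu_trace, cfg_hw


def run_single_neuron(
    params: PhysicalLIFParams,
    stimulus: SpikeTrainSet | None = None,
    cfg: MappingConfig | None = None,
    duration_ms: float = DEFAULT_DURATION_MS,
    subthreshold: bool = True,
) -> ComparisonReport:
    """Single-neuron cross-backend validation.

    Maps the neuron, runs the exact-integration reference and the
    fixed-point emulator for ``duration_ms``, inverse-maps the emulator
    trace to physical units and returns the comparison report.
    """
    cfg = cfg or MappingConfig()
    ref_trace, emu_trace, _ = _run_pair(params, stimulus, cfg, duration_ms, subthreshold)
    return compare(ref_trace, emu_trace, cfg, params)


@dataclass
class SweepResult:
    """One row per precision value: RMSE and correlation for both states.

    ``flagged`` marks rows where a time constant fell outside the
    representable window and the decay was clamped to full per-step decay.
    """

    axis: str
    values: list[float]
    rmse_v: list[float]
    rmse_i: list[float]
    r_v: list[float]
    r_i: list[float]
    flagged: list[bool]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.axis: self.values,
                "rmse_v_mV": self.rmse_v,
                "rmse_i_pA": self.rmse_i,
                "pearson_v": self.r_v,
                "pearson_i": self.r_i,
                "flagged": self.flagged,
            }
        )


def sweep_dt(
    params: PhysicalLIFParams,
    stimulus: SpikeTrainSet | None,
    dts=(0.1, 1.0, 10.0),
    V_s: float = 1e-4,
    duration_ms: float = DEFAULT_DURATION_MS,
    subthreshold: bool = True,
) -> SweepResult:
    """Temporal-precision sweep: vary the ms-per-step scale at fixed V_s.

    A step coarser than a time constant cannot be mapped exactly (the decay
    constant saturates); such rows are run with clamped decay and flagged
    rather than dropped, since the degraded dynamics are part of the result.
    """
    result = SweepResult("dt_ms", [], [], [], [], [], [])
    for dt in dts:
        cfg = MappingConfig(V_s=V_s, dt=dt)
        clamped = params.tau_v < dt or params.tau_syn < dt
        ref_trace, emu_trace, _ = _run_pair(
            params, stimulus, cfg, duration_ms, subthreshold, clamp_decay=clamped
        )
        report = compare(ref_trace, emu_trace, cfg, params)
        result.values.append(dt)
        result.rmse_v.append(report.V.rmse)
        result.rmse_i.append(report.I.rmse)
        result.r_v.append(report.V.pearson_r)
        result.r_i.append(report.I.pearson_r)
        result.flagged.append(clamped)
    return result


def sweep_vs(
    params: PhysicalLIFParams,
    stimulus: SpikeTrainSet | None,
    vs=(1e-3, 1e-4, 1e-5),
    dt: float = 1.0,
    duration_ms: float = DEFAULT_DURATION_MS,
    subthreshold: bool = True,
) -> SweepResult:
    """Voltage-precision sweep: vary the mV-per-level scale at fixed dt."""
    result = SweepResult("V_s_mV_per_level", [], [], [], [], [], [])
    for V_s in vs:
        cfg = MappingConfig(V_s=V_s, dt=dt)
        ref_trace, emu_trace, _ = _run_pair(params, stimulus, cfg, duration_ms, subthreshold)
        report = compare(ref_trace, emu_trace, cfg, params)
        result.values.append(V_s)
        result.rmse_v.append(report.V.rmse)
        result.rmse_i.append(report.I.rmse)
        result.r_v.append(report.V.pearson_r)
        result.r_i.append(report.I.pearson_r)
        result.flagged.append(False)
    return result


@dataclass
class EnsembleResult:
    """Per-class comparison reports plus aggregate and scatter summaries."""

    reports: list[ComparisonReport]
    labels: list[str]
    params: list[PhysicalLIFParams]

    @property
    def mean_r(self) -> float:
        return float(np.mean([r.V.pearson_r for r in self.reports]))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean([r.V.rmse for r in self.reports]))

    def scatter_data(self) -> pd.DataFrame:
        """Parameter scatter table: capacitance and bias current against the
        membrane time constant, marker-sized by RMSE."""
        return pd.DataFrame(
            {
                "label": self.labels,
                "C_pF": [p.C for p in self.params],
                "tau_v_ms": [p.tau_v for p in self.params],
                "I_bias_pA": [p.I_bias for p in self.params],
                "rmse_mV": [r.V.rmse for r in self.reports],
                "pearson_r": [r.V.pearson_r for r in self.reports],
            }
        )


def make_ensemble_table(
    n: int = 20, seed: int = 0
) -> tuple[list[PhysicalLIFParams], list[str]]:
    """Generate a synthetic table of neuron classes, half excitatory and half
    inhibitory.

    Stand-in for a cell-types parameter table (the measured per-class values
    are not part of this package): time constants span 10-40 ms, capacitances
    and bias currents are drawn so the bias-driven deflection R*I_bias stays
    in a physiological 5-25 mV band.  Seeded and reproducible.
    """
    rng = np.random.default_rng(seed)
    n_exc = n // 2
    params: list[PhysicalLIFParams] = []
    labels: list[str] = []
    for i in range(n):
        excitatory = i < n_exc
        tau_v = rng.uniform(15.0, 40.0) if excitatory else rng.uniform(10.0, 25.0)
        C = rng.uniform(120.0, 300.0) if excitatory else rng.uniform(40.0, 150.0)
        deflection = rng.uniform(10.0, 25.0) if excitatory else rng.uniform(5.0, 20.0)
        I_bias = deflection * C / tau_v
        params.append(
            PhysicalLIFParams(
                C=round(C, 2), tau_v=round(tau_v, 2), E_L=-70.0, V_r=-70.0,
                Theta=-43.0, I_bias=round(I_bias, 2),
            )
        )
        labels.append("excitatory" if excitatory else "inhibitory")
    return params, labels


def run_ensemble(
    param_table: list[PhysicalLIFParams],
    labels: list[str] | None = None,
    stimulus: SpikeTrainSet | None = None,
    cfg: MappingConfig | None = None,
    duration_ms: float = DEFAULT_DURATION_MS,
    subthreshold: bool = True,
) -> EnsembleResult:
    """Validate an ensemble of independent (unconnected) neuron classes.

    Each row is mapped and simulated on both backends; mapping failures are
    collected and re-raised together naming the offending rows.
    """
    cfg = cfg or MappingConfig()
    labels = labels or [f"class_{i}" for i in range(len(param_table))]
    if len(labels) != len(param_table):
        raise ValueError("one label per parameter set required")
    reports: list[ComparisonReport] = []
    failures: list[str] = []
    for i, p in enumerate(param_table):
        try:
            reports.append(
                run_single_neuron(p, stimulus, cfg, duration_ms, subthreshold)
            )
        except MappingError as e:
            failures.append(f"row {i} ({labels[i]}): {e}")
    if failures:
        raise MappingError("; ".join(failures))
    return EnsembleResult(reports=reports, labels=list(labels), params=list(param_table))


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Erdős–Rényi directed E/I network specification."""

    n_neurons: int
    p: float = 0.1
    ratio: tuple[int, int] = (1, 1)  # excitatory : inhibitory
    seed: int = 0
    weight_levels: int = 64

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("connection probability must be in [0, 1]")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if min(self.ratio) <= 0:
            raise ValueError("ratio components must be positive")


def build_random_network(
    spec: RandomNetworkSpec,
    params: PhysicalLIFParams | None = None,
    cfg: MappingConfig | None = None,
) -> emu_mod.NetworkSpec:
    """Draw a random directed network of identical bias-driven compartments.

    Each ordered pair (no self-loops) is connected with probability ``p``;
    presynaptically excitatory edges carry ``+weight_levels``, inhibitory
    edges ``-weight_levels``.  The split follows ``ratio`` with excitatory
    neurons first.  Fully determined by the seed.
    """
    from .params import EXAMPLE_NEURONS

    params = params or EXAMPLE_NEURONS["bias_driven"]
    cfg = cfg or MappingConfig()
    cfg_hw = map_neuron(params, cfg)
    n = spec.n_neurons
    n_exc = int(round(n * spec.ratio[0] / sum(spec.ratio)))
    rng = np.random.default_rng(spec.seed)
    mask = rng.random((n, n)) < spec.p
    np.fill_diagonal(mask, False)
    pre_idx, post_idx = np.nonzero(mask)
    w = np.where(pre_idx < n_exc, spec.weight_levels, -spec.weight_levels)
    edges = [(int(a), int(b), int(c)) for a, b, c in zip(pre_idx, post_idx, w)]
    return emu_mod.NetworkSpec(configs=[cfg_hw] * n, edges=edges)


def scaling_study(
    sizes,
    params: PhysicalLIFParams | None = None,
    cfg: MappingConfig | None = None,
    duration_ms: float = 100.0,
    p: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Wall-clock runtime of the emulator for connected vs unconnected
    networks of increasing size.  Informational only: absolute numbers are
    host- and implementation-dependent.  Overflowing compartments saturate
    rather than abort."""
    cfg = cfg or MappingConfig()
    n_steps = cfg.n_steps(duration_ms)
    rows = []
    for size in sizes:
        row = {"n_neurons": int(size)}
        for label, prob in (("connected_s", p), ("unconnected_s", 0.0)):
            spec = RandomNetworkSpec(n_neurons=int(size), p=prob, seed=seed)
            net = build_random_network(spec, params=params, cfg=cfg)
            t0 = time.perf_counter()
            emu_mod.run_network(net, n_steps=n_steps, saturate=True, record=False)
            row[label] = time.perf_counter() - t0
        rows.append(row)
    return pd.DataFrame(rows)
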