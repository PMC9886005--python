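"""File formats: traces, spike lists, configs and reports.

CSV dialect: header row, period decimal separator, time in ms.  HDF5 spike
files mirror the SONATA spike-report layout (``/spikes/node_ids`` and
``/spikes/timestamps``) so downstream point-network tooling can read them.
Everything written here can be read back losslessly by the matching reader.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .emulator import EmulatorTrace
from .params import LoihiNeuronConfig, MappingConfig, PhysicalLIFParams
from .reference import Trace
from .stimulus import SpikeTrainSet

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_hdf5",
    "read_trace_hdf5",
    "write_emulator_trace_csv",
    "read_emulator_trace_csv",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_spikes_hdf5",
    "read_spikes_hdf5",
    "write_report_json",
    "RunConfig",
    "load_run_config",
]


# ---------------------------------------------------------------- traces

def write_trace_csv(trace: Trace, path) -> None:
    pd.DataFrame(
        {"time_ms": trace.times, "V_mV": trace.V, "I_pA": trace.I_syn}
    ).to_csv(path, index=False)


def read_trace_csv(path, spike_times=None) -> Trace:
    df = pd.read_csv(path)
    return Trace(
        times=df["time_ms"].to_numpy(),
        V=df["V_mV"].to_numpy(),
        I_syn=df["I_pA"].to_numpy(),
        spike_times=np.asarray(spike_times if spike_times is not None else []),
    )


def write_trace_hdf5(trace: Trace, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=trace.times)
        f.create_dataset("V_mV", data=trace.V)
        f.create_dataset("I_pA", data=trace.I_syn)
        f.create_dataset("spike_times_ms", data=trace.spike_times)


def read_trace_hdf5(path) -> Trace:
    with h5py.File(path, "r") as f:
        return Trace(
            times=f["time_ms"][...],
            V=f["V_mV"][...],
            I_syn=f["I_pA"][...],
            spike_times=f["spike_times_ms"][...],
        )


def write_emulator_trace_csv(trace: EmulatorTrace, path) -> None:
    pd.DataFrame(
        {
            "step": np.arange(len(trace.v)),
            "v_levels": trace.v,
            "u_levels": trace.u,
        }
    ).to_csv(path, index=False)


def read_emulator_trace_csv(path, spike_steps=None) -> EmulatorTrace:
    df = pd.read_csv(path)
    return EmulatorTrace(
        v=df["v_levels"].to_numpy(),
        u=df["u_levels"].to_numpy(),
        spike_steps=np.asarray(spike_steps if spike_steps is not None else [], dtype=int),
    )


# ---------------------------------------------------------------- spikes

def write_spikes_csv(spikes: SpikeTrainSet, path) -> None:
    """Two-column CSV (source_id, time_ms), one row per event."""
    rows = [
        (source, t)
        for source in spikes.sources
        for t in spikes.times_of(source)
    ]
    pd.DataFrame(rows, columns=["source_id", "time_ms"]).to_csv(path, index=False)


def read_spikes_csv(path) -> SpikeTrainSet:
    df = pd.read_csv(path)
    trains = {
        int(source): np.sort(group["time_ms"].to_numpy())
        for source, group in df.groupby("source_id")
    }
    return SpikeTrainSet(trains=trains)


def write_spikes_hdf5(spikes: SpikeTrainSet, path) -> None:
    """SONATA-style spike report: /spikes/node_ids + /spikes/timestamps."""
    ids, ts = [], []
    for source in spikes.sources:
        times = spikes.times_of(source)
        ids.extend([source] * len(times))
        ts.extend(times)
    with h5py.File(path, "w") as f:
        grp = f.create_group("spikes")
        grp.create_dataset("node_ids", data=np.asarray(ids, dtype=np.int64))
        grp.create_dataset("timestamps", data=np.asarray(ts, dtype=float))
        grp["timestamps"].attrs["units"] = "ms"


def read_spikes_hdf5(path) -> SpikeTrainSet:
    with h5py.File(path, "r") as f:
        ids = f["spikes/node_ids"][...]
        ts = f["spikes/timestamps"][...]
    trains = {int(i): np.sort(ts[ids == i]) for i in np.unique(ids)}
    return SpikeTrainSet(trains=trains)


# ---------------------------------------------------------------- reports / configs

def write_report_json(report_dict: dict, path, **metadata) -> None:
    payload = dict(report_dict)
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass(frozen=True)
class RunConfig:
    """A complete simulation run description (YAML-serializable)."""

    params: str                    # path to a PhysicalLIFParams JSON
    backend: str = "both"          # reference | emulator | both
    V_s: float = 1e-4
    dt: float = 1.0
    duration_ms: float = 500.0
    stimulus: str = "none"         # none | fixture | path to a spike CSV
    subthreshold: bool = True
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.backend not in ("reference", "emulator", "both"):
            raise ValueError("backend must be reference, emulator or both")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")

    def mapping_config(self) -> MappingConfig:
        return MappingConfig(V_s=self.V_s, dt=self.dt)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def load_run_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**data)


def resolve_stimulus(descriptor: str) -> SpikeTrainSet | None:
    """Turn a stimulus descriptor into a spike-train set: 'none', 'fixture'
    (the frozen five-source set) or a path to a spike CSV."""
    from .stimulus import frozen_spike_fixture

    if descriptor == "none":
        return None
    if descriptor == "fixture":
        return frozen_spike_fixture()
    path = Path(descriptor)
    if not path.exists():
        raise FileNotFoundError(f"stimulus file not found: {descriptor}")
    return read_spikes_csv(path)
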