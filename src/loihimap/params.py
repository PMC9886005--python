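"""Parameter containers for the physical LIF model and its fixed-point image.

Physical units follow the conventions of intracellular electrophysiology
datasets: time in ms, voltage in mV, current in pA, capacitance in pF.
With these units the derived membrane resistance ``R = tau_v / C`` comes out
in GΩ and ``I * R`` directly in mV, so no unit conversion factors appear
anywhere in the dynamics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

__all__ = [
    "PhysicalLIFParams",
    "MappingConfig",
    "LoihiNeuronConfig",
    "psp_peak_weight",
    "EXAMPLE_NEURONS",
    "load_params",
    "load_params_table",
]

#: hardware word sizes of the compartment model
STATE_BITS = 23          # membrane potential and current: signed, |x| < 2**23
DECAY_BITS = 12          # per-step decay constant: 1 .. 2**12 (0 encodes 2**12)
THETA_MANTISSA_BITS = 17  # threshold: 17 high bits of a 23-bit word
THETA_GRANULE = 1 << (STATE_BITS - THETA_MANTISSA_BITS)  # 64
BIAS_MANTISSA_MAX = 1 << DECAY_BITS   # 4096
BIAS_EXPONENT_MAX = 7

STATE_MAX = 1 << STATE_BITS           # 8388608
DECAY_MAX = 1 << DECAY_BITS           # 4096


def psp_peak_weight(C: float, tau_v: float, tau_syn: float, peak_mv: float = 1.0) -> float:
    """Synaptic weight (pA) for which a single afferent spike deflects the
    membrane potential by ``peak_mv`` at the peak of the postsynaptic potential.

    For an exponential postsynaptic current the subthreshold voltage response
    to one spike of weight ``w`` is the double exponential

        V(t) = (w / C) * (exp(-t/tau_v) - exp(-t/tau_syn)) / (1/tau_syn - 1/tau_v)

    peaking at ``t_p = ln(tau_v/tau_syn) / (1/tau_syn - 1/tau_v)``.  When the
    two time constants coincide, the response degenerates to the alpha
    function ``(w/C) * t * exp(-t/tau)`` with peak ``(w/C) * tau / e``.
    """
    if C <= 0 or tau_v <= 0 or tau_syn <= 0:
        raise ValueError("C, tau_v and tau_syn must be positive")
    if math.isclose(tau_v, tau_syn, rel_tol=1e-9):
        peak_factor = tau_v / math.e
    else:
        rate_gap = 1.0 / tau_syn - 1.0 / tau_v
        t_peak = math.log(tau_v / tau_syn) / rate_gap
        peak_factor = (math.exp(-t_peak / tau_v) - math.exp(-t_peak / tau_syn)) / rate_gap
    return peak_mv * C / peak_factor


@dataclass(frozen=True)
class PhysicalLIFParams:
    """One neuron's LIF parameters in physical units.

    Parameters
    ----------
    C : membrane capacitance, pF
    tau_v : membrane time constant, ms
    E_L : resting potential, mV
    V_r : reset potential, mV
    Theta : firing threshold, mV
    I_bias : constant bias current, pA
    tau_syn : synaptic current time constant, ms
    w_syn : synaptic weight amplitude, pA per afferent spike.  ``None``
        (the default) selects the weight that yields a 1 mV peak
        postsynaptic potential, via :func:`psp_peak_weight`.
    """

    C: float
    tau_v: float
    E_L: float
    V_r: float
    Theta: float
    I_bias: float = 0.0
    tau_syn: float = 5.0
    w_syn: float | None = None

    def __post_init__(self) -> None:
        for name in ("C", "tau_v", "E_L", "V_r", "Theta", "I_bias", "tau_syn"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.tau_v <= 0:
            raise ValueError("tau_v must be positive")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if not self.Theta > self.V_r:
            raise ValueError("threshold Theta must exceed the reset potential V_r")
        if self.w_syn is None:
            object.__setattr__(
                self, "w_syn", psp_peak_weight(self.C, self.tau_v, self.tau_syn)
            )
        elif not math.isfinite(self.w_syn):
            raise ValueError("w_syn must be finite")

    @property
    def R(self) -> float:
        """Membrane resistance tau_v / C, GΩ."""
        return self.tau_v / self.C

    @property
    def V_inf(self) -> float:
        """Bias-driven steady-state potential E_L + R * I_bias (mV),
        ignoring threshold and synaptic input."""
        return self.E_L + self.R * self.I_bias

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhysicalLIFParams":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class MappingConfig:
    """The two free precision knobs of the physical-to-hardware mapping.

    V_s : voltage scale, mV per hardware level (1/V_s levels represent 1 mV)
    dt : temporal scale, ms of model time per hardware time step
    """

    V_s: float = 1e-4
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.V_s) and self.V_s > 0):
            raise ValueError("V_s must be positive and finite")
        if not (math.isfinite(self.dt) and self.dt > 0):
            raise ValueError("dt must be positive and finite")

    def n_steps(self, duration_ms: float) -> int:
        return int(round(duration_ms / self.dt))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LoihiNeuronConfig:
    """Quantized hardware-level compartment parameters.

    All fields are dimensionless integers on the hardware scales: state in
    "levels" (V_s mV each), decays on the 12-bit scale where delta encodes a
    per-step multiplication by (4096 - delta)/4096, the bias as
    mantissa * 2**exponent levels per step.
    """

    delta_v: int
    delta_u: int
    theta_hw: int
    bias_mantissa: int = 0
    bias_exponent: int = 0
    w_hw: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.delta_v <= DECAY_MAX:
            raise ValueError(f"delta_v must be in [1, {DECAY_MAX}], got {self.delta_v}")
        if not 1 <= self.delta_u <= DECAY_MAX:
            raise ValueError(f"delta_u must be in [1, {DECAY_MAX}], got {self.delta_u}")
        if not 0 <= self.theta_hw < STATE_MAX:
            raise ValueError(f"theta_hw must be in [0, {STATE_MAX}), got {self.theta_hw}")
        if self.theta_hw % THETA_GRANULE:
            raise ValueError(
                f"theta_hw must be a multiple of {THETA_GRANULE} "
                f"({THETA_MANTISSA_BITS} high bits of a {STATE_BITS}-bit word)"
            )
        if abs(self.bias_mantissa) > BIAS_MANTISSA_MAX:
            raise ValueError("bias mantissa out of [-4096, 4096]")
        if not 0 <= self.bias_exponent <= BIAS_EXPONENT_MAX:
            raise ValueError("bias exponent out of [0, 7]")
        if abs(self.bias) >= STATE_MAX:
            raise ValueError("effective bias exceeds the 23-bit state range")
        if abs(self.w_hw) >= STATE_MAX:
            raise ValueError("w_hw exceeds the 23-bit state range")

    @property
    def bias(self) -> int:
        """Effective bias b = mantissa * 2**exponent, levels per step."""
        return self.bias_mantissa * (1 << self.bias_exponent)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LoihiNeuronConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: int(v) for k, v in d.items() if k in known})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LoihiNeuronConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: The two worked single-neuron parameter sets used throughout the docs,
#: examples and validation experiments (LIF fits to mouse V1 cells).
#: "bias_driven" is stimulated by a 200 pA constant current, "spike_driven"
#: by external spike trains with zero bias.
EXAMPLE_NEURONS: dict[str, PhysicalLIFParams] = {
    "bias_driven": PhysicalLIFParams(
        C=170.21, tau_v=25.0, E_L=-70.0, V_r=-70.0, Theta=-43.0, I_bias=200.0
    ),
    "spike_driven": PhysicalLIFParams(
        C=170.0, tau_v=22.0, E_L=-70.0, V_r=-70.0, Theta=-43.0, I_bias=0.0
    ),
}


def load_params(path: str | Path) -> PhysicalLIFParams:
    """Read one parameter set from a JSON file keyed by field name."""
    return PhysicalLIFParams.from_dict(json.loads(Path(path).read_text()))


def load_params_table(path: str | Path) -> list[PhysicalLIFParams]:
    """Read a parameter table (CSV or JSON list) into a list of parameter sets.

    CSV columns / JSON keys must match :class:`PhysicalLIFParams` field names
    with the standard units (pF, ms, mV, pA).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows: Iterable[dict] = json.loads(path.read_text())
    else:
        import pandas as pd

        rows = pd.read_csv(path).to_dict("records")
    return [PhysicalLIFParams.from_dict(row) for row in rows]
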