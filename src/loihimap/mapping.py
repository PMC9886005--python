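"""Translate physical-unit LIF parameters into quantized hardware parameters.

The forward voltage transform shifts the reset potential to zero and
re-scales by the voltage precision ``V_s``::

    v = (V - V_r) / V_s        (levels)
    V = v * V_s + V_r          (mV)

so one hardware level represents ``V_s`` mV.  Time is re-scaled by ``dt``
(ms per hardware step), which fixes the 12-bit per-step decay constants::

    delta = (dt / tau) * 2**12

The remaining quantizers enforce the hardware word layout: a 17-high-bit
threshold (multiples of 64 levels), a bias encoded as mantissa * 2**exponent
with mantissa in [-4096, 4096] and exponent in [0, 7], and 23-bit signed
state words.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    BIAS_EXPONENT_MAX,
    BIAS_MANTISSA_MAX,
    DECAY_MAX,
    STATE_MAX,
    THETA_GRANULE,
    LoihiNeuronConfig,
    MappingConfig,
    PhysicalLIFParams,
)

__all__ = [
    "MappingError",
    "to_levels",
    "from_levels",
    "compute_decay",
    "compute_bias",
    "quantize_bias",
    "quantize_threshold",
    "map_weight",
    "map_neuron",
]


class MappingError(ValueError):
    """A parameter cannot be represented within the hardware bit constraints."""


def to_levels(V, V_r: float, V_s: float):
    """Forward voltage transform ``(V - V_r) / V_s`` (mV -> levels, no rounding).

    Accepts scalars or arrays.
    """
    if V_s <= 0:
        raise MappingError("V_s must be positive")
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise MappingError("voltage must be finite")
    out = (V - V_r) / V_s
    return float(out) if out.ndim == 0 else out


def from_levels(v, V_r: float, V_s: float):
    """Inverse voltage transform ``v * V_s + V_r`` (levels -> mV)."""
    if V_s <= 0:
        raise MappingError("V_s must be positive")
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise MappingError("level value must be finite")
    out = v * V_s + V_r
    return float(out) if out.ndim == 0 else out


def compute_decay(tau: float, dt: float, clamp: bool = False) -> tuple[float, int]:
    """Map a time constant to the 12-bit decay, ``delta = (dt / tau) * 2**12``.

    Returns ``(raw, quantized)`` where ``quantized`` is the nearest integer in
    [1, 4096].  Nearest rounding minimizes the effective-time-constant error.

    Raises
    ------
    MappingError
        ``tau < dt`` ("decay overflow": the state would have to lose more
        than its full value per step) or ``tau > 4096 * dt`` ("time constant
        unrepresentable": the decay would round below the minimum of 1).
        With ``clamp=True`` a too-fast time constant saturates at full decay
        (delta = 4096) instead of raising, which mimics running the hardware
        out of its representable window.
    """
    if tau <= 0 or dt <= 0:
        raise MappingError("tau and dt must be positive")
    raw = dt / tau * DECAY_MAX
    if raw > DECAY_MAX:
        if clamp:
            return raw, DECAY_MAX
        raise MappingError(
            f"decay overflow: tau = {tau} ms is shorter than dt = {dt} ms/step"
        )
    if tau > DECAY_MAX * dt:
        raise MappingError(
            f"time constant unrepresentable: tau = {tau} ms exceeds "
            f"4096 * dt = {DECAY_MAX * dt} ms"
        )
    quantized = min(max(int(round(raw)), 1), DECAY_MAX)
    return raw, quantized


def compute_bias(params: PhysicalLIFParams, cfg: MappingConfig) -> float:
    """Per-step bias drive in levels:
    ``b = [I_bias / (C * V_s) + (E_L - V_r) / (tau_v * V_s)] * dt``.

    The second term is the reference drive that appears when the resting and
    reset potentials differ; it vanishes for neurons with E_L = V_r.
    """
    b = (
        params.I_bias / (params.C * cfg.V_s)
        + (params.E_L - params.V_r) / (params.tau_v * cfg.V_s)
    ) * cfg.dt
    if abs(b) >= STATE_MAX:
        raise MappingError(f"bias overflow: |b| = {abs(b):.4g} >= 2**23")
    return b


def quantize_bias(b: float) -> tuple[int, int]:
    """Encode a real-valued bias as ``(mantissa, exponent)`` with
    ``mantissa in [-4096, 4096]`` and ``exponent in [0, 7]``.

    Exhaustively minimizes ``|mantissa * 2**exponent - b|``; ties go to the
    smallest exponent (finest granularity).  The representation error is at
    most ``2**(exponent - 1)``.
    """
    if not math.isfinite(b):
        raise MappingError("bias must be finite")
    if abs(b) > BIAS_MANTISSA_MAX * 2**BIAS_EXPONENT_MAX:
        raise MappingError(
            f"bias unrepresentable: |b| = {abs(b):.4g} > 4096 * 2**7"
        )
    best: tuple[float, int, int] | None = None
    for exponent in range(BIAS_EXPONENT_MAX + 1):
        mantissa = int(round(b / (1 << exponent)))
        mantissa = min(max(mantissa, -BIAS_MANTISSA_MAX), BIAS_MANTISSA_MAX)
        err = abs(mantissa * (1 << exponent) - b)
        if best is None or err < best[0]:
            best = (err, exponent, mantissa)
    _, exponent, mantissa = best
    return mantissa, exponent


def quantize_threshold(theta_levels: float) -> int:
    """Round a threshold (levels) to the nearest multiple of 64, the
    granularity of a 17-bit mantissa placed in the high bits of the 23-bit
    state word."""
    if not math.isfinite(theta_levels) or not 0 <= theta_levels < STATE_MAX:
        raise MappingError(
            f"threshold unrepresentable: {theta_levels!r} outside [0, 2**23)"
        )
    mantissa = int(math.floor(theta_levels / THETA_GRANULE + 0.5))
    theta_hw = mantissa * THETA_GRANULE
    if theta_hw >= STATE_MAX:  # rounding up at the top of the range
        theta_hw -= THETA_GRANULE
    return theta_hw


def map_weight(w_syn: float, params: PhysicalLIFParams, cfg: MappingConfig) -> int:
    """Synaptic weight in integer levels added to the hardware current per
    afferent spike: ``round(w_syn * dt / (C * V_s))``.

    This is the image of a w_syn pA jump of the postsynaptic current under
    the same scaling that maps the bias current.
    """
    if not math.isfinite(w_syn):
        raise MappingError("w_syn must be finite")
    w_hw = int(round(w_syn * cfg.dt / (params.C * cfg.V_s)))
    if abs(w_hw) >= STATE_MAX:
        raise MappingError(f"weight unrepresentable: |{w_hw}| >= 2**23")
    return w_hw


def map_neuron(
    params: PhysicalLIFParams, cfg: MappingConfig, clamp_decay: bool = False
) -> LoihiNeuronConfig:
    """Compose the full physical-to-hardware translation for one neuron.

    Quantizes both decays, the threshold, the bias and the synaptic weight;
    any representability failure is re-raised naming the offending field.
    """
    try:
        _, delta_v = compute_decay(params.tau_v, cfg.dt, clamp=clamp_decay)
    except MappingError as e:
        raise MappingError(f"tau_v: {e}") from None
    try:
        _, delta_u = compute_decay(params.tau_syn, cfg.dt, clamp=clamp_decay)
    except MappingError as e:
        raise MappingError(f"tau_syn: {e}") from None
    try:
        mantissa, exponent = quantize_bias(compute_bias(params, cfg))
    except MappingError as e:
        raise MappingError(f"bias: {e}") from None
    try:
        theta_hw = quantize_threshold(to_levels(params.Theta, params.V_r, cfg.V_s))
    except MappingError as e:
        raise MappingError(f"threshold: {e}") from None
    try:
        w_hw = map_weight(params.w_syn, params, cfg)
    except MappingError as e:
        raise MappingError(f"weight: {e}") from None
    return LoihiNeuronConfig(
        delta_v=delta_v,
        delta_u=delta_u,
        theta_hw=theta_hw,
        bias_mantissa=mantissa,
        bias_exponent=exponent,
        w_hw=w_hw,
    )
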