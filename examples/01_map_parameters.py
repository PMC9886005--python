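"""Map a physical-unit LIF parameter set onto hardware words.

Takes the worked bias-driven neuron (tau_v = 25 ms, C = 170.21 pF,
threshold -43 mV, rest/reset -70 mV, 200 pA bias) and translates it at the
default precision (1 ms per step, 1e-4 mV per level).
"""

from loihimap import EXAMPLE_NEURONS, MappingConfig, map_neuron

params = EXAMPLE_NEURONS["bias_driven"]
cfg = MappingConfig(V_s=1e-4, dt=1.0)
hw = map_neuron(params, cfg)

print(f"physical: tau_v={params.tau_v} ms, C={params.C} pF, "
      f"Theta={params.Theta} mV, I_bias={params.I_bias} pA")
print(f"hardware: delta_v={hw.delta_v}  (per-step decay factor "
      f"{(4096 - hw.delta_v) / 4096:.6f}, vs exact e^(-dt/tau) = "
      f"{2.718281828459045 ** (-1 / params.tau_v):.6f})")
print(f"          theta_hw={hw.theta_hw} levels "
      f"(= {hw.theta_hw * cfg.V_s:.4f} mV above reset; multiple of 64)")
print(f"          bias = {hw.bias_mantissa} * 2^{hw.bias_exponent} = {hw.bias} "
      f"levels/step (target was {params.I_bias / (params.C * cfg.V_s):.1f})")

# delta_v encodes how much of the state leaks per step; theta_hw is the
# threshold distance from reset in 1e-4 mV units; the bias is the per-step
# drive the 200 pA current contributes, encoded as mantissa * 2^exponent.
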