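"""Validate the fixed-point emulator against exact integration for the two
worked single-neuron protocols: bias-current drive and external-spike drive.

Each run lasts 500 ms at dt = 1 ms/step and V_s = 1e-4 mV/level; the
emulator trace is inverse-mapped to mV before comparison.  The correlation
quantifies shape agreement, the RMSE absolute agreement in mV.
"""

from loihimap import (
    EXAMPLE_NEURONS,
    MappingConfig,
    frozen_spike_fixture,
    run_single_neuron,
)

cfg = MappingConfig(V_s=1e-4, dt=1.0)

bias = run_single_neuron(EXAMPLE_NEURONS["bias_driven"], None, cfg)
print("bias-current drive (200 pA):")
print(f"  V: pearson r = {bias.V.pearson_r:.6f}, rmse = {bias.V.rmse:.4f} mV "
      f"over n = {bias.V.n} samples")

spikes = run_single_neuron(
    EXAMPLE_NEURONS["spike_driven"], frozen_spike_fixture(), cfg
)
print("external-spike drive (5 sources, 11 events, ~1 mV PSPs):")
print(f"  V: pearson r = {spikes.V.pearson_r:.6f}, rmse = {spikes.V.rmse:.4f} mV")
print(f"  I: pearson r = {spikes.I.pearson_r:.6f}, rmse = {spikes.I.rmse:.4f} pA")

# r > 0.999 with sub-0.1 mV RMSE means the 12-bit decay, the quantized bias
# and the integer state dynamics reproduce the continuous model to within a
# fraction of a percent of the signal range.

# The same protocol with the threshold active (the spiking regime): the two
# backends fire at slightly different periods (their effective time
# constants differ by the decay quantization), so spike counts match but the
# sample-wise correlation drops — which is why the numeric validation above
# is defined on the subthreshold dynamics.
spiking = run_single_neuron(EXAMPLE_NEURONS["bias_driven"], None, cfg,
                            subthreshold=False)
print("bias-current drive, spiking regime:")
print(f"  spikes: reference {spiking.spike_count_ref}, "
      f"emulator {spiking.spike_count_emu}; "
      f"V pearson r = {spiking.V.pearson_r:.4f}")
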