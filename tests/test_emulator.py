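"""Tests of the bit-faithful fixed-point compartment emulator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from loihimap import (
    LoihiNeuronConfig,
    MappingConfig,
    StateOverflowError,
    decay_multiply,
    frozen_spike_fixture,
    map_neuron,
    schedule_spikes,
)
from loihimap.emulator import EmulatorState, NetworkSpec, run, run_network, step


def naive_transcription(cfg, increments, n_steps, v0=0, u0=0):
    """Independent unbounded-integer transcription of the hardware update
    rule, written directly from its definition: current decays then receives
    input, voltage decays then adds bias and current, strict threshold, reset
    to zero.  Plain Python ints, no shared code with the implementation."""
    v, u = int(v0), int(u0)
    b = cfg.bias_mantissa * 2**cfg.bias_exponent
    vs, us, spikes = [v], [u], []
    for k in range(1, n_steps + 1):
        u = (u * (4096 - cfg.delta_u)) // 4096 + int(increments[k - 1])
        v = (v * (4096 - cfg.delta_v)) // 4096 + b + u
        if v > cfg.theta_hw:
            v = 0
            spikes.append(k)
        vs.append(v)
        us.append(u)
    return vs, us, spikes


class TestDecayMultiply:
    def test_full_decay(self):
        for x in (0, 1, -5, 2**22):
            assert decay_multiply(x, 4096) == 0

    def test_exact_integer_case(self):
        assert decay_multiply(4096, 164) == 3932

    def test_floor_semantics_on_negatives(self):
        # -1 * 3932 = -3932; -3932 >> 12 floors to -1, not 0
        assert decay_multiply(-1, 164) == -1

    @given(x=st.integers(-(2**23) + 1, 2**23 - 1), delta=st.integers(1, 4096))
    def test_matches_floor_division_oracle(self, x, delta):
        assert decay_multiply(x, delta) == (x * (4096 - delta)) // 4096

    def test_delta_out_of_range(self):
        with pytest.raises(ValueError):
            decay_multiply(1, 0)
        with pytest.raises(ValueError):
            decay_multiply(1, 4097)


class TestStep:
    def test_zero_config_is_quiescent(self):
        cfg = LoihiNeuronConfig(delta_v=100, delta_u=100, theta_hw=640)
        state = EmulatorState()
        for _ in range(10):
            state, spiked = step(state, cfg)
            assert (state.v, state.u) == (0, 0)
            assert not spiked

    def test_bias_fixed_point_matches_reference_steady_state(
        self, bias_params, default_cfg
    ):
        """The unthresholded fixed point b*4096/delta_v inverse-maps to within
        0.1 mV of the exact-integration steady state E_L + R*I."""
        from loihimap import from_levels

        cfg_hw = map_neuron(bias_params, default_cfg)
        trace = run(cfg_hw, n_steps=2000, apply_threshold=False)
        v_star = trace.v[-1]
        # floor rounding of the decay product biases the integer fixed point
        # below b*4096/delta_v by at most one rounding unit per decay time,
        # i.e. 4096/delta_v levels
        ideal = cfg_hw.bias * 4096 / cfg_hw.delta_v
        assert ideal - 4096 / cfg_hw.delta_v - 1 <= v_star <= ideal + 1
        V_star = from_levels(float(v_star), bias_params.V_r, default_cfg.V_s)
        assert V_star == pytest.approx(bias_params.V_inf, abs=0.1)

    def test_overflow_raises_with_state_and_step(self):
        cfg = LoihiNeuronConfig(
            delta_v=1, delta_u=1, theta_hw=2**23 - 64, bias_mantissa=4096,
            bias_exponent=7,
        )
        with pytest.raises(StateOverflowError, match=r"v.*step"):
            run(cfg, n_steps=100, apply_threshold=False)

    def test_saturation_mode_clips(self):
        cfg = LoihiNeuronConfig(
            delta_v=1, delta_u=1, theta_hw=2**23 - 64, bias_mantissa=4096,
            bias_exponent=7,
        )
        trace = run(cfg, n_steps=100, saturate=True, apply_threshold=False)
        assert trace.v.max() == 2**23 - 1

    def test_reset_to_zero_and_strict_threshold(self):
        cfg = LoihiNeuronConfig(
            delta_v=4096, delta_u=4096, theta_hw=640, bias_mantissa=640,
            bias_exponent=0,
        )
        # v jumps to 640 = theta each step: never strictly above, never spikes
        trace = run(cfg, n_steps=20)
        assert len(trace.spike_steps) == 0
        cfg2 = LoihiNeuronConfig(
            delta_v=4096, delta_u=4096, theta_hw=640, bias_mantissa=641,
            bias_exponent=0,
        )
        trace2 = run(cfg2, n_steps=20)
        assert len(trace2.spike_steps) == 20
        assert np.all(trace2.v[1:] == 0)  # post-spike value is the reset 0


class TestBitOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_configs_match_naive_transcription(self, seed):
        rng = np.random.default_rng(seed)
        cfg = LoihiNeuronConfig(
            delta_v=int(rng.integers(1, 4097)),
            delta_u=int(rng.integers(1, 4097)),
            theta_hw=int(rng.integers(0, 2**17)) * 64,
            bias_mantissa=int(rng.integers(-400, 401)),
            bias_exponent=int(rng.integers(0, 4)),
        )
        increments = rng.integers(-50, 200, size=1001)
        trace = run(cfg, increments=increments, n_steps=1000,
                    v0=int(rng.integers(-1000, 1000)))
        vs, us, spikes = naive_transcription(cfg, increments, 1000, v0=trace.v[0])
        assert trace.v.tolist() == vs
        assert trace.u.tolist() == us
        assert trace.spike_steps.tolist() == spikes


class TestSchedule:
    def test_fixture_source_two_at_unit_step(self, fixture_spikes):
        sched = schedule_spikes(fixture_spikes.times_of(2), dt=1.0, n_steps=500)
        assert sorted(np.flatnonzero(sched)) == [53, 258, 300, 424, 457]

    def test_rounding_at_coarse_step(self, fixture_spikes):
        sched = schedule_spikes(fixture_spikes.times_of(0), dt=10.0, n_steps=50)
        assert list(np.flatnonzero(sched)) == [45]  # 446/10 rounds to 45

    def test_empty(self):
        sched = schedule_spikes([], dt=1.0, n_steps=10)
        assert sched.sum() == 0

    def test_coincident_arrivals_sum(self):
        sched = schedule_spikes([5.0, 5.2], dt=1.0, n_steps=10, weight=3)
        assert sched[5] == 6

    def test_beyond_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            schedule_spikes([600.0], dt=1.0, n_steps=500)


class TestRun:
    @pytest.mark.parametrize("dt,expected", [(0.1, 5000), (1.0, 500), (10.0, 50)])
    def test_step_count_for_500ms(self, dt, expected):
        cfg = MappingConfig(V_s=1e-4, dt=dt)
        assert cfg.n_steps(500.0) == expected

    def test_determinism(self, spike_params, default_cfg, fixture_spikes):
        from loihimap.emulator import _external_schedule

        cfg_hw = map_neuron(spike_params, default_cfg)
        inc = _external_schedule(cfg_hw, fixture_spikes, spike_params, default_cfg, 500)
        t1 = run(cfg_hw, increments=inc, n_steps=500)
        t2 = run(cfg_hw, increments=inc, n_steps=500)
        assert np.array_equal(t1.v, t2.v) and np.array_equal(t1.u, t2.u)

    def test_one_step_delivery_of_external_events(self, spike_params, default_cfg):
        """An event scheduled at step s reaches u at step s+1."""
        cfg_hw = map_neuron(spike_params, default_cfg)
        inc = schedule_spikes([100.0], dt=1.0, n_steps=200, weight=cfg_hw.w_hw)
        trace = run(cfg_hw, increments=inc, n_steps=200)
        assert trace.u[100] == 0
        assert trace.u[101] == cfg_hw.w_hw

    def test_euler_consistency_and_convergence(self):
        """With quantization disabled the emulator is forward Euler on the
        hardware scale, and its error against exact integration shrinks
        roughly linearly with dt."""
        from loihimap import PhysicalLIFParams, from_levels
        from loihimap.reference import SimulationGrid
        from loihimap.reference import run as ref_run

        from loihimap.emulator import run_euler

        p = PhysicalLIFParams(C=170.0, tau_v=22.0, E_L=-70.0, V_r=-70.0,
                              Theta=-43.0, I_bias=200.0)
        errors = {}
        for dt in (1.0, 0.5, 0.25):
            cfg = MappingConfig(V_s=1e-4, dt=dt)
            n = cfg.n_steps(200.0)
            trace = run_euler(p, cfg, n_steps=n)
            ref = ref_run(p, grid=SimulationGrid(200.0, dt), apply_threshold=False)
            V_emu = from_levels(trace.v, p.V_r, cfg.V_s)
            errors[dt] = np.max(np.abs(V_emu - ref.V))
        assert errors[0.5] < errors[1.0]
        assert errors[0.25] < errors[0.5]
        # first-order: error ratio near 2 when halving dt
        assert errors[1.0] / errors[0.5] == pytest.approx(2.0, rel=0.3)

    def test_unquantized_run_matches_hand_euler(self, bias_params, default_cfg):
        """run_euler reproduces v <- v(1 - dt/tau) + b + u term for term."""
        from loihimap.emulator import run_euler
        from loihimap.mapping import compute_bias

        trace = run_euler(bias_params, default_cfg, n_steps=50)
        v = 0.0
        b = compute_bias(bias_params, default_cfg)
        for k in range(1, 51):
            v = v * (1 - 1.0 / bias_params.tau_v) + b
            assert trace.v[k] == pytest.approx(v, rel=1e-12)


class TestNetwork:
    def _simple_cfg(self):
        return LoihiNeuronConfig(delta_v=200, delta_u=800, theta_hw=64 * 10,
                                 bias_mantissa=0, bias_exponent=0)

    def test_two_neuron_chain_delivery(self):
        """A presynaptic spike at step t increments postsynaptic u at t+1."""
        driver = LoihiNeuronConfig(delta_v=4096, delta_u=4096, theta_hw=64,
                                   bias_mantissa=100, bias_exponent=0)
        target = self._simple_cfg()
        net = NetworkSpec(configs=[driver, target], edges=[(0, 1, 50)])
        traces = run_network(net, n_steps=10)
        # driver fires every step (bias 100 > theta 64 after full decay)
        assert traces[0].spike_steps.tolist() == list(range(1, 11))
        assert traces[1].u[1] == 0
        assert traces[1].u[2] == 50  # first spike at step 1 lands at step 2

    def test_unconnected_network_equals_independent_runs(
        self, bias_params, spike_params, default_cfg
    ):
        c1 = map_neuron(bias_params, default_cfg)
        c2 = map_neuron(spike_params, default_cfg)
        net = NetworkSpec(configs=[c1, c2], edges=[])
        traces = run_network(net, n_steps=300)
        solo1 = run(c1, n_steps=300)
        solo2 = run(c2, n_steps=300)
        assert np.array_equal(traces[0].v, solo1.v)
        assert np.array_equal(traces[0].spike_steps, solo1.spike_steps)
        assert np.array_equal(traces[1].v, solo2.v)

    def test_network_matches_single_run_with_external(self, spike_params, default_cfg):
        """One compartment driven through the network external path equals the
        single-compartment run with the same schedule."""
        from loihimap.emulator import _external_schedule

        cfg_hw = map_neuron(spike_params, default_cfg)
        inc = _external_schedule(cfg_hw, frozen_spike_fixture(), spike_params,
                                 default_cfg, 500)
        net = NetworkSpec(configs=[cfg_hw], edges=[], external={0: inc})
        net_traces = run_network(net, n_steps=500)
        solo = run(cfg_hw, increments=inc, n_steps=500)
        assert np.array_equal(net_traces[0].v, solo.v)
        assert np.array_equal(net_traces[0].u, solo.u)
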