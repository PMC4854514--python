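"""Calcium sensors: DICR voltage dependence, nicotinic build-up, switches."""

import numpy as np
import pytest

from nmjhomeo.membrane import Drive, VoltageTrace, simulate_membrane, syn_waveform
from nmjhomeo.sensors import (
    DICRSensor,
    NicotinicCaSensor,
    compute_sensor_state,
    dicr_activation,
    dicr_signal,
    nicotinic_ca_signal,
)

DT = 0.05


def flat_trace(v=-80.0, duration=200.0, dt=DT):
    n = int(duration / dt)
    return VoltageTrace(dt=dt, V=np.full(n, v), spike_times=np.empty(0))


def spike_train_trace(cell, synapse, n_events=5, dt=DT):
    n = int(250.0 / dt)
    t = np.arange(n) * dt
    gsyn = np.zeros(n)
    for k in range(n_events):
        gsyn += synapse.evoked_peak_conductance * syn_waveform(t - (5 + k * 1000 / 30.0))
    trace = simulate_membrane(cell, Drive(gsyn=gsyn), duration=250.0, dt=dt)
    return trace, gsyn


class TestDICRActivation:
    def test_zero_below_and_at_threshold(self):
        assert dicr_activation(-80.0) == 0.0
        assert dicr_activation(-40.0) == 0.0  # "above -40 mV" is strict

    def test_half_activation_at_v_half(self):
        sensor = DICRSensor()
        assert dicr_activation(sensor.v_half) == pytest.approx(0.5)

    def test_monotone_and_saturating(self):
        v = np.linspace(-39.9, 60.0, 200)
        act = dicr_activation(v)
        assert np.all(np.diff(act) > 0)
        assert np.all(act < 1.0)


class TestDICRSignal:
    def test_flat_resting_trace_gives_zero(self):
        assert np.all(dicr_signal(flat_trace()) == 0.0)

    def test_ryanodine_blocks_signal_on_spike_train(self, cell, synapse):
        trace, _ = spike_train_trace(cell, synapse)
        assert len(trace.spike_times) == 5
        assert np.all(dicr_signal(trace, ryanodine_blocked=True) == 0.0)
        assert dicr_signal(trace).max() > 0

    def test_independent_of_external_calcium(self, cell, synapse):
        # the SR release depends on voltage only: same trace -> same signal,
        # regardless of the bath calcium switch consumed by the nicotinic arm
        trace, gsyn = spike_train_trace(cell, synapse)
        with_ca = compute_sensor_state(trace, gsyn, external_Ca_present=True)
        without_ca = compute_sensor_state(trace, gsyn, external_Ca_present=False)
        assert with_ca.S_dicr == pytest.approx(without_ca.S_dicr)
        assert with_ca.S_dicr > 0
        assert without_ca.S_nico == 0.0


class TestNicotinicSignal:
    def test_zero_without_conductance(self):
        trace = flat_trace()
        sig = nicotinic_ca_signal(trace, np.zeros_like(trace.V))
        assert np.all(sig == 0.0)

    def test_zero_in_calcium_free_medium(self):
        trace = flat_trace()
        n = len(trace.V)
        t = np.arange(n) * trace.dt
        gsyn = 20.0 * syn_waveform(t - 10.0)
        assert np.all(nicotinic_ca_signal(trace, gsyn, external_Ca_present=False) == 0.0)
        assert nicotinic_ca_signal(trace, gsyn).max() > 0

    def test_doubling_conductance_strictly_increases_buildup(self):
        trace = flat_trace(duration=600.0)
        n = len(trace.V)
        t = np.arange(n) * trace.dt
        shape = sum(syn_waveform(t - (10 + 100 * k)) for k in range(5))
        low = nicotinic_ca_signal(trace, 10.0 * shape)
        high = nicotinic_ca_signal(trace, 20.0 * shape)
        assert high[-1] > low[-1]

    def test_buildup_decreases_with_holding_depolarisation(self):
        # driving-force property: same conductance, more depolarised hold,
        # strictly smaller build-up
        n = int(300.0 / DT)
        t = np.arange(n) * DT
        gsyn = 15.0 * syn_waveform(t - 10.0)
        signals = []
        for hold in (-80.0, -50.0, -20.0):
            sig = nicotinic_ca_signal(flat_trace(v=hold, duration=300.0), gsyn)
            signals.append(sig.max())
        assert signals[0] > signals[1] > signals[2] > 0

    def test_linear_in_flux_gain(self):
        trace = flat_trace()
        n = len(trace.V)
        t = np.arange(n) * trace.dt
        gsyn = 15.0 * syn_waveform(t - 10.0)
        one = nicotinic_ca_signal(trace, gsyn, NicotinicCaSensor(flux_gain=2e-3))
        three = nicotinic_ca_signal(trace, gsyn, NicotinicCaSensor(flux_gain=6e-3))
        assert np.allclose(three, 3 * one)


class TestSensorState:
    def test_scale_separation_dicr_vs_nicotinic(self, cell, synapse):
        # per suprathreshold event the DICR transient dominates the slow
        # nicotinic build-up by at least 5x
        trace, gsyn = spike_train_trace(cell, synapse, n_events=1)
        state = compute_sensor_state(trace, gsyn)
        assert state.ca_dicr.max() >= 5 * state.ca_nico.max() > 0

    def test_dicr_linear_in_amplitude(self, cell, synapse):
        trace, gsyn = spike_train_trace(cell, synapse)
        one = compute_sensor_state(trace, gsyn, dicr=DICRSensor(amplitude=1.0))
        two = compute_sensor_state(trace, gsyn, dicr=DICRSensor(amplitude=2.0))
        assert two.S_dicr == pytest.approx(2 * one.S_dicr)

    def test_integrals_non_negative_invariant(self, cell, synapse):
        trace, gsyn = spike_train_trace(cell, synapse)
        state = compute_sensor_state(trace, gsyn)
        assert state.S_nico >= 0 and state.S_dicr >= 0
        assert np.all(state.ca_nico >= 0) and np.all(state.ca_dicr >= 0)
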