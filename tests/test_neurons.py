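"""Single-neuron dynamics: KLT current, maturation, activity
classification, kick-and-decay synapses, and the behavioral contract of
the two cell classes (mature burst, immature quiescence, noise-driven
spontaneous spiking)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hvcgrow.neurons import (
    MaturationParams,
    NeuronState,
    NoiseParams,
    classify_activity,
    decay_conductance,
    deliver_spike,
    klt_current,
    klt_gate_steady_state,
    simulate_interneuron,
    simulate_projection_neuron,
    update_maturation,
)


class TestKLT:
    def test_zero_gate_zero_current(self):
        assert klt_current(-40.0, 0.0) == 0.0

    def test_reversal_potential(self):
        assert klt_current(-90.0, 0.5) == 0.0

    def test_printed_formula(self):
        # G * l * (V - E_K) = 3.5 * 1 * (-40 + 90)
        assert klt_current(-40.0, 1.0) == pytest.approx(175.0)

    def test_gate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            klt_current(-40.0, 1.5)

    def test_gate_steady_state_midpoint(self):
        assert klt_gate_steady_state(-40.0) == pytest.approx(0.5)

    def test_gate_steady_state_saturation(self):
        assert klt_gate_steady_state(200.0) == pytest.approx(1.0, abs=1e-9)
        assert klt_gate_steady_state(-400.0) == pytest.approx(0.0, abs=1e-9)

    def test_gate_steady_state_value(self):
        assert klt_gate_steady_state(-35.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0))
        )


class TestSynapseKinetics:
    def test_kick_adds(self):
        s = NeuronState()
        deliver_spike(s, 2.0)
        assert s.g_exc_d == 2.0

    def test_kicks_are_additive(self):
        s = NeuronState()
        deliver_spike(s, 1.5)
        deliver_spike(s, 1.5)
        assert s.g_exc_d == 3.0

    def test_exponential_decay(self):
        g = decay_conductance(2.0, 5.0, 5.0)
        assert g == pytest.approx(2.0 * np.exp(-1.0))

    def test_negative_kick_rejected(self):
        with pytest.raises(ValueError):
            deliver_spike(NeuronState(), -1.0)

    @given(
        st.lists(
            st.tuples(st.floats(0.0, 10.0), st.floats(0.1, 50.0)),
            min_size=1, max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_superposition_of_kicks(self, kicks):
        """Conductance after k kicks equals the sum of k decaying
        exponentials (linearity of kick-and-decay)."""
        tau = 5.0
        t_end = 60.0
        g = 0.0
        t_prev = 0.0
        # simulate sequential kicks at 1 ms apart
        times = np.cumsum([gap for gap, _ in kicks])
        for (gap, amp), t in zip(kicks, times):
            g = decay_conductance(g, t - t_prev, tau)
            g += amp
            t_prev = t
        g = decay_conductance(g, t_end - t_prev, tau)
        expected = sum(
            amp * np.exp(-(t_end - t) / tau)
            for (_, amp), t in zip(kicks, times)
        )
        assert g == pytest.approx(expected, rel=1e-12)


class TestMaturation:
    def test_fixed_point(self):
        s = NeuronState(g_ca_cond=55.0, e_leak=-80.0)
        update_maturation(s, 500.0, 0.5)
        assert s.g_ca_cond == pytest.approx(55.0)
        assert s.e_leak == pytest.approx(-80.0)

    def test_one_time_constant(self):
        s = NeuronState(g_ca_cond=0.0, e_leak=-55.0)
        update_maturation(s, 500.0, 500.0)
        assert s.e_leak == pytest.approx(-80.0 + 25.0 * np.exp(-1.0))
        assert s.g_ca_cond == pytest.approx(55.0 * (1 - np.exp(-1.0)))

    def test_limit_is_mature(self):
        s = NeuronState(g_ca_cond=0.0, e_leak=-55.0)
        for _ in range(200):
            update_maturation(s, 500.0, 500.0)
        assert s.g_ca_cond == pytest.approx(55.0)
        assert s.e_leak == pytest.approx(-80.0)

    @given(
        st.lists(st.floats(0.01, 5000.0), min_size=1, max_size=20),
        st.floats(0.0, 55.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_closed_form_for_any_increment_sequence(
        self, increments, g0
    ):
        """The discrete update equals the analytic exponential solution
        to machine precision for any sequence of clock steps."""
        tau = 50_000.0
        s = NeuronState(g_ca_cond=g0, e_leak=-55.0)
        for dt in increments:
            update_maturation(s, tau, dt)
        total = sum(increments)
        assert s.g_ca_cond == pytest.approx(
            55.0 + (g0 - 55.0) * np.exp(-total / tau), rel=1e-9
        )

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            update_maturation(NeuronState(), 0.0, 0.5)


class TestActivityClassification:
    def test_reliable_above_half(self):
        h = np.zeros(1000)
        h[:600] = 1
        assert classify_activity(h) == "reliable"

    def test_spontaneous_below_half(self):
        h = np.zeros(1000)
        h[:400] = 1
        assert classify_activity(h) == "spontaneous"

    def test_exactly_half_is_spontaneous(self):
        h = np.zeros(1000)
        h[:500] = 1
        assert classify_activity(h) == "spontaneous"

    def test_never_spiking(self):
        assert classify_activity(np.zeros(1000)) == "spontaneous"

    def test_short_history_uses_available_trials(self):
        assert classify_activity([1, 1, 0]) == "reliable"
        assert classify_activity([1, 0]) == "spontaneous"

    def test_only_recent_window_counts(self):
        h = np.concatenate([np.ones(600), np.zeros(1000)])
        assert classify_activity(h) == "spontaneous"

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            classify_activity([])

    def test_selects_time_constant(self):
        m = MaturationParams()
        assert m.tau_fast_s == 500.0
        assert m.tau_slow_s == 50_000.0


class TestProjectionNeuronBehavior:
    def test_mature_burst_on_strong_kick(self):
        """A 300 nS dendritic kick elicits a tight somatic burst within
        10 ms of delivery."""
        spikes, _ = simulate_projection_neuron(
            120.0, mature=True, kicks=[(50.0, 300.0)]
        )
        assert len(spikes) >= 3
        assert spikes[0] - 50.0 < 10.0
        assert np.all(np.diff(spikes) < 5.0)

    def test_immature_stays_at_rest_without_noise(self):
        spikes, _ = simulate_projection_neuron(500.0, mature=False)
        assert len(spikes) == 0

    def test_immature_never_bursts_like_mature(self):
        """Under identical stimulation the immature cell (no dendritic
        Ca) fires at most sparse single spikes with a much larger first
        ISI than the mature burst."""
        mat, _ = simulate_projection_neuron(
            120.0, mature=True, kicks=[(50.0, 300.0)]
        )
        imm, _ = simulate_projection_neuron(
            120.0, mature=False, kicks=[(50.0, 300.0)]
        )
        assert len(imm) < len(mat)
        if len(imm) >= 2:
            assert np.diff(imm)[0] > np.diff(mat)[0]

    def test_burst_is_all_or_none_in_kick_strength(self):
        """Spike count is a step-like non-decreasing function of the
        kick amplitude (dendritic Ca spike threshold)."""
        counts = []
        for kick in (5.0, 15.0, 25.0, 35.0, 60.0, 120.0, 300.0):
            sp, _ = simulate_projection_neuron(
                120.0, mature=True, kicks=[(50.0, kick)]
            )
            counts.append(len(sp))
        counts = np.array(counts)
        assert counts[0] == 0
        assert counts[-1] >= 3
        big = counts[counts >= 3]
        # once the dendritic spike fires, the burst is stereotyped
        assert big.size >= 2 and np.ptp(big) <= 2

    def test_spike_times_stable_under_dt_halving(self):
        """Standard burst test: halving dt moves spike times < 0.01 ms."""
        a, _ = simulate_projection_neuron(
            120.0, dt=0.02, mature=True, kicks=[(50.0, 300.0)]
        )
        b, _ = simulate_projection_neuron(
            120.0, dt=0.01, mature=True, kicks=[(50.0, 300.0)]
        )
        assert len(a) == len(b)
        assert np.max(np.abs(a - b)) < 0.01

    def test_spontaneous_rate_monotone_in_leak_reversal(self):
        """Spontaneous rate decreases as E_L matures from -55 to -80 mV
        (activity fades with age)."""
        rates = []
        for el in (-55.0, -62.0, -70.0, -80.0):
            sp, _ = simulate_projection_neuron(
                60_000.0, e_leak=el, g_ca=0.0, noise=NoiseParams(), seed=9
            )
            rates.append(len(sp) / 60.0)
        assert rates[0] > 0.2
        for a, b in zip(rates, rates[1:]):
            assert b <= a + 0.05
        assert rates[-1] < 0.05


class TestInterneuronBehavior:
    def test_silent_without_noise(self):
        spikes = simulate_interneuron(5000.0, with_noise=False)
        assert len(spikes) == 0

    def test_spontaneous_rate_near_10_hz(self):
        spikes = simulate_interneuron(60_000.0, seed=3)
        assert len(spikes) / 60.0 == pytest.approx(10.0, abs=2.5)

    def test_strong_drive_fires_well_above_baseline(self):
        base = simulate_interneuron(10_000.0, seed=5)
        driven = simulate_interneuron(10_000.0, drive_exc=0.3, seed=5)
        assert len(driven) > 5 * max(len(base), 1)
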