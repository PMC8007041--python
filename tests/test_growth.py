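"""Trial loop mechanics: burst segmentation, turnover and stopping
rules, recruitment-trial estimation, and small-network integration
behavior of the growth engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hvcgrow.geometry import ConnectivityParams
from hvcgrow.growth import (
    Network,
    TrialConfig,
    TurnoverParams,
    detect_bursts,
    estimate_recruitment_trial,
    stopping_check,
    turnover_check,
)
from hvcgrow.neurons import NoiseParams, simulate_projection_neuron


class TestDetectBursts:
    def test_gap_rule_splits(self):
        bursts = detect_bursts(np.array([10.0, 22.0, 60.0]))
        assert len(bursts) == 2
        assert bursts[0].onset_ms == 10.0
        assert bursts[0].first_isi_ms == pytest.approx(12.0)
        assert bursts[1].onset_ms == 60.0
        assert bursts[1].first_isi_ms is None

    def test_empty(self):
        assert detect_bursts(np.array([])) == []

    def test_singleton(self):
        b = detect_bursts(np.array([5.0]))
        assert len(b) == 1
        assert b[0].onset_ms == 5.0
        assert b[0].first_isi_ms is None

    def test_exact_gap_boundary_joins(self):
        b = detect_bursts(np.array([0.0, 30.0]))
        assert len(b) == 1

    def test_duration_rule_variant(self):
        # 0,20,40: gap rule joins all; duration rule splits at 40
        t = np.array([0.0, 20.0, 40.0])
        assert len(detect_bursts(t)) == 1
        assert len(detect_bursts(t, duration_rule=True)) == 2

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts(np.array([5.0, 1.0]))

    @given(
        st.lists(st.floats(0.0, 500.0), min_size=1, max_size=30),
        st.floats(-200.0, 200.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_shift_invariant(self, times, shift):
        t = np.sort(np.asarray(times))
        base = detect_bursts(t)
        shifted = detect_bursts(t + shift)
        assert len(base) == len(shifted)
        for a, b in zip(base, shifted):
            assert len(a.spikes) == len(b.spikes)
            assert b.onset_ms == pytest.approx(a.onset_ms + shift)


class TestTurnoverRule:
    def test_totally_silent_replaced(self):
        h = np.zeros(4000)
        assert turnover_check(h) is True

    def test_boundary_is_strict(self):
        h = np.zeros(4000)
        h[:80] = 1
        assert turnover_check(h) is False  # "less than 80" is strict
        h[0] = 0
        assert turnover_check(h) is True   # 79 spiking trials

    def test_young_neurons_exempt(self):
        assert turnover_check(np.zeros(3999)) is False


class TestStoppingRule:
    def test_constant_count_stops(self):
        assert stopping_check([3060] * 10_000, 10_000) is True

    def test_recent_change_continues(self):
        counts = [5] * 9_500 + [6] * 500
        assert stopping_check(counts, 10_000) is False

    def test_short_log_continues(self):
        assert stopping_check([5] * 100, 10_000) is False


class TestRecruitmentTrial:
    def test_step_to_reliable(self):
        # silent through trial k-1, one spike per trial from trial k on
        k = 40
        counts = np.concatenate([np.zeros(k - 1), np.ones(100)])
        assert estimate_recruitment_trial(counts) == k + 24

    def test_reliable_from_start(self):
        assert estimate_recruitment_trial(np.ones(100)) == 25

    def test_never_reliable_raises(self):
        with pytest.raises(ValueError):
            estimate_recruitment_trial(np.zeros(200))


@pytest.fixture(scope="module")
def tiny_net():
    """A very small network for fast engine-level checks."""
    return Network(
        n_ra=25, n_int=8, radius_um=30.0, seed=7,
        trial=TrialConfig(
            duration_ms=200.0, dt_ms=0.02, kick_window_ms=(40.0, 80.0)
        ),
        conn=ConnectivityParams(
            sigma_ra_to_int_um=15.0, sigma_int_to_ra_um=10.4,
            velocity_um_per_ms=11.5,
        ),
        turnover=TurnoverParams(
            window_trials=50, silence_threshold=2, stopping_window=100
        ),
    )


class TestNetworkEngine:
    def test_construction_invariants(self, tiny_net):
        net = tiny_net
        assert net.layout.min_geodesic_gap() >= net.layout.exclusion_um
        assert (net.w_rr == 0).all()          # no RA->RA edges at start
        assert net.el[net.training].max() == -80.0
        assert (net.gca[net.training] == 55.0).all()
        pool = ~net.is_training
        assert (net.el[pool] == -55.0).all()
        assert (net.gca[pool] == 0.0).all()

    def test_training_neurons_burst_at_kick(self, tiny_net):
        rec = tiny_net.run_trial(plastic=False, trial_seed=12345)
        for t in tiny_net.training:
            sp = rec.spike_times[rec.spike_ids == t]
            assert len(sp) >= 3
            assert 0 < sp.min() - rec.kick_time_ms < 10.0

    def test_trial_is_deterministic_given_seed(self, tiny_net):
        a = tiny_net.run_trial(plastic=False, trial_seed=77)
        b = tiny_net.run_trial(plastic=False, trial_seed=77)
        np.testing.assert_array_equal(a.spike_times, b.spike_times)
        np.testing.assert_array_equal(a.spike_ids, b.spike_ids)
        assert a.kick_time_ms == b.kick_time_ms

    def test_no_spikes_without_noise_or_kick(self):
        net = Network(
            n_ra=10, n_int=4, radius_um=25.0, seed=3,
            trial=TrialConfig(
                duration_ms=150.0, dt_ms=0.02,
                kick_window_ms=(40.0, 80.0), kick_ns=0.0,
            ),
            noise=NoiseParams(scale=0.0),
        )
        net.inter.rate_exc_khz = 0.0
        net.inter.rate_inh_khz = 0.0
        rec = net.run_trial(plastic=False)
        assert len(rec.spike_times) == 0
        assert len(rec.int_spike_times) == 0

    def test_network_burst_matches_isolated_neuron(self):
        """The network kernel and the single-neuron path integrate the
        same model: an isolated mature neuron kicked inside the network
        reproduces the stand-alone burst spike times to ~0.1 ms."""
        net = Network(
            n_ra=10, n_int=4, radius_um=25.0, seed=3,
            trial=TrialConfig(
                duration_ms=150.0, dt_ms=0.02,
                kick_window_ms=(50.0, 50.0),
            ),
            noise=NoiseParams(scale=0.0),
        )
        net.inter.rate_exc_khz = 0.0
        net.inter.rate_inh_khz = 0.0
        net.w_ra_int[:] = 0.0
        net.w_int_ra[:] = 0.0
        # make every neuron immature except the training set
        rec = net.run_trial(plastic=False)
        target = net.training[0]
        net_spikes = np.sort(
            rec.spike_times[rec.spike_ids == target]
        )
        iso, _ = simulate_projection_neuron(
            150.0, mature=True,
            kicks=[(rec.kick_time_ms, 300.0)], correctors=1,
        )
        assert len(net_spikes) == len(iso)
        np.testing.assert_allclose(net_spikes, iso, atol=0.1)

    def test_plasticity_emerges_from_training(self, tiny_net):
        """Silent connections appear out of the training neurons within
        a few trials of stimulation (weights start at zero)."""
        for _ in range(15):
            rec = tiny_net.run_trial()
            tiny_net.end_of_trial_update(rec)
        assert (tiny_net.w_rr > 0).sum() > 0
        # edges out of training neurons dominate early growth
        from_training = tiny_net.w_rr[tiny_net.training, :].sum()
        assert from_training > 0

    def test_end_of_trial_decays_all_weights(self, tiny_net):
        w_before = tiny_net.w_rr.copy()
        rec = tiny_net.run_trial(plastic=False, trial_seed=999)
        tiny_net.end_of_trial_update(rec)
        pos = w_before > 0
        assert np.all(
            tiny_net.w_rr[pos] <= np.maximum(w_before[pos] - 0.01, 0.0)
            + 1e-12
        )

    def test_replacement_resets_neuron(self, tiny_net):
        net = tiny_net
        i = int(np.flatnonzero(~net.is_training)[0])
        old_pos = net.pos_ra[i].copy()
        net.w_rr[i, :5] = 2.0
        net.w_rr[:5, i] = 2.0
        net._replace_neuron(i)
        assert net.el[i] == -55.0
        assert net.gca[i] == 0.0
        assert net.age[i] == 0
        assert (net.w_rr[i, :] == 0).all()
        assert (net.w_rr[:, i] == 0).all()
        assert not np.allclose(net.pos_ra[i], old_pos)
        assert net.birth_trial[i] == net.trial_index + 1
        assert net.layout.min_geodesic_gap() >= net.layout.exclusion_um


class TestRecruitmentIdentification:
    def test_strict_threshold(self):
        net = Network.__new__(Network)
        net.n_ra = 3
        counts = np.zeros((100, 3))
        counts[:96, 0] = 1   # 96/100 -> recruited
        counts[:95, 1] = 1   # 95/100 -> not recruited
        recs = [
            type("R", (), {"spike_counts": row})() for row in counts
        ]
        out = Network.identify_recruited(net, records=recs)
        assert list(out) == [0]
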