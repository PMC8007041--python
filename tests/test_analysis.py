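"""Analysis statistics: burst density/CV, jitter, Jaccard similarity,
trapezoid areas, inhibition metrics, correlation, and topology export."""

import networkx as nx
import numpy as np
import pytest

from hvcgrow import analysis as A
from hvcgrow.growth import TrialRecord


def make_record(trial, kick, onsets):
    onsets = np.asarray(onsets, dtype=float)
    ids = np.arange(len(onsets), dtype=np.int32)
    keep = np.isfinite(onsets)
    return TrialRecord(
        trial=trial, kick_time_ms=kick,
        spike_times=onsets[keep], spike_ids=ids[keep],
        int_spike_times=np.empty(0), int_spike_ids=np.empty(0, np.int32),
        onset_times=onsets[keep], onset_ids=ids[keep],
        spike_counts=keep.astype(np.int32),
    )


class TestBurstDensity:
    def test_uniform_counts_zero_cv(self):
        onsets = np.repeat(np.arange(0.5, 50.0, 1.0), 3)
        _, counts, cv = A.burst_density(onsets, 1.0, t_range=(0.0, 50.0))
        assert cv == pytest.approx(0.0)

    def test_alternating_counts(self):
        # bins 0-1 and 2-3... hold 2 onsets, odd bins none: mean 1, std 1
        onsets = np.concatenate(
            [[k + 0.4, k + 0.6] for k in range(0, 20, 2)]
        )
        _, counts, cv = A.burst_density(
            onsets, 1.0, t_range=(0.0, 20.0)
        )
        assert cv == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        onsets = rng.uniform(0, 100, 300)
        _, c1, cv1 = A.burst_density(onsets, 1.0, t_range=(0, 100))
        _, c3, cv3 = A.burst_density(
            np.repeat(onsets, 3), 1.0, t_range=(0, 100)
        )
        np.testing.assert_array_equal(c3, 3 * c1)
        assert cv3 == pytest.approx(cv1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            A.burst_density(np.array([]), 1.0)


class TestJitter:
    def test_identical_onsets_zero(self):
        recs = [make_record(k, 0.0, [10.0, 20.0]) for k in range(5)]
        jit, n = A.burst_jitter(recs, 2)
        np.testing.assert_allclose(jit, 0.0)
        assert (n == 5).all()

    def test_hand_computed_std(self):
        recs = [
            make_record(0, 0.0, [9.0]),
            make_record(1, 0.0, [11.0]),
        ]
        jit, _ = A.burst_jitter(recs, 1)
        assert jit[0] == pytest.approx(1.0)  # population convention

    def test_common_shift_invariance(self):
        """Shifting kick and onsets together leaves jitter unchanged."""
        rng = np.random.default_rng(0)
        base = rng.uniform(10, 50, (6, 3))
        recs_a = [make_record(k, 0.0, row) for k, row in enumerate(base)]
        recs_b = [
            make_record(k, 30.0, row + 30.0)
            for k, row in enumerate(base)
        ]
        ja, _ = A.burst_jitter(recs_a, 3)
        jb, _ = A.burst_jitter(recs_b, 3)
        np.testing.assert_allclose(ja, jb, atol=1e-9)

    def test_missing_neuron_counted(self):
        recs = [
            make_record(0, 0.0, [5.0, np.nan]),
            make_record(1, 0.0, [6.0, np.nan]),
        ]
        jit, n = A.burst_jitter(recs, 2)
        assert n[1] == 0
        assert np.isnan(jit[1])


class TestJaccard:
    def test_identical_sets(self):
        assert A.jaccard({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint_sets(self):
        assert A.jaccard({1, 2}, {3, 4}) == 0.0

    def test_partial_overlap(self):
        assert A.jaccard({1, 2, 3}, {2, 3, 4}) == pytest.approx(0.5)

    def test_one_empty(self):
        assert A.jaccard(set(), {1}) == 0.0

    def test_matches_brute_force_enumeration(self):
        """Mean similarity agrees with explicit pair enumeration on a
        small random graph."""
        rng = np.random.default_rng(9)
        n = 15
        pre = [set(rng.choice(20, rng.integers(0, 6), replace=False))
               for _ in range(n)]
        onsets = rng.uniform(0, 30, n)
        tw = 10.0
        curve = A.input_similarity(pre, onsets, tw)
        # brute force
        per = []
        for i in range(n):
            vals = [
                len(pre[i] & pre[j]) / len(pre[i] | pre[j])
                for j in range(n)
                if j != i and abs(onsets[j] - onsets[i]) < tw / 2
                and (pre[i] or pre[j])
            ]
            if vals:
                per.append(np.mean(vals))
        assert curve.mean_jaccard == pytest.approx(np.mean(per))


class TestTrapezoidArea:
    def test_constant_trace(self):
        tr = np.full(101, 2.0)
        assert A.trapezoid_area(tr, 1.0, 10.0, 40.0) == pytest.approx(60.0)

    def test_step_trace_closed_form(self):
        # 0 for t<50, 1 for t>=50, window [40, 60] -> area 10 + the
        # 0->1 interpolation triangle on [49, 50] (0.5)
        tr = np.concatenate([np.zeros(50), np.ones(51)])
        area = A.trapezoid_area(tr, 1.0, 40.0, 60.0)
        assert area == pytest.approx(10.0 + 0.5)

    def test_window_clipping(self):
        tr = np.ones(11)
        assert A.trapezoid_area(tr, 1.0, -5.0, 20.0) == pytest.approx(10.0)

    def test_piecewise_linear_exact(self):
        # trapezoid rule is exact for piecewise-linear traces
        t = np.arange(0, 21.0)
        tr = 3.0 * t
        assert A.trapezoid_area(tr, 1.0, 2.0, 10.0) == pytest.approx(
            1.5 * (10.0**2 - 2.0**2)
        )


class TestInhibitionMetrics:
    def test_rectangle_delta(self):
        """Recruited at 1, reference at 2 over a 30 ms window: area
        difference is -30."""
        tr = np.ones(200)
        ref = np.full(200, 2.0)
        d = A.ltp_window_delta(
            tr, ref, 1.0, np.array([50.0]), np.array([3.0])
        )
        assert d == pytest.approx(-30.0)

    def test_identical_traces_zero(self):
        tr = np.sin(np.linspace(0, 3, 300)) + 2
        d = A.ltp_window_delta(
            tr, tr, 0.5, np.array([20.0, 40.0]), np.array([1.0, 2.5])
        )
        assert d == pytest.approx(0.0)

    def test_no_parent_bursts_raises(self):
        with pytest.raises(ValueError):
            A.ltp_window_delta(
                np.ones(10), np.ones(10), 1.0, np.array([]), np.array([])
            )

    def test_pre_post_constant_trace(self):
        tr = np.full(100, 1.5)
        a, b = A.pre_post_burst_inhibition(tr, 1.0, 50.0)
        assert a == pytest.approx(b)

    def test_pre_post_step(self):
        tr = np.concatenate([np.zeros(50), np.ones(50)])
        a, b = A.pre_post_burst_inhibition(tr, 1.0, 50.0)
        # interpolation triangle before the onset contributes 0.5
        assert a == pytest.approx(0.5)
        assert b == pytest.approx(10.0)


class TestBirthBurstCorrelation:
    def test_perfect_order(self):
        rho, p, tab = A.birth_burst_correlation(
            np.arange(10), np.arange(10) * 3.0 + 5
        )
        assert rho == pytest.approx(1.0)
        assert len(tab) == 10

    def test_shuffled_is_null(self):
        rng = np.random.default_rng(2)
        births = np.arange(200)
        bursts = rng.permutation(200).astype(float)
        rho, p, _ = A.birth_burst_correlation(births, bursts)
        assert abs(rho) < 0.15

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            A.birth_burst_correlation([1, 2], [3.0, 4.0])


class TestTopologyExport:
    @pytest.fixture()
    def grown_net(self):
        from hvcgrow.geometry import ConnectivityParams
        from hvcgrow.growth import Network, TrialConfig

        net = Network(
            n_ra=20, n_int=6, radius_um=28.0, seed=2,
            trial=TrialConfig(duration_ms=100.0, dt_ms=0.04,
                              kick_window_ms=(20.0, 40.0)),
            conn=ConnectivityParams(sigma_ra_to_int_um=14.0,
                                    sigma_int_to_ra_um=9.7,
                                    velocity_um_per_ms=10.8),
        )
        rng = np.random.default_rng(0)
        pre = rng.integers(0, 20, 30)
        post = rng.integers(0, 20, 30)
        keep = pre != post
        net.w_rr[pre[keep], post[keep]] = rng.uniform(1.1, 3.9, keep.sum())
        return net

    def test_graphml_roundtrip(self, grown_net, tmp_path):
        path = tmp_path / "g.graphml"
        A.export_topology(grown_net, str(path))
        g = nx.read_graphml(path)
        pre, post = grown_net.super_edges()
        assert g.number_of_edges() == len(pre)
        edges = {(int(u), int(v)) for u, v in g.edges}
        assert edges == set(zip(pre.tolist(), post.tolist()))

    def test_pajek_and_csv(self, grown_net, tmp_path):
        A.export_topology(grown_net, str(tmp_path / "g.net"), "pajek")
        A.export_topology(grown_net, str(tmp_path / "g.csv"), "csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "g.csv")
        assert len(df) == len(grown_net.super_edges()[0])
        assert set(df.columns) == {
            "pre", "post", "weight_ns", "delay_ms", "state"
        }

    def test_empty_graph_is_valid(self, grown_net, tmp_path):
        grown_net.w_rr[:] = 0.0
        path = tmp_path / "empty.graphml"
        A.export_topology(grown_net, str(path))
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == grown_net.n_ra
        assert g.number_of_edges() == 0

    def test_unknown_format_lists_supported(self, grown_net, tmp_path):
        with pytest.raises(ValueError, match="graphml"):
            A.export_topology(grown_net, str(tmp_path / "x"), "dot")
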