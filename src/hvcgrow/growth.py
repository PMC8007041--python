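"""The growth engine: repeated stimulation trials that wire projection
neurons into a feedforward chain.

Each trial runs the full network for a fixed duration (default 500 ms at
dt = 0.02 ms). All dynamical variables start from rest. At a random time
within the trial the ten mature training neurons receive a synchronous
300 nS excitatory conductance kick to their dendrites and burst; spikes
propagate along synapses with per-edge axonal delays. Whenever a
projection neuron starts a new burst (first spike after a >30 ms silent
gap), every afferent and efferent projection-to-projection synapse is
updated by the BTDP rule using the most recent burst onsets, with the
presynaptic onset taken at its *arrival* time (emission + delay). After
the trial: all weights suffer the constant potentiation decay, axon
remodeling is re-checked, each pool neuron's maturation variables relax
toward their mature values (fast if it spiked reliably, slowly
otherwise), and persistently silent pool neurons are replaced by new
immature neurons at fresh random positions (neuronal turnover). Growth
stops when the supersynapse count has been constant for the stopping
window.

Saturation/withdrawal bookkeeping: a neuron holding >= N_s supersynapses
is *saturated*; its sub-supersynaptic efferents are withdrawn — they
deliver no conductance and are excluded from BTDP but still decay. The
withdrawn state is purely derived (saturated presynaptic neuron + weight
below the supersynapse threshold), so losing a supersynapse
automatically restores the remaining efferents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from hvcgrow import geometry
from hvcgrow.geometry import (
    ConnectivityParams,
    assign_delays,
    connection_probability,
    pairwise_geodesic,
)
from hvcgrow.neurons import (
    A_DEND,
    A_SOMA,
    C_M,
    NS_TO_MSCM2_DEND,
    SPIKE_THRESHOLD,
    TAB_RA_TAU_H,
    TAB_RA_TAU_N,
    InterneuronParams,
    MaturationParams,
    NoiseParams,
    ProjectionNeuronParams,
    SynapseKinetics,
    int_step,
    ra_step,
    settle_int,
    settle_ra,
)
from hvcgrow.plasticity import BTDPParams, StructuralParams

__all__ = [
    "TrialConfig",
    "TurnoverParams",
    "BurstRecord",
    "GrowthLog",
    "TrialRecord",
    "Network",
    "detect_bursts",
    "turnover_check",
    "stopping_check",
    "estimate_recruitment_trial",
]


@dataclass
class TrialConfig:
    """Per-trial stimulation protocol and integration settings."""

    duration_ms: float = 500.0
    dt_ms: float = 0.02
    kick_ns: float = 300.0
    kick_window_ms: tuple[float, float] = (100.0, 400.0)
    n_training: int = 10
    burst_max_gap_ms: float = 30.0
    #: if True, a burst is a spike group of total duration <= max gap
    #: instead of consecutive-gap-bounded (config variant)
    burst_duration_rule: bool = False

    def __post_init__(self) -> None:
        if self.dt_ms <= 0 or self.duration_ms <= 0:
            raise ValueError("duration and dt must be positive")
        lo, hi = self.kick_window_ms
        if not 0 <= lo <= hi <= self.duration_ms:
            raise ValueError("kick window must lie inside the trial")


@dataclass
class TurnoverParams:
    """Replacement rule for persistently silent pool neurons."""

    window_trials: int = 4000
    silence_threshold: int = 80   # replace if spiking trials < this
    stopping_window: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.silence_threshold <= self.window_trials:
            raise ValueError("need 0 < threshold <= window")


@dataclass
class BurstRecord:
    """One detected burst: onset, member spikes and first ISI."""

    neuron: int
    onset_ms: float
    spikes: np.ndarray
    first_isi_ms: float | None

    @property
    def n_spikes(self) -> int:
        return len(self.spikes)


@dataclass
class TrialRecord:
    """Output of one trial."""

    trial: int
    kick_time_ms: float
    spike_times: np.ndarray   # projection neurons
    spike_ids: np.ndarray
    int_spike_times: np.ndarray
    int_spike_ids: np.ndarray
    onset_times: np.ndarray   # burst onsets (projection neurons)
    onset_ids: np.ndarray
    spike_counts: np.ndarray  # per projection neuron
    inh_trace: np.ndarray | None = None   # (n_rec, n_ra) mS/cm^2
    inh_trace_dt_ms: float | None = None

    def bursts(self, max_gap_ms: float = 30.0) -> list[BurstRecord]:
        out: list[BurstRecord] = []
        for nid in np.unique(self.spike_ids):
            t = np.sort(self.spike_times[self.spike_ids == nid])
            out.extend(detect_bursts(t, max_gap_ms, neuron=int(nid)))
        return out


@dataclass
class GrowthLog:
    """Per-trial counters and event log of a growth run."""

    silent: list[int] = field(default_factory=list)
    active: list[int] = field(default_factory=list)
    super: list[int] = field(default_factory=list)
    n_replaced: list[int] = field(default_factory=list)
    kick_times: list[float] = field(default_factory=list)
    #: (trial, neuron) replacement events; the trial is the neuron's birth
    replacements: list[tuple[int, int]] = field(default_factory=list)
    #: per-trial spike counts, one int16 row per trial
    spike_count_rows: list[np.ndarray] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.super)

    def spike_count_matrix(self) -> np.ndarray:
        return (
            np.vstack(self.spike_count_rows)
            if self.spike_count_rows
            else np.empty((0, 0), dtype=np.int16)
        )


# ---------------------------------------------------------------------------
# Burst segmentation and simple trial-history rules
# ---------------------------------------------------------------------------


def detect_bursts(
    spike_times: np.ndarray,
    max_gap_ms: float = 30.0,
    neuron: int = -1,
    duration_rule: bool = False,
) -> list[BurstRecord]:
    """Partition sorted spike times into bursts.

    Default rule: a burst is a maximal group of spikes with consecutive
    gaps <= ``max_gap_ms``. With ``duration_rule`` a burst is instead a
    maximal group of total duration <= ``max_gap_ms``. Burst onset is the
    first spike; the first ISI is undefined for singletons.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    groups: list[list[float]] = [[float(t[0])]]
    for s in t[1:]:
        ref = groups[-1][0] if duration_rule else groups[-1][-1]
        if s - ref <= max_gap_ms:
            groups[-1].append(float(s))
        else:
            groups.append([float(s)])
    return [
        BurstRecord(
            neuron=neuron,
            onset_ms=g[0],
            spikes=np.asarray(g),
            first_isi_ms=(g[1] - g[0]) if len(g) > 1 else None,
        )
        for g in groups
    ]


def turnover_check(
    spiked_by_trial: np.ndarray, params: TurnoverParams | None = None
) -> bool:
    """True iff the neuron should be replaced (strictly fewer spiking
    trials than the silence threshold in the past window; younger
    histories are exempt)."""
    p = params or TurnoverParams()
    h = np.asarray(spiked_by_trial)
    if h.size < p.window_trials:
        return False
    recent = h[-p.window_trials:]
    return int(np.count_nonzero(recent)) < p.silence_threshold


def stopping_check(super_counts: list[int] | np.ndarray, window: int) -> bool:
    """True iff the supersynapse count was constant over the last window."""
    c = np.asarray(super_counts)
    if c.size < window:
        return False
    return bool(np.all(c[-window:] == c[-1]))


def estimate_recruitment_trial(
    spike_counts: np.ndarray, window: int = 25
) -> int:
    """First trial at which the trailing mean spike count reaches 1.

    ``spike_counts`` is the neuron's per-trial spike count; returns the
    1-based trial index of the end of the first window whose mean is
    >= 1. Raises if the average never reaches 1.
    """
    c = np.asarray(spike_counts, dtype=float)
    if c.size >= window:
        kernel = np.ones(window) / window
        means = np.convolve(c, kernel, mode="valid")
        hit = np.flatnonzero(means >= 1.0)
        if hit.size:
            return int(hit[0]) + window
    raise ValueError("trailing average spike count never reached 1")


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _settle_kernel(
    el, gca, rest,
    g_na, e_na, g_k, e_k, g_klt, tau_l, g_leak, g_leak_d,
    g_ca_k, k_ca, e_ca, tau_r, tau_ca, phi_ca, g_c_s, g_c_d,
):
    """Deterministic relaxation of selected projection neurons to rest."""
    for i in range(el.shape[0]):
        out = settle_ra(el[i], gca[i],
                        g_na, e_na, g_k, e_k, g_klt, tau_l, g_leak,
                        g_leak_d, g_ca_k, k_ca, e_ca, tau_r, tau_ca,
                        phi_ca, g_c_s, g_c_d)
        for k in range(7):
            rest[i, k] = out[k]


@njit(cache=True, fastmath=True)
def _settle_int_kernel(
    rest, n_int,
    g_na, e_na, g_k, e_k, g_leak, e_leak,
):
    v, h, n = settle_int(g_na, e_na, g_k, e_k, g_leak, e_leak)
    for i in range(n_int):
        rest[i, 0] = v
        rest[i, 1] = h
        rest[i, 2] = n


@njit(cache=True, inline="always", fastmath=True)
def _btdp_incr(g, dtv, a_p, a_d, t0, t_p, t_d, tau_p, tau_d):
    if dtv > t0:
        if dtv < t0 + t_p:
            return a_p * (dtv - t0) / t_p
        return a_p * np.exp(-(dtv - t0 - t_p) / tau_p)
    if dtv > t0 - t_d:
        return -a_d * g * (t0 - dtv) / t_d
    return -a_d * g * np.exp((dtv - t0 + t_d) / tau_d)


@njit(cache=True, inline="always", fastmath=True)
def _apply_btdp(w_rr, super_count, pre, post, dtv,
                a_p, a_d, t0, t_p, t_d, tau_p, tau_d, g_min, g_max, w_s):
    w = w_rr[pre, post]
    wn = w + _btdp_incr(w, dtv, a_p, a_d, t0, t_p, t_d, tau_p, tau_d)
    if wn < g_min:
        wn = g_min
    elif wn > g_max:
        wn = g_max
    w_rr[pre, post] = wn
    if (w >= w_s) != (wn >= w_s):
        if wn >= w_s:
            super_count[pre] += 1
        else:
            super_count[pre] -= 1


@njit(cache=True, fastmath=True)
def _trial_kernel(
    # mutable network weight state
    w_rr, super_count,
    # static per-trial connectivity (densities / delay steps)
    w_ra_int, d_ra_int, w_int_ra, d_int_ra, d_rr,
    # rest states
    rest_ra, rest_int,
    # protocol
    n_steps, dt, n_corr, kick_step, kick_ns, training,
    noise,                     # (n_steps, n_ra, 2) voltage-noise increments
    seed,                      # for interneuron Poisson draws
    plastic, burst_gap, duration_rule,
    # projection params
    g_na, e_na, g_k, e_k, g_klt, tau_l, g_leak, g_leak_d,
    g_ca_k, k_ca, e_ca, tau_r, tau_ca, phi_ca, g_c_s, g_c_d,
    el, gca,
    # interneuron params
    i_g_na, i_e_na, i_g_k, i_e_k, i_g_leak, i_e_leak,
    i_rate_exc, i_kick_exc, i_rate_inh, i_kick_inh,
    # synapse kinetics
    tau_exc, tau_inh,
    # plasticity params
    a_p, a_d, t0, t_p, t_d, tau_p, tau_d, g_min, g_max,
    w_a, w_s, n_super_max,
    # output caps and inhibition trace stride (0 = off)
    max_ra_spikes, max_int_spikes, inh_stride,
):
    n_ra = w_rr.shape[0]
    n_int = w_int_ra.shape[0]
    np.random.seed(seed)

    # --- state init from rest
    vs = rest_ra[:, 0].copy()
    vd = rest_ra[:, 1].copy()
    hh = rest_ra[:, 2].copy()
    nn = rest_ra[:, 3].copy()
    ll = rest_ra[:, 4].copy()
    rr = rest_ra[:, 5].copy()
    ca = rest_ra[:, 6].copy()
    g_exc_d = np.zeros(n_ra)   # mS/cm^2
    g_inh_s = np.zeros(n_ra)
    vi = np.empty(n_int)
    hi = np.empty(n_int)
    ni = np.empty(n_int)
    for j in range(n_int):
        vi[j] = rest_int[j, 0]
        hi[j] = rest_int[j, 1]
        ni[j] = rest_int[j, 2]
    gi_exc = np.zeros(n_int)
    gi_inh = np.zeros(n_int)

    # --- delay ring buffers
    max_delay = 2
    for i in range(n_ra):
        for j in range(n_int):
            if d_ra_int[i, j] > max_delay:
                max_delay = d_ra_int[i, j]
            if d_int_ra[j, i] > max_delay:
                max_delay = d_int_ra[j, i]
        for j in range(n_ra):
            if d_rr[i, j] > max_delay:
                max_delay = d_rr[i, j]
    ring = max_delay + 2
    fut_exc_ra = np.zeros((ring, n_ra))
    fut_inh_ra = np.zeros((ring, n_ra))
    fut_exc_int = np.zeros((ring, n_int))

    dec_e = np.exp(-dt / tau_exc)
    dec_i = np.exp(-dt / tau_inh)
    p_e = i_rate_exc * dt
    p_i = i_rate_inh * dt
    kick_dens = kick_ns * NS_TO_MSCM2_DEND
    ef_h = np.exp(-dt / TAB_RA_TAU_H)
    ef_n = np.exp(-dt / TAB_RA_TAU_N)
    ef_l = np.exp(-dt / tau_l)
    ef_r = np.exp(-dt / tau_r)
    ef_ca = np.exp(-dt / tau_ca)

    # --- outputs
    spk_t = np.empty(max_ra_spikes)
    spk_id = np.empty(max_ra_spikes, dtype=np.int32)
    n_spk = 0
    ispk_t = np.empty(max_int_spikes)
    ispk_id = np.empty(max_int_spikes, dtype=np.int32)
    n_ispk = 0
    onset_t = np.empty(max_ra_spikes)
    onset_id = np.empty(max_ra_spikes, dtype=np.int32)
    n_onset = 0
    counts = np.zeros(n_ra, dtype=np.int32)
    last_spike = np.full(n_ra, -1.0e9)
    last_onset = np.full(n_ra, -1.0e9)
    burst_start = np.full(n_ra, -1.0e9)
    if inh_stride > 0:
        n_rec = n_steps // inh_stride + 1
    else:
        n_rec = 1
    inh_trace = np.zeros((n_rec, n_ra), dtype=np.float32)
    overflow = 0

    prev_vs = vs.copy()
    prev_vi = vi.copy()
    for step in range(n_steps):
        t = step * dt
        slot = step % ring
        # scheduled deliveries
        for i in range(n_ra):
            g_exc_d[i] += fut_exc_ra[slot, i]
            g_inh_s[i] += fut_inh_ra[slot, i]
            fut_exc_ra[slot, i] = 0.0
            fut_inh_ra[slot, i] = 0.0
        for j in range(n_int):
            gi_exc[j] += fut_exc_int[slot, j]
            fut_exc_int[slot, j] = 0.0
        # training kick
        if step == kick_step:
            for k in range(training.shape[0]):
                g_exc_d[training[k]] += kick_dens
        # interneuron Poisson bombardment
        for j in range(n_int):
            if np.random.random() < p_e:
                gi_exc[j] += i_kick_exc
            if np.random.random() < p_i:
                gi_inh[j] += i_kick_inh

        # --- integrate projection neurons (split step + additive noise)
        for i in range(n_ra):
            out = ra_step(
                vs[i], vd[i], hh[i], nn[i], ll[i], rr[i], ca[i],
                el[i], gca[i], g_exc_d[i], g_inh_s[i], dt, n_corr,
                ef_h, ef_n, ef_l, ef_r, ef_ca,
                g_na, e_na, g_k, e_k, g_klt, g_leak, g_leak_d,
                g_ca_k, k_ca, e_ca, tau_ca, phi_ca, g_c_s, g_c_d,
            )
            vs[i] = out[0] + noise[step, i, 0]
            vd[i] = out[1] + noise[step, i, 1]
            hh[i] = out[2]
            nn[i] = out[3]
            ll[i] = out[4]
            rr[i] = out[5]
            ca[i] = out[6]
        # --- integrate interneurons
        for j in range(n_int):
            vi[j], hi[j], ni[j] = int_step(
                vi[j], hi[j], ni[j], gi_exc[j], gi_inh[j], dt, ef_h, ef_n,
                i_g_na, i_e_na, i_g_k, i_e_k, i_g_leak, i_e_leak,
            )

        # conductance decay
        for i in range(n_ra):
            g_exc_d[i] *= dec_e
            g_inh_s[i] *= dec_i
        for j in range(n_int):
            gi_exc[j] *= dec_e
            gi_inh[j] *= dec_i

        if inh_stride > 0:
            if step % inh_stride == 0:
                irow = step // inh_stride
                for i in range(n_ra):
                    inh_trace[irow, i] = g_inh_s[i]

        # --- interneuron spikes
        for j in range(n_int):
            if prev_vi[j] < SPIKE_THRESHOLD <= vi[j]:
                frac = (SPIKE_THRESHOLD - prev_vi[j]) / (vi[j] - prev_vi[j])
                ts = t + frac * dt
                if n_ispk < max_int_spikes:
                    ispk_t[n_ispk] = ts
                    ispk_id[n_ispk] = j
                    n_ispk += 1
                else:
                    overflow = 1
                for i in range(n_ra):
                    w = w_int_ra[j, i]
                    if w > 0.0:
                        fut_inh_ra[(step + d_int_ra[j, i]) % ring, i] += w
            prev_vi[j] = vi[j]

        # --- projection-neuron spikes, delivery and plasticity
        for i in range(n_ra):
            if prev_vs[i] < SPIKE_THRESHOLD <= vs[i]:
                frac = (SPIKE_THRESHOLD - prev_vs[i]) / (vs[i] - prev_vs[i])
                ts = t + frac * dt
                if n_spk < max_ra_spikes:
                    spk_t[n_spk] = ts
                    spk_id[n_spk] = i
                    n_spk += 1
                else:
                    overflow = 1
                counts[i] += 1
                # deliver to interneurons
                for j in range(n_int):
                    w = w_ra_int[i, j]
                    if w > 0.0:
                        fut_exc_int[(step + d_ra_int[i, j]) % ring, j] += w
                # deliver to projection targets (active or super, and
                # not withdrawn), in nS -> density
                sat_i = super_count[i] >= n_super_max
                for j in range(n_ra):
                    w = w_rr[i, j]
                    if w >= w_a and not (sat_i and w < w_s):
                        fut_exc_ra[(step + d_rr[i, j]) % ring, j] += (
                            w * NS_TO_MSCM2_DEND
                        )
                # burst onset?
                ref = burst_start[i] if duration_rule else last_spike[i]
                if ts - ref > burst_gap:
                    burst_start[i] = ts
                    if n_onset < onset_t.shape[0]:
                        onset_t[n_onset] = ts
                        onset_id[n_onset] = i
                        n_onset += 1
                    else:
                        overflow = 1
                    if plastic:
                        # update all afferent and efferent synapses of i
                        # against partners' most recent burst onsets,
                        # presynaptic onsets taken at arrival time
                        for k in range(n_ra):
                            if k == i or last_onset[k] < -1.0e8:
                                continue
                            # afferent k -> i
                            if not (super_count[k] >= n_super_max
                                    and w_rr[k, i] < w_s):
                                dtv = ts - (last_onset[k] + d_rr[k, i] * dt)
                                _apply_btdp(w_rr, super_count, k, i, dtv,
                                            a_p, a_d, t0, t_p, t_d,
                                            tau_p, tau_d, g_min, g_max, w_s)
                            # efferent i -> k
                            if not (super_count[i] >= n_super_max
                                    and w_rr[i, k] < w_s):
                                dtv = last_onset[k] - (ts + d_rr[i, k] * dt)
                                _apply_btdp(w_rr, super_count, i, k, dtv,
                                            a_p, a_d, t0, t_p, t_d,
                                            tau_p, tau_d, g_min, g_max, w_s)
                    last_onset[i] = ts
                last_spike[i] = ts
            prev_vs[i] = vs[i]

        # divergence guard (cheap scalar check on one neuron per step is
        # not enough; check all every 250 steps)
        if step % 250 == 0:
            for i in range(n_ra):
                if not np.isfinite(vs[i]):
                    raise RuntimeError(
                        "projection-neuron integration diverged"
                    )
            for j in range(n_int):
                if not np.isfinite(vi[j]):
                    raise RuntimeError("interneuron integration diverged")

    return (
        spk_t[:n_spk], spk_id[:n_spk],
        ispk_t[:n_ispk], ispk_id[:n_ispk],
        onset_t[:n_onset], onset_id[:n_onset],
        counts, inh_trace, overflow,
    )


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class Network:
    """A spatially embedded HVC model network with plastic RA->RA synapses.

    Construction places interneurons on the jittered Fibonacci lattice and
    projection neurons at random, samples the distance-dependent
    RA<->interneuron connectivity with uniform weights, assigns conduction
    delays, picks the training set, and initializes every pool neuron as
    new and immature. RA->RA synapses all start at weight zero.
    """

    def __init__(
        self,
        n_ra: int = 2000,
        n_int: int = 550,
        radius_um: float = 260.0,
        seed: int = 0,
        trial: TrialConfig | None = None,
        conn: ConnectivityParams | None = None,
        neuron: ProjectionNeuronParams | None = None,
        inter: InterneuronParams | None = None,
        noise: NoiseParams | None = None,
        kinetics: SynapseKinetics | None = None,
        btdp: BTDPParams | None = None,
        structural: StructuralParams | None = None,
        maturation: MaturationParams | None = None,
        turnover: TurnoverParams | None = None,
        n_training: int | None = None,
        turnover_enabled: bool = True,
        maturation_enabled: bool = True,
        start_mature_pool: bool = False,
        integrator_correctors: int = 1,
        spike_buffer_per_neuron: int = 80,
    ):
        self.master_seed = int(seed)
        self.trial_cfg = trial or TrialConfig()
        if n_training is not None:
            self.trial_cfg.n_training = n_training
        self.conn = conn or ConnectivityParams()
        self.neuron = neuron or ProjectionNeuronParams()
        self.inter = inter or InterneuronParams()
        self.noise = noise or NoiseParams()
        self.kinetics = kinetics or SynapseKinetics()
        self.btdp = btdp or BTDPParams()
        self.structural = structural or StructuralParams()
        self.maturation = maturation or MaturationParams()
        self.turnover = turnover or TurnoverParams()
        self.turnover_enabled = turnover_enabled
        self.maturation_enabled = maturation_enabled
        self.integrator_correctors = int(integrator_correctors)
        self.spike_buffer_per_neuron = int(spike_buffer_per_neuron)

        self.n_ra = n_ra
        self.n_int = n_int
        ss = np.random.SeedSequence(self.master_seed)
        s_place, s_conn, s_train, s_replace = ss.spawn(4)
        self._rng_place = np.random.default_rng(s_place)
        self._rng_replace = np.random.default_rng(s_replace)

        layout = geometry.place_interneurons(
            n_int, radius_um, self._rng_place
        )
        layout = geometry.place_projection_neurons(
            n_ra, layout, self._rng_place
        )
        self.layout = layout
        # positions: interneurons first, then projection neurons
        self.pos_int = layout.positions[:n_int]
        self.pos_ra = layout.positions[n_int:]
        rng_conn = np.random.default_rng(s_conn)

        self.w_ra_int = np.zeros((n_ra, n_int))
        self.w_int_ra = np.zeros((n_int, n_ra))
        self._sample_int_connectivity(rng_conn)

        self.d_rr_ms = assign_delays(
            pairwise_geodesic(self.pos_ra, self.pos_ra, radius_um),
            self.conn.velocity_um_per_ms,
        )
        np.fill_diagonal(self.d_rr_ms, 0.0)

        self.w_rr = np.zeros((n_ra, n_ra))
        self.super_count = np.zeros(n_ra, dtype=np.int64)

        rng_train = np.random.default_rng(s_train)
        self.training = np.sort(
            rng_train.choice(n_ra, self.trial_cfg.n_training, replace=False)
        ).astype(np.int64)
        self.is_training = np.zeros(n_ra, dtype=bool)
        self.is_training[self.training] = True

        # maturation state
        p = self.neuron
        self.el = np.full(n_ra, p.e_immature)
        self.gca = np.zeros(n_ra)
        if start_mature_pool:
            self.el[:] = p.e_mat
            self.gca[:] = p.g_mat
        self.el[self.training] = p.e_mat
        self.gca[self.training] = p.g_mat
        self.age = np.zeros(n_ra, dtype=np.int64)
        self.birth_trial = np.zeros(n_ra, dtype=np.int64)

        # trial-history ring buffers (spiked yes/no)
        wm = self.maturation.window_trials
        wt = self.turnover.window_trials
        self._hist_m = np.zeros((n_ra, wm), dtype=np.uint8)
        self._hist_t = np.zeros((n_ra, wt), dtype=np.uint8)
        self._hist_m_sum = np.zeros(n_ra, dtype=np.int64)
        self._hist_t_sum = np.zeros(n_ra, dtype=np.int64)

        self.trial_index = 0
        self.log = GrowthLog()

        self._rest_ra = np.zeros((n_ra, 7))
        self._rest_int = np.zeros((n_int, 3))
        self._rest_el = np.full(n_ra, np.nan)
        self._rest_gca = np.full(n_ra, np.nan)
        self._settle_int()

    # -- construction helpers ------------------------------------------------

    def _sample_int_connectivity(
        self, rng: np.random.Generator, rows: np.ndarray | None = None
    ) -> None:
        """(Re)sample RA<->INT connections for all or selected RA neurons."""
        c = self.conn
        R = self.layout.radius_um
        ra_idx = np.arange(self.n_ra) if rows is None else np.atleast_1d(rows)
        d = pairwise_geodesic(self.pos_ra[ra_idx], self.pos_int, R)
        p_ei = connection_probability(
            d, c.sigma_ra_to_int_um, c.sigma_as_std
        )
        p_ie = connection_probability(
            d, c.sigma_int_to_ra_um, c.sigma_as_std
        )
        hit_ei = rng.random(p_ei.shape) < p_ei
        hit_ie = rng.random(p_ie.shape) < p_ie
        w_ei = rng.uniform(0.0, c.g_ei_max, p_ei.shape)
        w_ie = rng.uniform(0.0, c.g_ie_max, p_ie.shape)
        self.w_ra_int[ra_idx, :] = np.where(hit_ei, w_ei, 0.0)
        self.w_int_ra[:, ra_idx] = np.where(hit_ie, w_ie, 0.0).T
        # delays (steps) are rebuilt lazily before each trial
        self._delay_cache = None

    def _delays_steps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cache = getattr(self, "_delay_cache", None)
        if cache is not None:
            return cache
        R = self.layout.radius_um
        v = self.conn.velocity_um_per_ms
        dt = self.trial_cfg.dt_ms
        d_ra_int = pairwise_geodesic(self.pos_ra, self.pos_int, R) / v
        d_int_ra = d_ra_int.T
        steps = lambda a: np.maximum(np.rint(a / dt), 1).astype(np.int64)
        self._delay_cache = (
            steps(d_ra_int), steps(d_int_ra), steps(self.d_rr_ms)
        )
        return self._delay_cache

    def _settle_int(self) -> None:
        p = self.inter
        _settle_int_kernel(
            self._rest_int, self.n_int,
            p.g_na, p.e_na, p.g_k, p.e_k, p.g_leak, p.e_leak,
        )

    def _refresh_rest(self) -> None:
        """Recompute rest states for neurons whose maturation moved."""
        stale = (
            np.isnan(self._rest_el)
            | (np.abs(self.el - self._rest_el) > 0.25)
            | (np.abs(self.gca - self._rest_gca) > 0.5)
        )
        if not np.any(stale):
            return
        idx = np.flatnonzero(stale)
        p = self.neuron
        sub_rest = np.zeros((idx.size, 7))
        _settle_kernel(
            self.el[idx], self.gca[idx], sub_rest,
            p.g_na, p.e_na, p.g_k, p.e_k, p.g_klt, p.tau_l, p.g_leak,
            p.g_leak_d, p.g_ca_k, p.k_ca, p.e_ca, p.tau_r, p.tau_ca,
            p.phi_ca, p.g_c, p.g_c * A_SOMA / A_DEND,
        )
        self._rest_ra[idx] = sub_rest
        self._rest_el[idx] = self.el[idx]
        self._rest_gca[idx] = self.gca[idx]

    # -- trial loop ----------------------------------------------------------

    def run_trial(
        self,
        plastic: bool = True,
        record_inh_stride: int = 0,
        trial_seed: int | None = None,
    ) -> TrialRecord:
        """Integrate one trial; mutates weights if ``plastic``."""
        cfg = self.trial_cfg
        if trial_seed is None:
            trial_seed = self.trial_index
        ss = np.random.SeedSequence(
            [self.master_seed, 7919, int(trial_seed)]
        )
        rng = np.random.default_rng(ss)
        kern_seed = int(
            np.random.SeedSequence([self.master_seed, 104729,
                                    int(trial_seed)]).generate_state(1)[0]
            % 2**31
        )
        n_steps = int(round(cfg.duration_ms / cfg.dt_ms))
        lo, hi = cfg.kick_window_ms
        kick_time = rng.uniform(lo, hi)
        kick_step = int(round(kick_time / cfg.dt_ms))
        # bulk voltage-noise increments (mV): amp nA -> uA/cm^2 -> mV
        nz = self.noise
        sq = np.sqrt(cfg.dt_ms)
        sig_s = nz.scale * nz.amp_soma_na * 1e3 / (A_SOMA * 1e6) * sq / C_M
        sig_d = nz.scale * nz.amp_dend_na * 1e3 / (A_DEND * 1e6) * sq / C_M
        noise = rng.standard_normal(
            (n_steps, self.n_ra, 2), dtype=np.float32
        )
        noise[:, :, 0] *= np.float32(sig_s)
        noise[:, :, 1] *= np.float32(sig_d)

        self._refresh_rest()
        d_ra_int, d_int_ra, d_rr = self._delays_steps()
        p, q, kin, b, st = (
            self.neuron, self.inter, self.kinetics, self.btdp,
            self.structural,
        )
        out = _trial_kernel(
            self.w_rr, self.super_count,
            self.w_ra_int, d_ra_int, self.w_int_ra, d_int_ra, d_rr,
            self._rest_ra, self._rest_int,
            n_steps, cfg.dt_ms, self.integrator_correctors,
            kick_step, cfg.kick_ns, self.training,
            noise, kern_seed,
            plastic, cfg.burst_max_gap_ms, cfg.burst_duration_rule,
            p.g_na, p.e_na, p.g_k, p.e_k, p.g_klt, p.tau_l, p.g_leak,
            p.g_leak_d, p.g_ca_k, p.k_ca, p.e_ca, p.tau_r, p.tau_ca,
            p.phi_ca, p.g_c, p.g_c * A_SOMA / A_DEND,
            self.el, self.gca,
            q.g_na, q.e_na, q.g_k, q.e_k, q.g_leak, q.e_leak,
            q.rate_exc_khz, q.kick_exc, q.rate_inh_khz, q.kick_inh,
            kin.tau_exc, kin.tau_inh,
            b.a_p, b.a_d, b.t0, b.t_p, b.t_d, b.tau_p, b.tau_d,
            b.g_min, b.g_max,
            st.w_active, st.w_super, st.n_super_max,
            self.n_ra * self.spike_buffer_per_neuron,
            max(self.n_int * 40 * max(self.spike_buffer_per_neuron // 80, 1),
                4000),
            record_inh_stride,
        )
        (spk_t, spk_id, ispk_t, ispk_id, onset_t, onset_id, counts,
         inh_trace, overflow) = out
        if overflow:
            raise RuntimeError(
                f"trial {self.trial_index}: spike buffer overflow "
                "(runaway network activity)"
            )
        return TrialRecord(
            trial=self.trial_index,
            kick_time_ms=kick_time,
            spike_times=spk_t, spike_ids=spk_id,
            int_spike_times=ispk_t, int_spike_ids=ispk_id,
            onset_times=onset_t, onset_ids=onset_id,
            spike_counts=counts,
            inh_trace=inh_trace if record_inh_stride > 0 else None,
            inh_trace_dt_ms=(
                record_inh_stride * cfg.dt_ms if record_inh_stride > 0
                else None
            ),
        )

    def end_of_trial_update(self, record: TrialRecord) -> None:
        """Decay, remodeling re-check, maturation, turnover, logging."""
        st = self.structural
        # potentiation decay on every RA->RA synapse (withdrawn included)
        pos = self.w_rr > 0.0
        self.w_rr[pos] = np.maximum(self.w_rr[pos] - st.decay, self.btdp.g_min)
        self.super_count = (self.w_rr >= st.w_super).sum(axis=1)

        spiked = (record.spike_counts > 0).astype(np.uint8)
        wm = self.maturation.window_trials
        wt = self.turnover.window_trials
        cm = self.trial_index % wm
        ct = self.trial_index % wt
        self._hist_m_sum += spiked.astype(np.int64) - self._hist_m[:, cm]
        self._hist_m[:, cm] = spiked
        self._hist_t_sum += spiked.astype(np.int64) - self._hist_t[:, ct]
        self._hist_t[:, ct] = spiked
        self.age += 1

        if self.maturation_enabled:
            m = self.maturation
            # trials before a neuron's birth count as non-spiking, so a
            # young neuron needs more than half of the *full* window
            reliable = self._hist_m_sum > m.reliable_fraction * wm
            tau = np.where(reliable, m.tau_fast_s, m.tau_slow_s)
            f = np.exp(-m.trial_increment_s / tau)
            pool = ~self.is_training
            p = self.neuron
            self.el[pool] = p.e_mat + (self.el[pool] - p.e_mat) * f[pool]
            self.gca[pool] = p.g_mat + (self.gca[pool] - p.g_mat) * f[pool]

        n_repl = 0
        if self.turnover_enabled:
            tv = self.turnover
            silent = (
                (self.age >= tv.window_trials)
                & (self._hist_t_sum < tv.silence_threshold)
                & ~self.is_training
            )
            for i in np.flatnonzero(silent):
                self._replace_neuron(int(i))
                n_repl += 1

        w = self.w_rr
        self.log.silent.append(int(((w > 0) & (w < st.w_active)).sum()))
        self.log.active.append(
            int(((w >= st.w_active) & (w < st.w_super)).sum())
        )
        self.log.super.append(int((w >= st.w_super).sum()))
        self.log.n_replaced.append(n_repl)
        self.log.kick_times.append(record.kick_time_ms)
        self.log.spike_count_rows.append(
            record.spike_counts.astype(np.int16)
        )
        self.trial_index += 1

    def _replace_neuron(self, i: int) -> None:
        """Swap neuron ``i`` for a new immature neuron at a new position."""
        others = np.delete(
            np.vstack([self.pos_int, self.pos_ra]), self.n_int + i, axis=0
        )
        newpos = geometry._sample_position_with_exclusion(
            others, self.layout.radius_um, self.layout.exclusion_um,
            self._rng_replace,
        )
        self.pos_ra[i] = newpos
        self._sample_int_connectivity(self._rng_replace, rows=np.array([i]))
        R = self.layout.radius_um
        v = self.conn.velocity_um_per_ms
        d_row = (
            R * np.arccos(np.clip(self.pos_ra @ newpos, -1.0, 1.0)) / v
        )
        self.d_rr_ms[i, :] = d_row
        self.d_rr_ms[:, i] = d_row
        self.d_rr_ms[i, i] = 0.0
        self._delay_cache = None
        self.w_rr[i, :] = 0.0
        self.w_rr[:, i] = 0.0
        self.super_count = (self.w_rr >= self.structural.w_super).sum(axis=1)
        p = self.neuron
        self.el[i] = p.e_immature
        self.gca[i] = 0.0
        self.age[i] = 0
        self.birth_trial[i] = self.trial_index + 1
        self._hist_m[i, :] = 0
        self._hist_t[i, :] = 0
        self._hist_m_sum[i] = 0
        self._hist_t_sum[i] = 0
        self._rest_el[i] = np.nan  # force rest recompute
        self.log.replacements.append((self.trial_index + 1, i))

    def grow(
        self,
        n_trials: int,
        stop_window: int | None = None,
        progress_every: int = 0,
    ) -> GrowthLog:
        """Run up to ``n_trials`` growth trials, stopping early when the
        supersynapse count has been constant for the stopping window."""
        stop_window = stop_window or self.turnover.stopping_window
        for _ in range(n_trials):
            rec = self.run_trial(plastic=True)
            self.end_of_trial_update(rec)
            if progress_every and self.trial_index % progress_every == 0:
                print(
                    f"trial {self.trial_index}: "
                    f"S={self.log.super[-1]} A={self.log.active[-1]} "
                    f"sil={self.log.silent[-1]} "
                    f"repl={sum(self.log.n_replaced)}"
                )
            if stopping_check(self.log.super, stop_window):
                break
        return self.log

    # -- frozen-network testing ----------------------------------------------

    def test_trials(
        self,
        n_trials: int = 100,
        record_inh_stride: int = 0,
        seed_offset: int = 10_000_000,
    ) -> list[TrialRecord]:
        """Run trials with plasticity frozen (no weight changes, no
        maturation, no turnover); network state is untouched."""
        out = []
        for k in range(n_trials):
            out.append(
                self.run_trial(
                    plastic=False,
                    record_inh_stride=record_inh_stride,
                    trial_seed=seed_offset + k,
                )
            )
        return out

    def identify_recruited(
        self, n_test: int = 100, min_trials: int = 95,
        records: list[TrialRecord] | None = None,
    ) -> np.ndarray:
        """Neurons spiking in more than ``min_trials`` of ``n_test``
        frozen test trials (strict inequality)."""
        records = records or self.test_trials(n_test)
        hits = np.zeros(self.n_ra, dtype=int)
        for rec in records:
            hits += (rec.spike_counts > 0).astype(int)
        return np.flatnonzero(hits > min_trials)

    # -- exports -------------------------------------------------------------

    def super_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(pre, post) index arrays of all supersynaptic RA->RA edges."""
        return np.nonzero(self.w_rr >= self.structural.w_super)

    def synapse_state_matrix(self) -> np.ndarray:
        """Integer state codes: 0 none, 1 silent, 2 active, 3 super,
        4 withdrawn."""
        st = self.structural
        w = self.w_rr
        out = np.zeros(w.shape, dtype=np.int8)
        out[(w > 0) & (w < st.w_active)] = 1
        out[(w >= st.w_active) & (w < st.w_super)] = 2
        out[w >= st.w_super] = 3
        saturated = self.super_count >= st.n_super_max
        out[(out > 0) & (out < 3) & saturated[:, None]] = 4
        return out
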