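"""Quantitative readouts of grown networks.

Covers the statistics used to characterize chain growth: the burst-onset
density histogram and its coefficient of variation (synfire vs
polychronous regimes), burst-onset jitter across frozen test trials,
input-similarity (Jaccard) curves, axonal delay distributions of grown
versus random edges, inhibitory-conductance timing metrics around
recruitment, and the birth-time/burst-time correlation induced by
neuronal turnover.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from hvcgrow.growth import Network, TrialRecord

__all__ = [
    "burst_density",
    "burst_jitter",
    "input_similarity",
    "delay_distribution",
    "ltp_window_delta",
    "pre_post_burst_inhibition",
    "birth_burst_correlation",
    "export_topology",
    "trapezoid_area",
    "median_onsets",
    "chain_span",
]


def burst_density(
    onsets_ms: np.ndarray, bin_ms: float = 1.0,
    t_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of burst onset times and its coefficient of variation.

    Returns ``(bin_edges, counts, cv)`` where CV = std/mean of the bin
    counts over the propagation span (first to last onset unless
    ``t_range`` is given). High CV indicates discrete synchronous groups
    (synfire); low CV a continuous (polychronous) regime.
    """
    onsets = np.asarray(onsets_ms, dtype=float)
    if onsets.size == 0:
        raise ValueError("no burst onsets")
    if bin_ms <= 0:
        raise ValueError("bin size must be positive")
    lo, hi = t_range if t_range else (onsets.min(), onsets.max())
    if hi <= lo:
        hi = lo + bin_ms
    edges = np.arange(lo, hi + bin_ms, bin_ms)
    counts, edges = np.histogram(onsets, bins=edges)
    mean = counts.mean()
    cv = float(counts.std() / mean) if mean > 0 else float("nan")
    return edges, counts, cv


def median_onsets(
    records: list[TrialRecord], n_ra: int, align_to_kick: bool = True
) -> np.ndarray:
    """Per-neuron median burst-onset time across trials (NaN if absent).

    Onsets are aligned to the stimulation time of each trial by default.
    """
    per_neuron: list[list[float]] = [[] for _ in range(n_ra)]
    for rec in records:
        shift = rec.kick_time_ms if align_to_kick else 0.0
        for t, i in zip(rec.onset_times, rec.onset_ids):
            per_neuron[int(i)].append(t - shift)
    return np.array(
        [np.median(v) if v else np.nan for v in per_neuron]
    )


def burst_jitter(
    records: list[TrialRecord], n_ra: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron std of (first) burst onsets across frozen test trials.

    Onsets are aligned to each trial's stimulation time. Returns
    ``(jitter_ms, n_trials_present)``; neurons bursting in fewer than two
    trials get NaN. The population std convention (ddof=0) is used.
    """
    per_neuron: list[list[float]] = [[] for _ in range(n_ra)]
    for rec in records:
        seen: set[int] = set()
        order = np.argsort(rec.onset_times)
        for k in order:
            i = int(rec.onset_ids[k])
            if i not in seen:  # first burst of the trial only
                seen.add(i)
                per_neuron[i].append(
                    float(rec.onset_times[k]) - rec.kick_time_ms
                )
    n_present = np.array([len(v) for v in per_neuron])
    jitter = np.array(
        [np.std(v) if len(v) >= 2 else np.nan for v in per_neuron]
    )
    return jitter, n_present


@dataclass
class SimilarityCurve:
    """Mean input-similarity (Jaccard) of synchronously bursting neurons."""

    window_ms: float
    mean_jaccard: float
    per_neuron: np.ndarray


def jaccard(a: set[int], b: set[int]) -> float:
    """Jaccard index of two presynaptic-input sets (empty pair excluded
    by the caller; one empty set gives 0)."""
    if not a and not b:
        raise ValueError("both input sets empty")
    union = len(a | b)
    return len(a & b) / union


def input_similarity(
    pre_sets: list[set[int]], onsets_ms: np.ndarray, window_ms: float
) -> SimilarityCurve:
    """Input-set similarity of neurons bursting within a time window.

    For each neuron i with an onset, the Jaccard index of its
    supersynaptic presynaptic set is computed against every other neuron
    whose onset falls within (t_i - T_w/2, t_i + T_w/2); per-neuron means
    are averaged uniformly. Pairs where both input sets are empty are
    excluded.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    onsets = np.asarray(onsets_ms, dtype=float)
    valid = np.flatnonzero(np.isfinite(onsets))
    per_neuron = np.full(len(pre_sets), np.nan)
    half = window_ms / 2.0
    for i in valid:
        vals = []
        for j in valid:
            if j == i or not abs(onsets[j] - onsets[i]) < half:
                continue
            if not pre_sets[i] and not pre_sets[j]:
                continue
            vals.append(jaccard(pre_sets[i], pre_sets[j]))
        if vals:
            per_neuron[i] = float(np.mean(vals))
    mean = float(np.nanmean(per_neuron)) if np.any(
        np.isfinite(per_neuron)
    ) else float("nan")
    return SimilarityCurve(window_ms, mean, per_neuron)


def delay_distribution(
    net: Network,
    reference: str = "grown",
    rng: np.random.Generator | None = None,
    n_random: int = 10_000,
) -> np.ndarray:
    """Axonal delays (ms) of a named edge population.

    ``reference`` is one of ``grown`` (supersynaptic RA->RA edges),
    ``ra_int`` (RA->interneuron edges), or ``random`` (uniformly sampled
    ordered RA pairs).
    """
    if reference == "grown":
        pre, post = net.super_edges()
        return net.d_rr_ms[pre, post]
    if reference == "ra_int":
        pre, post = np.nonzero(net.w_ra_int)
        from hvcgrow.geometry import pairwise_geodesic

        d = pairwise_geodesic(
            net.pos_ra, net.pos_int, net.layout.radius_um
        )
        return d[pre, post] / net.conn.velocity_um_per_ms
    if reference == "random":
        rng = rng or np.random.default_rng(0)
        i = rng.integers(0, net.n_ra, n_random)
        j = rng.integers(0, net.n_ra, n_random)
        keep = i != j
        return net.d_rr_ms[i[keep], j[keep]]
    raise ValueError(
        f"unknown reference {reference!r}; "
        "expected grown, ra_int or random"
    )


def trapezoid_area(
    trace: np.ndarray, dt_ms: float, t0_ms: float, t1_ms: float
) -> float:
    """Trapezoid-rule area under a regularly sampled trace on a window.

    The trace is treated as samples at times ``k * dt``; the window ends
    are clipped to the trace support and interior sample points are
    interpolated linearly at the window edges.
    """
    n = len(trace)
    if n < 2:
        raise ValueError("trace too short")
    t0 = max(t0_ms, 0.0)
    t1 = min(t1_ms, (n - 1) * dt_ms)
    if t1 <= t0:
        return 0.0
    ts = np.arange(n) * dt_ms
    inner = (ts > t0) & (ts < t1)
    xs = np.concatenate([[t0], ts[inner], [t1]])
    ys = np.concatenate([
        [np.interp(t0, ts, trace)], trace[inner], [np.interp(t1, ts, trace)]
    ])
    return float(np.trapezoid(ys, xs))


def ltp_window_delta(
    trace: np.ndarray,
    reference_trace: np.ndarray,
    dt_ms: float,
    parent_onsets_ms: np.ndarray,
    parent_delays_ms: np.ndarray,
    t0_ms: float = 2.0,
    tau_p_ms: float = 30.0,
) -> float:
    """Inhibition difference in the LTP windows after parent bursts.

    For each parent j with burst onset t_j and axonal delay d_ji, the LTP
    window is (t_j + d_ji + T0, t_j + d_ji + T0 + tau_P). The neuron's
    inhibitory conductance is averaged across parent-aligned windows and
    compared (trapezoid area of the difference) against the reference
    trace (non-recruited population average) in the same intervals.
    Returns the area difference (conductance x ms; negative means the
    neuron saw less inhibition than the reference).
    """
    onsets = np.asarray(parent_onsets_ms, dtype=float)
    delays = np.asarray(parent_delays_ms, dtype=float)
    if onsets.size == 0:
        raise ValueError("no parent bursts in trial")
    areas = []
    for t_j, d_ji in zip(onsets, delays):
        lo = t_j + d_ji + t0_ms
        hi = lo + tau_p_ms
        a = trapezoid_area(trace, dt_ms, lo, hi)
        b = trapezoid_area(reference_trace, dt_ms, lo, hi)
        areas.append(a - b)
    return float(np.mean(areas))


def pre_post_burst_inhibition(
    trace: np.ndarray,
    dt_ms: float,
    onset_ms: float,
    window_ms: float = 10.0,
) -> tuple[float, float]:
    """Areas under the inhibitory conductance 10 ms before/after a burst.

    Returns ``(A_before, A_after)``; windows crossing the trial boundary
    are truncated to the recorded support.
    """
    a_before = trapezoid_area(trace, dt_ms, onset_ms - window_ms, onset_ms)
    a_after = trapezoid_area(trace, dt_ms, onset_ms, onset_ms + window_ms)
    return a_before, a_after


def birth_burst_correlation(
    birth_trials: np.ndarray, burst_onsets_ms: np.ndarray
) -> tuple[float, float, pd.DataFrame]:
    """Spearman rank correlation of birth time against burst time.

    Inputs are matched arrays over recruited neurons. Returns
    ``(rho, p_value, table)`` with a tidy scatter table.
    """
    b = np.asarray(birth_trials, dtype=float)
    t = np.asarray(burst_onsets_ms, dtype=float)
    keep = np.isfinite(b) & np.isfinite(t)
    if keep.sum() < 3:
        raise ValueError("need at least 3 (birth, burst) pairs")
    rho, p = stats.spearmanr(b[keep], t[keep])
    table = pd.DataFrame(
        {"birth_trial": b[keep], "burst_onset_ms": t[keep]}
    )
    return float(rho), float(p), table


def chain_span(records: list[TrialRecord]) -> float:
    """Latest median burst onset (kick-aligned) — the chain's length in
    time. NaN-free only if at least one neuron bursts."""
    onsets = []
    for rec in records:
        if len(rec.onset_times):
            onsets.append(np.max(rec.onset_times) - rec.kick_time_ms)
    if not onsets:
        raise ValueError("no bursts in any record")
    return float(np.median(onsets))


def supersynaptic_graph(net: Network) -> nx.DiGraph:
    """The grown supersynaptic RA->RA network as a directed graph."""
    g = nx.DiGraph()
    g.add_nodes_from(range(net.n_ra))
    pre, post = net.super_edges()
    for i, j in zip(pre, post):
        g.add_edge(
            int(i), int(j),
            weight=float(net.w_rr[i, j]),
            delay_ms=float(net.d_rr_ms[i, j]),
        )
    return g


def export_topology(
    net: Network,
    path: str,
    fmt: str = "graphml",
    subset: np.ndarray | None = None,
) -> None:
    """Write the supersynaptic digraph for external layout tools.

    ``fmt`` is one of ``graphml``, ``pajek`` or ``csv`` (edge list with
    pre, post, weight_ns, delay_ms, state columns). ``subset`` optionally
    restricts to the given neuron ids (e.g. those bursting within a time
    range).
    """
    g = supersynaptic_graph(net)
    if subset is not None:
        g = g.subgraph([int(i) for i in subset]).copy()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "pajek":
        # pajek requires string labels and attributes
        h = nx.relabel_nodes(g, {i: str(i) for i in g.nodes})
        for _, _, d in h.edges(data=True):
            d["delay_ms"] = str(d["delay_ms"])
        nx.write_pajek(h, path)
    elif fmt == "csv":
        rows = [
            {
                "pre": u,
                "post": v,
                "weight_ns": d["weight"],
                "delay_ms": d["delay_ms"],
                "state": "super",
            }
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(
            rows, columns=["pre", "post", "weight_ns", "delay_ms", "state"]
        ).to_csv(path, index=False)
    else:
        raise ValueError(
            f"unknown format {fmt!r}; supported: graphml, pajek, csv"
        )
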