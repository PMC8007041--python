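"""Burst-timing-dependent plasticity (BTDP) and the structural rules for
projection-to-projection synapses: potentiation decay, weight-based synapse
states, and axon remodeling.

The BTDP rule acts on the lag ``dt`` between the postsynaptic burst onset
and the *arrival* of the presynaptic burst onset (emission time plus axonal
delay). Lags larger than ``T0 = 2 ms`` potentiate additively (triangular
ramp to a maximum of ``A_P = 0.25 nS`` at ``T0 + T_P = 5 ms``, then an
exponential tail with time constant ``tau_P = 30 ms``); lags at or below
``T0`` depress multiplicatively (maximum fractional loss ``A_D = 0.02`` at
``T0 - T_D = -1 ms``, exponential tail ``tau_D = 30 ms``). The small
positive shift ``T0`` makes exactly synchronous bursting depressing, so no
connections form between synchronously firing neurons. Weights are clipped
to ``[G_min, G_max] = [0, 4] nS``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "BTDPParams",
    "StructuralParams",
    "SynapseState",
    "btdp_update",
    "btdp_increment",
    "potentiation_decay",
    "classify_synapse",
    "axon_remodeling",
]


@dataclass
class BTDPParams:
    """Amplitudes, window widths and clip bounds of the BTDP rule."""

    a_p: float = 0.25   # nS, additive LTP amplitude
    a_d: float = 0.02   # unitless, fractional LTD amplitude
    t0: float = 2.0     # ms, LTD/LTP boundary shift
    t_p: float = 3.0    # ms, LTP ramp width
    t_d: float = 3.0    # ms, LTD ramp width
    tau_p: float = 30.0  # ms, LTP tail decay
    tau_d: float = 30.0  # ms, LTD tail decay
    g_min: float = 0.0  # nS
    g_max: float = 4.0  # nS

    def __post_init__(self) -> None:
        for name in ("t_p", "t_d", "tau_p", "tau_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.g_min >= self.g_max:
            raise ValueError("g_min must be below g_max")


@dataclass
class StructuralParams:
    """Synapse-state thresholds, supersynapse cap and potentiation decay."""

    w_active: float = 0.2   # nS, silent/active threshold
    w_super: float = 1.0    # nS, active/supersynapse threshold
    n_super_max: int = 10   # max supersynaptic outputs per neuron
    decay: float = 0.01     # nS, per-trial potentiation decay

    def __post_init__(self) -> None:
        if not 0 < self.w_active < self.w_super:
            raise ValueError("need 0 < w_active < w_super")
        if self.n_super_max < 1:
            raise ValueError("n_super_max must be >= 1")


class SynapseState(str, Enum):
    SILENT = "silent"
    ACTIVE = "active"
    SUPER = "super"
    WITHDRAWN = "withdrawn"


def btdp_increment(
    g: float | np.ndarray,
    dt_ms: float | np.ndarray,
    params: BTDPParams | None = None,
) -> float | np.ndarray:
    """Signed weight change of the BTDP rule (before clipping).

    ``dt_ms`` is postsynaptic burst onset minus presynaptic burst-onset
    arrival. The LTP branch is additive (independent of ``g``); the LTD
    branch is multiplicative (proportional to ``g``).
    """
    p = params or BTDPParams()
    g = np.asarray(g, dtype=float)
    dt = np.asarray(dt_ms, dtype=float)
    if np.any(np.isnan(dt)):
        raise ValueError("burst-onset lag is NaN")
    ltp_ramp = p.a_p * (dt - p.t0) / p.t_p
    ltp_tail = p.a_p * np.exp(-(dt - p.t0 - p.t_p) / p.tau_p)
    ltd_ramp = p.a_d * g * (p.t0 - dt) / p.t_d
    ltd_tail = p.a_d * g * np.exp((dt - p.t0 + p.t_d) / p.tau_d)
    out = np.where(
        dt > p.t0,
        np.where(dt < p.t0 + p.t_p, ltp_ramp, ltp_tail),
        -np.where(dt > p.t0 - p.t_d, ltd_ramp, ltd_tail),
    )
    return float(out) if out.ndim == 0 else out


def btdp_update(
    g: float | np.ndarray,
    dt_ms: float | np.ndarray,
    params: BTDPParams | None = None,
) -> float | np.ndarray:
    """Apply one BTDP update and clip the result to ``[g_min, g_max]``."""
    p = params or BTDPParams()
    out = np.clip(
        np.asarray(g, dtype=float) + btdp_increment(g, dt_ms, p),
        p.g_min,
        p.g_max,
    )
    return float(out) if out.ndim == 0 else out


def potentiation_decay(
    g: float | np.ndarray, decay: float = 0.01, g_min: float = 0.0
) -> float | np.ndarray:
    """End-of-trial constant decrement ``G -> max(G - delta, G_min)``."""
    out = np.maximum(np.asarray(g, dtype=float) - decay, g_min)
    return float(out) if out.ndim == 0 else out


def classify_synapse(
    w: float, params: StructuralParams | None = None
) -> SynapseState:
    """Weight-based state: silent below ``W_a``, super above ``W_s``.

    Boundary weights classify upward (exactly ``W_a`` -> active, exactly
    ``W_s`` -> super). Only active and super synapses deliver conductance;
    all states participate in BTDP.
    """
    p = params or StructuralParams()
    if w < 0:
        raise ValueError("synaptic weight must be non-negative")
    if w < p.w_active:
        return SynapseState.SILENT
    if w < p.w_super:
        return SynapseState.ACTIVE
    return SynapseState.SUPER


def axon_remodeling(
    weights: np.ndarray,
    withdrawn: np.ndarray,
    params: StructuralParams | None = None,
) -> np.ndarray:
    """Recompute the withdrawn mask for one neuron's efferent synapses.

    If the neuron holds at least ``N_s`` supersynapses it is saturated: all
    non-super efferents are withdrawn (no conductance, no BTDP; potentiation
    decay still applies). If it holds fewer, previously withdrawn synapses
    are restored to their weight-based states.

    Parameters are the neuron's efferent weight row and the matching
    withdrawn mask; a new mask is returned.
    """
    p = params or StructuralParams()
    weights = np.asarray(weights, dtype=float)
    is_super = weights >= p.w_super
    if int(is_super.sum()) >= p.n_super_max:
        return ~is_super
    return np.zeros_like(np.asarray(withdrawn, dtype=bool))
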