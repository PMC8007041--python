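"""Run configuration: defaults, YAML loading, and scaled-down presets.

The default ``RunConfig`` reproduces the full model: 2000 projection
neurons and 550 interneurons on a 260 um sphere, Gaussian connection
kernels of width 130/90 um, 100 um/ms conduction velocity, initial
weight bounds 0.4/0.03 mS/cm^2, 500 ms trials at dt = 0.02 ms with a
300 nS kick to 10 training neurons, the printed plasticity and
structural constants, maturation time constants 50,000/500 s, turnover
rule 80/4000, and a 10,000-trial stopping window.

Presets provide scaled-down study systems that preserve the full
model's structure: neuron density on the sphere is kept (radius shrinks
with sqrt(N)), connection-kernel widths and the conduction velocity
scale with the radius so that fractional connectivity and the axonal
delay range (in ms) match the full model, and the maturation clock is
compressed so that the slow/scheduled maturation, recruitment-driven
fast maturation, and neuronal turnover all unfold within a few thousand
trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from hvcgrow.geometry import ConnectivityParams
from hvcgrow.growth import Network, TrialConfig, TurnoverParams
from hvcgrow.neurons import (
    InterneuronParams,
    MaturationParams,
    NoiseParams,
    ProjectionNeuronParams,
    SynapseKinetics,
)
from hvcgrow.plasticity import BTDPParams, StructuralParams

__all__ = [
    "RunConfig",
    "load_config",
    "make_network",
    "make_fixture",
    "PRESETS",
]

FULL_RADIUS_UM = 260.0
FULL_N_RA = 2000
FULL_N_INT = 550


@dataclass
class RunConfig:
    """Complete, resolved configuration of a growth run."""

    n_ra: int = FULL_N_RA
    n_int: int = FULL_N_INT
    radius_um: float = FULL_RADIUS_UM
    seed: int = 0
    n_trials: int = 30_000
    checkpoint_every: int = 0
    out_dir: str = "."
    preset: str | None = None
    turnover_enabled: bool = True
    maturation_enabled: bool = True
    start_mature_pool: bool = False
    integrator_correctors: int = 1
    spike_buffer_per_neuron: int = 80
    trial: TrialConfig = field(default_factory=TrialConfig)
    conn: ConnectivityParams = field(default_factory=ConnectivityParams)
    neuron: ProjectionNeuronParams = field(
        default_factory=ProjectionNeuronParams
    )
    inter: InterneuronParams = field(default_factory=InterneuronParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    kinetics: SynapseKinetics = field(default_factory=SynapseKinetics)
    btdp: BTDPParams = field(default_factory=BTDPParams)
    structural: StructuralParams = field(default_factory=StructuralParams)
    maturation: MaturationParams = field(default_factory=MaturationParams)
    turnover: TurnoverParams = field(default_factory=TurnoverParams)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_BLOCK_TYPES = {
    "trial": TrialConfig,
    "conn": ConnectivityParams,
    "neuron": ProjectionNeuronParams,
    "inter": InterneuronParams,
    "noise": NoiseParams,
    "kinetics": SynapseKinetics,
    "btdp": BTDPParams,
    "structural": StructuralParams,
    "maturation": MaturationParams,
    "turnover": TurnoverParams,
}


def _build_block(cls, data: dict[str, Any], path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown keys in config block {path!r}: {sorted(unknown)}"
        )
    # tuples arrive from YAML as lists
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def config_from_dict(data: dict[str, Any] | None) -> RunConfig:
    """Resolve a (possibly partial) mapping into a full ``RunConfig``.

    Unknown keys raise; dataclass constraint violations (negative
    conductances, thresholds out of order, kick window outside the
    trial) propagate as descriptive errors.
    """
    data = dict(data or {})
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _BLOCK_TYPES:
            if not isinstance(value, dict):
                raise ValueError(f"config block {key!r} must be a mapping")
            kwargs[key] = _build_block(_BLOCK_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def load_config(path: str) -> RunConfig:
    """Load a YAML config file; an empty file yields pure defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return config_from_dict(data)


def make_network(cfg: RunConfig, seed: int | None = None) -> Network:
    """Instantiate the network described by a config."""
    return Network(
        n_ra=cfg.n_ra,
        n_int=cfg.n_int,
        radius_um=cfg.radius_um,
        seed=cfg.seed if seed is None else seed,
        trial=dataclasses.replace(cfg.trial),
        conn=dataclasses.replace(cfg.conn),
        neuron=dataclasses.replace(cfg.neuron),
        inter=dataclasses.replace(cfg.inter),
        noise=dataclasses.replace(cfg.noise),
        kinetics=dataclasses.replace(cfg.kinetics),
        btdp=dataclasses.replace(cfg.btdp),
        structural=dataclasses.replace(cfg.structural),
        maturation=dataclasses.replace(cfg.maturation),
        turnover=dataclasses.replace(cfg.turnover),
        turnover_enabled=cfg.turnover_enabled,
        maturation_enabled=cfg.maturation_enabled,
        start_mature_pool=cfg.start_mature_pool,
        integrator_correctors=cfg.integrator_correctors,
        spike_buffer_per_neuron=cfg.spike_buffer_per_neuron,
    )


def _mini_base(n_ra: int = 120, n_int: int = 36) -> RunConfig:
    """Scaled-down study system preserving the full model's structure."""
    radius = FULL_RADIUS_UM * np.sqrt(n_ra / FULL_N_RA)
    sc = radius / FULL_RADIUS_UM
    return RunConfig(
        n_ra=n_ra,
        n_int=n_int,
        radius_um=float(radius),
        n_trials=3000,
        trial=TrialConfig(
            duration_ms=320.0,
            dt_ms=0.04,
            kick_window_ms=(60.0, 140.0),
        ),
        conn=ConnectivityParams(
            sigma_ra_to_int_um=130.0 * sc,
            sigma_int_to_ra_um=90.0 * sc,
            velocity_um_per_ms=100.0 * sc,
        ),
        maturation=MaturationParams(
            window_trials=100, trial_increment_s=20.0
        ),
        turnover=TurnoverParams(
            window_trials=400, silence_threshold=8, stopping_window=1000
        ),
    )


def _preset_mini_growth() -> tuple[RunConfig, dict[str, Any]]:
    cfg = _mini_base()
    cfg.preset = "mini-growth"
    manifest = {
        "supersynaptic_graph_is_dag": True,
        "training_neurons_unique_sources": True,
        "birth_burst_spearman_positive": True,
        "median_recruited_jitter_below_ms": 1.0,
        "grown_mean_delay_below_random": True,
    }
    return cfg, manifest


def _preset_mini_growth_fast_velocity() -> tuple[RunConfig, dict[str, Any]]:
    cfg = _mini_base()
    cfg.preset = "mini-growth-fast-velocity"
    cfg.conn.velocity_um_per_ms *= 10.0
    cfg.n_trials = 2000
    manifest = {
        "burst_density_cv_exceeds_slow_velocity": True,
        "grown_delay_bias_absent": True,
    }
    return cfg, manifest


def _preset_mini_growth_no_maturation() -> tuple[RunConfig, dict[str, Any]]:
    """Uniformly mature, noisy pool (no maturation, no turnover): loop
    formation instead of a feedforward chain."""
    cfg = _mini_base()
    cfg.preset = "mini-growth-no-maturation"
    cfg.maturation_enabled = False
    cfg.turnover_enabled = False
    cfg.start_mature_pool = True
    cfg.noise = NoiseParams(amp_soma_na=0.25, amp_dend_na=0.5)
    cfg.conn.velocity_um_per_ms *= 10.0
    cfg.spike_buffer_per_neuron = 600
    cfg.n_trials = 300
    manifest = {"supersynaptic_graph_has_cycle": True}
    return cfg, manifest


def _preset_inhibition_probe() -> tuple[RunConfig, dict[str, Any]]:
    """Mini growth with turnover disabled so recruited and non-recruited
    neurons can be compared over the whole run (inhibition analysis)."""
    cfg = _mini_base()
    cfg.preset = "inhibition-probe"
    cfg.turnover_enabled = False
    cfg.n_trials = 1500
    manifest = {
        "median_ltp_window_delta_negative": True,
        "median_pre_minus_post_burst_area_positive": True,
    }
    return cfg, manifest


def _preset_single_neuron() -> tuple[RunConfig, dict[str, Any]]:
    """Rate-measurement harness: one neuron of each class, no network."""
    cfg = RunConfig(n_ra=1, n_int=4, n_trials=0, preset="single-neuron")
    manifest = {
        "immature_spontaneous_rate_hz": 0.6,
        "interneuron_spontaneous_rate_hz": 10.0,
        "measurement_seconds": {"projection": 500.0, "interneuron": 100.0},
    }
    return cfg, manifest


PRESETS = {
    "mini-growth": _preset_mini_growth,
    "mini-growth-fast-velocity": _preset_mini_growth_fast_velocity,
    "mini-growth-no-maturation": _preset_mini_growth_no_maturation,
    "inhibition-probe": _preset_inhibition_probe,
    "single-neuron": _preset_single_neuron,
}


def make_fixture(
    preset: str, seed: int = 0
) -> tuple[RunConfig, dict[str, Any]]:
    """Return the named preset config and its expected-property manifest."""
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    cfg, manifest = PRESETS[preset]()
    cfg.seed = int(seed)
    return cfg, manifest
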