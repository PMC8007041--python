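"""Checkpointing, spike export, structured logging, and trial replay.

Checkpoints are HDF5 containers holding the complete mutable state of a
``Network`` (weights, positions, maturation variables, trial histories,
growth log, RNG states) plus the serialized configuration, so a run can
be resumed — or any single trial replayed bit-for-bit — from the saved
trial index. Spikes stream to plain CSV; per-trial counters go to a
JSON-lines log.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any, Iterable

import h5py
import numpy as np
import pandas as pd

from hvcgrow.geometry import ConnectivityParams, SphereLayout
from hvcgrow.growth import GrowthLog, Network, TrialConfig, TrialRecord, TurnoverParams
from hvcgrow.neurons import (
    InterneuronParams,
    MaturationParams,
    NoiseParams,
    ProjectionNeuronParams,
    SynapseKinetics,
)
from hvcgrow.plasticity import BTDPParams, StructuralParams

__all__ = [
    "save_checkpoint",
    "load_checkpoint",
    "replay_trial",
    "write_spikes_csv",
    "append_jsonl",
]

_PARAM_BLOCKS = (
    "trial_cfg", "conn", "neuron", "inter", "noise", "kinetics",
    "btdp", "structural", "maturation", "turnover",
)

_ARRAYS = (
    "pos_int", "pos_ra", "w_ra_int", "w_int_ra", "d_rr_ms", "w_rr",
    "super_count", "training", "is_training", "el", "gca", "age",
    "birth_trial", "_hist_m", "_hist_t", "_hist_m_sum", "_hist_t_sum",
)

_SCALARS = (
    "master_seed", "n_ra", "n_int", "trial_index",
    "turnover_enabled", "maturation_enabled", "integrator_correctors",
    "spike_buffer_per_neuron",
)


def save_checkpoint(net: Network, path: str) -> None:
    """Write the full network state to an HDF5 checkpoint."""
    with h5py.File(path, "w") as f:
        for name in _ARRAYS:
            f.create_dataset(name, data=getattr(net, name))
        for name in _SCALARS:
            f.attrs[name] = getattr(net, name)
        f.attrs["radius_um"] = net.layout.radius_um
        f.attrs["exclusion_um"] = net.layout.exclusion_um
        params = {
            name: dataclasses.asdict(getattr(net, name))
            for name in _PARAM_BLOCKS
        }
        f.attrs["params_json"] = json.dumps(params)
        f.attrs["rng_place_json"] = json.dumps(
            net._rng_place.bit_generator.state
        )
        f.attrs["rng_replace_json"] = json.dumps(
            net._rng_replace.bit_generator.state
        )
        log = f.create_group("log")
        log.create_dataset("silent", data=np.asarray(net.log.silent))
        log.create_dataset("active", data=np.asarray(net.log.active))
        log.create_dataset("super", data=np.asarray(net.log.super))
        log.create_dataset(
            "n_replaced", data=np.asarray(net.log.n_replaced)
        )
        log.create_dataset(
            "kick_times", data=np.asarray(net.log.kick_times)
        )
        log.create_dataset(
            "replacements",
            data=np.asarray(net.log.replacements, dtype=np.int64).reshape(
                -1, 2
            ),
        )
        log.create_dataset(
            "spike_counts", data=net.log.spike_count_matrix()
        )


def load_checkpoint(path: str) -> Network:
    """Reconstruct a ``Network`` from a checkpoint.

    The rebuilt object continues exactly where the saved run stopped:
    per-trial seeds derive from the master seed and trial index, and the
    replacement RNG stream is restored bitwise.
    """
    types = {
        "trial_cfg": TrialConfig,
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
    net = object.__new__(Network)
    with h5py.File(path, "r") as f:
        for name in _ARRAYS:
            setattr(net, name, f[name][...])
        for name in _SCALARS:
            setattr(net, name, _native(f.attrs[name]))
        params = json.loads(f.attrs["params_json"])
        for name, cls in types.items():
            kw = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in params[name].items()
            }
            setattr(net, name, cls(**kw))
        net.layout = SphereLayout(
            radius_um=float(f.attrs["radius_um"]),
            positions=np.vstack([net.pos_int, net.pos_ra]),
            classes=np.concatenate([
                np.ones(net.n_int, dtype=int),
                np.zeros(net.n_ra, dtype=int),
            ]),
            exclusion_um=float(f.attrs["exclusion_um"]),
        )
        net._rng_place = np.random.default_rng()
        net._rng_place.bit_generator.state = json.loads(
            f.attrs["rng_place_json"]
        )
        net._rng_replace = np.random.default_rng()
        net._rng_replace.bit_generator.state = json.loads(
            f.attrs["rng_replace_json"]
        )
        log = f["log"]
        net.log = GrowthLog(
            silent=[int(x) for x in log["silent"][...]],
            active=[int(x) for x in log["active"][...]],
            super=[int(x) for x in log["super"][...]],
            n_replaced=[int(x) for x in log["n_replaced"][...]],
            kick_times=[float(x) for x in log["kick_times"][...]],
            replacements=[
                (int(a), int(b)) for a, b in log["replacements"][...]
            ],
            spike_count_rows=[
                row.astype(np.int16) for row in log["spike_counts"][...]
            ],
        )
    net.is_training = net.is_training.astype(bool)
    net._delay_cache = None
    net._rest_ra = np.zeros((net.n_ra, 7))
    net._rest_int = np.zeros((net.n_int, 3))
    net._rest_el = np.full(net.n_ra, np.nan)
    net._rest_gca = np.full(net.n_ra, np.nan)
    net._settle_int()
    return net


def _native(v: Any) -> Any:
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    return v


def replay_trial(checkpoint_path: str, trial_index: int | None = None) -> TrialRecord:
    """Re-simulate one trial from a checkpoint, bit-identically.

    The checkpoint must hold the network state at the start of the
    requested trial (its ``trial_index``); requesting a different trial
    is refused, since the weight state for it is not in the file.
    """
    net = load_checkpoint(checkpoint_path)
    if trial_index is not None and trial_index != net.trial_index:
        raise ValueError(
            f"checkpoint holds the state at trial {net.trial_index}; "
            f"cannot replay trial {trial_index} from it"
        )
    return net.run_trial()


def write_spikes_csv(
    records: Iterable[TrialRecord], path: str, include_int: bool = False
) -> None:
    """Stream spikes (trial, neuron_id, spike_time_ms) to CSV."""
    rows = []
    for rec in records:
        for t, i in zip(rec.spike_times, rec.spike_ids):
            rows.append((rec.trial, int(i), float(t)))
        if include_int:
            for t, i in zip(rec.int_spike_times, rec.int_spike_ids):
                rows.append((rec.trial, -1 - int(i), float(t)))
    pd.DataFrame(
        rows, columns=["trial", "neuron_id", "spike_time_ms"]
    ).to_csv(path, index=False)


def append_jsonl(path: str, record: dict[str, Any]) -> None:
    """Append one JSON object per line to a log file."""
    with open(path, "a") as fh:
        fh.write(json.dumps(record) + "\n")
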