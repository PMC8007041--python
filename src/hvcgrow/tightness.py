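"""Burst-tightness analysis of spike trains across song development.

Projection neurons fire tight stereotyped bursts once mature; the first
interspike interval (first ISI) of a burst measures its tightness. The
analysis segments spike trains into bursts (spikes separated by gaps of
at most 30 ms), computes each neuron's median first ISI per developmental
stage (subsong, protosyllable, multisyllable, motif), and regresses first
ISI against the burst's latency relative to an event (syllable) onset.
In a growing chain, later-bursting neurons are younger and less mature,
so first ISIs shrink across stages and grow with latency within a stage.

Input is a tidy spike table (neuron_id, rendition_id, spike_time_ms, plus
a stage label and optional event onset); ``generate_synthetic_recordings``
emits tables with configurable per-stage medians and ISI-vs-latency
slopes for testing and demonstration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hvcgrow.growth import detect_bursts

__all__ = [
    "STAGES",
    "TightnessRecord",
    "SyntheticConfig",
    "neuron_tightness",
    "stage_tightness_table",
    "tightness_vs_latency",
    "generate_synthetic_recordings",
    "load_spike_table",
]

#: developmental stage vocabulary, in order
STAGES = ("subsong", "protosyllable", "multisyllable", "motif")

REQUIRED_COLUMNS = ("neuron_id", "rendition_id", "spike_time_ms")


@dataclass
class TightnessRecord:
    """Median first ISI of one neuron at one stage."""

    neuron_id: int
    stage: str
    median_first_isi_ms: float
    n_bursts: int
    n_singleton_bursts: int
    latency_ms: float | None = None


class NoTightnessError(ValueError):
    """Neuron produced only singleton bursts — no first ISI exists."""


def load_spike_table(path: str) -> pd.DataFrame:
    """Read a headered CSV spike table and validate its columns."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table lacks columns: {missing}")
    if "stage" in df.columns:
        bad = set(df["stage"].unique()) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
    return df


def _first_isis(
    table: pd.DataFrame, max_gap_ms: float
) -> tuple[list[float], list[float], int]:
    """First ISIs and onsets of all multi-spike bursts, plus singleton
    count, across the renditions of one neuron."""
    isis: list[float] = []
    onsets: list[float] = []
    n_singleton = 0
    for _, rend in table.groupby("rendition_id"):
        t = np.sort(rend["spike_time_ms"].to_numpy(dtype=float))
        for b in detect_bursts(t, max_gap_ms):
            if b.first_isi_ms is None:
                n_singleton += 1
            else:
                isis.append(b.first_isi_ms)
                onsets.append(b.onset_ms)
    return isis, onsets, n_singleton


def neuron_tightness(
    table: pd.DataFrame,
    neuron_id: int,
    stage: str | None = None,
    max_gap_ms: float = 30.0,
) -> TightnessRecord:
    """Median first ISI of all bursts of one neuron at one stage.

    Bursts are segmented by the gap rule; singleton bursts carry no first
    ISI and are excluded (counted in the record). The latency field is
    the median burst onset relative to the event onset when the table has
    an ``event_onset_ms`` column.
    """
    sub = table[table["neuron_id"] == neuron_id]
    if stage is not None:
        sub = sub[sub["stage"] == stage]
    if sub.empty:
        raise ValueError(f"no spikes for neuron {neuron_id} at {stage!r}")
    isis, onsets, n_singleton = _first_isis(sub, max_gap_ms)
    if not isis:
        raise NoTightnessError(
            f"neuron {neuron_id} at {stage!r} has only singleton bursts"
        )
    latency = None
    if "event_onset_ms" in sub.columns and sub["event_onset_ms"].notna().any():
        ev = float(sub["event_onset_ms"].dropna().iloc[0])
        latency = float(np.median(np.asarray(onsets) - ev))
    return TightnessRecord(
        neuron_id=int(neuron_id),
        stage=stage if stage is not None else "all",
        median_first_isi_ms=float(np.median(isis)),
        n_bursts=len(isis) + n_singleton,
        n_singleton_bursts=n_singleton,
        latency_ms=latency,
    )


def stage_tightness_table(
    table: pd.DataFrame, max_gap_ms: float = 30.0
) -> pd.DataFrame:
    """Tightness records for every (neuron, stage) with >= 1 multi-spike
    burst, as a tidy frame; neurons with only singletons are skipped and
    counted in the ``skipped_only_singletons`` attribute."""
    rows = []
    skipped = 0
    stages = (
        table["stage"].unique() if "stage" in table.columns else [None]
    )
    for stage in stages:
        sub = table if stage is None else table[table["stage"] == stage]
        for nid in sub["neuron_id"].unique():
            try:
                rec = neuron_tightness(sub, nid, stage, max_gap_ms)
            except NoTightnessError:
                skipped += 1
                continue
            rows.append(vars(rec))
    out = pd.DataFrame(rows)
    out.attrs["skipped_only_singletons"] = skipped
    return out


def tightness_vs_latency(
    records: pd.DataFrame,
) -> tuple[float, float, float]:
    """OLS slope of median first ISI against burst latency.

    Returns ``(slope_ms_per_ms, intercept_ms, p_value)`` with a
    two-tailed t-test on the slope. Requires >= 3 records with latencies
    and non-constant latency.
    """
    sub = records.dropna(subset=["latency_ms"])
    if len(sub) < 3:
        raise ValueError("need at least 3 records with latencies")
    x = sub["latency_ms"].to_numpy(dtype=float)
    y = sub["median_first_isi_ms"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("latencies are constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


@dataclass
class SyntheticConfig:
    """Generator settings emulating stage-dependent burst tightness.

    Per stage: the target median first ISI shrinks as development
    progresses, and within a stage the first ISI grows with the burst's
    latency after the syllable onset with the configured slope. Bursts
    are separated by >= 40 ms so the 30 ms gap rule segments them
    unambiguously.
    """

    stage_median_isi_ms: dict[str, float] = field(
        default_factory=lambda: {
            "subsong": 7.0,
            "protosyllable": 5.0,
            "multisyllable": 3.5,
            "motif": 2.5,
        }
    )
    stage_slope: dict[str, float] = field(
        default_factory=lambda: {
            "subsong": 0.0,
            "protosyllable": 0.04,
            "multisyllable": 0.0,
            "motif": 0.0,
        }
    )
    neurons_per_stage: int = 25
    renditions: int = 20
    spikes_per_burst: int = 4
    latency_range_ms: tuple[float, float] = (0.0, 100.0)
    isi_jitter_frac: float = 0.15
    event_onset_ms: float = 50.0

    def __post_init__(self) -> None:
        for stage, m in self.stage_median_isi_ms.items():
            if m <= 0:
                raise ValueError(f"median first ISI for {stage} must be > 0")


def generate_synthetic_recordings(
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emit a synthetic spike table with the configured tightness
    structure (one burst per rendition per neuron, locked to the event).

    Each neuron gets a fixed latency (uniform over the configured range);
    its typical first ISI is ``stage_median + slope * latency`` with
    lognormal-like per-rendition jitter; later ISIs in a burst grow
    geometrically, as in accommodating bursts.
    """
    cfg = config or SyntheticConfig()
    rng = rng or np.random.default_rng()
    rows = []
    nid = 0
    for stage, med in cfg.stage_median_isi_ms.items():
        slope = cfg.stage_slope.get(stage, 0.0)
        mid_latency = 0.5 * (
            cfg.latency_range_ms[0] + cfg.latency_range_ms[1]
        )
        for _ in range(cfg.neurons_per_stage):
            latency = rng.uniform(*cfg.latency_range_ms)
            # center the latency trend so the stage's population median
            # first ISI equals the configured value
            base_isi = med + slope * (latency - mid_latency)
            if base_isi <= 0:
                raise ValueError(
                    "configured slope yields non-positive first ISI"
                )
            for rend in range(cfg.renditions):
                onset = cfg.event_onset_ms + latency
                isi0 = base_isi * np.exp(
                    cfg.isi_jitter_frac * rng.standard_normal()
                )
                t = onset
                spikes = [t]
                isi = isi0
                for _ in range(cfg.spikes_per_burst - 1):
                    t += isi
                    spikes.append(t)
                    isi *= 1.3  # bursts accommodate
                for s in spikes:
                    rows.append(
                        {
                            "neuron_id": nid,
                            "rendition_id": rend,
                            "spike_time_ms": round(float(s), 4),
                            "stage": stage,
                            "event_onset_ms": cfg.event_onset_ms,
                        }
                    )
            nid += 1
    return pd.DataFrame(rows)
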