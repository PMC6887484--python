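"""Synthetic in-vivo-like datasets with known ground truth.

Generates complete recording sessions — spinal units of both functional
classes, primary afferents, a tactile stimulation log, condition epochs
— so that every stage of the analysis pipeline can be validated against
the generator's ground truth.

Two backends produce unit spike trains:

* ``rate``: inhomogeneous Poisson spiking with per-unit rate profiles
  ``r(t) = spont + evoked * (exp(-t/tau_class)`` for adapting units,
  constant for non-adapting).  Fast enough for large unit counts.
* ``mechanistic``: stimuli are mapped through each unit's receptive
  field onto noisy synaptic conductances and integrated through the
  conductance-based neuron models.  Slow; meant for small unit counts.

Condition modifiers (KCC2 blockade, BDNF, BDNF + acetazolamide,
glycine-receptor blockade) act on generation parameters through
:func:`apply_condition`, mirroring how the corresponding drugs act on
chloride regulation or receptor availability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .canonical import canonical_neuron, canonical_rf
from .neuron_models import DEFAULT_DT, NeuronModel, SpikeTrain, integrate
from .protocols import CONDITION_EINH, CONDITION_KAPPA, stimulus_drive
from .receptive_field import (
    RATE_GAIN,
    RFSpec,
    StimulusEvent,
    force_scale,
    mid_surround_position,
    net_drive,
)

__all__ = [
    "UnitSpec",
    "AfferentSpec",
    "Connection",
    "ConditionEpoch",
    "GenerationParams",
    "DatasetConfig",
    "RecordingDataset",
    "DatasetConfigError",
    "apply_condition",
    "generate_afferent_train",
    "generate_dataset",
]

# Afferent response conventions (standard textbook values).
RA_BURST_RATE = 200.0  # spk/s during onset/offset bursts
RA_BURST_DURATION = 30.0  # ms
SA_SUSTAINED_RATE = 50.0  # spk/s throughout the stimulus

# Class-specific recording depths (um), metadata only.
DEPTH_MEAN_SD = {"adapting": (156.0, 72.0), "non_adapting": (234.0, 57.0)}

# Spontaneous-rate increment under complete chloride dysregulation for
# units that receive strong tonic inhibitory input (non-adapting class).
DYSREGULATION_SPONT_INCREMENT = 8.0  # spk/s
# Evoked-response scaling applied by conditions in the rate backend is
# carried by the RF inhibitory factor kappa (see apply_condition).
RATE_KAPPA = {
    "baseline": 1.0,
    "kcc2_block": 0.0,
    "bdnf": 0.0,
    "bdnf_actz": 0.8,
    "glycine_block": 0.5,
}


class DatasetConfigError(ValueError):
    """Invalid dataset configuration; message lists every failure."""


@dataclass(frozen=True)
class UnitSpec:
    """One recorded spinal unit and its ground-truth properties."""

    unit_id: str
    cell_class: str  # {adapting, non_adapting}
    rf: RFSpec
    neuron: NeuronModel | None  # None = rate backend
    depth_um: float
    spont_rate_baseline: float  # spk/s
    tau_class: float  # ms; inf for non-adapting units


@dataclass(frozen=True)
class Connection:
    """Afferent-to-unit synaptic connection with transmission statistics."""

    unit_id: str
    probability: float
    latency_ms: float

    def __post_init__(self) -> None:
        if not 0.0 < self.probability <= 1.0:
            raise ValueError("connection probability must be in (0, 1]")
        if self.latency_ms <= 0:
            raise ValueError("connection latency must be > 0 ms")


@dataclass(frozen=True)
class AfferentSpec:
    """One primary afferent: response kind and its spinal connections."""

    afferent_id: str
    kind: str  # {RA, SA}
    center: tuple[float, float]
    connections: tuple[Connection, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("RA", "SA"):
            raise ValueError(f"unknown afferent kind {self.kind!r}")


@dataclass(frozen=True)
class ConditionEpoch:
    """Time span during which one experimental condition applies."""

    condition: str
    start_ms: float
    end_ms: float


@dataclass(frozen=True)
class GenerationParams:
    """Per-unit generation parameters under one condition."""

    spont_rate: float  # spk/s
    kappa: float  # RF inhibitory-component factor (rate backend)
    E_inh: float  # inhibitory reversal (mechanistic backend)


@dataclass(frozen=True)
class DatasetConfig:
    """Specification of one synthetic recording session."""

    n_adapting: int = 20
    n_non_adapting: int = 10
    backend: str = "rate"  # {rate, mechanistic}
    conditions: tuple[str, ...] = ("baseline",)
    stimulus_zones: tuple[str, ...] = ("center",)
    stimulus_kind: str = "brush"  # {brush, vf}
    vf_force_g: float = 10.0
    n_repeats: int = 10
    stim_duration: float = 1000.0
    inter_onset: float = 2000.0
    quiet_before: float = 12000.0  # ms of rest preceding each block
    spont_non_adapting: float = 4.0  # baseline spontaneous rate, spk/s
    tau_adapting_median: float = 80.0  # ms
    tau_adapting_gsd: float = 1.5
    n_ra_afferents: int = 0
    n_sa_afferents: int = 0
    connection_fraction: float = 0.5  # fraction of afferents connected
    connection_probability: float = 0.3
    connection_latency: float = 3.0  # ms
    connection_jitter: float = 0.3  # ms SD

    def validate(self) -> None:
        problems = []
        if self.n_adapting < 0 or self.n_non_adapting < 0:
            problems.append("unit counts must be >= 0")
        if self.backend not in ("rate", "mechanistic"):
            problems.append(f"unknown backend {self.backend!r}")
        for c in self.conditions:
            if c not in CONDITION_EINH:
                problems.append(f"unknown condition {c!r}")
        for z in self.stimulus_zones:
            if z not in ("center", "surround", "costim"):
                problems.append(f"unknown stimulus zone {z!r}")
        if self.stimulus_kind not in ("brush", "vf"):
            problems.append(f"unknown stimulus kind {self.stimulus_kind!r}")
        if self.n_repeats < 1:
            problems.append("n_repeats must be >= 1")
        if self.stim_duration != 1000.0:
            problems.append("stimulus applications are 1 s long by protocol")
        if self.inter_onset < self.stim_duration:
            problems.append("inter_onset must be >= stim_duration")
        if not 0.0 <= self.connection_fraction <= 1.0:
            problems.append("connection_fraction must be in [0, 1]")
        if problems:
            raise DatasetConfigError("; ".join(problems))


@dataclass
class RecordingDataset:
    """A complete synthetic recording with ground truth."""

    config: DatasetConfig
    units: list[UnitSpec]
    afferents: list[AfferentSpec]
    stimuli: list[StimulusEvent]
    epochs: list[ConditionEpoch]
    spikes: dict[str, SpikeTrain]  # unit_id -> train
    afferent_spikes: dict[str, SpikeTrain]
    ground_truth: dict
    duration: float  # ms
    master_seed: int


def apply_condition(
    params: GenerationParams, condition: str, cell_class: str
) -> GenerationParams:
    """Condition modifiers on generation parameters.

    * ``baseline``: identity.
    * ``kcc2_block`` / ``bdnf``: complete chloride dysregulation —
      E_inh to -45 mV; the RF inhibitory component loses efficacy
      (kappa 0) so evoked rates rise in both classes; spontaneous rate
      rises only in non-adapting units (they sit under strong tonic
      inhibitory input).
    * ``bdnf_actz``: acetazolamide after BDNF — E_inh back to -65 mV,
      inhibitory efficacy mostly restored, spontaneous rate back to its
      baseline value.
    * ``glycine_block``: receptor block halves the inhibitory amplitude
      without touching E_inh or spontaneous firing.
    """
    if condition not in CONDITION_EINH:
        raise ValueError(f"unknown condition {condition!r}")
    if cell_class not in ("adapting", "non_adapting"):
        raise ValueError(f"unknown cell class {cell_class!r}")
    spont = params.spont_rate
    if condition in ("kcc2_block", "bdnf") and cell_class == "non_adapting":
        spont = params.spont_rate + DYSREGULATION_SPONT_INCREMENT
    return GenerationParams(
        spont_rate=spont,
        kappa=RATE_KAPPA[condition],
        E_inh=CONDITION_EINH[condition],
    )


def _poisson_times(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    """Homogeneous Poisson event times in [t0, t1) (times in ms, rate in spk/s)."""
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0) / 1000.0)
    return np.sort(rng.uniform(t0, t1, n))


def generate_afferent_train(
    afferent: AfferentSpec,
    stims: Sequence[StimulusEvent] | StimulusEvent,
    duration: float,
    rng: np.random.Generator | int | None = 0,
) -> SpikeTrain:
    """Afferent response to the stimulus log.

    RA afferents fire short high-rate bursts at stimulus onset and
    offset; SA afferents fire throughout each stimulus.  Off-stimulus
    rate is zero.
    """
    if isinstance(stims, StimulusEvent):
        stims = [stims]
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    parts = []
    for s in stims:
        if afferent.kind == "RA":
            for t0 in (s.onset, s.onset + s.duration):
                parts.append(_poisson_times(rng, RA_BURST_RATE, t0, t0 + RA_BURST_DURATION))
        else:
            parts.append(_poisson_times(rng, SA_SUSTAINED_RATE, s.onset, s.onset + s.duration))
    times = np.sort(np.concatenate(parts)) if parts else np.empty(0)
    times = times[times < duration]
    return SpikeTrain(times=times, duration=duration, unit_id=afferent.afferent_id)


def _build_units(cfg: DatasetConfig, rng: np.random.Generator) -> list[UnitSpec]:
    units = []
    plans = [("adapting", cfg.n_adapting), ("non_adapting", cfg.n_non_adapting)]
    i = 0
    for cls, n in plans:
        rf = canonical_rf(cls)
        neuron = canonical_neuron(cls) if cfg.backend == "mechanistic" else None
        mu, sd = DEPTH_MEAN_SD[cls]
        for _ in range(n):
            depth = float(abs(rng.normal(mu, sd)))
            if cls == "adapting":
                tau = float(
                    cfg.tau_adapting_median
                    * math.exp(rng.normal(0.0, math.log(cfg.tau_adapting_gsd)))
                )
                spont = 0.0
            else:
                tau = math.inf
                spont = float(max(rng.normal(cfg.spont_non_adapting, 1.0), 0.5))
            units.append(
                UnitSpec(
                    unit_id=f"u{i:03d}",
                    cell_class=cls,
                    rf=rf,
                    neuron=neuron,
                    depth_um=depth,
                    spont_rate_baseline=spont,
                    tau_class=tau,
                )
            )
            i += 1
    return units


def _build_afferents(
    cfg: DatasetConfig, units: list[UnitSpec], rng: np.random.Generator
) -> list[AfferentSpec]:
    afferents = []
    kinds = ["RA"] * cfg.n_ra_afferents + ["SA"] * cfg.n_sa_afferents
    n_connected = int(round(cfg.connection_fraction * len(kinds)))
    for i, kind in enumerate(kinds):
        conns: tuple[Connection, ...] = ()
        if i < n_connected and units:
            target = units[int(rng.integers(len(units)))]
            conns = (
                Connection(
                    unit_id=target.unit_id,
                    probability=cfg.connection_probability,
                    latency_ms=cfg.connection_latency,
                ),
            )
        afferents.append(
            AfferentSpec(
                afferent_id=f"a{i:03d}",
                kind=kind,
                center=(0.0, 0.0),
                connections=conns,
            )
        )
    return afferents


def _stimulus_schedule(
    cfg: DatasetConfig, rf_for_positions: RFSpec
) -> tuple[list[StimulusEvent], list[ConditionEpoch], float]:
    """Lay out condition epochs and stimulus blocks on the timeline."""
    positions = {
        "center": rf_for_positions.center,
        "surround": mid_surround_position(rf_for_positions),
    }
    stims: list[StimulusEvent] = []
    epochs: list[ConditionEpoch] = []
    t = 0.0
    k = 0
    for cond in cfg.conditions:
        epoch_start = t
        for zone in cfg.stimulus_zones:
            t += cfg.quiet_before
            for _ in range(cfg.n_repeats):
                if zone == "costim":
                    for z in ("center", "surround"):
                        stims.append(
                            StimulusEvent(
                                stim_id=f"s{k:04d}",
                                kind=cfg.stimulus_kind,
                                position=positions[z],
                                onset=t,
                                duration=cfg.stim_duration,
                                force_g=cfg.vf_force_g if cfg.stimulus_kind == "vf" else None,
                                zone="costim",
                            )
                        )
                        k += 1
                else:
                    stims.append(
                        StimulusEvent(
                            stim_id=f"s{k:04d}",
                            kind=cfg.stimulus_kind,
                            position=positions[zone],
                            onset=t,
                            duration=cfg.stim_duration,
                            force_g=cfg.vf_force_g if cfg.stimulus_kind == "vf" else None,
                            zone=zone,
                        )
                    )
                    k += 1
                t += cfg.inter_onset
        t += 1000.0  # tail after the last block of the epoch
        epochs.append(ConditionEpoch(condition=cond, start_ms=epoch_start, end_ms=t))
    return stims, epochs, t


def _rate_backend_train(
    unit: UnitSpec,
    stims: list[StimulusEvent],
    epochs: list[ConditionEpoch],
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times for one unit."""
    parts = []
    for ep in epochs:
        params = apply_condition(
            GenerationParams(unit.spont_rate_baseline, 1.0, -70.0),
            ep.condition,
            unit.cell_class,
        )
        parts.append(_poisson_times(rng, params.spont_rate, ep.start_ms, ep.end_ms))
        for s in stims:
            if not (ep.start_ms <= s.onset < ep.end_ms):
                continue
            evoked = float(
                force_scale(s)
                * RATE_GAIN
                * net_drive(unit.rf, s.position, kappa=params.kappa)
            )
            if evoked <= 0:
                continue
            # evoked profile on top of the spontaneous rate
            cand = _poisson_times(rng, evoked, s.onset, s.onset + s.duration)
            if math.isfinite(unit.tau_class):
                rel = (cand - s.onset) / unit.tau_class
                cand = cand[rng.uniform(size=len(cand)) < np.exp(-rel)]
            parts.append(cand)
    times = np.sort(np.concatenate(parts)) if parts else np.empty(0)
    return times[(times >= 0) & (times < duration)]


def _mechanistic_train(
    unit: UnitSpec,
    stims: list[StimulusEvent],
    epochs: list[ConditionEpoch],
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conductance-based simulation of one unit's session.

    Stimulus windows are simulated with the mapped synaptic drive; the
    rest of each epoch is simulated in one stretch with tonic input only
    (a unit with no tonic input is silent between stimuli, so those
    stretches are skipped).
    """
    assert unit.neuron is not None
    parts = []
    for ep in epochs:
        stim_windows = [
            s for s in stims if ep.start_ms <= s.onset < ep.end_ms
        ]
        # group simultaneous stimuli (co-stimulation shares an onset)
        by_onset: dict[float, list[StimulusEvent]] = {}
        for s in stim_windows:
            by_onset.setdefault(s.onset, []).append(s)
        for onset, group in sorted(by_onset.items()):
            model0, drive = stimulus_drive(
                unit.neuron, unit.rf, group, ep.condition
            )
            _, st = integrate(
                model0, drive, group[0].duration, DEFAULT_DT,
                E_tonic=drive.E_inh, rng=rng,
            )
            parts.append(st.times + onset)
        if unit.neuron.g_tonic > 0:
            # tonic-only background across the epoch's quiet time,
            # simulated as one contiguous stretch per gap
            gaps = _quiet_gaps(ep, sorted(by_onset))
            for g0, g1 in gaps:
                model0, drive = stimulus_drive(
                    unit.neuron, unit.rf,
                    [StimulusEvent("quiet", "vf", (1e6, 1e6), force_g=1.0)],
                    ep.condition,
                )
                _, st = integrate(model0, drive, g1 - g0, DEFAULT_DT,
                                  E_tonic=drive.E_inh, rng=rng)
                parts.append(st.times + g0)
    times = np.sort(np.concatenate(parts)) if parts else np.empty(0)
    return times[(times >= 0) & (times < duration)]


def _quiet_gaps(ep: ConditionEpoch, onsets: list[float]) -> list[tuple[float, float]]:
    gaps = []
    t = ep.start_ms
    for onset in onsets:
        if onset > t:
            gaps.append((t, onset))
        t = onset + 1000.0
    if ep.end_ms > t:
        gaps.append((t, ep.end_ms))
    return gaps


def generate_dataset(config: DatasetConfig, master_seed: int = 0) -> RecordingDataset:
    """Generate a full synthetic recording session.

    All randomness derives from ``master_seed`` through a seed tree, so
    the dataset is bit-reproducible.
    """
    config.validate()
    ss = np.random.SeedSequence(master_seed)
    s_units, s_aff, s_spk, s_conn = ss.spawn(4)
    rng_units = np.random.default_rng(s_units)
    units = _build_units(config, rng_units)
    afferents = _build_afferents(config, units, np.random.default_rng(s_aff))
    rf_positions = canonical_rf("adapting")
    stims, epochs, duration = _stimulus_schedule(config, rf_positions)

    spike_rngs = np.random.default_rng(s_spk).spawn(max(len(units), 1))
    spikes: dict[str, SpikeTrain] = {}
    for unit, urng in zip(units, spike_rngs):
        if config.backend == "rate":
            times = _rate_backend_train(unit, stims, epochs, duration, urng)
        else:
            times = _mechanistic_train(unit, stims, epochs, duration, urng)
        spikes[unit.unit_id] = SpikeTrain(times=times, duration=duration, unit_id=unit.unit_id)

    aff_rngs = np.random.default_rng(s_aff).spawn(max(len(afferents), 1))
    conn_rng = np.random.default_rng(s_conn)
    afferent_spikes: dict[str, SpikeTrain] = {}
    for aff, arng in zip(afferents, aff_rngs):
        train = generate_afferent_train(aff, stims, duration, arng)
        afferent_spikes[aff.afferent_id] = train
        for conn in aff.connections:
            transmitted = train.times[
                conn_rng.uniform(size=len(train.times)) < conn.probability
            ]
            extra = transmitted + conn.latency_ms + conn_rng.normal(
                0.0, config.connection_jitter, len(transmitted)
            )
            merged = np.sort(np.concatenate([spikes[conn.unit_id].times, extra]))
            merged = merged[(merged >= 0) & (merged < duration)]
            spikes[conn.unit_id] = SpikeTrain(
                times=merged, duration=duration, unit_id=conn.unit_id
            )

    ground_truth = {
        "classes": {u.unit_id: u.cell_class for u in units},
        "tau_class_ms": {
            u.unit_id: (None if math.isinf(u.tau_class) else u.tau_class) for u in units
        },
        "spont_rate_baseline": {u.unit_id: u.spont_rate_baseline for u in units},
        "depth_um": {u.unit_id: u.depth_um for u in units},
        "connections": [
            {
                "afferent_id": a.afferent_id,
                "unit_id": c.unit_id,
                "probability": c.probability,
                "latency_ms": c.latency_ms,
            }
            for a in afferents
            for c in a.connections
        ],
        "epochs": [
            {"condition": e.condition, "start_ms": e.start_ms, "end_ms": e.end_ms}
            for e in epochs
        ],
        "E_inh_per_epoch": {e.condition: CONDITION_EINH[e.condition] for e in epochs},
        "backend": config.backend,
        "master_seed": master_seed,
    }
    return RecordingDataset(
        config=config,
        units=units,
        afferents=afferents,
        stimuli=stims,
        epochs=epochs,
        spikes=spikes,
        afferent_spikes=afferent_spikes,
        ground_truth=ground_truth,
        duration=duration,
        master_seed=master_seed,
    )
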