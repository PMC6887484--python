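"""File formats, dataset persistence and figure-style summary reports.

Datasets live on disk as a plain directory of CSV/JSON files (schemas in
``FORMATS.md``): ``units.csv``, ``afferents.csv``, ``stimuli.csv``,
``spikes.csv``, ``afferent_spikes.csv``, ``conditions.csv``,
``ground_truth.json`` and ``config.json``.  Times are milliseconds from
recording start (0-based); positions are millimetres in a paw-centered
frame.

:func:`analyze_dataset` runs the full spike-train analysis pipeline on a
dataset and compares the results to the generator's ground truth;
:func:`reproduce_summary` regenerates the headline summary tables (the
disinhibition slope/spontaneous-rate matrix, the co-stimulation ratio
table and the zone-drive table) from the canonical models and evaluates
every direction check of the invariant suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .canonical import canonical_neuron, canonical_rf
from .neuron_models import SpikeTrain
from .protocols import (
    ProtocolSpec,
    io_summary_matrix,
    run_costim_protocol,
)
from .receptive_field import (
    RFSpec,
    StimulusEvent,
    compute_zones,
    costim_ratio_analytic,
    zone_drive,
)
from .spike_analysis import (
    classify_unit,
    cross_correlogram,
    fit_adaptation,
    is_connected,
)
from .synthetic_recordings import (
    AfferentSpec,
    ConditionEpoch,
    Connection,
    DatasetConfig,
    RecordingDataset,
    UnitSpec,
)

__all__ = [
    "SpikeTableError",
    "DatasetIOError",
    "read_spike_table",
    "write_spike_table",
    "save_dataset",
    "load_dataset",
    "analyze_dataset",
    "reproduce_summary",
]

DATASET_FILES = (
    "units.csv",
    "afferents.csv",
    "stimuli.csv",
    "spikes.csv",
    "afferent_spikes.csv",
    "conditions.csv",
    "ground_truth.json",
    "config.json",
)


class SpikeTableError(ValueError):
    """Malformed spike-table CSV; the message cites the offending lines."""


class DatasetIOError(ValueError):
    """Invalid dataset directory; the message enumerates every problem."""


# ---------------------------------------------------------------------------
# spike tables


def write_spike_table(
    trains: Mapping[str, SpikeTrain] | Iterable[SpikeTrain], path: str | Path
) -> None:
    """Write spike trains to a ``unit_id,t_ms`` CSV, sorted per unit."""
    if isinstance(trains, Mapping):
        trains = list(trains.values())
    else:
        trains = list(trains)
    frames = [
        pd.DataFrame({"unit_id": t.unit_id, "t_ms": np.sort(t.times)})
        for t in trains
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["unit_id", "t_ms"])
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_spike_table(
    path: str | Path, duration: float | None = None
) -> dict[str, SpikeTrain]:
    """Read a ``unit_id,t_ms`` CSV into per-unit spike trains.

    Unsorted input is accepted and sorted per unit.  ``duration`` sets
    the recording length for every train; if omitted it is taken as the
    latest spike time rounded up to the next millisecond.  Malformed
    rows raise :class:`SpikeTableError` citing their line numbers
    (1-based, counting the header).
    """
    path = Path(path)
    if not path.exists():
        raise DatasetIOError(f"spike table not found: {path}")
    df = pd.read_csv(path, dtype={"unit_id": str}, float_precision="round_trip")
    missing = [c for c in ("unit_id", "t_ms") if c not in df.columns]
    if missing:
        raise SpikeTableError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    t = pd.to_numeric(df["t_ms"], errors="coerce")
    bad = df.index[t.isna() | ~np.isfinite(t.fillna(0.0)) | (t < 0)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:20])
        raise SpikeTableError(
            f"{path}: {len(bad)} malformed row(s) "
            f"(non-numeric, non-finite or negative t_ms) at line(s) {lines}"
        )
    if duration is None:
        duration = float(math.ceil(t.max())) + 1.0 if len(t) else 1000.0
    out: dict[str, SpikeTrain] = {}
    for unit_id, grp in df.assign(t_ms=t).groupby("unit_id", sort=True):
        times = np.sort(grp["t_ms"].to_numpy())
        dup = np.flatnonzero(np.diff(times) <= 0)
        if len(dup):
            raise SpikeTableError(
                f"{path}: unit {unit_id!r} has duplicate spike times "
                f"(e.g. t_ms={times[dup[0]]:g})"
            )
        out[str(unit_id)] = SpikeTrain(
            times=times, duration=duration, unit_id=str(unit_id)
        )
    return out


# ---------------------------------------------------------------------------
# dataset directories


def save_dataset(ds: RecordingDataset, out_dir: str | Path) -> Path:
    """Write a dataset to a directory (schemas in ``FORMATS.md``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "cell_class": u.cell_class,
                "depth_um": u.depth_um,
                "spont_rate_baseline": u.spont_rate_baseline,
                "tau_class_ms": None if math.isinf(u.tau_class) else u.tau_class,
                "A_En": u.rf.A_En,
                "w_En": u.rf.w_En,
                "A_Eb": u.rf.A_Eb,
                "w_Eb": u.rf.w_Eb,
                "A_I": u.rf.A_I,
                "w_I": u.rf.w_I,
                "theta": u.rf.theta,
                "center_x_mm": u.rf.center[0],
                "center_y_mm": u.rf.center[1],
            }
            for u in ds.units
        ],
        columns=[
            "unit_id", "cell_class", "depth_um", "spont_rate_baseline",
            "tau_class_ms", "A_En", "w_En", "A_Eb", "w_Eb", "A_I", "w_I",
            "theta", "center_x_mm", "center_y_mm",
        ],
    ).to_csv(out / "units.csv", index=False, float_format="%.17g")

    aff_rows = []
    for a in ds.afferents:
        conns = a.connections or (None,)
        for c in conns:
            aff_rows.append(
                {
                    "afferent_id": a.afferent_id,
                    "kind": a.kind,
                    "center_x_mm": a.center[0],
                    "center_y_mm": a.center[1],
                    "connected_unit_id": c.unit_id if c else None,
                    "probability": c.probability if c else None,
                    "latency_ms": c.latency_ms if c else None,
                }
            )
    pd.DataFrame(
        aff_rows,
        columns=[
            "afferent_id", "kind", "center_x_mm", "center_y_mm",
            "connected_unit_id", "probability", "latency_ms",
        ],
    ).to_csv(out / "afferents.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [
            {
                "stim_id": s.stim_id,
                "kind": s.kind,
                "position_x_mm": s.position[0],
                "position_y_mm": s.position[1],
                "onset_ms": s.onset,
                "duration_ms": s.duration,
                "force_g": s.force_g,
                "zone": s.zone,
            }
            for s in ds.stimuli
        ],
        columns=[
            "stim_id", "kind", "position_x_mm", "position_y_mm",
            "onset_ms", "duration_ms", "force_g", "zone",
        ],
    ).to_csv(out / "stimuli.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [
            {"condition": e.condition, "start_ms": e.start_ms, "end_ms": e.end_ms}
            for e in ds.epochs
        ],
        columns=["condition", "start_ms", "end_ms"],
    ).to_csv(out / "conditions.csv", index=False, float_format="%.17g")

    write_spike_table(ds.spikes, out / "spikes.csv")
    write_spike_table(ds.afferent_spikes, out / "afferent_spikes.csv")

    gt = dict(ds.ground_truth)
    gt["duration_ms"] = ds.duration
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    (out / "config.json").write_text(json.dumps(asdict(ds.config), indent=1))
    return out


def load_dataset(path: str | Path) -> RecordingDataset:
    """Load a dataset directory written by :func:`save_dataset`."""
    root = Path(path)
    if not root.is_dir():
        raise DatasetIOError(f"not a dataset directory: {root}")
    missing = [f for f in DATASET_FILES if not (root / f).exists()]
    if missing:
        raise DatasetIOError(
            f"{root}: missing dataset file(s): {', '.join(missing)}"
        )
    cfg_d = json.loads((root / "config.json").read_text())
    for key in ("conditions", "stimulus_zones"):
        cfg_d[key] = tuple(cfg_d[key])
    config = DatasetConfig(**cfg_d)

    gt = json.loads((root / "ground_truth.json").read_text())
    duration = float(gt.pop("duration_ms"))

    units_df = pd.read_csv(
        root / "units.csv", dtype={"unit_id": str}, float_precision="round_trip"
    )
    units = []
    for _, r in units_df.iterrows():
        rf = RFSpec(
            A_En=r["A_En"], w_En=r["w_En"], A_Eb=r["A_Eb"], w_Eb=r["w_Eb"],
            A_I=r["A_I"], w_I=r["w_I"], theta=r["theta"],
            cell_class=r["cell_class"],
            center=(float(r["center_x_mm"]), float(r["center_y_mm"])),
        )
        tau = r["tau_class_ms"]
        units.append(
            UnitSpec(
                unit_id=r["unit_id"],
                cell_class=r["cell_class"],
                rf=rf,
                neuron=(
                    canonical_neuron(r["cell_class"])
                    if config.backend == "mechanistic"
                    else None
                ),
                depth_um=float(r["depth_um"]),
                spont_rate_baseline=float(r["spont_rate_baseline"]),
                tau_class=math.inf if pd.isna(tau) else float(tau),
            )
        )

    aff_df = pd.read_csv(
        root / "afferents.csv", dtype={"afferent_id": str},
        float_precision="round_trip",
    )
    afferents = []
    for aff_id, grp in aff_df.groupby("afferent_id", sort=True):
        first = grp.iloc[0]
        conns = tuple(
            Connection(
                unit_id=str(r["connected_unit_id"]),
                probability=float(r["probability"]),
                latency_ms=float(r["latency_ms"]),
            )
            for _, r in grp.iterrows()
            if pd.notna(r["connected_unit_id"])
        )
        afferents.append(
            AfferentSpec(
                afferent_id=str(aff_id),
                kind=first["kind"],
                center=(float(first["center_x_mm"]), float(first["center_y_mm"])),
                connections=conns,
            )
        )

    stim_df = pd.read_csv(
        root / "stimuli.csv", dtype={"stim_id": str},
        float_precision="round_trip",
    )
    stimuli = [
        StimulusEvent(
            stim_id=r["stim_id"],
            kind=r["kind"],
            position=(float(r["position_x_mm"]), float(r["position_y_mm"])),
            onset=float(r["onset_ms"]),
            duration=float(r["duration_ms"]),
            force_g=None if pd.isna(r["force_g"]) else float(r["force_g"]),
            zone=r["zone"],
        )
        for _, r in stim_df.iterrows()
    ]

    cond_df = pd.read_csv(root / "conditions.csv", float_precision="round_trip")
    epochs = [
        ConditionEpoch(
            condition=r["condition"],
            start_ms=float(r["start_ms"]),
            end_ms=float(r["end_ms"]),
        )
        for _, r in cond_df.iterrows()
    ]

    spikes = read_spike_table(root / "spikes.csv", duration=duration)
    for u in units:  # units with zero spikes still need a train
        spikes.setdefault(
            u.unit_id, SpikeTrain(np.empty(0), duration, unit_id=u.unit_id)
        )
    aff_spikes = read_spike_table(root / "afferent_spikes.csv", duration=duration)
    for a in afferents:
        aff_spikes.setdefault(
            a.afferent_id, SpikeTrain(np.empty(0), duration, unit_id=a.afferent_id)
        )

    return RecordingDataset(
        config=config,
        units=units,
        afferents=afferents,
        stimuli=stimuli,
        epochs=epochs,
        spikes=spikes,
        afferent_spikes=aff_spikes,
        ground_truth=gt,
        duration=duration,
        master_seed=int(gt.get("master_seed", -1)),
    )


# ---------------------------------------------------------------------------
# dataset analysis


def _epoch_spont(train: SpikeTrain, ep: ConditionEpoch,
                 stims: Sequence[StimulusEvent]) -> float:
    """Spontaneous rate from the quiet period preceding the epoch's
    first stimulus (the whole epoch if it has no stimuli)."""
    onsets = [s.onset for s in stims if ep.start_ms <= s.onset < ep.end_ms]
    t1 = min(onsets) if onsets else ep.end_ms
    if t1 <= ep.start_ms:
        return 0.0
    return train.rate(ep.start_ms, t1)


def analyze_dataset(
    source: RecordingDataset | str | Path,
    out_dir: str | Path | None = None,
    tau_threshold: float = 300.0,
) -> dict:
    """Run the analysis pipeline over a dataset and score it against
    ground truth.

    Per unit: adapting/non-adapting classification from the baseline
    response CDF, the fitted adaptation time constant, and spontaneous /
    evoked rates per condition epoch.  When afferents are present, every
    afferent-unit pair is tested for functional connectivity via the
    cross-correlogram criterion.  Returns the report dict; when
    ``out_dir`` is given, also writes ``unit_summary.csv`` and
    ``recovery.json`` there.
    """
    ds = (
        source
        if isinstance(source, RecordingDataset)
        else load_dataset(source)
    )
    gt_classes = ds.ground_truth.get("classes", {})
    rows = []
    for u in ds.units:
        train = ds.spikes[u.unit_id]
        row: dict = {"unit_id": u.unit_id, "depth_um": u.depth_um}
        # classification from the baseline epoch's center-zone stimuli
        base_eps = [e for e in ds.epochs if e.condition == "baseline"]
        aligned = []
        for ep in base_eps:
            for s in ds.stimuli:
                if s.zone != "center" or not (ep.start_ms <= s.onset < ep.end_ms):
                    continue
                rel = train.times[
                    (train.times >= s.onset) & (train.times <= s.onset + s.duration)
                ] - s.onset
                aligned.append(rel)
        pooled = np.concatenate(aligned) if aligned else np.empty(0)
        if len(pooled):
            fit = fit_adaptation(
                SpikeTrain(np.unique(pooled), 1000.0), stim_duration=1000.0
            )
            row["tau_ms"] = fit.tau
            row["class_recovered"] = classify_unit(fit, tau_threshold)
            row["low_spike_count"] = fit.low_count
        else:
            row["tau_ms"] = math.nan
            row["class_recovered"] = "unclassified"
            row["low_spike_count"] = True
        row["class_true"] = gt_classes.get(u.unit_id)
        for ep in ds.epochs:
            spont = _epoch_spont(train, ep, ds.stimuli)
            stim_rates = [
                train.rate(s.onset, s.onset + s.duration)
                for s in ds.stimuli
                if ep.start_ms <= s.onset < ep.end_ms
            ]
            row[f"spont_{ep.condition}"] = spont
            row[f"evoked_{ep.condition}"] = (
                float(np.mean(stim_rates)) - spont if stim_rates else math.nan
            )
        rows.append(row)

    summary = pd.DataFrame(rows)
    scored = [r for r in rows if r["class_true"] is not None]
    accuracy = (
        sum(r["class_recovered"] == r["class_true"] for r in scored) / len(scored)
        if scored
        else None
    )

    # connectivity: every afferent-unit pair with spikes on both sides
    true_conns = {
        (c["afferent_id"], c["unit_id"])
        for c in ds.ground_truth.get("connections", [])
    }
    flagged = []
    n_true_hit = 0
    n_null_hit = 0
    n_pairs = 0
    for a in ds.afferents:
        atrain = ds.afferent_spikes[a.afferent_id]
        if len(atrain) == 0:
            continue
        for u in ds.units:
            utrain = ds.spikes[u.unit_id]
            if len(utrain) == 0:
                continue
            n_pairs += 1
            corr = cross_correlogram(atrain, utrain)
            hit = is_connected(corr)
            if hit:
                flagged.append(
                    {
                        "afferent_id": a.afferent_id,
                        "unit_id": u.unit_id,
                        "peak_lag_ms": corr.peak_lag,
                        "peak_prob": corr.peak_prob,
                    }
                )
            if (a.afferent_id, u.unit_id) in true_conns:
                n_true_hit += hit
            else:
                n_null_hit += hit

    report = {
        "n_units": len(ds.units),
        "n_afferents": len(ds.afferents),
        "class_accuracy": accuracy,
        "n_unclassified": sum(
            r["class_recovered"] == "unclassified" for r in rows
        ),
        "connections": {
            "n_pairs_tested": n_pairs,
            "n_true": len(true_conns),
            "true_positive_rate": (
                n_true_hit / len(true_conns) if true_conns else None
            ),
            "false_positives": n_null_hit,
            "flagged": flagged,
        },
        "per_unit": rows,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "unit_summary.csv", index=False)
        (out / "recovery.json").write_text(json.dumps(report, indent=1))
    return report


# ---------------------------------------------------------------------------
# figure-style summary reports


def _drive_table(rf: RFSpec) -> dict:
    z = compute_zones(rf, resolution=0.1)
    d = {
        (zone, cond): zone_drive(rf, z, zone, cond).drive
        for zone in ("center", "surround")
        for cond in ("baseline", "disinhibited")
    }
    return {
        "center_area": z.center_area,
        "surround_area": z.surround_area,
        "total_area_disinhibited": z.center_area + z.surround_area,
        "drive_center_baseline": d[("center", "baseline")],
        "drive_center_disinhibited": d[("center", "disinhibited")],
        "drive_surround_baseline": d[("surround", "baseline")],
        "drive_surround_disinhibited": d[("surround", "disinhibited")],
        "center_drive_increase": d[("center", "disinhibited")]
        - d[("center", "baseline")],
        "surround_drive_increase": d[("surround", "disinhibited")]
        - d[("surround", "baseline")],
    }


def reproduce_summary(
    seed: int = 0,
    n_trials: int = 20,
    out_dir: str | Path | None = None,
) -> dict:
    """Regenerate the headline summary tables and run every direction check.

    Three tables come out of one command:

    * the disinhibition matrix — i-o slope, intercept and spontaneous
      rate for each cell model x alpha x E_inh combination under
      dynamic-clamp-style stimulation,
    * the co-stimulation ratio table — analytic ratios for both RF
      classes plus a spiking-simulation ratio for the adapting setup,
    * the zone-drive table — RF zone areas and drives per class before
      and after disinhibition.

    The report's ``checks`` dict records every direction assertion;
    ``ok`` is their conjunction and ``failures`` lists the violated
    ones.  When ``out_dir`` is given the tables are written as CSV and
    the report as ``summary.json``.
    """
    models = {
        "inhibitory_tonic": canonical_neuron("inhibitory_tonic"),
        "excitatory_delayed": canonical_neuron("excitatory_delayed"),
    }
    spec = ProtocolSpec(seed=seed, n_trials=n_trials)
    matrix = io_summary_matrix(models, spec=spec)
    by = {(r["cell"], r["alpha"], r["E_inh"]): r for r in matrix}

    checks: dict[str, bool] = {}
    for cell in models:
        for alpha in (0.5, 2.0):
            checks[f"slope_up[{cell},alpha={alpha}]"] = (
                by[(cell, alpha, -45.0)]["slope"] > by[(cell, alpha, -70.0)]["slope"]
            )
        checks[f"gain_alpha2_lt_alpha05[{cell}]"] = (
            by[(cell, 2.0, -70.0)]["slope"] < by[(cell, 0.5, -70.0)]["slope"]
        )
    checks["spont_up_tonic_only"] = (
        by[("inhibitory_tonic", 0.5, -45.0)]["spont_rate"]
        - by[("inhibitory_tonic", 0.5, -70.0)]["spont_rate"]
        > 1.0
    ) and (by[("excitatory_delayed", 0.5, -45.0)]["spont_rate"] < 0.5)
    checks["intercept_up_tonic"] = (
        by[("inhibitory_tonic", 0.5, -45.0)]["intercept"]
        > by[("inhibitory_tonic", 0.5, -70.0)]["intercept"]
    )

    # co-stimulation ratio table
    rfs = {c: canonical_rf(c) for c in ("adapting", "non_adapting")}
    costim = {
        c: {
            cond: costim_ratio_analytic(rf, cond)
            for cond in ("baseline", "disinhibited")
        }
        for c, rf in rfs.items()
    }
    checks["costim_baseline_lt_1"] = all(
        costim[c]["baseline"] < 1 for c in costim
    )
    checks["costim_disinhibited_gt_1"] = all(
        costim[c]["disinhibited"] > 1 for c in costim
    )
    checks["costim_adapting_more_extreme"] = (
        costim["adapting"]["baseline"] < costim["non_adapting"]["baseline"]
        and costim["adapting"]["disinhibited"]
        > costim["non_adapting"]["disinhibited"]
    )
    spiking = run_costim_protocol(
        models["excitatory_delayed"],
        rfs["adapting"],
        ProtocolSpec(kind="costim", seed=seed),
    )
    costim["adapting_spiking"] = {
        "baseline": spiking["baseline"].ratio,
        "kcc2_block": spiking["kcc2_block"].ratio,
    }
    checks["costim_spiking_directions"] = (
        spiking["baseline"].ratio < 1.0 and spiking["kcc2_block"].ratio > 1.0
    )

    # zone-drive table
    drives = {c: _drive_table(rf) for c, rf in rfs.items()}
    dc_ad = drives["adapting"]["center_drive_increase"]
    dc_na = drives["non_adapting"]["center_drive_increase"]
    ds_ad = drives["adapting"]["surround_drive_increase"]
    ds_na = drives["non_adapting"]["surround_drive_increase"]
    checks["center_increase_equal_10pct"] = (
        abs(dc_ad - dc_na) <= 0.1 * max(dc_ad, dc_na)
    )
    checks["surround_gt_center_increase"] = ds_ad > dc_ad and ds_na > dc_na
    checks["baseline_area_ad_lt_na"] = (
        drives["adapting"]["center_area"] < drives["non_adapting"]["center_area"]
    )
    ta = drives["adapting"]["total_area_disinhibited"]
    tn = drives["non_adapting"]["total_area_disinhibited"]
    checks["disinhibited_areas_within_20pct"] = abs(ta - tn) <= 0.2 * max(ta, tn)
    ror = (ds_ad / dc_ad) / (ds_na / dc_na)
    checks["ratio_of_ratios_about_2"] = 1.5 <= ror <= 2.5

    failures = sorted(name for name, ok in checks.items() if not ok)
    report = {
        "seed": seed,
        "n_trials": n_trials,
        "io_matrix": [
            {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in r.items()}
            for r in matrix
        ],
        "costim_ratios": costim,
        "zone_drives": drives,
        "ratio_of_ratios": ror,
        "checks": checks,
        "failures": failures,
        "ok": not failures,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {k: v for k, v in r.items() if k != "rates"}
                for r in report["io_matrix"]
            ]
        ).to_csv(out / "io_matrix.csv", index=False)
        pd.DataFrame(
            [
                {"cell_class": c, "condition": cond, "ratio": val}
                for c, d in costim.items()
                for cond, val in d.items()
            ]
        ).to_csv(out / "costim_ratios.csv", index=False)
        pd.DataFrame(
            [{"cell_class": c, **d} for c, d in drives.items()]
        ).to_csv(out / "zone_drives.csv", index=False)
        (out / "summary.json").write_text(json.dumps(report, indent=1))
    return report
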