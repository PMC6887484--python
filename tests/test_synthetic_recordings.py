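"""Unit tests for the synthetic-dataset generator."""

import numpy as np
import pytest

from dorsalhorn.receptive_field import StimulusEvent
from dorsalhorn.synthetic_recordings import (
    AfferentSpec,
    Connection,
    DatasetConfig,
    DatasetConfigError,
    GenerationParams,
    apply_condition,
    generate_afferent_train,
    generate_dataset,
)


def test_config_validation_lists_all_problems():
    cfg = DatasetConfig(
        n_adapting=-1,
        backend="quantum",
        conditions=("baseline", "tetrodotoxin"),
        stim_duration=500.0,
    )
    with pytest.raises(DatasetConfigError) as exc:
        cfg.validate()
    msg = str(exc.value)
    for fragment in ("unit counts", "quantum", "tetrodotoxin", "1 s long"):
        assert fragment in msg


def test_connection_and_afferent_validation():
    with pytest.raises(ValueError):
        Connection(unit_id="u", probability=0.0, latency_ms=3.0)
    with pytest.raises(ValueError):
        Connection(unit_id="u", probability=0.5, latency_ms=0.0)
    with pytest.raises(ValueError):
        AfferentSpec(afferent_id="a", kind="C_fiber", center=(0.0, 0.0))


def test_empty_dataset():
    # no stimuli and no spontaneously active units -> empty spike tables
    cfg = DatasetConfig(n_adapting=3, n_non_adapting=0, stimulus_zones=())
    ds = generate_dataset(cfg, master_seed=1)
    assert all(len(t) == 0 for t in ds.spikes.values())
    assert ds.stimuli == []


def test_apply_condition_examples():
    base = GenerationParams(spont_rate=4.0, kappa=1.0, E_inh=-70.0)
    # identity
    assert apply_condition(base, "baseline", "non_adapting") == base
    # dysregulation raises spontaneous firing only in non-adapting units
    bdnf_na = apply_condition(base, "bdnf", "non_adapting")
    assert bdnf_na.spont_rate > base.spont_rate
    assert bdnf_na.E_inh == -45.0
    bdnf_ad = apply_condition(
        GenerationParams(0.0, 1.0, -70.0), "bdnf", "adapting"
    )
    assert bdnf_ad.spont_rate == 0.0
    # acetazolamide restores spontaneous firing to near baseline
    actz = apply_condition(base, "bdnf_actz", "non_adapting")
    assert abs(actz.spont_rate - base.spont_rate) <= 0.2 * base.spont_rate
    # glycine block leaves spontaneous rate and E_inh untouched
    gly = apply_condition(base, "glycine_block", "non_adapting")
    assert gly.spont_rate == base.spont_rate and gly.E_inh == -70.0
    assert gly.kappa < 1.0
    with pytest.raises(ValueError):
        apply_condition(base, "capsaicin", "adapting")
    with pytest.raises(ValueError):
        apply_condition(base, "baseline", "wide_dynamic_range")


def test_sa_afferent_mean_count():
    aff = AfferentSpec("a0", "SA", (0.0, 0.0))
    stim = StimulusEvent("s", "brush", (0.0, 0.0), onset=100.0, duration=1000.0)
    counts = [
        len(generate_afferent_train(aff, stim, 2000.0, rng=seed))
        for seed in range(200)
    ]
    assert abs(np.mean(counts) - 50.0) < 2.0  # 50 spk/s for 1 s


def test_ra_afferent_bursts_at_onset_and_offset():
    aff = AfferentSpec("a0", "RA", (0.0, 0.0))
    stim = StimulusEvent("s", "brush", (0.0, 0.0), onset=500.0, duration=1000.0)
    tr = generate_afferent_train(aff, stim, 3000.0, rng=0)
    t = tr.times
    in_windows = ((t >= 500.0) & (t <= 530.0)) | ((t >= 1500.0) & (t <= 1530.0))
    assert len(t) > 0
    assert np.mean(in_windows) >= 0.95


def test_afferent_no_stimulus_is_silent():
    aff = AfferentSpec("a0", "SA", (0.0, 0.0))
    assert len(generate_afferent_train(aff, [], 1000.0, rng=0)) == 0


def test_dataset_seed_determinism():
    cfg = DatasetConfig(n_adapting=4, n_non_adapting=2, n_sa_afferents=2)
    a = generate_dataset(cfg, master_seed=7)
    b = generate_dataset(cfg, master_seed=7)
    assert all(
        np.array_equal(a.spikes[k].times, b.spikes[k].times) for k in a.spikes
    )
    c = generate_dataset(cfg, master_seed=8)
    assert any(
        not np.array_equal(a.spikes[k].times, c.spikes[k].times)
        for k in a.spikes
    )


def test_dataset_structure_and_ground_truth():
    cfg = DatasetConfig(
        n_adapting=3, n_non_adapting=2,
        conditions=("baseline", "kcc2_block"),
        n_ra_afferents=2, n_sa_afferents=1,
    )
    ds = generate_dataset(cfg, master_seed=3)
    assert len(ds.units) == 5 and len(ds.afferents) == 3
    # stimuli follow the 1 s on / 1 s off protocol within each block;
    # blocks are separated by longer quiet stretches
    onsets = np.sort([s.onset for s in ds.stimuli])
    assert all(s.duration == 1000.0 for s in ds.stimuli)
    gaps = np.diff(onsets)
    assert np.all((np.isclose(gaps, 2000.0)) | (gaps > 2000.0))
    # epochs tile the recording and ground truth is complete
    assert ds.epochs[0].start_ms == 0.0
    assert ds.epochs[-1].end_ms == ds.duration
    gt = ds.ground_truth
    assert set(gt["classes"]) == {u.unit_id for u in ds.units}
    assert gt["E_inh_per_epoch"]["kcc2_block"] == -45.0
    # adapting units silent at baseline; non-adapting spontaneously active
    for u in ds.units:
        if u.cell_class == "adapting":
            assert u.spont_rate_baseline == 0.0
        else:
            assert u.spont_rate_baseline > 0.0
    # every spike belongs to a known unit and lies inside the recording
    for uid, tr in ds.spikes.items():
        assert uid in gt["classes"]
        assert tr.duration == ds.duration


def test_mechanistic_backend_smoke():
    cfg = DatasetConfig(
        n_adapting=1, n_non_adapting=1, backend="mechanistic",
        n_repeats=3, quiet_before=2000.0,
    )
    ds = generate_dataset(cfg, master_seed=5)
    ad = next(u for u in ds.units if u.cell_class == "adapting")
    # center brush stimulation drives the mechanistic adapting unit
    assert len(ds.spikes[ad.unit_id]) > 0
    assert ds.ground_truth["backend"] == "mechanistic"
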