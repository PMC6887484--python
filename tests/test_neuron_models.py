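"""Unit tests for the conductance-based neuron models."""

import dataclasses

import numpy as np
import pytest

from dorsalhorn.neuron_models import (
    ClassificationError,
    NeuronModel,
    SpikeTrain,
    classify_spiking_pattern,
    detect_spikes,
    find_rheobase,
    integrate,
    resting_potential,
)
from dorsalhorn.ou_synapse import OUParams, SynapticDriveSpec


def test_canonical_classification(tonic_model, delayed_model, single_model):
    assert classify_spiking_pattern(tonic_model) == "tonic"
    assert classify_spiking_pattern(delayed_model) == "delayed"
    assert classify_spiking_pattern(single_model) == "single"


def test_resting_potentials_in_range(tonic_model, delayed_model, single_model):
    for m in (tonic_model, delayed_model, single_model):
        assert -75.0 <= resting_potential(m) <= -60.0


def test_rest_is_stable_without_drive(delayed_model):
    V_rest = resting_potential(delayed_model)
    trace, st = integrate(delayed_model, None, duration=1000.0)
    assert len(st) == 0
    assert abs(trace.values[-1] - V_rest) < 0.5


def test_einh_sensitivity_at_rest(tonic_model, delayed_model):
    # the tonic conductance couples rest to E_inh; without it rest is inert
    d_tonic = resting_potential(tonic_model, E_tonic=-45.0) - resting_potential(
        tonic_model, E_tonic=-70.0
    )
    assert d_tonic > 1.0
    d_exc = resting_potential(delayed_model, E_tonic=-45.0) - resting_potential(
        delayed_model, E_tonic=-70.0
    )
    assert abs(d_exc) < 0.1


def test_disinhibited_gaba_not_excitatory(delayed_model):
    # inhibitory conductance reversing at -45 mV alone never drives spiking
    drive = SynapticDriveSpec(
        exc=OUParams(g0=0.0, sigma=0.0, tau=3.0),
        inh=OUParams(g0=5.0, sigma=5.0 / 3.0, tau=10.0, seed=11),
        E_exc=0.0,
        E_inh=-45.0,
    )
    _, st = integrate(delayed_model, drive, duration=10_000.0, E_tonic=-45.0)
    assert len(st) == 0


def test_tonic_rate_monotonic_in_current(tonic_model):
    rheo = find_rheobase(tonic_model)
    counts = [
        len(integrate(tonic_model, f * rheo, duration=500.0)[1])
        for f in (1.1, 1.5, 2.0, 3.0)
    ]
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_no_spiking_mechanism_raises(tonic_model):
    # no fast sodium and a leak so large that no step up to the search
    # ceiling can depolarize the cell past the detection threshold
    dead = dataclasses.replace(tonic_model, gNa=0.0, gL=200.0)
    with pytest.raises(ClassificationError):
        classify_spiking_pattern(dead)


def test_detect_spikes():
    dt = 0.1
    V = np.full(100, -70.0)
    V[20:23] = 10.0
    V[60:63] = 10.0
    times = detect_spikes(V, dt)
    assert times == pytest.approx([2.0, 6.0])
    # crossings closer than the dead time collapse to one spike
    V2 = np.full(100, -70.0)
    V2[20] = 10.0
    V2[22] = 10.0
    V2[21] = -70.0
    assert len(detect_spikes(V2, dt)) == 1


def test_spike_train_validation():
    with pytest.raises(ValueError):
        SpikeTrain(np.array([2.0, 1.0]), duration=10.0)
    with pytest.raises(ValueError):
        SpikeTrain(np.array([1.0, 1.0]), duration=10.0)
    with pytest.raises(ValueError):
        SpikeTrain(np.array([-1.0]), duration=10.0)
    st = SpikeTrain(np.array([100.0, 300.0]), duration=1000.0)
    assert st.rate() == pytest.approx(2.0)
    with pytest.raises(ValueError):
        st.rate(5.0, 5.0)


def test_model_roundtrip(tonic_model):
    assert NeuronModel.from_dict(tonic_model.to_dict()) == tonic_model


def test_model_validation():
    with pytest.raises(ValueError):
        NeuronModel(label="inhibitory_tonic", gL=-1.0)
    with pytest.raises(ValueError):
        NeuronModel(label="pyramidal")


def test_integrate_seed_determinism(tonic_model):
    drive = SynapticDriveSpec(
        exc=OUParams(g0=3.0, sigma=1.0, tau=3.0, seed=5),
        inh=OUParams(g0=6.0, sigma=2.0, tau=10.0, seed=6),
    )
    _, a = integrate(tonic_model, drive, duration=2000.0)
    _, b = integrate(tonic_model, drive, duration=2000.0)
    assert np.array_equal(a.times, b.times)
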