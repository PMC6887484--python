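"""Unit tests for the spike-train and I-V analyses."""

import numpy as np
import pytest

from dorsalhorn.neuron_models import SpikeTrain
from dorsalhorn.spike_analysis import (
    AdaptationFit,
    ReversalEstimate,
    classify_unit,
    cross_correlogram,
    drive_from_measurements,
    estimate_reversal,
    evoked_rate,
    extrusion_capacity,
    fit_adaptation,
    fit_io,
    is_connected,
    mean_evoked_rate,
)


def poisson_train(rate, duration, seed, t0=0.0):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * (duration - t0) / 1000.0)
    times = np.sort(rng.uniform(t0, duration, n))
    return SpikeTrain(np.unique(times), duration)


# -- evoked rates -----------------------------------------------------------


def test_evoked_rate_empty_train():
    st = SpikeTrain(np.empty(0), duration=20_000.0)
    assert evoked_rate(st, 11_000.0, 1000.0).evoked == 0.0


def test_evoked_rate_window_errors():
    st = SpikeTrain(np.array([1.0]), duration=2000.0)
    with pytest.raises(ValueError):
        evoked_rate(st, 1500.0, 1000.0)  # extends past the recording
    with pytest.raises(ValueError):
        evoked_rate(st, 0.0, 0.0)


def test_evoked_rate_truncates_baseline_with_warning():
    st = SpikeTrain(np.array([500.0]), duration=5000.0)
    with pytest.warns(UserWarning):
        r = evoked_rate(st, 2000.0, 1000.0)
    assert r.spont_rate == pytest.approx(0.5)  # 1 spike in 2 s


def test_evoked_rate_homogeneous_poisson_is_zero_mean():
    vals = [
        evoked_rate(poisson_train(20.0, 12_000.0, seed), 10_000.0, 1000.0).evoked
        for seed in range(100)
    ]
    assert abs(np.mean(vals)) < 1.5


def test_evoked_rate_shift_invariance():
    times = np.array([10_500.0, 10_600.0, 10_900.0])
    a = evoked_rate(SpikeTrain(times, 12_000.0), 10_000.0, 1000.0)
    b = evoked_rate(SpikeTrain(times + 3000.0, 15_000.0), 13_000.0, 1000.0)
    assert a.evoked == pytest.approx(b.evoked)


def test_mean_evoked_rate_averages():
    st = SpikeTrain(np.array([10_100.0, 10_200.0, 22_500.0]), 24_000.0)
    r = mean_evoked_rate(st, [10_000.0, 22_000.0], 1000.0)
    assert r.stim_rate == pytest.approx(1.5)
    with pytest.raises(ValueError):
        mean_evoked_rate(st, [], 1000.0)


# -- adaptation fit and classification --------------------------------------


def test_fit_adaptation_recovers_tau():
    rng = np.random.default_rng(12)
    tau_true = 50.0
    trains = []
    for _ in range(10):
        # density proportional to exp(-t/tau) truncated to the 1 s stimulus
        u = rng.uniform(size=30)
        t = -tau_true * np.log1p(-u * (1 - np.exp(-1000.0 / tau_true)))
        trains.append(SpikeTrain(np.unique(np.sort(t)), 1000.0))
    fit = fit_adaptation(trains, 1000.0)
    assert fit.tau == pytest.approx(tau_true, rel=0.10)


def test_fit_adaptation_uniform_hits_upper_range():
    st = SpikeTrain(np.linspace(0.5, 999.5, 200), 1000.0)
    assert fit_adaptation(st, 1000.0).tau >= 1000.0


def test_fit_adaptation_step_cdf_hits_lower_bound():
    st = SpikeTrain(np.linspace(0.01, 0.2, 20), 1000.0)
    assert fit_adaptation(st, 1000.0).tau == pytest.approx(1.0)


def test_fit_adaptation_trial_order_and_duplication_invariance():
    a = SpikeTrain(np.array([10.0, 30.0, 90.0]), 1000.0)
    b = SpikeTrain(np.array([5.0, 20.0, 50.0, 200.0]), 1000.0)
    t1 = fit_adaptation([a, b], 1000.0).tau
    t2 = fit_adaptation([b, a], 1000.0).tau
    t3 = fit_adaptation([a, b, a, b], 1000.0).tau
    assert t1 == pytest.approx(t2)
    assert t1 == pytest.approx(t3, rel=1e-6)


def test_fit_adaptation_low_count_flag_and_empty_error():
    fit = fit_adaptation(SpikeTrain(np.array([1.0, 5.0]), 1000.0), 1000.0)
    assert fit.low_count
    with pytest.raises(ValueError):
        fit_adaptation(SpikeTrain(np.empty(0), 1000.0), 1000.0)


def test_classify_unit_thresholds():
    def mk(tau):
        return AdaptationFit(tau=tau, goodness=0.0, n_spikes=100)

    assert classify_unit(mk(50.0)) == "adapting"
    assert classify_unit(mk(1200.0)) == "non_adapting"
    assert classify_unit(mk(450.0)) == "unclassified"


# -- i-o fit ----------------------------------------------------------------


def test_fit_io_exact_line():
    slope, intercept, r2 = fit_io([(x, 2 * x + 1) for x in (0, 1, 2, 3)])
    assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))
    slope, _, _ = fit_io(list(zip((2, 4, 6, 8, 10), (4, 8, 12, 16, 20))))
    assert slope == pytest.approx(2.0)


def test_fit_io_degenerate():
    with pytest.raises(ValueError):
        fit_io([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])
    with pytest.raises(ValueError):
        fit_io([(1.0, 2.0), (2.0, 3.0)])


# -- correlograms -----------------------------------------------------------


def test_correlogram_shifted_train():
    aff = poisson_train(20.0, 100_000.0, 3)
    spinal = SpikeTrain(aff.times + 2.0, aff.duration + 10.0)
    corr = cross_correlogram(aff, spinal)
    assert corr.peak_lag == pytest.approx(2.5)  # bin center of (2, 3]
    # each reference spike has its shifted partner in the peak bin, plus
    # occasional coincidences from neighbouring spikes < 1 ms apart
    assert corr.peak_prob == pytest.approx(1.0, abs=0.05)
    assert is_connected(corr)


def test_correlogram_independent_poisson_flat():
    aff = poisson_train(20.0, 100_000.0, 4)
    spinal = poisson_train(20.0, 100_000.0, 5)
    corr = cross_correlogram(aff, spinal)
    p = 20.0 / 1000.0  # rate x 1 ms bin
    sd = np.sqrt(p * (1 - p) / corr.n_pairs)
    assert np.all(np.abs(corr.prob - p) < 4 * sd)
    assert not is_connected(corr)


def test_correlogram_symmetry_property():
    a = poisson_train(15.0, 50_000.0, 6)
    b = poisson_train(25.0, 50_000.0, 7)
    ab = cross_correlogram(a, b)
    ba = cross_correlogram(b, a)
    # counts: prob * n_reference; A->B at lag l equals B->A at -l
    counts_ab = ab.prob * ab.n_pairs
    counts_ba = (ba.prob * ba.n_pairs)[::-1]
    assert np.allclose(counts_ab, counts_ba)


def test_correlogram_empty_train_error():
    a = poisson_train(10.0, 1000.0, 8)
    with pytest.raises(ValueError):
        cross_correlogram(a, SpikeTrain(np.empty(0), 1000.0))


# -- reversal potentials ----------------------------------------------------


def test_estimate_reversal_exact():
    pts = [(v, 5.0 * (v + 70.0)) for v in (-90.0, -70.0, -50.0)]
    est = estimate_reversal(pts)
    assert est.E_rev == pytest.approx(-70.0)
    assert est.slope_conductance == pytest.approx(5.0)


def test_estimate_reversal_equivariance():
    rng = np.random.default_rng(9)
    V = np.linspace(-100.0, -40.0, 7)
    I = 4.0 * (V + 62.0) + rng.normal(0, 3.0, len(V))
    base = estimate_reversal(list(zip(V, I))).E_rev
    for delta in (-7.5, 5.0, 20.0):
        shifted = estimate_reversal(list(zip(V + delta, I))).E_rev
        assert shifted == pytest.approx(base + delta)


def test_estimate_reversal_errors():
    with pytest.raises(ValueError):
        estimate_reversal([(-70.0, 0.0), (-70.0, 1.0), (-70.0, 2.0)])
    with pytest.raises(ValueError):
        # negative slope: no reversal
        estimate_reversal([(v, -2.0 * (v + 70.0)) for v in (-90.0, -70.0, -50.0)])


def test_extrusion_capacity():
    before = ReversalEstimate(E_rev=-55.0, slope_conductance=5.0, r_squared=1.0)
    after = ReversalEstimate(E_rev=-45.0, slope_conductance=5.0, r_squared=1.0)
    assert extrusion_capacity(before, after) == pytest.approx(10.0)


def test_drive_from_measurements():
    assert drive_from_measurements(0.0, 100.0).drive == 0.0
    assert drive_from_measurements(5.0, 10.0).drive == pytest.approx(50.0)
    with pytest.raises(ValueError):
        drive_from_measurements(-1.0, 10.0)
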