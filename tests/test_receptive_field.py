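"""Unit tests for the center-surround receptive-field model."""

import math

import numpy as np
import pytest

from dorsalhorn.receptive_field import (
    EmptyRFError,
    RFSpec,
    StimulusEvent,
    compute_zones,
    costim_ratio_analytic,
    mid_surround_position,
    net_drive,
    rf_edge_radius,
    stimulus_to_drive,
    tuning,
    zone_drive,
)


def simple_rf(**kw):
    d = dict(A_En=10.0, w_En=2.0, A_Eb=0.0, w_Eb=6.0, A_I=6.0, w_I=5.0,
             theta=1.0, cell_class="adapting")
    d.update(kw)
    return RFSpec(**d)


def test_tuning_peak_and_decay():
    rf = simple_rf(A_Eb=3.0)
    E, I = tuning(rf, rf.center)
    assert E == pytest.approx(rf.A_En + rf.A_Eb)
    assert I == pytest.approx(rf.A_I)
    E_far, I_far = tuning(rf, (100.0, 100.0))
    assert E_far < 1e-10 and I_far < 1e-10


def test_tuning_closed_form():
    rf = simple_rf()
    E, _ = tuning(rf, (2.0, 0.0))
    assert E == pytest.approx(10.0 * math.exp(-0.5), rel=1e-12)


def test_net_drive_rectified_and_dominance():
    rf = simple_rf()
    rng = np.random.default_rng(0)
    pts = rng.uniform(-10, 10, size=(200, 2))
    base = net_drive(rf, pts, "baseline")
    disinh = net_drive(rf, pts, "disinhibited")
    assert np.all(base >= 0)
    assert np.all(disinh >= base)
    with pytest.raises(ValueError):
        net_drive(rf, (0.0, 0.0), "blocked")
    with pytest.raises(ValueError):
        net_drive(rf, (0.0, 0.0), kappa=1.5)


def test_rfspec_validation():
    with pytest.raises(ValueError):
        simple_rf(w_I=1.0)  # inhibition narrower than excitation
    with pytest.raises(ValueError):
        simple_rf(theta=0.0)
    with pytest.raises(ValueError):
        simple_rf(cell_class="wide_dynamic_range")


def test_empty_rf_error():
    rf = simple_rf(A_En=1.0, A_I=6.0, w_I=5.0, w_En=2.0, theta=50.0)
    with pytest.raises(EmptyRFError):
        compute_zones(rf)


def test_grid_area_matches_radial_oracle(adapting_rf, non_adapting_rf):
    for rf in (adapting_rf, non_adapting_rf):
        z = compute_zones(rf, resolution=0.05)
        r_base = rf_edge_radius(rf, "baseline")
        r_dis = rf_edge_radius(rf, "disinhibited")
        assert z.center_area == pytest.approx(math.pi * r_base**2, rel=0.02)
        assert z.center_area + z.surround_area == pytest.approx(
            math.pi * r_dis**2, rel=0.02
        )


def test_area_converged_in_resolution(adapting_rf):
    a1 = compute_zones(adapting_rf, resolution=0.1).center_area
    a2 = compute_zones(adapting_rf, resolution=0.05).center_area
    assert abs(a1 - a2) / a2 < 0.02


def test_canonical_area_directions(adapting_rf, non_adapting_rf):
    za = compute_zones(adapting_rf, resolution=0.1)
    zn = compute_zones(non_adapting_rf, resolution=0.1)
    assert za.center_area < zn.center_area
    ta = za.center_area + za.surround_area
    tn = zn.center_area + zn.surround_area
    assert abs(ta - tn) <= 0.2 * max(ta, tn)


def test_zone_drive_identities(adapting_rf):
    z = compute_zones(adapting_rf, resolution=0.1)
    d = zone_drive(adapting_rf, z, "surround", "disinhibited")
    assert d.drive == pytest.approx(d.area * d.rate)
    # canonical adapting: surround out-drives center after disinhibition
    dc = zone_drive(adapting_rf, z, "center", "disinhibited")
    assert d.drive > dc.drive
    # empty surround -> zero drive
    rf0 = simple_rf(A_I=0.001, w_I=5.0, theta=5.0)
    z0 = compute_zones(rf0)
    s0 = zone_drive(rf0, z0, "surround", "disinhibited")
    assert s0.area == 0.0 and s0.drive == 0.0


def test_stimulus_to_drive_alpha_anchors(adapting_rf, non_adapting_rf):
    for rf in (adapting_rf, non_adapting_rf):
        center = stimulus_to_drive(rf, StimulusEvent("c", "brush", rf.center))
        assert 0.3 <= center.alpha <= 0.8
        surround = stimulus_to_drive(
            rf, StimulusEvent("s", "brush", mid_surround_position(rf))
        )
        assert surround.alpha > 1.0


def test_stimulus_to_drive_additivity_and_decay(adapting_rf):
    stim = StimulusEvent("c", "brush", adapting_rf.center)
    one = stimulus_to_drive(adapting_rf, stim)
    two = stimulus_to_drive(adapting_rf, [stim, stim])
    assert two.exc.g0 == pytest.approx(2 * one.exc.g0)
    assert two.inh.g0 == pytest.approx(2 * one.inh.g0)
    far = stimulus_to_drive(
        adapting_rf, StimulusEvent("f", "brush", (50.0, 50.0))
    )
    assert far.exc.g0 < 0.01 * one.exc.g0
    assert far.inh.g0 < 0.01 * one.inh.g0


def test_stimulus_event_validation():
    with pytest.raises(ValueError):
        StimulusEvent("x", "laser", (0.0, 0.0))
    with pytest.raises(ValueError):
        StimulusEvent("x", "vf", (0.0, 0.0))  # force required


def test_costim_ratio_directions(adapting_rf, non_adapting_rf):
    for rf in (adapting_rf, non_adapting_rf):
        assert costim_ratio_analytic(rf, "baseline") < 1.0
        assert costim_ratio_analytic(rf, "disinhibited") > 1.0
    assert (
        costim_ratio_analytic(adapting_rf, "baseline")
        < costim_ratio_analytic(non_adapting_rf, "baseline")
    )
    assert (
        costim_ratio_analytic(adapting_rf, "disinhibited")
        > costim_ratio_analytic(non_adapting_rf, "disinhibited")
    )
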