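"""Unit tests for the OU conductance generator and synaptic current."""

import numpy as np
import pytest

from dorsalhorn.ou_synapse import (
    OUParams,
    SynapticDriveSpec,
    generate_ou_trace,
    synaptic_current,
)

DT = 0.05


def test_sigma_zero_is_constant():
    tr = generate_ou_trace(OUParams(g0=2.0, sigma=0.0, tau=3.0), 100.0, DT)
    assert np.all(tr.values == 2.0)


def test_stationary_mean_and_sd():
    # closed-form stationary law N(g0, sigma^2), unrectified path
    tr = generate_ou_trace(
        OUParams(g0=5.0, sigma=1.0, tau=10.0, seed=1), 200_000.0, DT,
        rectify=False,
    )
    assert abs(tr.values.mean() - 5.0) / 5.0 < 0.02
    assert abs(tr.values.std() - 1.0) < 0.05


def test_autocorrelation_matches_exponential():
    tau = 3.0
    tr = generate_ou_trace(
        OUParams(g0=5.0, sigma=1.0, tau=tau, seed=2), 100_000.0, DT,
        rectify=False,
    )
    x = tr.values - tr.values.mean()
    var = float(np.dot(x, x) / len(x))
    for lag_ms in (1.0, 3.0, 5.0, 10.0):
        k = int(round(lag_ms / DT))
        acf = float(np.dot(x[:-k], x[k:]) / (len(x) - k)) / var
        # absolute slack covers sampling noise where the ACF is small
        assert acf == pytest.approx(np.exp(-lag_ms / tau), rel=0.05, abs=0.01)


def test_exact_vs_euler_maruyama_oracle():
    # dt <= tau/100: the two schemes agree within 2% in mean and SD
    tau = 3.0
    p = OUParams(g0=5.0, sigma=1.0, tau=tau, seed=3)
    dt = tau / 100.0
    a = generate_ou_trace(p, 100_000.0, dt, method="exact", rectify=False).values
    b = generate_ou_trace(p, 100_000.0, dt, method="euler", rectify=False).values
    assert abs(a.mean() - b.mean()) / b.mean() < 0.02
    assert abs(a.std() - b.std()) / b.std() < 0.02


def test_rectification():
    # all samples >= 0; with g0 >= 4 sigma rectification is essentially inert
    low = generate_ou_trace(OUParams(g0=0.5, sigma=1.0, tau=3.0, seed=4), 10_000.0, DT)
    assert np.all(low.values >= 0.0)
    p = OUParams(g0=4.0, sigma=1.0, tau=3.0, seed=5)
    raw = generate_ou_trace(p, 100_000.0, DT, rectify=False).values
    assert np.mean(raw < 0) < 1e-3


def test_seed_determinism_and_independence():
    p = OUParams(g0=5.0, sigma=1.0, tau=10.0, seed=6)
    a = generate_ou_trace(p, 100_000.0, DT).values
    b = generate_ou_trace(p, 100_000.0, DT).values
    assert np.array_equal(a, b)
    c = generate_ou_trace(
        OUParams(g0=5.0, sigma=1.0, tau=10.0, seed=7), 100_000.0, DT
    ).values
    r = np.corrcoef(a, c)[0, 1]
    assert abs(r) < 0.05


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(g0=-1.0, sigma=1.0, tau=3.0),
        dict(g0=1.0, sigma=-1.0, tau=3.0),
        dict(g0=1.0, sigma=1.0, tau=0.0),
        dict(g0=float("nan"), sigma=1.0, tau=3.0),
    ],
)
def test_invalid_params(kwargs):
    with pytest.raises(ValueError):
        OUParams(**kwargs)


def test_generate_argument_errors():
    p = OUParams(g0=1.0, sigma=0.5, tau=3.0)
    with pytest.raises(ValueError):
        generate_ou_trace(p, 10.0, 0.0)
    with pytest.raises(ValueError):
        generate_ou_trace(p, 0.01, 0.05)  # duration < dt
    with pytest.raises(ValueError):
        generate_ou_trace(p, 10.0, 0.05, method="rk4")


def _spec(E_inh=-70.0):
    return SynapticDriveSpec(
        exc=OUParams(g0=1.0, sigma=0.0, tau=3.0),
        inh=OUParams(g0=2.0, sigma=0.0, tau=10.0),
        E_exc=0.0,
        E_inh=E_inh,
    )


def test_synaptic_current_examples():
    # zero driving force
    assert synaptic_current(5.0, 0.0, 0.0, _spec()) == 0.0
    # 10 nS inhibition at -65 mV: outward for E_inh = -70, inward for -45
    assert synaptic_current(0.0, 10.0, -65.0, _spec(-70.0)) == pytest.approx(50.0)
    assert synaptic_current(0.0, 10.0, -65.0, _spec(-45.0)) == pytest.approx(-200.0)


def test_synaptic_current_rejects_nonfinite():
    with pytest.raises(ValueError):
        synaptic_current(float("nan"), 0.0, -70.0, _spec())


def test_drive_spec_invariants():
    assert _spec().alpha == pytest.approx(2.0)
    with pytest.raises(ValueError):
        SynapticDriveSpec(
            exc=OUParams(g0=1.0, sigma=0.0, tau=3.0),
            inh=OUParams(g0=1.0, sigma=0.0, tau=10.0),
            E_exc=-80.0,
            E_inh=-70.0,
        )
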