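"""Conductance-based point-neuron models for the two dorsal horn cell classes.

Superficial dorsal horn interneurons fall into two electrophysiological
groups: tonic-spiking inhibitory neurons, which convert sustained
depolarization into sustained firing, and delayed- or single-spiking
excitatory neurons, whose A-type potassium current suppresses or delays
firing at depolarization onset.  We represent both with a Morris-Lecar-
style spiking core — instantaneous sodium activation m_inf(V) plus one
recovery variable w — augmented by an inactivating A-type potassium
current (activation a_inf(V), slow inactivation b) for the excitatory
classes, and by a standing ("tonic") chloride conductance for the
inhibitory class.  The tonic conductance is what couples the resting
potential of inhibitory neurons to the chloride reversal potential E_inh:
a depolarizing shift of E_inh (chloride dysregulation) depolarizes these
cells even without any stimulus-evoked input, whereas excitatory-class
cells, lacking the tonic conductance, keep their resting potential.

Units are absolute — pF, nS, mV, pA, ms — so OU conductances in nS plug
in directly and dV/dt = I/C comes out in mV/ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from ._core import ml_loop
from .ou_synapse import OUParams, SynapticDriveSpec, Trace, generate_ou_trace

__all__ = [
    "NeuronModel",
    "SpikeTrain",
    "IntegrationError",
    "ClassificationError",
    "integrate",
    "resting_potential",
    "find_rheobase",
    "classify_spiking_pattern",
    "detect_spikes",
]

SPIKE_THRESHOLD = -10.0  # mV, upward crossing
SPIKE_DEAD_TIME = 1.0  # ms
DEFAULT_DT = 0.05  # ms


class IntegrationError(RuntimeError):
    """Numerical blow-up during integration."""


class ClassificationError(RuntimeError):
    """The model produced no classifiable step response."""


@dataclass(frozen=True)
class NeuronModel:
    """Parameter set of one model neuron.

    The spike-generating core has instantaneous activation
    m_inf(V) = 0.5*(1 + tanh((V - beta_m)/gamma_m)) and recovery
    dw/dt = phi_w * cosh((V - beta_w)/(2*gamma_w)) * (w_inf(V) - w).
    The A-current (excitatory classes) is gA * a_inf(V) * b * (V - EK)
    with sigmoidal activation a_inf, inactivation b_inf and inactivation
    time constant tau_b.  ``g_tonic`` is a standing conductance reversing
    at the inhibitory reversal potential supplied at integration time.
    """

    label: str  # {excitatory_delayed, excitatory_single, inhibitory_tonic}
    C: float = 20.0  # pF
    gL: float = 20.0  # nS
    EL: float = -70.0  # mV
    gNa: float = 200.0
    ENa: float = 50.0
    gK: float = 200.0
    EK: float = -100.0
    beta_m: float = -1.2
    gamma_m: float = 18.0
    beta_w: float = -10.0
    gamma_w: float = 10.0
    phi_w: float = 0.15
    gA: float = 0.0
    beta_a: float = -45.0
    gamma_a: float = 10.0
    beta_b: float = -65.0
    gamma_b: float = 6.0
    tau_b: float = 300.0
    g_tonic: float = 0.0

    def __post_init__(self) -> None:
        for name in ("C", "gL", "gNa", "gK", "gA", "g_tonic", "tau_b", "phi_w"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"NeuronModel.{name} must be finite and >= 0, got {v}")
        if self.C == 0:
            raise ValueError("capacitance must be positive")
        if self.label not in (
            "excitatory_delayed",
            "excitatory_single",
            "inhibitory_tonic",
        ):
            raise ValueError(f"unknown cell label {self.label!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronModel":
        return cls(**d)

    # gating helpers (vectorized, used by the fixed-point solver and tests)
    def m_inf(self, V):
        return 0.5 * (1.0 + np.tanh((V - self.beta_m) / self.gamma_m))

    def w_inf(self, V):
        return 0.5 * (1.0 + np.tanh((V - self.beta_w) / self.gamma_w))

    def a_inf(self, V):
        return 1.0 / (1.0 + np.exp(-(V - self.beta_a) / self.gamma_a))

    def b_inf(self, V):
        return 1.0 / (1.0 + np.exp((V - self.beta_b) / self.gamma_b))


@dataclass
class SpikeTrain:
    """Ordered spike times (ms) of one unit over a recording of known length."""

    times: np.ndarray
    duration: float
    unit_id: str = "unit"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if len(self.times) and (np.any(np.diff(self.times) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if len(self.times) and (self.times[0] < 0 or self.times[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return len(self.times)

    def rate(self, t0: float = 0.0, t1: float | None = None) -> float:
        """Mean firing rate (spikes/s) in the window [t0, t1)."""
        if t1 is None:
            t1 = self.duration
        if t1 <= t0:
            raise ValueError("empty rate window")
        n = np.count_nonzero((self.times >= t0) & (self.times < t1))
        return 1000.0 * n / (t1 - t0)


def detect_spikes(V: np.ndarray, dt: float, threshold: float = SPIKE_THRESHOLD,
                  dead_time: float = SPIKE_DEAD_TIME) -> np.ndarray:
    """Spike times from a voltage trace: upward threshold crossings
    separated by at least ``dead_time`` ms."""
    above = V >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if len(crossings) == 0:
        return np.empty(0)
    times = crossings * dt
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= dead_time:
            kept.append(t)
    return np.asarray(kept)


def _steady_current(model: NeuronModel, V: float, E_tonic: float) -> float:
    I = (
        model.gL * (V - model.EL)
        + model.gNa * model.m_inf(V) * (V - model.ENa)
        + model.gK * model.w_inf(V) * (V - model.EK)
    )
    if model.gA > 0:
        I += model.gA * model.a_inf(V) * model.b_inf(V) * (V - model.EK)
    if model.g_tonic > 0:
        I += model.g_tonic * (V - E_tonic)
    return I


def resting_potential(model: NeuronModel, E_tonic: float = -70.0) -> float:
    """Lowest zero-current fixed point of the steady-state I-V curve."""
    grid = np.linspace(-100.0, -20.0, 401)
    I = np.array([_steady_current(model, v, E_tonic) for v in grid])
    sign = np.sign(I)
    for i in range(len(grid) - 1):
        if sign[i] < 0 and sign[i + 1] >= 0:
            return brentq(lambda v: _steady_current(model, v, E_tonic), grid[i], grid[i + 1])
    raise ValueError("no stable resting fixed point found in [-100, -20] mV")


def _as_sample_array(drive, n: int, dt: float):
    """Normalize a drive argument to (g_exc, g_inh, E_exc, E_inh, I_app)."""
    zero = np.zeros(1)
    if drive is None:
        return zero, zero, 0.0, -70.0, zero
    if isinstance(drive, (int, float)):
        return zero, zero, 0.0, -70.0, np.full(1, float(drive))
    if isinstance(drive, Trace):
        if drive.kind != "current":
            raise ValueError("a Trace drive must be a current trace")
        vals = drive.values
        if len(vals) < n:
            raise ValueError("current trace shorter than the simulation")
        if abs(drive.dt - dt) > 1e-12:
            raise ValueError("current trace dt must match the integration dt")
        return zero, zero, 0.0, -70.0, vals[:n]
    raise TypeError(f"unsupported drive type {type(drive)!r}")


def integrate(
    model: NeuronModel,
    drive=None,
    duration: float = 1000.0,
    dt: float = DEFAULT_DT,
    V0: float | None = None,
    *,
    E_tonic: float = -70.0,
    unit_id: str = "unit",
    rng: np.random.Generator | None = None,
) -> tuple[Trace, SpikeTrain]:
    """Integrate the neuron model under a drive.

    ``drive`` may be ``None``/a constant current step (pA), a current
    ``Trace``, or a ``SynapticDriveSpec`` whose OU conductances are
    realized here and converted to current from the instantaneous voltage
    at every step (the dynamic-clamp loop).  ``E_tonic`` sets the reversal
    of the model's standing tonic conductance; under chloride
    dysregulation it shifts along with the drive's E_inh.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    n = int(round(duration / dt)) + 1

    if isinstance(drive, SynapticDriveSpec):
        if rng is not None:
            ge = generate_ou_trace(drive.exc, duration, dt, rng=rng).values
            gi = generate_ou_trace(drive.inh, duration, dt, rng=rng).values
        else:
            ge = generate_ou_trace(drive.exc, duration, dt).values
            gi = generate_ou_trace(drive.inh, duration, dt).values
        E_exc, E_inh = drive.E_exc, drive.E_inh
        I_app = np.zeros(1)
    else:
        ge, gi, E_exc, E_inh, I_app = _as_sample_array(drive, n, dt)

    if V0 is None:
        try:
            V0 = resting_potential(model, E_tonic)
        except ValueError:
            # no stable rest (e.g. tonic conductance with depolarized
            # reversal drives spontaneous firing): start from the leak reversal
            V0 = model.EL
    w0 = float(model.w_inf(V0))
    b0 = float(model.b_inf(V0))

    V, bad = ml_loop(
        V0, w0, b0, n, dt,
        model.C, model.gL, model.EL, model.gNa, model.ENa, model.gK, model.EK,
        model.beta_m, model.gamma_m, model.beta_w, model.gamma_w, model.phi_w,
        model.gA, model.beta_a, model.gamma_a, model.beta_b, model.gamma_b,
        model.tau_b, model.g_tonic, E_tonic,
        np.ascontiguousarray(ge), np.ascontiguousarray(gi), E_exc, E_inh,
        np.ascontiguousarray(I_app),
    )
    if bad >= 0:
        raise IntegrationError(
            f"integration blew up at step {bad} (t = {bad * dt:.3f} ms)"
        )
    spikes = detect_spikes(V, dt)
    return (
        Trace(dt=dt, values=V, kind="voltage"),
        SpikeTrain(times=spikes, duration=duration, unit_id=unit_id),
    )


def _step_response(model: NeuronModel, amp: float, duration: float, dt: float,
                   E_tonic: float) -> SpikeTrain:
    _, st = integrate(model, float(amp), duration, dt, E_tonic=E_tonic)
    return st


def find_rheobase(
    model: NeuronModel,
    duration: float = 500.0,
    dt: float = DEFAULT_DT,
    tol: float = 1.0,
    I_max: float = 6400.0,
    E_tonic: float = -70.0,
) -> float:
    """Minimal current step (pA) evoking >= 1 spike in ``duration`` ms,
    found by bisection to ``tol`` pA."""
    lo, hi = 0.0, 50.0
    while hi <= I_max and len(_step_response(model, hi, duration, dt, E_tonic)) == 0:
        lo, hi = hi, hi * 2.0
    if hi > I_max:
        raise ClassificationError(
            f"no spikes up to {I_max} pA: model has no accessible spiking regime"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if len(_step_response(model, mid, duration, dt, E_tonic)) > 0:
            hi = mid
        else:
            lo = mid
    return hi


def classify_spiking_pattern(
    model: NeuronModel,
    dt: float = DEFAULT_DT,
    step_duration: float = 500.0,
    latency_criterion: float = 100.0,
    E_tonic: float = -70.0,
) -> str:
    """Classify the step-response phenotype on 500 ms current steps.

    Steps at 1.1x, 1.5x and 2x rheobase are applied.  ``single``: exactly
    one spike at every amplitude.  ``delayed``: first-spike latency
    > 100 ms at 1.1x rheobase.  ``tonic``: spikes in the final 100 ms at
    every amplitude (and prompt onset, so delayed takes precedence).
    Anything else: ``other``.
    """
    rheo = find_rheobase(model, step_duration, dt, E_tonic=E_tonic)
    trains = [
        _step_response(model, f * rheo, step_duration, dt, E_tonic)
        for f in (1.1, 1.5, 2.0)
    ]
    counts = [len(st) for st in trains]
    if min(counts) == 0:
        # rheobase bracketed at 500 ms, so 1.1x must spike; guard anyway
        raise ClassificationError("no spikes at suprarheobase amplitudes")
    if all(c == 1 for c in counts):
        return "single"
    if trains[0].times[0] > latency_criterion:
        return "delayed"
    if all(st.times[-1] >= step_duration - 100.0 for st in trains):
        return "tonic"
    return "other"
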