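"""Stochastic synaptic conductances and their conversion to current.

Noisy excitatory and inhibitory synaptic bombardment is modelled as a pair
of independent Ornstein-Uhlenbeck (OU) processes

    dg/dt = -(g - g0)/tau + sqrt(2/tau) * sigma * xi(t),

where ``xi`` is unit-variance white noise, ``g0`` the mean conductance,
``sigma`` the stationary standard deviation and ``tau`` the correlation
time.  Excitatory kinetics are fast (tau ~ 3 ms) and inhibitory kinetics
slower (tau ~ 10 ms), reflecting AMPA- versus GABA/glycine-receptor decay.
Generated conductances are rectified at zero: a conductance cannot be
negative, and with g0 well above sigma rectification is a rare event.

Conductances are converted to membrane current through the driving force,

    I_syn = g_exc * (V - E_exc) + g_inh * (V - E_inh),

with the convention that positive I_syn is outward (hyperpolarizing); the
current injected into a neuron is ``-I_syn``.  Units throughout: nS, mV,
pA, ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "OUParams",
    "Trace",
    "SynapticDriveSpec",
    "generate_ou_trace",
    "synaptic_current",
]


@dataclass(frozen=True)
class OUParams:
    """Parameters of one OU conductance channel.

    Attributes
    ----------
    g0 : float
        Mean conductance (nS), >= 0.
    sigma : float
        Stationary standard deviation of the fluctuations (nS), >= 0.
    tau : float
        Correlation time (ms), > 0.
    seed : int
        Seed for the channel's private random stream.  Identical
        ``(params, dt, duration)`` reproduce identical traces.
    """

    g0: float
    sigma: float
    tau: float
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("g0", "sigma", "tau"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"OUParams.{name} must be finite, got {v!r}")
        if self.g0 < 0:
            raise ValueError(f"mean conductance g0 must be >= 0, got {self.g0}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.tau <= 0:
            raise ValueError(f"correlation time tau must be > 0, got {self.tau}")


@dataclass
class Trace:
    """A uniformly sampled signal (conductance, voltage or current)."""

    dt: float
    values: np.ndarray
    kind: str = "conductance"  # {"conductance", "voltage", "current"}

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")
        if self.kind not in ("conductance", "voltage", "current"):
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def t(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(len(self.values)) * self.dt

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) * self.dt

    def units(self) -> str:
        return {"conductance": "nS", "voltage": "mV", "current": "pA"}[self.kind]


# alpha = g_inh0 / g_exc0: ~0.5 models stimulation in the receptive-field
# center (excitation-dominated), ~2 stimulation in the surround.
@dataclass(frozen=True)
class SynapticDriveSpec:
    """Paired excitatory + inhibitory OU drives with reversal potentials."""

    exc: OUParams
    inh: OUParams
    E_exc: float = 0.0
    E_inh: float = -70.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.E_exc) and math.isfinite(self.E_inh)):
            raise ValueError("reversal potentials must be finite")
        if self.E_exc <= self.E_inh:
            raise ValueError(
                f"E_exc ({self.E_exc} mV) must exceed E_inh ({self.E_inh} mV)"
            )

    @property
    def alpha(self) -> float:
        """Inhibition-to-excitation ratio g_inh0 / g_exc0."""
        if self.exc.g0 == 0:
            return math.inf if self.inh.g0 > 0 else math.nan
        return self.inh.g0 / self.exc.g0


def _n_samples(duration: float, dt: float) -> int:
    return int(round(duration / dt)) + 1


def generate_ou_trace(
    params: OUParams,
    duration: float,
    dt: float,
    *,
    rectify: bool = True,
    method: str = "exact",
    rng: np.random.Generator | None = None,
) -> Trace:
    """Generate one OU conductance path.

    The default integrator is the exact discretization of the OU process,

        g[n+1] = g0 + (g[n] - g0) * a + sigma * sqrt(1 - a^2) * xi[n],
        a = exp(-dt / tau),

    initialized at ``g[0] = g0``, which is unconditionally stable and has
    the exact stationary law N(g0, sigma^2) at every step.  ``method
    ="euler"`` selects the Euler-Maruyama scheme (``g += dt*(g0-g)/tau +
    sqrt(2*dt/tau)*sigma*xi``), useful as an independent cross-check at
    small dt.

    Parameters
    ----------
    params : OUParams
    duration : float
        Trace length (ms); the trace has round(duration/dt)+1 samples.
    dt : float
        Sample interval (ms).
    rectify : bool
        Replace negative samples by 0 (a conductance cannot be negative).
        Pass ``rectify=False`` to retrieve the raw path; the same seed
        yields the identical underlying path either way.
    method : {"exact", "euler"}
    rng : numpy Generator, optional
        Overrides the seeded stream from ``params.seed`` (used when a
        caller manages its own stream).
    """
    if dt <= 0 or not math.isfinite(dt):
        raise ValueError(f"dt must be positive and finite, got {dt}")
    if duration < dt:
        raise ValueError(f"duration ({duration}) must be >= dt ({dt})")
    n = _n_samples(duration, dt)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    if params.sigma == 0.0:
        values = np.full(n, params.g0)
        return Trace(dt=dt, values=values, kind="conductance")

    xi = rng.standard_normal(n - 1)
    if method == "exact":
        a = math.exp(-dt / params.tau)
        s = params.sigma * math.sqrt(1.0 - a * a)
    elif method == "euler":
        a = 1.0 - dt / params.tau
        s = params.sigma * math.sqrt(2.0 * dt / params.tau)
        if a <= -1.0:
            raise ValueError("Euler-Maruyama unstable: dt must be < 2*tau")
    else:
        raise ValueError(f"unknown method {method!r}")

    # AR(1) recursion x[n] = a*x[n-1] + s*xi[n] as an IIR filter (x = g - g0)
    x = lfilter([1.0], [1.0, -a], s * xi)
    values = np.empty(n)
    values[0] = params.g0
    values[1:] = params.g0 + x
    if rectify:
        np.maximum(values, 0.0, out=values)
    return Trace(dt=dt, values=values, kind="conductance")


def synaptic_current(g_exc, g_inh, V, spec: SynapticDriveSpec):
    """Total synaptic current (pA) at membrane potential ``V``.

    Positive values are outward (hyperpolarizing); the current delivered
    to a neuron model is ``-synaptic_current(...)``.  Accepts scalars or
    arrays (broadcast element-wise).
    """
    g_exc = np.asarray(g_exc, dtype=float)
    g_inh = np.asarray(g_inh, dtype=float)
    V = np.asarray(V, dtype=float)
    if not (
        np.all(np.isfinite(g_exc))
        and np.all(np.isfinite(g_inh))
        and np.all(np.isfinite(V))
    ):
        raise ValueError("synaptic_current inputs must be finite")
    I = g_exc * (V - spec.E_exc) + g_inh * (V - spec.E_inh)
    return float(I) if I.ndim == 0 else I
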