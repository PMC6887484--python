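"""Center-surround receptive-field model and its disinhibition predictions.

A unit's cutaneous receptive field (RF) is built from radially symmetric
Gaussian tuning curves on the 2-D skin surface: a narrow excitatory
component (amplitude ``A_En``, width ``w_En``), a broad excitatory
component (``A_Eb``, ``w_Eb``) and a broad inhibitory component
(``A_I``, ``w_I``) with ``w_I > w_En``.  Under normal chloride
regulation the net drive at a skin position is the rectified difference
``max(E(x) - I(x), 0)``; the region where it exceeds a threshold
``theta`` is the RF *center*.  Chloride dysregulation removes the
hyperpolarizing efficacy of the inhibitory component, so the
disinhibited net drive is ``E(x)`` alone; the additional suprathreshold
region is the RF *surround*.  Partial dysregulation is exposed as a
scalar ``kappa`` multiplying the inhibitory component (1 = intact, 0 =
complete loss).

The *drive* contributed by an RF zone is the product of zone area and
the mean evoked firing rate in that zone — the metric used to compare
how much excitation each zone supplies before and after disinhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .ou_synapse import OUParams, SynapticDriveSpec

__all__ = [
    "RFSpec",
    "RFZones",
    "ZoneDrive",
    "StimulusEvent",
    "EmptyRFError",
    "tuning",
    "net_drive",
    "compute_zones",
    "zone_drive",
    "stimulus_to_drive",
    "default_rate_map",
    "rf_edge_radius",
    "mid_surround_position",
    "costim_ratio_analytic",
    "force_scale",
    "RATE_GAIN",
    "VF_FORCES_G",
]

CONDITIONS = ("baseline", "disinhibited")

# Linear rate-map gain (spikes/s per nS of net drive).  Fixed so that
# brush stimulation of the canonical adapting RF center at baseline
# evokes on the order of 15 spk/s; any monotone map with rate_map(0)=0
# preserves every direction check in this module.
RATE_GAIN = 4.2

VF_FORCES_G = (2.0, 4.0, 6.0, 8.0, 10.0)
BRUSH_FORCE_SCALE = 0.6


class EmptyRFError(ValueError):
    """The drive threshold exceeds the maximum net drive: no RF exists."""


@dataclass(frozen=True)
class RFSpec:
    """Spatial tuning parameters of one unit's receptive field."""

    A_En: float
    w_En: float
    A_Eb: float
    w_Eb: float
    A_I: float
    w_I: float
    theta: float
    cell_class: str = "adapting"  # {adapting, non_adapting}
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("A_En", "w_En", "A_I", "w_I", "theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RFSpec.{name} must be > 0")
        if self.A_Eb < 0 or (self.A_Eb > 0 and self.w_Eb <= 0):
            raise ValueError("broad excitatory component needs A_Eb >= 0, w_Eb > 0")
        if self.w_I <= self.w_En:
            raise ValueError(
                "inhibition must be broader than the narrow excitatory "
                f"component (w_I={self.w_I} <= w_En={self.w_En})"
            )
        if self.cell_class not in ("adapting", "non_adapting"):
            raise ValueError(f"unknown cell class {self.cell_class!r}")


@dataclass
class RFZones:
    """Grid-derived RF zones and their areas (mm^2)."""

    center_area: float
    surround_area: float
    resolution: float
    # grid bookkeeping for zone averages
    xx: np.ndarray
    yy: np.ndarray
    center_mask: np.ndarray
    surround_mask: np.ndarray


@dataclass(frozen=True)
class ZoneDrive:
    """Excitatory drive from one RF zone: area x evoked rate."""

    zone: str  # {center, surround}
    condition: str  # {baseline, disinhibited}
    area: float  # mm^2
    rate: float  # spikes/s

    @property
    def drive(self) -> float:
        return self.area * self.rate


@dataclass(frozen=True)
class StimulusEvent:
    """One 1 s tactile stimulus application on the skin."""

    stim_id: str
    kind: str  # {brush, vf}
    position: tuple[float, float]  # mm
    onset: float = 0.0  # ms
    duration: float = 1000.0  # ms
    force_g: float | None = None  # von Frey force, grams
    zone: str = "center"  # {center, surround, costim}

    def __post_init__(self) -> None:
        if self.kind not in ("brush", "vf"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "vf":
            if self.force_g is None or self.force_g <= 0:
                raise ValueError("von Frey stimulus needs a positive force_g")


def _r2(rf: RFSpec, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    cx, cy = rf.center
    if x.ndim == 1:
        return (x[0] - cx) ** 2 + (x[1] - cy) ** 2
    return (x[..., 0] - cx) ** 2 + (x[..., 1] - cy) ** 2


def tuning(rf: RFSpec, x):
    """Excitatory and inhibitory conductance tuning (nS) at position ``x``.

    ``x`` is a length-2 position or an array of positions with last axis 2.
    """
    r2 = _r2(rf, x)
    E = rf.A_En * np.exp(-r2 / (2.0 * rf.w_En**2))
    if rf.A_Eb > 0:
        E = E + rf.A_Eb * np.exp(-r2 / (2.0 * rf.w_Eb**2))
    I = rf.A_I * np.exp(-r2 / (2.0 * rf.w_I**2))
    return E, I


def net_drive(rf: RFSpec, x, condition: str = "baseline", kappa: float | None = None):
    """Net suprathreshold-able drive at ``x`` (nS), >= 0.

    ``condition`` selects kappa = 1 (baseline) or 0 (disinhibited); an
    explicit ``kappa`` in [0, 1] models partial chloride dysregulation.
    """
    if kappa is None:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        kappa = 1.0 if condition == "baseline" else 0.0
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [0, 1], got {kappa}")
    E, I = tuning(rf, x)
    return np.maximum(E - kappa * I, 0.0)


def _radial_net(rf: RFSpec, r: float, kappa: float) -> float:
    x = (rf.center[0] + r, rf.center[1])
    return float(net_drive(rf, x, kappa=kappa))


def rf_edge_radius(rf: RFSpec, condition: str = "baseline", r_max: float | None = None) -> float:
    """Outermost radius where the net drive crosses theta (1-D root finding).

    Serves as the analytic oracle for the grid areas of radially
    symmetric RFs (area = pi * r_edge^2 when the suprathreshold region
    is a disc).
    """
    kappa = 1.0 if condition == "baseline" else 0.0
    if r_max is None:
        r_max = 6.0 * max(rf.w_En, rf.w_Eb, rf.w_I)
    rr = np.linspace(0.0, r_max, 2000)
    pos = np.stack([rf.center[0] + rr, np.full_like(rr, rf.center[1])], axis=-1)
    vals = net_drive(rf, pos, kappa=kappa) - rf.theta
    above = np.flatnonzero(vals > 0)
    if len(above) == 0:
        raise EmptyRFError("net drive never exceeds theta")
    i = above[-1]
    if i == len(rr) - 1:
        raise ValueError("r_max too small to bracket the RF edge")
    return brentq(lambda r: _radial_net(rf, r, kappa) - rf.theta, rr[i], rr[i + 1])


def compute_zones(rf: RFSpec, resolution: float = 0.1, extent: float | None = None) -> RFZones:
    """RF center/surround areas by 2-D grid integration.

    ``resolution`` is the grid spacing (mm); ``extent`` the half-width of
    the integration square around the RF center (defaults to 4x the
    widest tuning curve, beyond which all components are negligible).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if extent is None:
        extent = 4.0 * max(rf.w_En, rf.w_Eb if rf.A_Eb > 0 else 0.0, rf.w_I)
    g = np.arange(-extent, extent + resolution / 2, resolution)
    xx, yy = np.meshgrid(g + rf.center[0], g + rf.center[1])
    pos = np.stack([xx, yy], axis=-1)
    base = net_drive(rf, pos, "baseline")
    disinh = net_drive(rf, pos, "disinhibited")
    center_mask = base > rf.theta
    surround_mask = (disinh > rf.theta) & ~center_mask
    if not center_mask.any() and not surround_mask.any():
        raise EmptyRFError("theta exceeds the maximum net drive everywhere")
    cell = resolution**2
    return RFZones(
        center_area=float(center_mask.sum() * cell),
        surround_area=float(surround_mask.sum() * cell),
        resolution=resolution,
        xx=xx,
        yy=yy,
        center_mask=center_mask,
        surround_mask=surround_mask,
    )


def default_rate_map(drive):
    """Rectified-linear map from net drive (nS) to evoked rate (spk/s)."""
    return RATE_GAIN * np.maximum(drive, 0.0)


def zone_drive(
    rf: RFSpec,
    zones: RFZones,
    zone: str,
    condition: str,
    rate_map: Callable = default_rate_map,
) -> ZoneDrive:
    """Drive (area x mean evoked rate) from one RF zone under a condition."""
    if zone not in ("center", "surround"):
        raise ValueError(f"unknown zone {zone!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    mask = zones.center_mask if zone == "center" else zones.surround_mask
    area = zones.center_area if zone == "center" else zones.surround_area
    if not mask.any():
        return ZoneDrive(zone=zone, condition=condition, area=0.0, rate=0.0)
    pos = np.stack([zones.xx[mask], zones.yy[mask]], axis=-1)
    rates = rate_map(net_drive(rf, pos, condition))
    return ZoneDrive(zone=zone, condition=condition, area=area, rate=float(np.mean(rates)))


def mid_surround_position(rf: RFSpec) -> tuple[float, float]:
    """A canonical surround stimulation site: the annulus midpoint radius
    between the baseline RF edge and the disinhibited RF edge, on the +x
    axis from the RF center."""
    r0 = rf_edge_radius(rf, "baseline")
    r1 = rf_edge_radius(rf, "disinhibited")
    r = 0.5 * (r0 + r1)
    return (rf.center[0] + r, rf.center[1])


def force_scale(stim: StimulusEvent) -> float:
    """Stimulus-strength scaling of the mapped conductances.

    Von Frey forces 2-10 g map linearly onto [0.2, 1.0]; brush is a
    moderate, fixed-strength stimulus at 0.6.
    """
    if stim.kind == "brush":
        return BRUSH_FORCE_SCALE
    return float(stim.force_g) / 10.0


def costim_ratio_analytic(rf: RFSpec, condition: str = "baseline") -> float:
    """Analytic co-stimulation ratio: response(center + surround) / response(center).

    Brush stimuli at the RF center and at the mid-surround position add
    their mapped conductances component-wise; the responses go through
    the default rectified-linear rate map.  Below 1 the surround supplies
    net inhibition (normal chloride regulation), above 1 net excitation
    (disinhibition).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    kappa = 1.0 if condition == "baseline" else 0.0
    c = StimulusEvent("c", "brush", rf.center)
    s = StimulusEvent("s", "brush", mid_surround_position(rf))

    def resp(stims):
        E = sum(force_scale(st) * float(tuning(rf, st.position)[0]) for st in stims)
        I = sum(force_scale(st) * float(tuning(rf, st.position)[1]) for st in stims)
        return float(default_rate_map(max(E - kappa * I, 0.0)))

    r_center = resp([c])
    if r_center == 0:
        raise EmptyRFError("no center response: co-stimulation ratio undefined")
    return resp([c, s]) / r_center


def stimulus_to_drive(
    rf: RFSpec,
    stim: StimulusEvent | Sequence[StimulusEvent],
    *,
    sigma_factor: float = 1.0 / 3.0,
    tau_exc: float = 3.0,
    tau_inh: float = 10.0,
    E_exc: float = 0.0,
    E_inh: float = -70.0,
    seed: int = 0,
) -> SynapticDriveSpec:
    """Map one or several simultaneous stimuli to a synaptic drive.

    Mean conductances are the RF tuning at the stimulus position scaled
    by stimulus strength; simultaneous stimuli add component-wise
    (co-stimulation).  Fluctuation SDs default to one third of the means.
    """
    stims = [stim] if isinstance(stim, StimulusEvent) else list(stim)
    if not stims:
        raise ValueError("need at least one stimulus")
    g_exc0 = 0.0
    g_inh0 = 0.0
    for s in stims:
        fs = force_scale(s)
        E, I = tuning(rf, s.position)
        g_exc0 += fs * float(E)
        g_inh0 += fs * float(I)
    return SynapticDriveSpec(
        exc=OUParams(g0=g_exc0, sigma=sigma_factor * g_exc0, tau=tau_exc, seed=seed),
        inh=OUParams(g0=g_inh0, sigma=sigma_factor * g_inh0, tau=tau_inh, seed=seed + 1),
        E_exc=E_exc,
        E_inh=E_inh,
    )
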