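"""Compiled inner loop for the point-neuron integrator.

Kept separate so the numba dependency stays behind one small surface.
All quantities are in absolute units: pF, nS, mV, pA, ms.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _deriv(
    v: float,
    w: float,
    b: float,
    C: float,
    gL: float,
    EL: float,
    gNa: float,
    ENa: float,
    gK: float,
    EK: float,
    beta_m: float,
    gamma_m: float,
    beta_w: float,
    gamma_w: float,
    phi_w: float,
    gA: float,
    beta_a: float,
    gamma_a: float,
    beta_b: float,
    gamma_b: float,
    tau_b: float,
    g_tonic: float,
    E_tonic: float,
    ge: float,
    gi: float,
    E_exc: float,
    E_inh: float,
    Ia: float,
):
    m_inf = 0.5 * (1.0 + np.tanh((v - beta_m) / gamma_m))
    w_inf = 0.5 * (1.0 + np.tanh((v - beta_w) / gamma_w))
    tau_w_inv = phi_w * np.cosh((v - beta_w) / (2.0 * gamma_w))
    I_ion = (
        gL * (v - EL)
        + gNa * m_inf * (v - ENa)
        + gK * w * (v - EK)
    )
    db = 0.0
    if gA > 0.0:
        a_inf = 1.0 / (1.0 + np.exp(-(v - beta_a) / gamma_a))
        I_ion += gA * a_inf * b * (v - EK)
        b_inf = 1.0 / (1.0 + np.exp((v - beta_b) / gamma_b))
        db = (b_inf - b) / tau_b
    if g_tonic > 0.0:
        I_ion += g_tonic * (v - E_tonic)
    I_ion += ge * (v - E_exc) + gi * (v - E_inh)
    dV = (Ia - I_ion) / C
    dw = tau_w_inv * (w_inf - w)
    return dV, dw, db


@njit(cache=True)
def ml_loop(
    V0: float,
    w0: float,
    b0: float,
    n: int,
    dt: float,
    C: float,
    gL: float,
    EL: float,
    gNa: float,
    ENa: float,
    gK: float,
    EK: float,
    beta_m: float,
    gamma_m: float,
    beta_w: float,
    gamma_w: float,
    phi_w: float,
    gA: float,
    beta_a: float,
    gamma_a: float,
    beta_b: float,
    gamma_b: float,
    tau_b: float,
    g_tonic: float,
    E_tonic: float,
    g_exc: np.ndarray,
    g_inh: np.ndarray,
    E_exc: float,
    E_inh: float,
    I_app: np.ndarray,
):
    """Fixed-step Heun (RK2) integration of the 3-variable conductance model.

    g_exc/g_inh/I_app are length-n sample arrays (may be length-1 for a
    constant); the synaptic current is recomputed from the instantaneous
    voltage at every step (the dynamic-clamp loop).  The trapezoidal
    corrector keeps the spike-timing phase error second order in dt so
    that spike counts are stable under dt refinement.  Returns the
    voltage array and the index of the first non-finite/run-away step
    (-1 if the integration stayed sane).
    """
    V = np.empty(n)
    V[0] = V0
    w = w0
    b = b0
    bad = -1
    for i in range(n - 1):
        v = V[i]
        ge = g_exc[i] if g_exc.shape[0] > 1 else g_exc[0]
        gi = g_inh[i] if g_inh.shape[0] > 1 else g_inh[0]
        Ia = I_app[i] if I_app.shape[0] > 1 else I_app[0]
        j = i + 1
        ge1 = g_exc[j] if g_exc.shape[0] > 1 else g_exc[0]
        gi1 = g_inh[j] if g_inh.shape[0] > 1 else g_inh[0]
        Ia1 = I_app[j] if I_app.shape[0] > 1 else I_app[0]
        dV1, dw1, db1 = _deriv(
            v, w, b, C, gL, EL, gNa, ENa, gK, EK, beta_m, gamma_m,
            beta_w, gamma_w, phi_w, gA, beta_a, gamma_a, beta_b,
            gamma_b, tau_b, g_tonic, E_tonic, ge, gi, E_exc, E_inh, Ia,
        )
        vp = v + dt * dV1
        wp = w + dt * dw1
        bp = b + dt * db1
        dV2, dw2, db2 = _deriv(
            vp, wp, bp, C, gL, EL, gNa, ENa, gK, EK, beta_m, gamma_m,
            beta_w, gamma_w, phi_w, gA, beta_a, gamma_a, beta_b,
            gamma_b, tau_b, g_tonic, E_tonic, ge1, gi1, E_exc, E_inh, Ia1,
        )
        V[i + 1] = v + 0.5 * dt * (dV1 + dV2)
        w += 0.5 * dt * (dw1 + dw2)
        b += 0.5 * dt * (db1 + db2)
        if w < 0.0:
            w = 0.0
        elif w > 1.0:
            w = 1.0
        if b < 0.0:
            b = 0.0
        elif b > 1.0:
            b = 1.0
        if not np.isfinite(V[i + 1]) or abs(V[i + 1]) > 200.0:
            bad = i + 1
            V[i + 1:] = V0
            break
    return V, bad
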