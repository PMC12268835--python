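"""Compiled numerical kernels for the spin-up integrator.

The steady-state policy integrates the seven-pool system for decades from a
standard initial condition before root-polishing, and Monte Carlo
calibration does this tens of thousands of times.  This module packs the
temperature/moisture-resolved kinetic constants into a flat coefficient
vector and integrates with an adaptive Dormand-Prince (RK45) stepper
compiled by numba.  When numba is unavailable the caller falls back to
scipy's LSODA; a unit test pins both paths to the reference derivative
function.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


N_COEF = 36


def pack_coefficients(params, forcing, rates) -> np.ndarray:
    """Flatten per-evaluation constants for the jitted right-hand side."""
    theta = forcing.moisture
    theta_som = theta if params.moisture_on_som else 1.0
    v, km, ko = rates.vmax, rates.km, params.k_o
    cue, fs_r, fs_k = params.cue, params.f_s["r"], params.f_s["k"]
    c = np.empty(N_COEF)
    c[0] = v[("r", "m")] * theta
    c[1] = v[("r", "s")] * theta
    c[2] = v[("k", "m")] * theta
    c[3] = v[("k", "s")] * theta
    c[4] = v[("r", "a")] * theta_som
    c[5] = v[("k", "a")] * theta_som
    c[6] = v[("r", "s")] * theta_som
    c[7] = v[("k", "s")] * theta_som
    c[8] = km[("r", "m")]
    c[9] = km[("r", "s")]
    c[10] = km[("k", "m")]
    c[11] = km[("k", "s")]
    c[12] = ko["r"] * km[("r", "a")]
    c[13] = ko["k"] * km[("k", "a")]
    c[14] = ko["r"] * km[("r", "s")]
    c[15] = ko["k"] * km[("k", "s")]
    c[16] = cue["r_m"]
    c[17] = cue["r_s"]
    c[18] = cue["r_a"]
    c[19] = cue["k_m"]
    c[20] = cue["k_s"]
    c[21] = cue["k_a"]
    c[22] = rates.tau["r"]
    c[23] = rates.tau["k"]
    c[24] = params.beta
    c[25] = fs_r["som_p"]
    c[26] = fs_r["som_c"]
    c[27] = fs_r["som_a"]
    c[28] = fs_k["som_p"]
    c[29] = fs_k["som_c"]
    c[30] = fs_k["som_a"]
    c[31] = forcing.litter_input * rates.fmet
    c[32] = forcing.litter_input * (1.0 - rates.fmet)
    c[33] = params.f_i["m"]
    c[34] = params.f_i["s"]
    c[35] = rates.desorb
    return c


@njit(cache=True)
def _rhs(y, c, out):
    lit_m = y[0] if y[0] > 0.0 else 0.0
    lit_s = y[1] if y[1] > 0.0 else 0.0
    mic_r = y[2] if y[2] > 0.0 else 0.0
    mic_k = y[3] if y[3] > 0.0 else 0.0
    som_p = y[4] if y[4] > 0.0 else 0.0
    som_c = y[5] if y[5] > 0.0 else 0.0
    som_a = y[6] if y[6] > 0.0 else 0.0
    u_rm = mic_r * c[0] * lit_m / (c[8] + lit_m)
    u_rs = mic_r * c[1] * lit_s / (c[9] + lit_s)
    u_km = mic_k * c[2] * lit_m / (c[10] + lit_m)
    u_ks = mic_k * c[3] * lit_s / (c[11] + lit_s)
    u_ra = mic_r * c[4] * som_a / (c[12] + som_a)
    u_ka = mic_k * c[5] * som_a / (c[13] + som_a)
    oxid = mic_r * c[6] * som_c / (c[14] + som_c) + mic_k * c[7] * som_c / (c[15] + som_c)
    trn_r = mic_r ** c[24] * c[22]
    trn_k = mic_k ** c[24] * c[23]
    des = som_p * c[35]
    inp_m, inp_s, fi_m, fi_s = c[31], c[32], c[33], c[34]
    out[0] = inp_m * (1.0 - fi_m) - u_rm - u_km
    out[1] = inp_s * (1.0 - fi_s) - u_rs - u_ks
    out[2] = c[16] * u_rm + c[17] * u_rs + c[18] * u_ra - trn_r
    out[3] = c[19] * u_km + c[20] * u_ks + c[21] * u_ka - trn_k
    out[4] = inp_m * fi_m + trn_r * c[25] + trn_k * c[28] - des
    out[5] = inp_s * fi_s + trn_r * c[26] + trn_k * c[29] - oxid
    out[6] = trn_r * c[27] + trn_k * c[30] + des + oxid - u_ra - u_ka


@njit(cache=True)
def integrate_rk45(y0, c, t_end, rtol, atol):
    """Adaptive Dormand-Prince integration of the pool system to ``t_end``
    hours; returns the final state (clipped non-negative)."""
    n = y0.shape[0]
    y = y0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    k7 = np.empty(n)
    ytmp = np.empty(n)
    y5 = np.empty(n)
    t = 0.0
    h = 1.0
    _rhs(y, c, k1)
    while t < t_end:
        if t + h > t_end:
            h = t_end - t
        for i in range(n):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _rhs(ytmp, c, k2)
        for i in range(n):
            ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _rhs(ytmp, c, k3)
        for i in range(n):
            ytmp[i] = y[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i] + 32.0 / 9.0 * k3[i])
        _rhs(ytmp, c, k4)
        for i in range(n):
            ytmp[i] = y[i] + h * (
                19372.0 / 6561.0 * k1[i]
                - 25360.0 / 2187.0 * k2[i]
                + 64448.0 / 6561.0 * k3[i]
                - 212.0 / 729.0 * k4[i]
            )
        _rhs(ytmp, c, k5)
        for i in range(n):
            ytmp[i] = y[i] + h * (
                9017.0 / 3168.0 * k1[i]
                - 355.0 / 33.0 * k2[i]
                + 46732.0 / 5247.0 * k3[i]
                + 49.0 / 176.0 * k4[i]
                - 5103.0 / 18656.0 * k5[i]
            )
        _rhs(ytmp, c, k6)
        for i in range(n):
            y5[i] = y[i] + h * (
                35.0 / 384.0 * k1[i]
                + 500.0 / 1113.0 * k3[i]
                + 125.0 / 192.0 * k4[i]
                - 2187.0 / 6784.0 * k5[i]
                + 11.0 / 84.0 * k6[i]
            )
        _rhs(y5, c, k7)
        # embedded 4th-order error estimate
        err = 0.0
        for i in range(n):
            e = h * (
                71.0 / 57600.0 * k1[i]
                - 71.0 / 16695.0 * k3[i]
                + 71.0 / 1920.0 * k4[i]
                - 17253.0 / 339200.0 * k5[i]
                + 22.0 / 525.0 * k6[i]
                - 1.0 / 40.0 * k7[i]
            )
            sc = atol + rtol * (abs(y[i]) if abs(y[i]) > abs(y5[i]) else abs(y5[i]))
            ratio = e / sc
            err += ratio * ratio
        err = (err / n) ** 0.5
        if err <= 1.0:
            t += h
            for i in range(n):
                y[i] = y5[i] if y5[i] > 0.0 else 0.0
            _rhs(y, c, k1)  # re-evaluate: clipping may have moved y off y5
        factor = 0.9 * err ** -0.2 if err > 1e-10 else 5.0
        if factor > 5.0:
            factor = 5.0
        if factor < 0.2:
            factor = 0.2
        h *= factor
        if h < 1e-6:
            h = 1e-6
    return y
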