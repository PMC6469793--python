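"""Independent scalar transcription of the 1998 human atrial membrane model.

This file is the test oracle for the package's ionic engine. It is written
directly from the published equation set in a deliberately different style
(per-current closures over a state dict, alpha/beta rate form, SciPy LSODA
integration with dense output) and shares no code with the package, so a
transcription or integration error in either path shows up as a voltage
mismatch.

State vector order (21): V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, w,
f_Ca, u, v, Na_i, K_i, Ca_i, Ca_up, Ca_rel.
"""

import numpy as np
from scipy.integrate import solve_ivp

R = 8.3143
T = 310.0
F = 96.4867
Cm = 100.0           # pF
Vi = 13668.0
Vup = 1109.52
Vrel = 96.48
Ko = 5.4
Nao = 140.0
Cao = 1.8

REST = np.array([
    -81.18, 2.908e-3, 9.649e-1, 9.775e-1, 3.043e-2, 9.992e-1,
    4.966e-3, 9.986e-1, 3.296e-5, 1.869e-2, 1.367e-4, 9.996e-1,
    9.992e-1, 7.755e-1, 0.0, 1.0, 1.117e1, 1.39e2, 1.013e-4,
    1.488, 1.488,
])


def _exp(x):
    return np.exp(x)


def rhs(t, y, i_stim_pa=0.0, kr_scale=1.0, ks_scale=1.0):
    (V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, w,
     fca, u, v, Nai, Ki, Cai, Caup, Carel) = y
    RTonF = R * T / F

    E_Na = RTonF * np.log(Nao / Nai)
    E_K = RTonF * np.log(Ko / Ki)
    E_Ca = RTonF / 2.0 * np.log(Cao / Cai)

    # --- fast sodium current (pA) ---
    g_Na = 7.8
    I_Na = Cm * g_Na * m ** 3 * h * j * (V - E_Na)
    if abs(V + 47.13) < 1e-8:
        alpha_m = 3.2
    else:
        alpha_m = 0.32 * (V + 47.13) / (1.0 - _exp(-0.1 * (V + 47.13)))
    beta_m = 0.08 * _exp(-V / 11.0)
    if V >= -40.0:
        alpha_h = 0.0
        beta_h = 1.0 / (0.13 * (1.0 + _exp((V + 10.66) / -11.1)))
        alpha_j = 0.0
        beta_j = (0.3 * _exp(-2.535e-7 * V)
                  / (1.0 + _exp(-0.1 * (V + 32.0))))
    else:
        alpha_h = 0.135 * _exp((V + 80.0) / -6.8)
        beta_h = 3.56 * _exp(0.079 * V) + 3.1e5 * _exp(0.35 * V)
        alpha_j = ((-1.2714e5 * _exp(0.2444 * V)
                    - 3.474e-5 * _exp(-0.04391 * V)) * (V + 37.78)
                   / (1.0 + _exp(0.311 * (V + 79.23))))
        beta_j = (0.1212 * _exp(-0.01052 * V)
                  / (1.0 + _exp(-0.1378 * (V + 40.14))))

    # --- time-independent K+ current ---
    g_K1 = 0.09
    I_K1 = Cm * g_K1 * (V - E_K) / (1.0 + _exp(0.07 * (V + 80.0)))

    # --- transient outward ---
    g_to = 0.1652
    I_to = Cm * g_to * oa ** 3 * oi * (V - E_K)
    KQ10 = 3.0
    alpha_oa = 0.65 / (_exp((V + 10.0) / -8.5) + _exp((V - 30.0) / -59.0))
    beta_oa = 0.65 / (2.5 + _exp((V + 82.0) / 17.0))
    tau_oa = 1.0 / ((alpha_oa + beta_oa) * KQ10)
    oa_inf = 1.0 / (1.0 + _exp((V + 20.47) / -17.54))
    alpha_oi = 1.0 / (18.53 + _exp((V + 113.7) / 10.95))
    beta_oi = 1.0 / (35.56 + _exp((V + 1.26) / -7.44))
    tau_oi = 1.0 / ((alpha_oi + beta_oi) * KQ10)
    oi_inf = 1.0 / (1.0 + _exp((V + 43.1) / 5.3))

    # --- ultrarapid delayed rectifier ---
    g_Kur = 0.005 + 0.05 / (1.0 + _exp((V - 15.0) / -13.0))
    I_Kur = Cm * g_Kur * ua ** 3 * ui * (V - E_K)
    alpha_ua = 0.65 / (_exp((V + 10.0) / -8.5) + _exp((V - 30.0) / -59.0))
    beta_ua = 0.65 / (2.5 + _exp((V + 82.0) / 17.0))
    tau_ua = 1.0 / ((alpha_ua + beta_ua) * KQ10)
    ua_inf = 1.0 / (1.0 + _exp((V + 30.3) / -9.6))
    alpha_ui = 1.0 / (21.0 + _exp((V - 185.0) / -28.0))
    beta_ui = _exp((V - 158.0) / 16.0)
    tau_ui = 1.0 / ((alpha_ui + beta_ui) * KQ10)
    ui_inf = 1.0 / (1.0 + _exp((V - 99.45) / 27.48))

    # --- rapid delayed rectifier ---
    g_Kr = 0.029411765
    I_Kr = (Cm * kr_scale * g_Kr * xr * (V - E_K)
            / (1.0 + _exp((V + 15.0) / 22.4)))
    if abs(V + 14.1) < 1e-8:
        alpha_xr = 0.0015
    else:
        alpha_xr = (0.0003 * (V + 14.1)
                    / (1.0 - _exp((V + 14.1) / -5.0)))
    if abs(V - 3.3328) < 1e-8:
        beta_xr = 3.7836118e-4
    else:
        beta_xr = (7.3898e-5 * (V - 3.3328)
                   / (_exp((V - 3.3328) / 5.1237) - 1.0))
    tau_xr = 1.0 / (alpha_xr + beta_xr)
    xr_inf = 1.0 / (1.0 + _exp((V + 14.1) / -6.5))

    # --- slow delayed rectifier ---
    g_Ks = 0.12941176
    I_Ks = Cm * ks_scale * g_Ks * xs ** 2 * (V - E_K)
    if abs(V - 19.9) < 1e-8:
        alpha_xs = 0.00068
        beta_xs = 0.000315
    else:
        alpha_xs = (4e-5 * (V - 19.9)
                    / (1.0 - _exp((V - 19.9) / -17.0)))
        beta_xs = (3.5e-5 * (V - 19.9)
                   / (_exp((V - 19.9) / 9.0) - 1.0))
    tau_xs = 0.5 / (alpha_xs + beta_xs)
    xs_inf = 1.0 / np.sqrt(1.0 + _exp((V - 19.9) / -12.7))

    # --- L-type calcium ---
    g_CaL = 0.12375
    I_CaL = Cm * g_CaL * d * f * fca * (V - 65.0)
    if abs(V + 10.0) < 1e-8:
        tau_d = 4.579 / (1.0 + _exp((V + 10.0) / -6.24))
    else:
        tau_d = ((1.0 - _exp((V + 10.0) / -6.24))
                 / (0.035 * (V + 10.0) * (1.0 + _exp((V + 10.0) / -6.24))))
    d_inf = 1.0 / (1.0 + _exp((V + 10.0) / -8.0))
    tau_f = 9.0 / (0.0197 * _exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)
    f_inf = _exp(-(V + 28.0) / 6.9) / (1.0 + _exp(-(V + 28.0) / 6.9))

    # --- pumps and exchangers ---
    sigma = 1.0 / 7.0 * (_exp(Nao / 67.3) - 1.0)
    f_NaK = 1.0 / (1.0 + 0.1245 * _exp(-0.1 * F * V / (R * T))
                   + 0.0365 * sigma * _exp(-F * V / (R * T)))
    I_NaK = (Cm * 0.59933874 * f_NaK
             * 1.0 / (1.0 + (10.0 / Nai) ** 1.5)
             * Ko / (Ko + 1.5))
    I_NaCa = (Cm * 1600.0
              * (_exp(0.35 * F * V / (R * T)) * Nai ** 3 * Cao
                 - _exp((0.35 - 1.0) * F * V / (R * T)) * Nao ** 3 * Cai)
              / ((87.5 ** 3 + Nao ** 3) * (1.38 + Cao)
                 * (1.0 + 0.1 * _exp((0.35 - 1.0) * F * V / (R * T)))))
    I_pCa = Cm * 0.275 * Cai / (0.0005 + Cai)
    I_bNa = Cm * 0.0006744375 * (V - E_Na)
    I_bCa = Cm * 0.001131 * (V - E_Ca)

    # --- SR handling ---
    I_rel = 30.0 * u ** 2 * v * w * (Carel - Cai)
    Fn = (1e-12 * Vrel * I_rel
          - 5e-13 / F * (0.5 * I_CaL - 0.2 * I_NaCa))
    u_inf = 1.0 / (1.0 + _exp(-(Fn - 3.4175e-13) / 13.67e-16))
    tau_u = 8.0
    tau_v = 1.91 + 2.09 / (1.0 + _exp(-(Fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + _exp(-(Fn - 6.835e-14) / 13.67e-16))
    if abs(V - 7.9) < 1e-8:
        tau_w = 6.0 * 0.2 / 1.3
    else:
        tau_w = (6.0 * (1.0 - _exp(-(V - 7.9) / 5.0))
                 / ((1.0 + 0.3 * _exp(-(V - 7.9) / 5.0)) * (V - 7.9)))
    w_inf = 1.0 - 1.0 / (1.0 + _exp(-(V - 40.0) / 17.0))
    fca_inf = 1.0 / (1.0 + Cai / 0.00035)
    tau_fca = 2.0

    I_up = 0.005 / (1.0 + 0.00092 / Cai)
    I_up_leak = 0.005 * Caup / 15.0
    I_tr = (Caup - Carel) / 180.0

    dV = -(I_Na + I_K1 + I_to + I_Kur + I_Kr + I_Ks + I_CaL + I_pCa
           + I_NaK + I_NaCa + I_bNa + I_bCa + i_stim_pa) / Cm
    dNai = (-3.0 * I_NaK - 3.0 * I_NaCa - I_bNa - I_Na) / (F * Vi)
    dKi = (2.0 * I_NaK - I_K1 - I_to - I_Kur - I_Kr - I_Ks) / (F * Vi)
    B1 = ((2.0 * I_NaCa - I_pCa - I_CaL - I_bCa) / (2.0 * F * Vi)
          + (Vup * (I_up_leak - I_up) + I_rel * Vrel) / Vi)
    B2 = (1.0 + 0.07 * 0.0005 / (Cai + 0.0005) ** 2
          + 0.05 * 0.00238 / (Cai + 0.00238) ** 2)
    dCaup = I_up - I_up_leak - I_tr * Vrel / Vup
    dCarel = (I_tr - I_rel) / (1.0 + 10.0 * 0.8 / (Carel + 0.8) ** 2)

    return [
        dV,
        alpha_m * (1.0 - m) - beta_m * m,
        alpha_h * (1.0 - h) - beta_h * h,
        alpha_j * (1.0 - j) - beta_j * j,
        (oa_inf - oa) / tau_oa,
        (oi_inf - oi) / tau_oi,
        (ua_inf - ua) / tau_ua,
        (ui_inf - ui) / tau_ui,
        (xr_inf - xr) / tau_xr,
        (xs_inf - xs) / tau_xs,
        (d_inf - d) / tau_d,
        (f_inf - f) / tau_f,
        (w_inf - w) / tau_w,
        (fca_inf - fca) / tau_fca,
        (u_inf - u) / tau_u,
        (v_inf - v) / tau_v,
        dNai,
        dKi,
        B1 / B2,
        dCaup,
        dCarel,
    ]


def paced_beat(duration_ms=600.0, stim_pa=-2900.0, stim_ms=1.5,
               sample_dt=1.0, y0=None, rtol=1e-8, atol=1e-8,
               kr_scale=1.0, ks_scale=1.0):
    """One stimulated beat from rest, densely sampled: (t, Vm)."""
    y0 = REST.copy() if y0 is None else np.asarray(y0, dtype=float)
    sol1 = solve_ivp(rhs, (0.0, stim_ms), y0, method="LSODA",
                     args=(stim_pa, kr_scale, ks_scale),
                     dense_output=True, rtol=rtol, atol=atol,
                     max_step=0.1)
    sol2 = solve_ivp(rhs, (stim_ms, duration_ms), sol1.y[:, -1],
                     method="LSODA", args=(0.0, kr_scale, ks_scale),
                     dense_output=True, rtol=rtol, atol=atol)
    t = np.arange(0.0, duration_ms + sample_dt / 2, sample_dt)
    early = t <= stim_ms
    vm = np.concatenate([sol1.sol(t[early])[0], sol2.sol(t[~early])[0]])
    return t, vm


def equilibrated_rest(duration_ms=100_000.0):
    """State after a long quiescent integration (equilibration check)."""
    sol = solve_ivp(rhs, (0.0, duration_ms), REST.copy(), method="LSODA",
                    rtol=1e-9, atol=1e-10)
    return sol.y[:, -1]
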