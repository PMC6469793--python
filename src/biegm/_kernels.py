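"""Numba-compiled integration kernels.

The per-node membrane update uses Rush-Larsen integration for all gating
variables and forward Euler for Vm and the ionic pools. Every purely
voltage-dependent quantity (gate steady states, Rush-Larsen factors,
rectification/pump factors, exchanger exponentials) is linearly interpolated
from tables precomputed in :mod:`biegm.ionic` for the fixed time step, which
removes almost all transcendental calls from the hot loop.

The tissue driver keeps the whole time loop in compiled code: CSR
sparse-matrix diffusion, stimulus episodes, field recording at the
electrogram sampling grid, and first-activation detection.
"""

import numpy as np
from numba import njit

from .ionic import (
    RTF, CM_PF, V_I, V_UP, V_REL, K_O, NA_O, CA_O,
    KM_NAI, KM_KO, KM_NA, KM_CA, K_SAT, FARADAY,
    K_REL, I_UP_MAX, K_UP, CA_UP_MAX,
    CMDN_MAX, TRPN_MAX, CSQN_MAX, KM_CMDN, KM_TRPN, KM_CSQN,
    TAU_TR, TAU_F_CA, TAU_U,
)

# gpars layout: g_na, g_to, g_ks, g_cal, i_nak_max, i_naca_max, i_pca_max,
#               g_b_na, g_b_ca
N_GPARS = 9


@njit(cache=True, fastmath=True)
def _update_node(y, tab, vmin, inv_dv, dt, rl_fca, rl_u, sc, gpars, ext):
    """Advance one node's 21-variable state by dt.

    ``ext`` is the non-ionic dVm/dt contribution (diffusion minus stimulus,
    both in mV/ms); ``sc`` holds the 5 per-node conductance multipliers
    (na, cal, k1, kr, ks).
    """
    v = y[0]
    x = (v - vmin) * inv_dv
    if x < 0.0:
        x = 0.0
    hi = float(tab.shape[0] - 2)
    if x > hi:
        x = hi
    i0 = int(x)
    fr = x - i0
    t0 = tab[i0]
    t1 = tab[i0 + 1]

    m = y[1]; h = y[2]; jj = y[3]
    oa = y[4]; oi = y[5]; ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]; d = y[10]; f = y[11]; w = y[12]
    fca = y[13]; u = y[14]; vg = y[15]
    nai = y[16]; ki = y[17]; cai = y[18]; caup = y[19]; carel = y[20]

    ck1 = t0[24] + fr * (t1[24] - t0[24])
    gkur = t0[25] + fr * (t1[25] - t0[25])
    ckr = t0[26] + fr * (t1[26] - t0[26])
    fnak = t0[27] + fr * (t1[27] - t0[27])
    expg = t0[28] + fr * (t1[28] - t0[28])
    expg1 = t0[29] + fr * (t1[29] - t0[29])

    ena = RTF * np.log(NA_O / nai)
    ek = RTF * np.log(K_O / ki)
    eca = 0.5 * RTF * np.log(CA_O / cai)

    ina = sc[0] * gpars[0] * m * m * m * h * jj * (v - ena)
    ik1 = sc[2] * ck1 * (v - ek)
    ito = gpars[1] * oa * oa * oa * oi * (v - ek)
    ikur = gkur * ua * ua * ua * ui * (v - ek)
    ikr = sc[3] * ckr * xr * (v - ek)
    iks = sc[4] * gpars[2] * xs * xs * (v - ek)
    ical = sc[1] * gpars[3] * d * f * fca * (v - 65.0)
    ipca = gpars[6] * cai / (0.0005 + cai)
    rk = KM_NAI / nai
    inak = (gpars[4] * fnak * K_O
            / ((1.0 + rk * np.sqrt(rk)) * (K_O + KM_KO)))
    nai3 = nai * nai * nai
    inaca = (gpars[5] * (expg * nai3 * CA_O - expg1 * (NA_O ** 3) * cai)
             / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                * (1.0 + K_SAT * expg1)))
    ibna = gpars[7] * (v - ena)
    ibca = gpars[8] * (v - eca)

    irel = K_REL * u * u * vg * w * (carel - cai)
    itr = (caup - carel) / TAU_TR
    iup = I_UP_MAX / (1.0 + K_UP / cai)
    iupleak = I_UP_MAX * caup / CA_UP_MAX

    fn = (1e-12 * V_REL * irel
          - (5e-13 / FARADAY) * (0.5 * ical * CM_PF - 0.2 * inaca * CM_PF))
    u_inf = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 1.367e-15))
    tau_v = 1.91 + 2.09 * u_inf
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 1.367e-15))
    fca_inf = 1.0 / (1.0 + cai / 0.00035)

    iion = (ina + ik1 + ito + ikur + ikr + iks + ical + ipca + inak + inaca
            + ibna + ibca)

    # voltage gates: Rush-Larsen with tabulated inf / exp(-dt/tau)
    for k in range(12):
        inf = t0[2 * k] + fr * (t1[2 * k] - t0[2 * k])
        rl = t0[2 * k + 1] + fr * (t1[2 * k + 1] - t0[2 * k + 1])
        y[1 + k] = inf + (y[1 + k] - inf) * rl
    y[13] = fca_inf + (fca - fca_inf) * rl_fca
    y[14] = u_inf + (u - u_inf) * rl_u
    y[15] = v_inf + (vg - v_inf) * np.exp(-dt / tau_v)

    y[16] = nai + dt * ((-3.0 * inak - 3.0 * inaca - ibna - ina)
                        * CM_PF / (FARADAY * V_I))
    y[17] = ki + dt * ((2.0 * inak - (ik1 + ito + ikur + ikr + iks))
                       * CM_PF / (FARADAY * V_I))
    b1 = ((2.0 * inaca - (ipca + ical + ibca)) * CM_PF / (2.0 * FARADAY * V_I)
          + (V_UP * (iupleak - iup) + irel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / ((cai + KM_TRPN) * (cai + KM_TRPN))
          + CMDN_MAX * KM_CMDN / ((cai + KM_CMDN) * (cai + KM_CMDN)))
    y[18] = cai + dt * (b1 / b2)
    y[19] = caup + dt * (iup - iupleak - itr * V_REL / V_UP)
    y[20] = carel + dt * ((itr - irel)
                          / (1.0 + CSQN_MAX * KM_CSQN
                             / ((carel + KM_CSQN) * (carel + KM_CSQN))))
    y[0] = v + dt * (ext - iion)


@njit(cache=True, fastmath=True)
def run_cell(y0, tab, vmin, inv_dv, dt, n_steps, pcl_steps, dur_steps,
             stim_pa_pf, sc):
    """Paced single cell; returns (vm trace incl. t=0, final state, blowup index)."""
    y = y0.copy()
    gpars = _default_gpars()
    vm = np.empty(n_steps + 1)
    vm[0] = y[0]
    rl_fca = np.exp(-dt / TAU_F_CA)
    rl_u = np.exp(-dt / TAU_U)
    blow = -1
    for t in range(n_steps):
        ist = stim_pa_pf if (t % pcl_steps) < dur_steps else 0.0
        _update_node(y, tab, vmin, inv_dv, dt, rl_fca, rl_u, sc, gpars, -ist)
        vm[t + 1] = y[0]
        if np.abs(y[0]) > 200.0:
            blow = t
            break
    return vm, y, blow


@njit(cache=True)
def _default_gpars():
    g = np.empty(N_GPARS)
    g[0] = 7.8; g[1] = 0.1652; g[2] = 0.12941176; g[3] = 0.12375
    g[4] = 0.59933874; g[5] = 1600.0; g[6] = 0.275
    g[7] = 0.0006744375; g[8] = 0.001131
    return g


def gpars_from_params(params) -> np.ndarray:
    g = np.empty(N_GPARS)
    g[0] = params.g_na; g[1] = params.g_to; g[2] = params.g_ks
    g[3] = params.g_cal; g[4] = params.i_nak_max; g[5] = params.i_naca_max
    g[6] = params.i_pca_max; g[7] = params.g_b_na; g[8] = params.g_b_ca
    return g


@njit(cache=True, fastmath=True)
def run_tissue(Y, indptr, indices, wts, inv_area, d_eff,
               tab, vmin, inv_dv, dt, n_steps, sc, gpars,
               ep_start, ep_end, ep_amp, ep_ptr, ep_nodes,
               rec_start, rec_stride, vrec, srec,
               act, act_thresh, t_offset):
    """Monodomain time loop over a mesh.

    Y: (n, 21) per-node states, updated in place. wts/indptr/indices: CSR
    symmetric coupling weights; diffusion source at node i is
    d_eff * inv_area[i] * sum_j w_ij (V_j - V_i), in mV/ms.

    Episodes: half-open step intervals [ep_start, ep_end) applying
    ep_amp (pA/pF) to node slices ep_nodes[ep_ptr[e]:ep_ptr[e+1]].

    Recording stores pre-update Vm and the diffusion source at steps
    rec_start + k*rec_stride into vrec/srec (k rows, possibly zero rows).
    First crossings of act_thresh are written to act as absolute times
    (t_offset + step time); pass act from a previous segment to continue.
    Returns the index of the blow-up step, or -1.
    """
    n = Y.shape[0]
    n_rec = vrec.shape[0]
    src = np.empty(n)
    istim = np.zeros(n)
    rl_fca = np.exp(-dt / TAU_F_CA)
    rl_u = np.exp(-dt / TAU_U)
    rec_i = 0
    blow = -1
    for t in range(n_steps):
        for i in range(n):
            vi = Y[i, 0]
            acc = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                acc += wts[k] * (Y[indices[k], 0] - vi)
            src[i] = acc * inv_area[i] * d_eff
        for i in range(n):
            istim[i] = 0.0
        for e in range(ep_start.size):
            if ep_start[e] <= t < ep_end[e]:
                for k in range(ep_ptr[e], ep_ptr[e + 1]):
                    istim[ep_nodes[k]] = ep_amp[e]
        if rec_i < n_rec and t == rec_start + rec_i * rec_stride:
            for i in range(n):
                vrec[rec_i, i] = Y[i, 0]
                srec[rec_i, i] = src[i]
            rec_i += 1
        for i in range(n):
            _update_node(Y[i], tab, vmin, inv_dv, dt, rl_fca, rl_u,
                         sc[i], gpars, src[i] - istim[i])
            if act[i] < 0.0 and Y[i, 0] >= act_thresh:
                act[i] = t_offset + (t + 1) * dt
            if np.abs(Y[i, 0]) > 200.0:
                blow = t
        if blow >= 0:
            break
    return blow
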