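"""Human atrial action-potential model (Courtemanche, Ramirez & Nattel 1998).

This module provides the membrane kinetics used at every tissue node: the 21
state variables (membrane potential, 15 gating variables, 5 ionic pools), the
full ionic current set, single-cell pacing, APD90 measurement, and calibration
of the action-potential duration by joint scaling of the rapid and slow
delayed-rectifier K+ conductances.

Two evaluation paths exist on purpose:

* :func:`ionic_rhs` — a plain, readable NumPy transcription of the published
  equation set, used for diagnostics and as the slow reference inside the
  package.
* the lookup-table Rush–Larsen engine in :mod:`biegm._kernels` — the fast
  path used by the single-cell and tissue drivers. Tables of all
  voltage-dependent quantities are precomputed on a fine Vm grid for a fixed
  time step.

Units follow the original publication: mV, ms, mM, pA/pF (currents are kept
per unit membrane capacitance; the whole-cell capacitance is 100 pF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import CalibrationError, NumericalBlowupError, UndefinedApdError

# ---------------------------------------------------------------------------
# Published constants
# ---------------------------------------------------------------------------

R_GAS = 8.3143        # J / (mol K)
TEMP = 310.0          # K
FARADAY = 96.4867     # C / mmol
RTF = R_GAS * TEMP / FARADAY

CM_PF = 100.0         # whole-cell membrane capacitance, pF

V_I = 13668.0         # intracellular volume, um^3
V_UP = 1109.52        # SR uptake compartment volume, um^3
V_REL = 96.48         # SR release compartment volume, um^3

K_O = 5.4             # mM
NA_O = 140.0
CA_O = 1.8

G_NA = 7.8            # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375

I_NAK_MAX = 0.59933874   # pA/pF
KM_NAI = 10.0            # mM
KM_KO = 1.5
I_NACA_MAX = 1600.0      # pA/pF
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275        # pA/pF

K_REL = 30.0             # 1/ms
I_UP_MAX = 0.005         # mM/ms
K_UP = 0.00092           # mM
CA_UP_MAX = 15.0         # mM

CMDN_MAX = 0.05          # mM
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

TAU_TR = 180.0           # ms
TAU_F_CA = 2.0
TAU_U = 8.0
KQ10 = 3.0

# State vector layout: vm, 12 voltage gates, 3 non-voltage gates, 5 pools.
V_GATE_NAMES = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "w")
GATE_NAMES = V_GATE_NAMES + ("fca", "u", "v")
CONC_NAMES = ("nai", "ki", "cai", "ca_up", "ca_rel")
N_STATE = 1 + len(GATE_NAMES) + len(CONC_NAMES)
IDX_VM = 0
IDX_GATE0 = 1
IDX_FCA = 13
IDX_U = 14
IDX_V = 15
IDX_NAI = 16
IDX_KI = 17
IDX_CAI = 18
IDX_CAUP = 19
IDX_CAREL = 20

_REST = np.array([
    -81.18,
    2.908e-3, 9.649e-1, 9.775e-1,        # m h j
    3.043e-2, 9.992e-1,                  # oa oi
    4.966e-3, 9.986e-1,                  # ua ui
    3.296e-5, 1.869e-2,                  # xr xs
    1.367e-4, 9.996e-1, 9.992e-1,        # d f w
    7.755e-1, 0.0, 1.0,                  # fca u v
    1.117e1, 1.39e2, 1.013e-4, 1.488, 1.488,
])


def resting_state() -> np.ndarray:
    """Published resting state of the model, as a fresh state vector."""
    return _REST.copy()


@dataclass
class CellState:
    """One node's membrane state: Vm, gates, and ionic concentrations."""

    vm: float
    gates: dict
    concentrations: dict

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "CellState":
        y = np.asarray(y, dtype=float)
        gates = {n: float(y[IDX_GATE0 + i]) for i, n in enumerate(GATE_NAMES)}
        conc = {n: float(y[IDX_NAI + i]) for i, n in enumerate(CONC_NAMES)}
        return cls(vm=float(y[IDX_VM]), gates=gates, concentrations=conc)

    def to_vector(self) -> np.ndarray:
        y = np.empty(N_STATE)
        y[IDX_VM] = self.vm
        for i, n in enumerate(GATE_NAMES):
            y[IDX_GATE0 + i] = self.gates[n]
        for i, n in enumerate(CONC_NAMES):
            y[IDX_NAI + i] = self.concentrations[n]
        return y

    def validate(self) -> None:
        y = self.to_vector()
        if not np.all(np.isfinite(y)):
            names = ["vm", *GATE_NAMES, *CONC_NAMES]
            bad = [names[i] for i in np.flatnonzero(~np.isfinite(y))]
            raise ValueError(f"non-finite state variable(s): {', '.join(bad)}")
        for n in GATE_NAMES:
            g = self.gates[n]
            if not -1e-9 <= g <= 1 + 1e-9:
                raise ValueError(f"gate {n}={g} outside [0, 1]")
        for n in CONC_NAMES:
            if self.concentrations[n] <= 0:
                raise ValueError(f"concentration {n} not strictly positive")


@dataclass
class IonicParams:
    """Maximal conductances plus the scaling knobs used by this study.

    ``scale_kr``/``scale_ks`` multiply the rapid/slow delayed-rectifier
    conductances (the APD-calibration handle). ``remodeling_scales`` are the
    multiplicative factors applied to fibrotic nodes.
    """

    g_na: float = G_NA
    g_k1: float = G_K1
    g_to: float = G_TO
    g_kr: float = G_KR
    g_ks: float = G_KS
    g_cal: float = G_CAL
    g_b_ca: float = G_B_CA
    g_b_na: float = G_B_NA
    i_nak_max: float = I_NAK_MAX
    i_naca_max: float = I_NACA_MAX
    i_pca_max: float = I_PCA_MAX
    cm_cell: float = CM_PF
    scale_kr: float = 1.0
    scale_ks: float = 1.0
    remodeling_scales: Mapping[str, float] = field(
        default_factory=lambda: {"i_na": 0.9, "i_cal": 0.5, "i_k1": 0.8}
    )

    def __post_init__(self):
        for name in ("g_na", "g_k1", "g_to", "g_kr", "g_ks", "g_cal",
                     "scale_kr", "scale_ks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for k, v in self.remodeling_scales.items():
            if v < 0:
                raise ValueError(f"remodeling scale {k} must be >= 0")


@dataclass
class PacingProtocol:
    """Fixed-rate stimulation: PCL, stimulus strength/duration, conditioning."""

    pcl: float = 600.0              # ms
    stim_amplitude: float = -2900.0  # pA, negative depolarizes
    stim_duration: float = 1.5       # ms
    n_beats: int = 20

    def __post_init__(self):
        if not self.pcl > self.stim_duration > 0:
            raise ValueError("require pcl > stim_duration > 0")


# ---------------------------------------------------------------------------
# Voltage-dependent gate kinetics (vectorized over vm)
# ---------------------------------------------------------------------------

def _safe_ratio(num, den, limit):
    """num/den with a finite limit where den ~ 0 (removable singularities)."""
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < 1e-10
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def gate_rates(vm):
    """inf and tau (ms) for the 12 voltage-dependent gates at potential vm."""
    v = np.asarray(vm, dtype=float)
    out = {}

    # fast Na+ gates (Luo-Rudy style kinetics as adopted by the model)
    a_m = _safe_ratio(0.32 * (v + 47.13), 1.0 - np.exp(-0.1 * (v + 47.13)), 3.2)
    b_m = 0.08 * np.exp(-v / 11.0)
    out["m"] = (a_m / (a_m + b_m), 1.0 / (a_m + b_m))

    lo = v < -40.0
    a_h = np.where(lo, 0.135 * np.exp(-(v + 80.0) / 6.8), 0.0)
    b_h = np.where(
        lo,
        3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
        1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))),
    )
    out["h"] = (a_h / (a_h + b_h), 1.0 / (a_h + b_h))

    a_j = np.where(
        lo,
        (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
        * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))),
        0.0,
    )
    b_j = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
        0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
    )
    out["j"] = (a_j / (a_j + b_j), 1.0 / (a_j + b_j))

    # transient outward
    a_oa = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    out["oa"] = (1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54)),
                 1.0 / ((a_oa + b_oa) * KQ10))
    a_oi = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
    out["oi"] = (1.0 / (1.0 + np.exp((v + 43.1) / 5.3)),
                 1.0 / ((a_oi + b_oi) * KQ10))

    # ultra-rapid delayed rectifier
    a_ua = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    out["ua"] = (1.0 / (1.0 + np.exp(-(v + 30.3) / 9.6)),
                 1.0 / ((a_ua + b_ua) * KQ10))
    a_ui = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
    b_ui = np.exp((v - 158.0) / 16.0)
    out["ui"] = (1.0 / (1.0 + np.exp((v - 99.45) / 27.48)),
                 1.0 / ((a_ui + b_ui) * KQ10))

    # rapid / slow delayed rectifiers
    a_xr = _safe_ratio(0.0003 * (v + 14.1),
                       1.0 - np.exp(-(v + 14.1) / 5.0), 0.0015)
    b_xr = _safe_ratio(7.3898e-5 * (v - 3.3328),
                       np.exp((v - 3.3328) / 5.1237) - 1.0,
                       7.3898e-5 * 5.1237)
    out["xr"] = (1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5)), 1.0 / (a_xr + b_xr))
    a_xs = _safe_ratio(4e-5 * (v - 19.9),
                       1.0 - np.exp(-(v - 19.9) / 17.0), 4e-5 * 17.0)
    b_xs = _safe_ratio(3.5e-5 * (v - 19.9),
                       np.exp((v - 19.9) / 9.0) - 1.0, 3.5e-5 * 9.0)
    out["xs"] = ((1.0 + np.exp(-(v - 19.9) / 12.7)) ** -0.5,
                 0.5 / (a_xs + b_xs))

    # L-type Ca2+
    ed = np.exp(-(v + 10.0) / 6.24)
    tau_d = _safe_ratio((1.0 - ed), 0.035 * (v + 10.0) * (1.0 + ed),
                        1.0 / (0.035 * 6.24 * 2.0))
    out["d"] = (1.0 / (1.0 + np.exp(-(v + 10.0) / 8.0)), tau_d)
    out["f"] = (1.0 / (1.0 + np.exp((v + 28.0) / 6.9)),
                9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02))

    # SR release voltage gate w
    ew = np.exp(-(v - 7.9) / 5.0)
    tau_w = _safe_ratio(6.0 * (1.0 - ew), (1.0 + 0.3 * ew) * (v - 7.9),
                        6.0 / 6.5)
    out["w"] = (1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0)), tau_w)
    return out


def _voltage_helpers(vm, params: IonicParams):
    """Voltage-only current factors (conductance scalings folded in)."""
    v = np.asarray(vm, dtype=float)
    ck1 = params.g_k1 / (1.0 + np.exp(0.07 * (v + 80.0)))
    gkur = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
    ckr = params.g_kr / (1.0 + np.exp((v + 15.0) / 22.4))
    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF)
                  + 0.0365 * sigma * np.exp(-v / RTF))
    expg = np.exp(GAMMA * v / RTF)
    expg1 = np.exp((GAMMA - 1.0) * v / RTF)
    return ck1, gkur, ckr, fnak, expg, expg1


# ---------------------------------------------------------------------------
# Full right-hand side (reference path)
# ---------------------------------------------------------------------------

def crn_currents(y: np.ndarray, params: IonicParams | None = None,
                 scales: Mapping[str, float] | None = None) -> dict:
    """All membrane currents (pA/pF) and SR fluxes (mM/ms) at state ``y``.

    ``scales`` optionally remodels i_na / i_cal / i_k1 (fibrosis use).
    """
    params = params or IonicParams()
    sc = {"i_na": 1.0, "i_cal": 1.0, "i_k1": 1.0}
    if scales:
        sc.update(scales)
    y = np.asarray(y, dtype=float)
    v = y[IDX_VM]
    g = {n: y[IDX_GATE0 + i] for i, n in enumerate(V_GATE_NAMES)}
    fca, u, vg = y[IDX_FCA], y[IDX_U], y[IDX_V]
    nai, ki, cai = y[IDX_NAI], y[IDX_KI], y[IDX_CAI]
    ca_up, ca_rel = y[IDX_CAUP], y[IDX_CAREL]

    ena = RTF * np.log(NA_O / nai)
    ek = RTF * np.log(K_O / ki)
    eca = 0.5 * RTF * np.log(CA_O / cai)
    ck1, gkur, ckr, fnak, expg, expg1 = _voltage_helpers(v, params)

    cur = {}
    cur["i_na"] = sc["i_na"] * params.g_na * g["m"] ** 3 * g["h"] * g["j"] * (v - ena)
    cur["i_k1"] = sc["i_k1"] * ck1 * (v - ek)
    cur["i_to"] = params.g_to * g["oa"] ** 3 * g["oi"] * (v - ek)
    cur["i_kur"] = gkur * g["ua"] ** 3 * g["ui"] * (v - ek)
    cur["i_kr"] = params.scale_kr * ckr * g["xr"] * (v - ek)
    cur["i_ks"] = params.scale_ks * params.g_ks * g["xs"] ** 2 * (v - ek)
    cur["i_cal"] = sc["i_cal"] * params.g_cal * g["d"] * g["f"] * fca * (v - 65.0)
    cur["i_pca"] = params.i_pca_max * cai / (0.0005 + cai)
    cur["i_nak"] = (params.i_nak_max * fnak * K_O
                    / ((1.0 + (KM_NAI / nai) ** 1.5) * (K_O + KM_KO)))
    cur["i_naca"] = (params.i_naca_max
                     * (expg * nai ** 3 * CA_O - expg1 * NA_O ** 3 * cai)
                     / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
                        * (1.0 + K_SAT * expg1)))
    cur["i_b_na"] = params.g_b_na * (v - ena)
    cur["i_b_ca"] = params.g_b_ca * (v - eca)
    cur["i_rel"] = K_REL * u ** 2 * vg * g["w"] * (ca_rel - cai)
    cur["i_tr"] = (ca_up - ca_rel) / TAU_TR
    cur["i_up"] = I_UP_MAX / (1.0 + K_UP / cai)
    cur["i_up_leak"] = I_UP_MAX * ca_up / CA_UP_MAX
    return cur


def ionic_rhs(state, params: IonicParams | None = None, i_stim: float = 0.0,
              scales: Mapping[str, float] | None = None) -> np.ndarray:
    """Time derivative of the full state vector.

    ``i_stim`` is a whole-cell current in pA (negative depolarizes); it is
    divided by the whole-cell capacitance internally. Accepts a
    :class:`CellState` or a raw length-21 vector; returns a length-21 vector
    of derivatives (mV/ms, 1/ms, mM/ms).
    """
    params = params or IonicParams()
    if isinstance(state, CellState):
        state.validate()
        y = state.to_vector()
    else:
        y = np.asarray(state, dtype=float)
        if not np.all(np.isfinite(y)):
            names = ["vm", *GATE_NAMES, *CONC_NAMES]
            bad = [names[i] for i in np.flatnonzero(~np.isfinite(y))]
            raise ValueError(f"non-finite state variable(s): {', '.join(bad)}")

    v = y[IDX_VM]
    cur = crn_currents(y, params, scales)
    rates = gate_rates(v)

    dy = np.empty(N_STATE)
    i_ion = (cur["i_na"] + cur["i_k1"] + cur["i_to"] + cur["i_kur"]
             + cur["i_kr"] + cur["i_ks"] + cur["i_cal"] + cur["i_pca"]
             + cur["i_nak"] + cur["i_naca"] + cur["i_b_na"] + cur["i_b_ca"])
    dy[IDX_VM] = -(i_ion + i_stim / params.cm_cell)

    for i, n in enumerate(V_GATE_NAMES):
        inf, tau = rates[n]
        dy[IDX_GATE0 + i] = (inf - y[IDX_GATE0 + i]) / tau

    cai = y[IDX_CAI]
    fca_inf = 1.0 / (1.0 + cai / 0.00035)
    dy[IDX_FCA] = (fca_inf - y[IDX_FCA]) / TAU_F_CA

    # SR release gating is driven by Fn, a function of whole-cell currents (pA)
    fn = (1e-12 * V_REL * cur["i_rel"]
          - (5e-13 / FARADAY) * (0.5 * cur["i_cal"] * CM_PF
                                 - 0.2 * cur["i_naca"] * CM_PF))
    u_inf = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 1.367e-15))
    tau_v = 1.91 + 2.09 / (1.0 + np.exp(-(fn - 3.4175e-13) / 1.367e-15))
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 1.367e-15))
    dy[IDX_U] = (u_inf - y[IDX_U]) / TAU_U
    dy[IDX_V] = (v_inf - y[IDX_V]) / tau_v

    dy[IDX_NAI] = (-3.0 * cur["i_nak"] - 3.0 * cur["i_naca"]
                   - cur["i_b_na"] - cur["i_na"]) * CM_PF / (FARADAY * V_I)
    dy[IDX_KI] = (2.0 * cur["i_nak"]
                  - (cur["i_k1"] + cur["i_to"] + cur["i_kur"]
                     + cur["i_kr"] + cur["i_ks"])) * CM_PF / (FARADAY * V_I)
    b1 = ((2.0 * cur["i_naca"] - (cur["i_pca"] + cur["i_cal"] + cur["i_b_ca"]))
          * CM_PF / (2.0 * FARADAY * V_I)
          + (V_UP * (cur["i_up_leak"] - cur["i_up"])
             + cur["i_rel"] * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2)
    dy[IDX_CAI] = b1 / b2
    dy[IDX_CAUP] = cur["i_up"] - cur["i_up_leak"] - cur["i_tr"] * V_REL / V_UP
    ca_rel = y[IDX_CAREL]
    dy[IDX_CAREL] = ((cur["i_tr"] - cur["i_rel"])
                     / (1.0 + CSQN_MAX * KM_CSQN / (ca_rel + KM_CSQN) ** 2))
    return dy


# ---------------------------------------------------------------------------
# Lookup tables for the fast Rush-Larsen engine
# ---------------------------------------------------------------------------

TAB_VMIN = -120.0
TAB_VMAX = 80.0
TAB_DV = 0.05
TAB_ROWS = 30  # 12 gates x (inf, rl) + 6 current helpers

_table_cache: dict = {}


def build_tables(params: IonicParams, dt: float) -> np.ndarray:
    """Voltage lookup tables for one (params, dt) combination, cached.

    Shape (n_v, 30), one row per grid potential so that all of a node's
    lookups share a few cache lines. Columns 2k/2k+1: steady state and
    Rush-Larsen factor exp(-dt/tau) of the k-th voltage gate; columns 24-29:
    IK1 factor, g_Kur(V), IKr rectification factor, f_NaK, and the two
    Na/Ca exchanger exponentials.
    """
    key = (round(dt, 9), params.g_na, params.g_k1, params.g_to, params.g_kr,
           params.g_ks, params.g_cal)
    if key in _table_cache:
        return _table_cache[key]
    v = np.arange(TAB_VMIN, TAB_VMAX + TAB_DV / 2, TAB_DV)
    tab = np.empty((TAB_ROWS, v.size))
    rates = gate_rates(v)
    for k, name in enumerate(V_GATE_NAMES):
        inf, tau = rates[name]
        tab[2 * k] = inf
        tab[2 * k + 1] = np.exp(-dt / tau)
    ck1, gkur, ckr, fnak, expg, expg1 = _voltage_helpers(v, params)
    tab[24], tab[25], tab[26] = ck1, gkur, ckr
    tab[27], tab[28], tab[29] = fnak, expg, expg1
    tab = np.ascontiguousarray(tab.T)
    _table_cache[key] = tab
    return tab


def node_scale_arrays(n: int, params: IonicParams,
                      fibrosis_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-node conductance multipliers (5, n): na, cal, k1, kr, ks.

    Fibrotic nodes get the remodeling factors on INa/ICaL/IK1 on top of the
    global delayed-rectifier scalings.
    """
    sc = np.ones((5, n))
    sc[3] *= params.scale_kr
    sc[4] *= params.scale_ks
    if fibrosis_mask is not None and fibrosis_mask.any():
        rs = params.remodeling_scales
        m = np.asarray(fibrosis_mask, dtype=bool)
        sc[0, m] *= rs.get("i_na", 1.0)
        sc[1, m] *= rs.get("i_cal", 1.0)
        sc[2, m] *= rs.get("i_k1", 1.0)
    return sc


# ---------------------------------------------------------------------------
# Single-cell simulation and APD measurement
# ---------------------------------------------------------------------------

def simulate_cell(params: IonicParams | None = None,
                  protocol: PacingProtocol | None = None,
                  dt: float = 0.02,
                  initial_state: np.ndarray | None = None,
                  return_state: bool = False):
    """Pace a single cell and return the last conditioned beat.

    Returns ``(t, vm)`` sampled every integration step ``dt`` over the final
    beat (from the last stimulus to the end of its cycle). With
    ``return_state`` also returns the full state vector at the end of pacing,
    which tissue simulations use as their conditioned initial condition.
    """
    from ._kernels import run_cell

    params = params or IonicParams()
    protocol = protocol or PacingProtocol()
    if dt > 0.02 + 1e-12:
        raise ValueError("dt must be <= 0.02 ms to resolve the Na+ upstroke")

    y0 = resting_state() if initial_state is None else np.array(initial_state, dtype=float)
    tab = build_tables(params, dt)
    sc = node_scale_arrays(1, params)
    pcl_steps = int(round(protocol.pcl / dt))
    dur_steps = int(round(protocol.stim_duration / dt))
    n_steps = pcl_steps * protocol.n_beats
    stim_pa_pf = protocol.stim_amplitude / params.cm_cell

    vm_all, y_end, blow = run_cell(
        y0, tab, TAB_VMIN, 1.0 / TAB_DV, dt, n_steps, pcl_steps, dur_steps,
        stim_pa_pf, sc[:, 0])
    if blow >= 0:
        raise NumericalBlowupError(
            f"|vm| exceeded 200 mV at step {blow} (t={blow * dt:.3f} ms)")

    start = pcl_steps * (protocol.n_beats - 1)
    vm = vm_all[start:]
    t = np.arange(vm.size) * dt
    if return_state:
        return t, vm, y_end
    return t, vm


def measure_apd90(vm_series: np.ndarray, dt: float) -> float:
    """APD90 from a single-beat Vm series.

    Measured from the point of maximum upstroke velocity to the first
    subsequent downward crossing of rest + 10% of (peak - rest), with linear
    interpolation between samples. ``rest`` is the first sample of the series.
    """
    vm = np.asarray(vm_series, dtype=float)
    if vm.size < 3:
        raise UndefinedApdError("series too short")
    dvdt = np.diff(vm) / dt
    k_up = int(np.argmax(dvdt))
    rest = vm[0]
    peak = float(vm.max())
    if peak - rest < 10.0 or dvdt[k_up] <= 0:
        raise UndefinedApdError("no action potential upstroke in series")
    level = rest + 0.1 * (peak - rest)  # 90% repolarized
    k_peak = int(np.argmax(vm))
    below = np.flatnonzero(vm[k_peak + 1:] < level)
    if below.size == 0:
        raise UndefinedApdError("no repolarization to the 90% level")
    i = k_peak + below[0]  # vm[i] >= level > vm[i+1]
    frac = (vm[i] - level) / (vm[i] - vm[i + 1])
    t_cross = (i + frac) * dt
    return t_cross - k_up * dt


def calibrate_apd(target_apd90: float,
                  protocol: PacingProtocol | None = None,
                  params: IonicParams | None = None,
                  dt: float = 0.02,
                  tol_ms: float = 0.5,
                  scale_bounds: tuple = (0.1, 10.0)) -> tuple:
    """Find a common IKr/IKs scale factor hitting a target APD90.

    Both delayed-rectifier conductances are multiplied by the same factor
    (the published description adjusts both without stating a ratio) and the
    factor is found by bisection; APD90 is monotone decreasing in it.
    Returns ``(scale_kr, scale_ks)`` with equal entries.
    """
    if not 120.0 <= target_apd90 <= 350.0:
        raise ValueError("target APD90 outside [120, 350] ms")
    protocol = protocol or PacingProtocol()
    base = params or IonicParams()

    def apd_at(s: float) -> float:
        p = IonicParams(
            g_na=base.g_na, g_k1=base.g_k1, g_to=base.g_to, g_kr=base.g_kr,
            g_ks=base.g_ks, g_cal=base.g_cal, g_b_ca=base.g_b_ca,
            g_b_na=base.g_b_na, i_nak_max=base.i_nak_max,
            i_naca_max=base.i_naca_max, i_pca_max=base.i_pca_max,
            cm_cell=base.cm_cell, scale_kr=s, scale_ks=s,
            remodeling_scales=base.remodeling_scales)
        t, vm = simulate_cell(p, protocol, dt)
        return measure_apd90(vm, dt)

    lo, hi = scale_bounds
    apd_1 = apd_at(1.0)
    if abs(apd_1 - target_apd90) <= tol_ms:
        return (1.0, 1.0)
    apd_lo, apd_hi = apd_at(lo), apd_at(hi)
    if not (apd_hi <= target_apd90 <= apd_lo):
        raise CalibrationError(
            f"target {target_apd90} ms unreachable: scale {lo} -> {apd_lo:.1f} ms, "
            f"scale {hi} -> {apd_hi:.1f} ms")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        apd = apd_at(mid)
        if abs(apd - target_apd90) <= tol_ms:
            return (mid, mid)
        if apd > target_apd90:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    raise CalibrationError(
        f"bisection stalled in [{lo:.6f}, {hi:.6f}] for target {target_apd90} ms")
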