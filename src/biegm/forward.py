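"""Extracellular-potential forward model and bipolar electrogram assembly.

Each tissue node is treated as a current source of strength proportional to
the local diffusion current density (the source term stored in
:class:`~biegm.tissue.SimulationResult`), radiating in an infinite
homogeneous volume conductor:

    phi(r) = K * sum_j s_j * A_j * th / max(|r - x_j|, d_min)

with s_j the diffusion source (mV/ms), A_j the lumped node area (mm^2), th
the uniform wall thickness (mm), d_min a clamp equal to the catheter contact
clearance, and K a single global gain (mV * ms / mm^2 per source unit). The
absolute voltage scale of such a model is set by conductivities the study
chain does not constrain, so K is a configuration constant chosen to put
homogeneous-sheet Thermocool amplitudes at CO = CA = 0 in the 1-2 mV range;
every amplitude ratio and ordering the experiments report is K-independent.

Electrode voltages are the unweighted mean of their patch potentials (the
patches are near-equal-area by construction; an area-weighted option is
provided) and the bipolar trace is the signed difference distal - proximal,
sampled at 1 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.spatial.distance import cdist

from .catheter import CONTACT_CLEARANCE_MM, ElectrodePatches
from .errors import ConfigurationError
from .mesh import TissueModel
from .tissue import SimulationResult

#: global source-to-potential gain; see module docstring
DEFAULT_GAIN = 3.2e-2


@dataclass
class EgmTrace:
    """Uniformly sampled unipolar and bipolar electrogram channels (mV)."""

    times: np.ndarray       # ms, 1 kHz
    v_distal: np.ndarray
    v_proximal: np.ndarray
    v_bipolar: np.ndarray
    filter_applied: str = "none"
    meta: dict | None = None

    def __post_init__(self):
        diff = self.v_distal - self.v_proximal
        if not (np.allclose(self.v_bipolar, diff, atol=1e-9)
                or np.allclose(self.v_bipolar, -diff, atol=1e-9)):
            raise ConfigurationError(
                "bipolar channel must be the signed difference of the "
                "unipolar channels")

    @property
    def sample_dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _source_strengths(source_field: np.ndarray, tissue: TissueModel
                      ) -> np.ndarray:
    if not np.all(np.isfinite(source_field)):
        raise ValueError("non-finite source field")
    return source_field * (tissue.node_area * tissue.wall_thickness)


def extracellular_potential(source_field: np.ndarray, tissue: TissueModel,
                            points, *, gain: float = DEFAULT_GAIN,
                            d_min: float = CONTACT_CLEARANCE_MM) -> np.ndarray:
    """Potential (mV) at query points from one or many source snapshots.

    ``source_field`` is (n,) or (T, n); returns (p,) or (T, p).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    src = np.asarray(source_field, dtype=float)
    single = src.ndim == 1
    strengths = _source_strengths(np.atleast_2d(src), tissue)
    r = np.maximum(cdist(pts, tissue.nodes), d_min)
    phi = gain * strengths @ (1.0 / r).T
    if single:
        phi = phi[0]
        if phi.size == 1 and np.ndim(points) == 1:
            return float(phi[0])
    return phi


def electrode_weight_vectors(patches: ElectrodePatches, tissue: TissueModel,
                             *, gain: float = DEFAULT_GAIN,
                             d_min: float = CONTACT_CLEARANCE_MM,
                             area_weighted: bool = False) -> np.ndarray:
    """(2, n) node-weight rows turning a source snapshot into electrode voltages.

    Row e is the patch-average of K * A_j * th / r over electrode e's
    patches, so ``weights @ source`` gives the two unipolar voltages.
    """
    if patches.n_patches == 0:
        raise ConfigurationError("empty patch set")
    r = np.maximum(cdist(patches.centers, tissue.nodes), d_min)
    kern = gain * (tissue.node_area * tissue.wall_thickness) / r
    out = np.empty((2, tissue.n_nodes))
    for e in (0, 1):
        sel = patches.electrode == e
        if not sel.any():
            raise ConfigurationError(f"electrode {e} has no patches")
        if area_weighted:
            a = patches.areas[sel]
            out[e] = (a[:, None] * kern[sel]).sum(axis=0) / a.sum()
        else:
            out[e] = kern[sel].mean(axis=0)
    return out


def electrode_voltage(patches: ElectrodePatches, source_field: np.ndarray,
                      tissue: TissueModel, *, gain: float = DEFAULT_GAIN,
                      d_min: float = CONTACT_CLEARANCE_MM,
                      area_weighted: bool = False) -> np.ndarray:
    """Per-electrode voltages (2,) or (T, 2) for source snapshot(s)."""
    w = electrode_weight_vectors(patches, tissue, gain=gain, d_min=d_min,
                                 area_weighted=area_weighted)
    src = np.asarray(source_field, dtype=float)
    return src @ w.T


def record_bipolar(result: SimulationResult, patches: ElectrodePatches,
                   tissue: TissueModel, *, gain: float = DEFAULT_GAIN,
                   d_min: float = CONTACT_CLEARANCE_MM,
                   sign: int = +1, meta: dict | None = None) -> EgmTrace:
    """Bipolar electrogram of a placed catheter over a recorded simulation.

    ``sign=+1`` gives distal - proximal; ``sign=-1`` flips the convention.
    No filter is applied.
    """
    v = electrode_voltage(patches, result.source_field, tissue,
                          gain=gain, d_min=d_min)
    v_d, v_p = v[:, 0], v[:, 1]
    return EgmTrace(times=result.times.copy(), v_distal=v_d, v_proximal=v_p,
                    v_bipolar=sign * (v_d - v_p),
                    meta=meta)


def bandpass(trace: EgmTrace, low_hz: float, high_hz: float,
             order: int = 4) -> EgmTrace:
    """Zero-phase Butterworth band-pass of all channels (DC fully rejected)."""
    fs = 1000.0 / trace.sample_dt
    nyq = fs / 2.0
    if not 0.0 < low_hz < high_hz < nyq:
        raise ConfigurationError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=fs, output="sos")
    f = lambda x: signal.sosfiltfilt(sos, x)
    return replace(trace,
                   v_distal=f(trace.v_distal),
                   v_proximal=f(trace.v_proximal),
                   v_bipolar=f(trace.v_bipolar),
                   filter_applied=f"bandpass {low_hz:g}-{high_hz:g} Hz")
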