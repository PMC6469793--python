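"""Monodomain reaction-diffusion solver on tissue meshes.

The transmembrane potential obeys

    dVm/dt = 1/(beta*Cm) div(D grad Vm) - (I_ion + I_s)/Cm

with the atrial membrane kinetics of :mod:`biegm.ionic` at every node, an
isotropic scalar D, no-flux boundaries, and scar nodes fully uncoupled.
Stimuli are whole-cell currents (pA) divided by the whole-cell capacitance,
applied to explicit node sets. Fields are recorded on the 1 kHz electrogram
sampling grid; the stored source field is the diffusion term
d_eff * Laplacian(Vm) (mV/ms), which is the current-source density the
extracellular forward model integrates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .errors import (CalibrationError, ConfigurationError, InductionError,
                     NumericalBlowupError)
from .ionic import (IonicParams, PacingProtocol, build_tables,
                    node_scale_arrays, resting_state, simulate_cell,
                    TAB_VMIN, TAB_DV, N_STATE)
from .mesh import TissueModel

ACT_THRESHOLD_MV = -40.0
SAMPLE_DT_MS = 1.0   # electrogram sampling period (1 kHz)


@dataclass
class StimEpisode:
    """One stimulation episode: window (ms), whole-cell amplitude (pA), nodes."""

    start_ms: float
    end_ms: float
    amplitude_pa: float
    nodes: np.ndarray


@dataclass
class SimulationResult:
    """Recorded fields of one tissue run."""

    times: np.ndarray             # (T,) ms, uniform at the sampling period
    vm_field: np.ndarray          # (T, n) mV, float32
    source_field: np.ndarray      # (T, n) mV/ms, float32
    activation_times: np.ndarray  # (n,) ms; NaN where never activated
    meta: dict

    @property
    def n_nodes(self) -> int:
        return self.vm_field.shape[1]


def edge_band_nodes(tissue: TissueModel, depth_mm: float = 1.0) -> np.ndarray:
    """Nodes within ``depth_mm`` of the left (min-x) edge: planar-wave pacing site.

    A site of finite depth is needed for capture — a single node column loses
    its stimulus charge to the diffusive sink of the surrounding tissue.
    """
    x = tissue.nodes[:, 0]
    return np.flatnonzero(x < x.min() + depth_mm + 1e-9)


def disc_nodes(tissue: TissueModel, center, radius_mm: float = 1.0) -> np.ndarray:
    """Nodes within a disc on the sheet: point-like pacing site."""
    from .geometry import sheet_coordinates

    uv = sheet_coordinates(tissue)
    d = np.linalg.norm(uv - np.asarray(center, dtype=float), axis=1)
    return np.flatnonzero(d <= radius_mm + 1e-9)


def _episode_arrays(episodes: Sequence[StimEpisode], dt: float,
                    cm_cell: float):
    ep_start = np.array([int(round(e.start_ms / dt)) for e in episodes],
                        dtype=np.int64)
    ep_end = np.array([int(round(e.end_ms / dt)) for e in episodes],
                      dtype=np.int64)
    ep_amp = np.array([e.amplitude_pa / cm_cell for e in episodes])
    lens = [len(e.nodes) for e in episodes]
    ep_ptr = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)
    ep_nodes = (np.concatenate([np.asarray(e.nodes, dtype=np.int64)
                                for e in episodes])
                if episodes else np.empty(0, dtype=np.int64))
    return ep_start, ep_end, ep_amp, ep_ptr, ep_nodes


def _run_segment(tissue: TissueModel, Y: np.ndarray, params: IonicParams,
                 sc: np.ndarray, episodes: Sequence[StimEpisode],
                 duration_ms: float, dt: float,
                 rec_start_ms: float | None, rec_duration_ms: float,
                 act: np.ndarray, t_offset: float,
                 sample_dt: float = SAMPLE_DT_MS):
    """Advance the tissue by one time segment, mutating Y and act in place."""
    c = tissue.coupling()
    tab = build_tables(params, dt)
    gpars = _kernels.gpars_from_params(params)
    n_steps = int(round(duration_ms / dt))
    stride = int(round(sample_dt / dt))
    if rec_start_ms is None:
        rec_start, n_rec = 0, 0
    else:
        rec_start = int(round(rec_start_ms / dt))
        n_rec = int(round(rec_duration_ms / sample_dt))
    vrec = np.empty((n_rec, tissue.n_nodes), dtype=np.float32)
    srec = np.empty((n_rec, tissue.n_nodes), dtype=np.float32)
    ep = _episode_arrays(episodes, dt, params.cm_cell)
    blow = _kernels.run_tissue(
        Y, c.indptr, c.indices, c.weights, c.inv_area, tissue.d_eff,
        tab, TAB_VMIN, 1.0 / TAB_DV, dt, n_steps, sc, gpars,
        *ep, rec_start, stride, vrec, srec, act, ACT_THRESHOLD_MV, t_offset)
    if blow >= 0:
        raise NumericalBlowupError(
            f"|vm| exceeded 200 mV at step {blow} (t={t_offset + blow * dt:.2f} ms)")
    times = (t_offset + (rec_start_ms or 0.0)
             + np.arange(n_rec) * sample_dt)
    return times, vrec, srec


def conditioned_state(params: IonicParams | None = None,
                      protocol: PacingProtocol | None = None,
                      dt: float = 0.02) -> np.ndarray:
    """Single-cell state after the protocol's conditioning beats.

    Used as the uniform tissue initial condition so that tissue runs start
    from rate-adapted membrane state without paying for tissue-scale
    conditioning beats.
    """
    _, _, y_end = simulate_cell(params, protocol, dt, return_state=True)
    return y_end


def _init_states(tissue: TissueModel, initial_state: np.ndarray | None,
                 params: IonicParams, protocol: PacingProtocol | None,
                 dt: float) -> np.ndarray:
    if initial_state is None:
        if protocol is not None and protocol.n_beats > 0:
            y0 = conditioned_state(params, protocol, dt)
        else:
            y0 = resting_state()
    else:
        y0 = np.asarray(initial_state, dtype=float)
    if y0.ndim == 1:
        Y = np.tile(y0, (tissue.n_nodes, 1))
    else:
        Y = np.array(y0, dtype=float)
    if Y.shape != (tissue.n_nodes, N_STATE):
        raise ConfigurationError("initial state has wrong shape")
    return Y


def pace(tissue: TissueModel, protocol: PacingProtocol,
         pacing_nodes, *, params: IonicParams | None = None,
         dt: float = 0.02, n_tissue_beats: int = 1,
         record_start: float = 0.0, record_duration: float | None = None,
         sample_dt: float = SAMPLE_DT_MS,
         initial_state: np.ndarray | None = None,
         return_states: bool = False):
    """Pace the tissue at a node set and record fields around the last beat.

    Conditioning happens at the single-cell level (``protocol.n_beats``
    beats); the tissue itself is stimulated ``n_tissue_beats`` times at the
    protocol's cycle length and the recording window (default: the full last
    cycle) is placed on the final beat. Each pacing node receives the
    protocol's whole-cell stimulus current.
    """
    params = params or IonicParams()
    pacing_nodes = np.atleast_1d(np.asarray(pacing_nodes, dtype=np.int64))
    if pacing_nodes.size == 0:
        raise ConfigurationError("pacing node set is empty")
    if tissue.scar_mask[pacing_nodes].any():
        raise ConfigurationError("pacing site lies inside a scar")
    tissue.check_dt(dt)

    Y = _init_states(tissue, initial_state, params, protocol, dt)
    sc = np.ascontiguousarray(
        node_scale_arrays(tissue.n_nodes, params, tissue.fibrosis_mask).T)
    episodes = [
        StimEpisode(k * protocol.pcl, k * protocol.pcl + protocol.stim_duration,
                    protocol.stim_amplitude, pacing_nodes)
        for k in range(n_tissue_beats)
    ]
    if record_duration is None:
        record_duration = protocol.pcl - record_start
    rec_abs_start = (n_tissue_beats - 1) * protocol.pcl + record_start
    duration = rec_abs_start + record_duration
    act = np.full(tissue.n_nodes, -1.0)
    times, vrec, srec = _run_segment(
        tissue, Y, params, sc, episodes, duration, dt,
        rec_abs_start, record_duration, act, 0.0, sample_dt)

    act_out = np.where(act < 0, np.nan, act)
    n_active = int(np.isfinite(act_out).sum())
    meta = {
        "pcl": protocol.pcl,
        "n_tissue_beats": n_tissue_beats,
        "pacing_nodes": pacing_nodes,
        "capture": n_active > pacing_nodes.size,
        "dt": dt,
    }
    result = SimulationResult(times=times, vm_field=vrec, source_field=srec,
                              activation_times=act_out, meta=meta)
    if return_states:
        return result, Y
    return result


# ---------------------------------------------------------------------------
# Conduction-velocity calibration
# ---------------------------------------------------------------------------

def measure_planar_cv(tissue: TissueModel, *, params: IonicParams | None = None,
                      protocol: PacingProtocol | None = None, dt: float = 0.02,
                      probe_sep_mm: float = 10.0,
                      expected_cv: float = 0.05) -> float:
    """Planar-wave CV (m/s) on a strip from two interior probes.

    The left edge is stimulated once and the conduction delay between two
    probes ``probe_sep_mm`` apart on the centre row (both >= 10 mm from the
    strip ends) gives CV = distance/delay (mm/ms == m/s).
    """
    params = params or IonicParams()
    protocol = protocol or PacingProtocol()
    p = tissue.nodes
    width = p[:, 0].max() - p[:, 0].min()
    ymid = 0.5 * (p[:, 1].max() + p[:, 1].min())
    x0 = 0.5 * (width - probe_sep_mm)
    probe_a = tissue.nearest_node([x0, ymid, 0.0])
    probe_b = tissue.nearest_node([x0 + probe_sep_mm, ymid, 0.0])
    left = edge_band_nodes(tissue)

    # one stimulus; simulate until the far probe should long have activated
    duration = min(protocol.pcl,
                   (x0 + probe_sep_mm) / expected_cv * 1.3 + 30.0)
    proto1 = PacingProtocol(pcl=protocol.pcl,
                            stim_amplitude=protocol.stim_amplitude,
                            stim_duration=protocol.stim_duration,
                            n_beats=protocol.n_beats)
    res = pace(tissue, proto1, left, params=params, dt=dt, n_tissue_beats=1,
               record_start=0.0, record_duration=duration,
               sample_dt=duration)  # fields not needed; keep recording tiny
    ta = res.activation_times[probe_a]
    tb = res.activation_times[probe_b]
    if not (np.isfinite(ta) and np.isfinite(tb)) or tb <= ta:
        raise CalibrationError("wave did not traverse both probes (conduction block)")
    return probe_sep_mm / (tb - ta)


def calibrate_cv(target_cv: float, *, spacing: float = 0.25,
                 strip_length: float = 40.0,
                 params: IonicParams | None = None,
                 protocol: PacingProtocol | None = None, dt: float = 0.02,
                 tol_frac: float = 0.01, max_iter: int = 15,
                 full_output: bool = False):
    """Diffusion coefficient d_base reproducing a planar CV on a strip.

    Exploits CV ~ sqrt(D): fixed-point updates d <- d (target/cv)^2, which
    converges in a few iterations. Raises :class:`CalibrationError` on
    conduction block (source-sink failure at low targets).
    """
    if not 0.05 <= target_cv <= 1.5:
        raise ValueError("target CV outside [0.05, 1.5] m/s")
    from .geometry import make_sheet

    strip = make_sheet(strip_length, 6 * spacing, spacing)
    d = 0.35 * (target_cv / 0.6) ** 2   # cable-theory scaling from a known point
    cv = None
    for _ in range(max_iter):
        strip.d_base = d
        cv = measure_planar_cv(strip, params=params, protocol=protocol, dt=dt,
                               expected_cv=0.6 * target_cv)
        if abs(cv - target_cv) <= tol_frac * target_cv:
            if full_output:
                return d, cv
            return d
        d *= (target_cv / cv) ** 2
    raise CalibrationError(
        f"CV calibration did not converge: last d_base={d:g}, cv={cv:g} m/s")


# ---------------------------------------------------------------------------
# AF induction
# ---------------------------------------------------------------------------

def count_activations(vm_series: np.ndarray, thresh: float = ACT_THRESHOLD_MV,
                      reset: float = -60.0):
    """Indices of upward threshold crossings with hysteresis (local activations)."""
    v = np.asarray(vm_series, dtype=float)
    armed = v[0] < reset
    hits = []
    for i in range(1, v.size):
        if armed and v[i] >= thresh:
            hits.append(i)
            armed = False
        elif v[i] < reset:
            armed = True
    return np.array(hits, dtype=int)


@dataclass
class AfConfig:
    """Cross-field S1-S2 induction recipe for self-sustained reentry.

    The substrate must be AF-remodelled (short APD, reduced CV) for the
    reentrant wavelength to fit the sheet. The S2 timing is scanned over a
    small window around the S1 repolarization tail until reentry is
    observed.
    """

    stim_amplitude: float = -2900.0
    stim_duration: float = 3.0
    record_duration: float = 6000.0
    s2_offsets_ms: tuple = (0.0, -15.0, 15.0, -30.0, 30.0, -45.0, 45.0)
    probe_margin_frac: float = 0.25


def induce_af(tissue: TissueModel, params: IonicParams, *,
              config: AfConfig | None = None, dt: float = 0.02,
              sample_dt: float = SAMPLE_DT_MS) -> SimulationResult:
    """Induce and record self-sustained fibrillatory activity.

    Cross-field stimulation: a planar S1 from the left edge, then a
    quadrant S2 timed into the repolarization tail; candidate S2 times are
    tried in turn (deterministic schedule) and the first that yields
    re-entrant activity is extended to the full recording window.
    """
    config = config or AfConfig()
    tissue.check_dt(dt)
    p = tissue.nodes
    lo, hi = p.min(axis=0), p.max(axis=0)
    w, h = hi[0] - lo[0], hi[1] - lo[1]
    left = edge_band_nodes(tissue)
    quadrant = np.flatnonzero((p[:, 0] < lo[0] + w / 2) & (p[:, 1] < lo[1] + h / 2))

    # reference probes for re-entry detection
    probes = [tissue.nearest_node([lo[0] + f1 * w, lo[1] + f2 * h, 0])
              for f1, f2 in ((0.5, 0.5), (0.7, 0.3), (0.3, 0.7))]

    sc = np.ascontiguousarray(
        node_scale_arrays(tissue.n_nodes, params, tissue.fibrosis_mask).T)
    y0 = conditioned_state(params, PacingProtocol(n_beats=8), dt)

    # S1-only probe run: find when the S2 quadrant becomes excitable again
    Y = np.tile(y0, (tissue.n_nodes, 1))
    act = np.full(tissue.n_nodes, -1.0)
    s1 = StimEpisode(0.0, config.stim_duration, config.stim_amplitude, left)
    probe_dur = w / 0.1 * 1.2 + 50.0
    _, v_probe, _ = _run_segment(tissue, Y, params, sc, [s1], probe_dur, dt,
                                 0.0, probe_dur, act, 0.0, sample_dt)
    q_ref = tissue.nearest_node([lo[0] + 0.45 * w, lo[1] + 0.25 * h, 0])
    if act[q_ref] < 0:
        raise InductionError("S1 failed to propagate across the sheet")
    vq = v_probe[:, q_ref]
    rep = np.flatnonzero((vq[:-1] >= -65.0) & (vq[1:] < -65.0))
    if rep.size == 0:
        raise InductionError("S2 quadrant never repolarized in the probe window")
    s2_base = float(rep[-1]) * sample_dt + 5.0

    tried = []
    for off in config.s2_offsets_ms:
        s2_time = s2_base + off
        tried.append(s2_time)
        Y = np.tile(y0, (tissue.n_nodes, 1))
        act = np.full(tissue.n_nodes, -1.0)
        episodes = [s1, StimEpisode(s2_time, s2_time + config.stim_duration,
                                    config.stim_amplitude, quadrant)]
        trial_dur = s2_time + 600.0
        _, vtrial, _ = _run_segment(tissue, Y, params, sc, episodes,
                                    trial_dur, dt, 0.0, trial_dur, act, 0.0,
                                    sample_dt)
        post = int((s2_time + 150.0) / sample_dt)
        n_acts = max(count_activations(vtrial[post:, pr]).size for pr in probes)
        if n_acts >= 2:
            # reentry initiated: extend the same run to the recording window
            times, vrec, srec = _run_segment(
                tissue, Y, params, sc, [], config.record_duration, dt,
                0.0, config.record_duration, act, trial_dur, sample_dt)
            best = None
            for pr in probes:
                hits = count_activations(vrec[:, pr])
                if best is None or hits.size > best[1].size:
                    best = (pr, hits)
            pr, hits = best
            t_hits = hits * sample_dt
            sustained = (hits.size >= 2
                         and t_hits[-1] > config.record_duration - 1500.0)
            cls = np.diff(t_hits)
            if sustained and cls.size >= 2 and np.ptp(cls) > 1e-9:
                act_out = np.where(act < 0, np.nan, act)
                meta = {"s2_time": s2_time, "s2_times_tried": tried,
                        "reference_node": pr,
                        "cycle_lengths": cls, "dt": dt, "af": True}
                return SimulationResult(times=times, vm_field=vrec,
                                        source_field=srec,
                                        activation_times=act_out, meta=meta)
    raise InductionError(
        f"no sustained reentry for S2 times {np.round(tried, 1)} ms; "
        "shorten APD / reduce CV or enlarge the sheet")
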