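"""Morphology feature extraction and the study's experiment drivers.

Everything here operates on a :class:`SheetStudy` — a bundle of one tissue
model, one recorded propagation episode, and the membrane/conduction
parameters that produced it — and turns catheter poses into electrogram
features (peak-to-peak amplitude in mV, peak-to-peak width in ms). The
drivers reproduce the study designs: orientation / contact-angle sweeps,
conduction-velocity and APD comparisons, scar-size series, catheter-type
comparisons, fibrillation recordings, virtual voltage maps with segment
averaging, and the scar cut-off sensitivity analysis.

All stochastic choices (site sampling, random orientations) flow from
explicit integer seeds, so any run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catheter import (CatheterDesign, CatheterPose, ElectrodePatches,
                       builtin_designs, place, subdivide_electrodes,
                       wavefront_direction)
from .errors import ConfigurationError, PlacementError
from .forward import DEFAULT_GAIN, EgmTrace, bandpass, record_bipolar
from .geometry import ScarSpec, apply_scar, make_sheet, sheet_coordinates
from .ionic import IonicParams, PacingProtocol, calibrate_apd
from .mesh import TissueModel
from .tissue import (SimulationResult, calibrate_cv, edge_band_nodes,
                     induce_af, pace)

AF_BAND_HZ = (30.0, 150.0)


@dataclass
class EgmFeatures:
    """Peak-to-peak amplitude (mV) and peak-to-peak width (ms) of one beat."""

    amplitude: float
    width: float
    flat: bool = False


def extract_features(trace: EgmTrace, window: tuple | None = None,
                     noise_floor: float = 1e-6) -> EgmFeatures:
    """Features of the bipolar deflection inside a time window.

    Amplitude is max - min of the bipolar channel; width is the time between
    the (earliest) positive and negative extrema. A trace whose range is
    below ``noise_floor`` is flagged flat with zero features.
    """
    v = trace.v_bipolar
    t = trace.times
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        if not sel.any():
            raise ConfigurationError("empty feature window")
        v, t = v[sel], t[sel]
    amp = float(v.max() - v.min())
    if amp < noise_floor:
        return EgmFeatures(0.0, 0.0, flat=True)
    width = float(abs(t[int(np.argmax(v))] - t[int(np.argmin(v))]))
    return EgmFeatures(amp, width)


# ---------------------------------------------------------------------------
# Study context
# ---------------------------------------------------------------------------

@dataclass
class SheetStudy:
    """One tissue + one recorded propagation episode + its parameters."""

    tissue: TissueModel
    result: SimulationResult
    params: IonicParams
    protocol: PacingProtocol
    gain: float = DEFAULT_GAIN
    _patch_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def paced_sheet(cls, *, width: float = 40.0, height: float = 40.0,
                    spacing: float = 0.5, cv: float = 0.48,
                    apd90: float | None = None,
                    scar: ScarSpec | None = None,
                    d_base: float | None = None,
                    apd_scales: tuple | None = None,
                    pcl: float = 600.0, n_conditioning_beats: int = 8,
                    n_tissue_beats: int = 1,
                    record_duration: float | None = None,
                    dt: float = 0.02, gain: float = DEFAULT_GAIN
                    ) -> "SheetStudy":
        """Planar-wave study: sheet + left-edge pacing at calibrated CV/APD.

        ``d_base`` and ``apd_scales`` short-circuit the (more expensive)
        calibrations when known; otherwise :func:`calibrate_cv` /
        :func:`calibrate_apd` run first.
        """
        protocol = PacingProtocol(pcl=pcl, n_beats=n_conditioning_beats)
        if apd_scales is None and apd90 is not None:
            apd_scales = calibrate_apd(apd90, PacingProtocol(pcl=pcl, n_beats=20))
        params = (IonicParams() if apd_scales is None
                  else IonicParams(scale_kr=apd_scales[0], scale_ks=apd_scales[1]))
        if d_base is None:
            d_base = calibrate_cv(cv, spacing=spacing, params=params)
        sheet = make_sheet(width, height, spacing, d_base=d_base)
        if scar is not None:
            sheet = apply_scar(sheet, scar)
        if record_duration is None:
            record_duration = width / cv * 1.3 + 120.0
        result = pace(sheet, protocol, edge_band_nodes(sheet), params=params,
                      dt=dt, n_tissue_beats=n_tissue_beats,
                      record_duration=record_duration)
        return cls(tissue=sheet, result=result, params=params,
                   protocol=protocol, gain=gain)

    def local_patches(self, design: CatheterDesign) -> ElectrodePatches:
        if design.name not in self._patch_cache:
            self._patch_cache[design.name] = subdivide_electrodes(design)
        return self._patch_cache[design.name]

    def global_wave_direction(self) -> np.ndarray:
        """Sheet-mean propagation direction (activation-time plane fit)."""
        act = self.result.activation_times
        ok = np.isfinite(act)
        A = self.tissue.nodes[ok] - self.tissue.nodes[ok].mean(axis=0)
        g, *_ = np.linalg.lstsq(A, act[ok] - act[ok].mean(), rcond=None)
        g[2] = 0.0
        return g / np.linalg.norm(g)

    def wave_direction_at(self, node: int,
                          in_scar: str = "global") -> np.ndarray:
        """Local propagation direction from the activation-time gradient.

        Inside a scar no neighbour ever activates; ``in_scar`` picks the
        reference there: ``"global"`` uses the macroscopic (sheet-mean)
        incoming-wave direction, ``"nearest"`` uses the activation-time
        gradient at the closest activated node — i.e. the detouring boundary
        flow, the only wave in the neighbourhood of a fully in-scar
        catheter.
        """
        if self.tissue.scar_mask[node]:
            if in_scar == "nearest":
                act = self.result.activation_times
                ok = np.isfinite(act)
                d = np.linalg.norm(self.tissue.nodes - self.tissue.nodes[node],
                                   axis=1)
                d[~ok] = np.inf
                node = int(np.argmin(d))
            else:
                return self.global_wave_direction()
        for radius in (2.0, 4.0, 8.0):
            try:
                return wavefront_direction(self.tissue,
                                           self.result.activation_times,
                                           node, radius)
            except ConfigurationError:
                continue
        return self.global_wave_direction()

    def trace(self, design: CatheterDesign, node: int, co: float, ca: float,
              filtered: bool = False) -> EgmTrace:
        pose = CatheterPose(self.tissue.nodes[node], co=co, ca=ca)
        patches = place(design, pose, self.tissue,
                        self.wave_direction_at(node),
                        patches=self.local_patches(design))
        tr = record_bipolar(self.result, patches, self.tissue, gain=self.gain,
                            meta={"design": design.name, "node": node,
                                  "co": co, "ca": ca})
        if filtered:
            tr = bandpass(tr, *AF_BAND_HZ)
        return tr

    def features(self, design: CatheterDesign, node: int, co: float,
                 ca: float) -> EgmFeatures:
        return extract_features(self.trace(design, node, co, ca))


def sample_sites(tissue: TissueModel, n: int, *, margin_mm: float = 9.0,
                 seed: int = 0, exclude_scar: bool = True) -> np.ndarray:
    """Replicate measurement sites drawn without replacement from the interior."""
    ok = tissue.interior_mask(margin_mm)
    if exclude_scar:
        ok &= ~tissue.scar_mask
    idx = np.flatnonzero(ok)
    if idx.size < n:
        raise ConfigurationError(
            f"only {idx.size} interior nodes available for {n} sites")
    rng = np.random.default_rng(seed)
    return rng.choice(idx, size=n, replace=False)


# ---------------------------------------------------------------------------
# Sweeps and comparisons
# ---------------------------------------------------------------------------

def sweep(study: SheetStudy, designs: Sequence[CatheterDesign],
          sites: Sequence[int], co_values: Sequence[float],
          ca_values: Sequence[float],
          condition: dict | None = None) -> pd.DataFrame:
    """Feature table over sites x poses x designs (one tidy row each).

    Placement failures are recorded as excluded rows (``excluded`` column
    with the reason) rather than aborting the sweep.
    """
    rows = []
    for design in designs:
        for site in sites:
            for co in co_values:
                for ca in ca_values:
                    row = {"design": design.name, "site": int(site),
                           "co": co, "ca": ca, "excluded": ""}
                    if condition:
                        row.update(condition)
                    try:
                        f = study.features(design, int(site), co, ca)
                        row.update(amplitude=f.amplitude, width=f.width,
                                   flat=f.flat)
                    except PlacementError as exc:
                        row.update(amplitude=np.nan, width=np.nan, flat=True,
                                   excluded=str(exc))
                    rows.append(row)
    return pd.DataFrame(rows)


def compare_designs(study: SheetStudy, sites: Sequence[int], *,
                    co: float = 0.0, ca: float = 0.0,
                    designs: Sequence[CatheterDesign] | None = None
                    ) -> pd.DataFrame:
    """Paired per-site amplitudes for the built-in designs at one pose."""
    designs = tuple(designs) if designs is not None else builtin_designs()
    return sweep(study, designs, sites, [co], [ca])


def summarize(table: pd.DataFrame, value: str = "amplitude",
              by: Sequence[str] = ("design",)) -> pd.DataFrame:
    """Group mean +/- SD (and n) of a feature column."""
    g = table.groupby(list(by))[value]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    return out


def welch_p(a, b) -> float:
    """Welch two-sample t-test p-value (supporting statistic only)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("need >= 2 replicates per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def scar_size_series(studies, design: CatheterDesign, center,
                     n_sites: int = 10, jitter_mm: float = 0.6,
                     seed: int = 0) -> pd.DataFrame:
    """Electrogram features over a series of scar diameters.

    ``studies`` maps scar diameter (mm; 0 = no scar) to a
    :class:`SheetStudy` on the same sheet/calibration. The catheter is laid
    flat (CA = CO = 0) with its bipole midpoint on the scar centre — the
    pose in which both electrodes sense the wave entering and leaving the
    non-conductive zone — and replicate sites jitter that position by up to
    ``jitter_mm`` in each sheet direction (same jitter across diameters, so
    the series is paired).
    """
    from .catheter import bipole_half_extent

    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-jitter_mm, jitter_mm, size=(n_sites, 2))
    half = bipole_half_extent(design)
    cx, cy = float(center[0]), float(center[1])
    rows = []
    for diam, study in sorted(studies.items()):
        wave = study.global_wave_direction()
        for k, (dx, dy) in enumerate(jitter):
            contact = np.array([cx, cy, 0.0]) - half * wave
            contact[0] += dx
            contact[1] += dy
            node = study.tissue.nearest_node(contact)
            f = study.features(design, node, 0.0, 0.0)
            rows.append({"diameter": diam, "site": k, "design": design.name,
                         "amplitude": f.amplitude, "width": f.width})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fibrillation recordings
# ---------------------------------------------------------------------------

def af_study(*, width: float = 40.0, height: float = 40.0,
             spacing: float = 0.5, cv: float = 0.30, apd90: float = 120.0,
             d_base: float | None = None, apd_scales: tuple | None = None,
             record_duration: float = 6000.0, dt: float = 0.02,
             gain: float = DEFAULT_GAIN) -> SheetStudy:
    """Self-sustained fibrillation on an AF-remodelled sheet.

    The substrate is remodelled (short APD via delayed-rectifier upscaling,
    reduced CV) so the re-entrant wavelength fits the sheet; activity is
    recorded for 6 s by default.
    """
    from .tissue import AfConfig

    if apd_scales is None:
        apd_scales = calibrate_apd(apd90, PacingProtocol(pcl=600.0, n_beats=20))
    params = IonicParams(scale_kr=apd_scales[0], scale_ks=apd_scales[1])
    if d_base is None:
        d_base = calibrate_cv(cv, spacing=spacing, params=params)
    sheet = make_sheet(width, height, spacing, d_base=d_base)
    cfg = AfConfig(record_duration=record_duration)
    result = induce_af(sheet, params, config=cfg, dt=dt)
    return SheetStudy(tissue=sheet, result=result, params=params,
                      protocol=PacingProtocol(), gain=gain)


def af_amplitude(trace: EgmTrace, *, threshold_mads: float = 3.0,
                 refractory_ms: float = 50.0, window_ms: float = 60.0) -> dict:
    """Per-deflection amplitudes of a band-passed fibrillation strip.

    Local activations are detected on the rectified bipolar signal at
    ``threshold_mads`` times its median absolute deviation with a refractory
    period; each deflection's peak-to-peak amplitude is measured in a window
    around the detection. Returns deflection times, amplitudes, and their
    mean (0 deflections -> mean 0).
    """
    from scipy.signal import find_peaks

    v = trace.v_bipolar
    t = trace.times
    dt = trace.sample_dt
    x = np.abs(v)
    mad = float(np.median(np.abs(x - np.median(x))))
    # a clean sparse trace has zero MAD; any positive excursion then counts
    peaks, _ = find_peaks(x, height=max(threshold_mads * mad, 1e-9),
                          distance=max(1, int(refractory_ms / dt)))
    half = int(window_ms / 2 / dt)
    amps = []
    for k in peaks:
        wlo, whi = max(0, k - half), min(v.size, k + half + 1)
        amps.append(v[wlo:whi].max() - v[wlo:whi].min())
    amps = np.asarray(amps)
    return {"times": t[peaks], "amplitudes": amps,
            "mean": float(amps.mean()) if amps.size else 0.0}


def af_vs_paced(paced: SheetStudy, af: SheetStudy,
                design: CatheterDesign, n_sites: int = 10,
                seed: int = 0) -> pd.DataFrame:
    """Mean AF deflection amplitude vs paced amplitude at matched sites.

    Sites are sampled once on the paced sheet and mapped to the AF sheet by
    position; the catheter is placed with the same fixed orientation in both
    rhythms (in fibrillation the wave direction relative to the catheter is
    then effectively random, as it is clinically).
    """
    sites = sample_sites(paced.tissue, n_sites, seed=seed)
    rows = []
    for s in sites:
        xy = paced.tissue.nodes[s]
        f_p = paced.features(design, int(s), 0.0, 0.0)
        node_af = af.tissue.nearest_node(xy)
        tr = af.trace(design, node_af, 0.0, 0.0, filtered=True)
        det = af_amplitude(tr)
        rows.append({"site": int(s), "paced_amplitude": f_p.amplitude,
                     "af_amplitude": det["mean"],
                     "n_deflections": det["amplitudes"].size})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Virtual voltage maps
# ---------------------------------------------------------------------------

@dataclass
class VoltageMap:
    """Interpolated bipolar-amplitude map with a 10-segment partition."""

    sampled_nodes: np.ndarray
    sampled_amplitudes: np.ndarray
    interpolated: np.ndarray      # (n,) mV
    segments: np.ndarray          # (n,) labels 0..n_segments-1
    segment_means: np.ndarray     # (n_segments,) mV
    seed: int


def _idw_interpolate(tissue: TissueModel, nodes: np.ndarray,
                     values: np.ndarray, k: int = 6, power: float = 2.0
                     ) -> np.ndarray:
    from scipy.spatial import cKDTree

    uv = sheet_coordinates(tissue)
    tree = cKDTree(uv[nodes])
    k = min(k, nodes.size)
    d, j = tree.query(uv, k=k)
    d = np.atleast_2d(d.T).T
    j = np.atleast_2d(j.T).T
    w = 1.0 / np.maximum(d, 1e-12) ** power
    out = (w * values[j]).sum(axis=1) / w.sum(axis=1)
    exact = d[:, 0] < 1e-9
    out[exact] = values[j[exact, 0]]
    return out


def build_voltage_map(study: SheetStudy, design: CatheterDesign,
                      n_sites: int = 810, seed: int = 0,
                      n_segments: int = 10, margin_mm: float = 9.0
                      ) -> VoltageMap:
    """Voltage map from random placements with random orientations.

    ``n_sites`` nodes are sampled without replacement, the catheter is posed
    with independent uniform CO/CA at each, amplitudes are interpolated to
    every node (inverse-distance weighting, exact at sampled nodes), and the
    sheet is split into ``n_segments`` spatially contiguous segments by
    k-means on node coordinates for per-segment averaging.
    """
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(seed)
    sites = sample_sites(study.tissue, n_sites, margin_mm=margin_mm,
                         seed=int(rng.integers(2 ** 31)))
    cos = rng.uniform(0.0, 90.0, size=sites.size)
    cas = rng.uniform(0.0, 90.0, size=sites.size)
    amps = np.empty(sites.size)
    for i, s in enumerate(sites):
        amps[i] = study.features(design, int(s), cos[i], cas[i]).amplitude
    interp = _idw_interpolate(study.tissue, sites, amps)
    uv = sheet_coordinates(study.tissue)
    km = KMeans(n_clusters=n_segments, n_init=1,
                random_state=seed % (2 ** 31)).fit(uv)
    labels = km.labels_
    seg_means = np.array([interp[labels == s].mean()
                          for s in range(n_segments)])
    return VoltageMap(sampled_nodes=sites, sampled_amplitudes=amps,
                      interpolated=interp, segments=labels,
                      segment_means=seg_means, seed=seed)


# ---------------------------------------------------------------------------
# Scar cut-off sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class CutoffResult:
    """Lower cut-off voltage separating in-scar placements, per design/mode."""

    design: str
    mode: str                # "parallel" | "perpendicular" | "random"
    cutoff_mv: float         # max amplitude over in-scar placements
    n_in_scar: int
    n_placements: int


def _in_scar(patches: ElectrodePatches, center: np.ndarray,
             radius: float) -> bool:
    """Both electrodes fully inside the scar disc (sheet projection)."""
    d = np.linalg.norm(patches.centers[:, :2] - center[None, :], axis=1)
    return bool(np.all(d < radius))


def sensitivity_cutoffs(study: SheetStudy, scar: ScarSpec,
                        n_placements: int = 303, seed: int = 0,
                        designs: Sequence[CatheterDesign] | None = None,
                        modes: Sequence[str] = ("parallel", "perpendicular",
                                                "random"),
                        placement_margin_mm: float = 2.0) -> pd.DataFrame:
    """Scar-detection cut-offs from random placements in and around a scar.

    Placements are uniform over a disc extending ``placement_margin_mm``
    beyond the scar. A placement counts as in-scar for a design when both
    electrodes lie fully inside the non-conductive zone in every tested
    orientation, so all orientation modes of one design are compared on the
    same (paired) placement set. Per design and mode the cut-off is the
    maximum in-scar amplitude — the smallest threshold classifying every
    in-scar point as scar. CA is 0 throughout; CO is 0 (parallel), 90
    (perpendicular), or uniform on [0, 90] (random, one draw per
    placement).
    """
    designs = tuple(designs) if designs is not None else builtin_designs()
    if study.tissue.scar_mask.sum() == 0:
        raise ConfigurationError("study tissue carries no scar")
    rng = np.random.default_rng(seed)
    center = np.asarray(scar.center, dtype=float)
    r_scar = scar.diameter / 2.0
    r_max = r_scar + placement_margin_mm
    rr = r_max * np.sqrt(rng.random(n_placements))
    th = rng.uniform(0, 2 * np.pi, n_placements)
    pts = center + np.column_stack([rr * np.cos(th), rr * np.sin(th)])
    nodes = [study.tissue.nearest_node([p[0], p[1], 0.0]) for p in pts]
    random_cos = rng.uniform(0.0, 90.0, n_placements)

    def mode_co(mode: str, i: int) -> float:
        return {"parallel": 0.0, "perpendicular": 90.0}.get(
            mode, random_cos[i])

    rows = []
    for design in designs:
        local = study.local_patches(design)
        # orientation referenced to the local activation flow: for an
        # in-scar catheter that is the wave detouring along the boundary
        waves = [study.wave_direction_at(node, in_scar="nearest")
                 for node in nodes]
        placed = {}   # (mode, i) -> patches where that pose is in-scar
        for i, node in enumerate(nodes):
            for mode in modes:
                try:
                    p = place(design,
                              CatheterPose(study.tissue.nodes[node],
                                           co=mode_co(mode, i), ca=0.0),
                              study.tissue, waves[i], patches=local)
                except PlacementError:
                    continue
                if _in_scar(p, center, r_scar):
                    placed[(mode, i)] = p
        # pair the modes on a common placement set when the geometry allows
        # it (large footprints may not fit a small zone in every direction)
        paired = [i for i in range(len(nodes))
                  if all((m, i) in placed for m in modes)]
        for mode in modes:
            idx = paired if paired else [i for i in range(len(nodes))
                                         if (mode, i) in placed]
            if not idx:
                raise ConfigurationError(
                    f"no fully in-scar placements for {design.name}/{mode}; "
                    "increase n_placements")
            amps = []
            for i in idx:
                tr = record_bipolar(study.result, placed[(mode, i)],
                                    study.tissue, gain=study.gain)
                amps.append(extract_features(tr).amplitude)
            rows.append(CutoffResult(design=design.name, mode=mode,
                                     cutoff_mv=float(np.max(amps)),
                                     n_in_scar=len(idx),
                                     n_placements=n_placements))
    return pd.DataFrame([r.__dict__ for r in rows])
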