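"""Forward-model physics: 1/r kernel, linearity, averaging, filtering."""

import numpy as np
import pytest

from biegm.catheter import CatheterPose, builtin_designs, place, subdivide_electrodes
from biegm.errors import ConfigurationError
from biegm.forward import (EgmTrace, bandpass, electrode_voltage,
                           electrode_weight_vectors, extracellular_potential,
                           record_bipolar)
from biegm.geometry import make_sheet
from biegm.mesh import diffusion_source


@pytest.fixture(scope="module")
def sheet():
    return make_sheet(20, 20, 0.5)


def _point_source(sheet, node):
    src = np.zeros(sheet.n_nodes)
    src[node] = 1.0
    return src


class TestExtracellularPotential:
    def test_inverse_distance_decay(self, sheet):
        node = sheet.nearest_node([10, 10, 0])
        src = _point_source(sheet, node)
        p1 = extracellular_potential(src, sheet, [10, 10, 2.0])
        p2 = extracellular_potential(src, sheet, [10, 10, 4.0])
        assert p1 / p2 == pytest.approx(2.0, rel=1e-9)

    def test_uniform_vm_gives_zero_potential(self, sheet):
        src = diffusion_source(sheet, np.full(sheet.n_nodes, -81.0))
        phi = extracellular_potential(src, sheet, [10, 10, 1.0])
        assert abs(phi) < 1e-12

    def test_antisymmetric_sources_cancel_on_midplane(self, sheet):
        a = sheet.nearest_node([8, 10, 0])
        b = sheet.nearest_node([12, 10, 0])
        src = np.zeros(sheet.n_nodes)
        src[a], src[b] = 1.0, -1.0
        phi = extracellular_potential(src, sheet, [10, 10, 1.5])
        assert abs(phi) < 1e-12

    def test_linearity_in_sources(self, sheet, rng):
        s1 = rng.normal(size=sheet.n_nodes)
        s2 = rng.normal(size=sheet.n_nodes)
        pt = [7.0, 13.0, 1.0]
        lhs = extracellular_potential(s1 + 2.5 * s2, sheet, pt)
        rhs = (extracellular_potential(s1, sheet, pt)
               + 2.5 * extracellular_potential(s2, sheet, pt))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_non_finite_sources_rejected(self, sheet):
        src = _point_source(sheet, 0)
        src[5] = np.inf
        with pytest.raises(ValueError):
            extracellular_potential(src, sheet, [10, 10, 1.0])


class TestElectrodeAveraging:
    def test_coincident_patches_equal_point_potential(self, sheet, rng):
        from biegm.catheter import ElectrodePatches

        src = rng.normal(size=sheet.n_nodes)
        pt = np.array([10.0, 10.0, 1.0])
        patches = ElectrodePatches(
            centers=np.tile(pt, (8, 1)),
            areas=np.full(8, 0.05),
            electrode=np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.int8))
        v = electrode_voltage(patches, src, sheet)
        phi = extracellular_potential(src, sheet, pt)
        assert v[0] == pytest.approx(phi, rel=1e-12)
        assert v[1] == pytest.approx(phi, rel=1e-12)

    def test_flat_face_beats_equal_area_cylinder(self, sheet, rng):
        """A flat face at height h collects more signal than a cylinder whose
        near side is at h but whose far side is lifted by its diameter."""
        src = np.abs(rng.normal(size=sheet.n_nodes))  # one-sided sources
        n = 16
        h = 0.1
        diam = 2.0
        xs = np.linspace(9.0, 11.0, n)
        flat = np.column_stack([xs, np.full(n, 10.0), np.full(n, h)])
        phis = np.linspace(0, 2 * np.pi, n, endpoint=False)
        cyl = np.column_stack([xs, np.full(n, 10.0),
                               h + diam / 2 + diam / 2 * np.sin(phis)])
        v_flat = extracellular_potential(src, sheet, flat).mean()
        v_cyl = extracellular_potential(src, sheet, cyl).mean()
        assert v_flat >= v_cyl

    def test_patch_refinement_converges(self, sheet, rng):
        src = rng.normal(size=sheet.n_nodes)
        tc = builtin_designs()[0]
        pose = CatheterPose(np.array([10.0, 10.0, 0.0]), co=0, ca=30.0)
        wave = np.array([1.0, 0, 0])
        vs = {}
        for a in (0.07, 0.035):
            p = place(tc, pose, sheet, wave,
                      patches=subdivide_electrodes(tc, a))
            vs[a] = electrode_voltage(p, src, sheet)
        assert np.abs(vs[0.07] - vs[0.035]).max() < 0.01 * np.abs(
            vs[0.035]).max()

    def test_area_weighted_close_to_unweighted(self, baseline_study):
        """Patches are near-equal-area by construction, so area weighting
        barely moves the measured amplitude on the built-in designs."""
        study = baseline_study
        node = study.tissue.nearest_node([20.0, 20.0, 0.0])
        wave = np.array([1.0, 0, 0])
        for design in builtin_designs():
            p = place(design, CatheterPose(study.tissue.nodes[node],
                                           co=0, ca=0), study.tissue, wave)
            amps = {}
            for aw in (False, True):
                v = electrode_voltage(p, study.result.source_field,
                                      study.tissue, area_weighted=aw)
                bip = v[:, 0] - v[:, 1]
                amps[aw] = np.ptp(bip)
            assert amps[True] == pytest.approx(amps[False], rel=0.005)


class TestRecordBipolar:
    def _mini_result(self, sheet, rng):
        from biegm.tissue import SimulationResult

        T = 40
        return SimulationResult(
            times=np.arange(T, dtype=float),
            vm_field=np.zeros((T, sheet.n_nodes), dtype=np.float32),
            source_field=rng.normal(size=(T, sheet.n_nodes)).astype(np.float32),
            activation_times=np.zeros(sheet.n_nodes), meta={})

    def test_coincident_electrodes_cancel(self, sheet, rng):
        from biegm.catheter import ElectrodePatches

        res = self._mini_result(sheet, rng)
        pt = np.array([10.0, 10.0, 0.5])
        patches = ElectrodePatches(centers=np.tile(pt, (2, 1)),
                                   areas=np.full(2, 0.05),
                                   electrode=np.array([0, 1], dtype=np.int8))
        tr = record_bipolar(res, patches, sheet)
        assert np.abs(tr.v_bipolar).max() < 1e-12

    def test_swapping_electrodes_negates_bipolar(self, sheet, rng):
        res = self._mini_result(sheet, rng)
        tc = builtin_designs()[0]
        p = place(tc, CatheterPose(np.array([10.0, 10.0, 0.0]), co=0, ca=0),
                  sheet, np.array([1.0, 0, 0]))
        tr = record_bipolar(res, p, sheet)
        tr_swapped = record_bipolar(res, p, sheet, sign=-1)
        assert np.allclose(tr.v_bipolar, -tr_swapped.v_bipolar)
        assert (np.ptp(tr.v_bipolar)
                == pytest.approx(np.ptp(tr_swapped.v_bipolar)))

    def test_bipolar_channel_contract_enforced(self):
        with pytest.raises(ConfigurationError):
            EgmTrace(times=np.arange(3.0), v_distal=np.ones(3),
                     v_proximal=np.zeros(3), v_bipolar=np.zeros(3))

    def test_retreating_catheter_loses_signal(self, baseline_study):
        """Both unipolar peak magnitudes shrink as the catheter is lifted."""
        study = baseline_study
        tc = builtin_designs()[0]
        node = study.tissue.nearest_node([20.0, 20.0, 0.0])
        p = place(tc, CatheterPose(study.tissue.nodes[node], co=0, ca=0),
                  study.tissue, np.array([1.0, 0, 0]))
        peaks = []
        for lift in (0.0, 1.0, 3.0):
            shifted = type(p)(centers=p.centers + [0, 0, lift],
                              areas=p.areas, electrode=p.electrode)
            tr = record_bipolar(study.result, shifted, study.tissue)
            peaks.append((np.abs(tr.v_distal).max(),
                          np.abs(tr.v_proximal).max()))
        assert peaks[0][0] > peaks[1][0] > peaks[2][0]
        assert peaks[0][1] > peaks[1][1] > peaks[2][1]


class TestBandpass:
    def _trace(self, v):
        t = np.arange(v.size, dtype=float)
        return EgmTrace(times=t, v_distal=v, v_proximal=np.zeros_like(v),
                        v_bipolar=v)

    def test_dc_rejected(self):
        tr = bandpass(self._trace(np.full(2000, 3.7)), 30, 150)
        assert np.abs(tr.v_bipolar).max() < 3.7 * 1e-2

    def test_passband_preserved(self):
        t = np.arange(2000) / 1000.0
        tr = bandpass(self._trace(np.sin(2 * np.pi * 80 * t)), 30, 150)
        mid = tr.v_bipolar[500:1500]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated(self):
        t = np.arange(4000) / 1000.0
        tr = bandpass(self._trace(np.sin(2 * np.pi * 5 * t)), 30, 150)
        mid = tr.v_bipolar[1000:3000]
        assert np.abs(mid).max() < 10 ** (-40 / 20)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass(self._trace(np.zeros(100)), 30, 600)


def test_perpendicular_contact_distal_dominates(baseline_study):
    """At CA = 90 deg the proximal electrode is several mm off the tissue,
    so the bipolar trace is essentially the distal unipolar deflection
    (one positive and one negative peak)."""
    study = baseline_study
    tc = builtin_designs()[0]
    node = study.tissue.nearest_node([20.0, 20.0, 0.0])
    p = place(tc, CatheterPose(study.tissue.nodes[node], co=0.0, ca=90.0),
              study.tissue, np.array([1.0, 0.0, 0.0]))
    tr = record_bipolar(study.result, p, study.tissue)
    assert np.abs(tr.v_distal).max() > 3.0 * np.abs(tr.v_proximal).max()
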