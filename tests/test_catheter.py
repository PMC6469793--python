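"""Catheter designs, electrode subdivision, and rigid placement geometry."""

import numpy as np
import pytest

from biegm.catheter import (CatheterPose, builtin_designs, place,
                            subdivide_electrodes, wavefront_direction,
                            CONTACT_CLEARANCE_MM)
from biegm.errors import ConfigurationError
from biegm.geometry import make_sheet
from biegm.ionic import PacingProtocol
from biegm.tissue import disc_nodes, pace


@pytest.fixture(scope="module")
def designs():
    tc, pent, orion = builtin_designs()
    return {"Thermocool": tc, "Pentaray": pent, "Orion": orion}


@pytest.fixture(scope="module")
def flat_sheet():
    return make_sheet(30, 30, 0.5)


def test_builtin_dimensions(designs):
    assert designs["Thermocool"].distal_length == 3.5
    assert designs["Thermocool"].spacing == 2.0
    assert designs["Pentaray"].distal_length == 1.0
    assert designs["Pentaray"].spacing == 2.0
    assert designs["Orion"].flat_area == 0.4
    assert designs["Orion"].spacing == 2.5
    for d in designs.values():
        assert set(np.unique(subdivide_electrodes(d).electrode)) == {0, 1}


class TestSubdivision:
    def test_cylindrical_area_sums(self, designs):
        for name in ("Thermocool", "Pentaray"):
            d = designs[name]
            p = subdivide_electrodes(d, 0.07)
            # dome-tipped distal electrode: total area pi * diameter * length
            assert p.electrode_area(0) == pytest.approx(
                np.pi * d.shaft_diameter * d.distal_length, rel=0.01)
            assert p.electrode_area(1) == pytest.approx(
                np.pi * d.shaft_diameter * d.proximal_length, rel=0.01)
            assert p.areas.max() <= 0.07 + 1e-9

    def test_flat_area_sum_and_count(self, designs):
        p = subdivide_electrodes(designs["Orion"], 0.07)
        assert p.electrode_area(0) == pytest.approx(0.4, rel=0.01)
        assert (p.electrode == 0).sum() >= 6  # ceil(0.4 / 0.07)

    def test_halving_patch_area_at_least_doubles_count(self, designs):
        for d in designs.values():
            n1 = subdivide_electrodes(d, 0.08).n_patches
            n2 = subdivide_electrodes(d, 0.04).n_patches
            assert n2 >= 2 * n1

    def test_patch_area_ceiling_enforced(self, designs):
        with pytest.raises(ConfigurationError):
            subdivide_electrodes(designs["Orion"], 0.2)


class TestPlacement:
    wave = np.array([1.0, 0.0, 0.0])

    def _centroids(self, patches):
        out = []
        for e in (0, 1):
            sel = patches.electrode == e
            w = patches.areas[sel]
            out.append((w[:, None] * patches.centers[sel]).sum(0) / w.sum())
        return out

    def test_perpendicular_contact_geometry(self, designs, flat_sheet):
        d = designs["Thermocool"]
        pose = CatheterPose(np.array([15.0, 15.0, 0.0]), co=0.0, ca=90.0)
        p = place(d, pose, flat_sheet, self.wave)
        c_dist, c_prox = self._centroids(p)
        # proximal ring centroid height = clearance + tip length + spacing
        # + half its own length; distal centroid well below it
        expected = (CONTACT_CLEARANCE_MM + d.distal_length + d.spacing
                    + d.proximal_length / 2.0)
        assert c_prox[2] == pytest.approx(expected, abs=0.1)
        assert c_prox[2] - c_dist[2] > d.spacing
        assert p.centers[:, 2].min() == pytest.approx(CONTACT_CLEARANCE_MM,
                                                      abs=1e-9)

    def test_parallel_contact_geometry(self, designs, flat_sheet):
        d = designs["Thermocool"]
        pose = CatheterPose(np.array([15.0, 15.0, 0.0]), co=0.0, ca=0.0)
        p = place(d, pose, flat_sheet, self.wave)
        c_dist, c_prox = self._centroids(p)
        assert c_dist[2] == pytest.approx(c_prox[2], abs=1e-6)
        sep = c_prox - c_dist
        sep /= np.linalg.norm(sep)
        assert abs(sep @ self.wave) == pytest.approx(1.0, abs=1e-9)

    def test_orientation_rotation_preserves_heights(self, designs, flat_sheet):
        d = designs["Pentaray"]
        heights = {}
        for co in (0.0, 45.0, 90.0):
            pose = CatheterPose(np.array([15.0, 15.0, 0.0]), co=co, ca=0.0)
            heights[co] = np.sort(
                place(d, pose, flat_sheet, self.wave).centers[:, 2])
        assert np.allclose(heights[0.0], heights[45.0], atol=1e-9)
        assert np.allclose(heights[0.0], heights[90.0], atol=1e-9)

    def test_rigid_body_distances_invariant(self, designs, flat_sheet):
        d = designs["Orion"]
        poses = [CatheterPose(np.array([15.0, 15.0, 0.0]), co=c, ca=a)
                 for c, a in ((0, 0), (30, 20), (90, 90), (45, 60))]
        ref = None
        for pose in poses:
            pts = place(d, pose, flat_sheet, self.wave).centers
            dist = np.linalg.norm(pts[1:] - pts[0], axis=1)
            if ref is None:
                ref = dist
            else:
                assert np.abs(dist - ref).max() < 1e-9

    def test_angles_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            CatheterPose(np.zeros(3), co=120.0, ca=0.0)


def test_orientation_recovered_from_radial_wave():
    """With a radially spreading wave, placing at CO = theta against the
    local activation gradient reproduces that angle within 2 degrees."""
    sheet = make_sheet(24, 24, 0.5, d_base=0.2)
    res = pace(sheet, PacingProtocol(n_beats=4),
               disc_nodes(sheet, (12.0, 12.0), 1.0), record_duration=120.0)
    node = sheet.nearest_node([18.0, 16.0, 0.0])  # off-axis sample point
    grad = wavefront_direction(sheet, res.activation_times, node)
    radial = sheet.nodes[node] - np.array([12.0, 12.0, 0.0])
    radial /= np.linalg.norm(radial)
    # gradient tracks the radial direction up to the lattice anisotropy of
    # the 5-point stencil (a few degrees off the grid axes)
    assert np.degrees(np.arccos(np.clip(grad @ radial, -1, 1))) < 8.0

    tc = builtin_designs()[0]
    for theta in (0.0, 30.0, 60.0):
        pose = CatheterPose(sheet.nodes[node], co=theta, ca=0.0)
        p = place(tc, pose, sheet, grad)
        sel = p.electrode == 1
        axis = p.centers[sel].mean(0) - p.centers[~sel].mean(0)
        axis[2] = 0.0
        axis /= np.linalg.norm(axis)
        measured = np.degrees(np.arccos(np.clip(abs(axis @ grad), -1, 1)))
        assert measured == pytest.approx(theta, abs=2.0)


def test_placement_on_curved_surface():
    """On a cylindrical patch the catheter sits at clearance above the
    local tangent plane and keeps its rigid geometry."""
    sheet = make_sheet(30, 20, 0.5, curvature=25.0)
    node = sheet.nearest_node([15.0, 10.0, 0.0])
    normal = sheet.node_normals()[node]
    tc = builtin_designs()[0]
    wave = np.array([1.0, 0.0, 0.0])
    flat = place(tc, CatheterPose(sheet.nodes[node], co=0.0, ca=30.0),
                 make_sheet(30, 20, 0.5), wave)
    curved = place(tc, CatheterPose(sheet.nodes[node], co=0.0, ca=30.0),
                   sheet, wave)
    heights = (curved.centers - sheet.nodes[node]) @ normal
    assert heights.min() == pytest.approx(CONTACT_CLEARANCE_MM, abs=1e-9)
    d_flat = np.linalg.norm(flat.centers[1:] - flat.centers[0], axis=1)
    d_curv = np.linalg.norm(curved.centers[1:] - curved.centers[0], axis=1)
    assert np.abs(d_flat - d_curv).max() < 1e-9
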