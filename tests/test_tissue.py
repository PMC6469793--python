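"""Monodomain solver tests: conservation, stability, CV physics, scars."""

import numpy as np
import pytest

from biegm.errors import ConfigurationError, StabilityError
from biegm.geometry import ScarSpec, apply_scar, make_sheet
from biegm.ionic import PacingProtocol, resting_state
from biegm.mesh import diffusion_source
from biegm.tissue import (calibrate_cv, disc_nodes, edge_band_nodes,
                          measure_planar_cv, pace)

from conftest import SCAR_CENTER


def test_diffusion_conserves_area_weighted_flux(rng):
    sheet = make_sheet(10, 8, 0.5)
    field = rng.normal(size=sheet.n_nodes)
    src = diffusion_source(sheet, field)
    total = float(np.sum(src * sheet.node_area))
    assert abs(total) < 1e-9 * np.abs(src).max()


def test_uniform_field_has_zero_diffusion():
    sheet = make_sheet(10, 8, 0.5)
    src = diffusion_source(sheet, np.full(sheet.n_nodes, -55.3))
    assert np.abs(src).max() < 1e-12


def test_curved_sheet_diffusion_also_conserves(rng):
    sheet = make_sheet(20, 10, 0.5, curvature=15.0)
    field = rng.normal(size=sheet.n_nodes)
    src = diffusion_source(sheet, field)
    assert abs(float(np.sum(src * sheet.node_area))) < 1e-9 * np.abs(src).max()


def test_stability_bound_enforced():
    sheet = make_sheet(10, 5, 0.5)
    sheet.d_base = 50.0  # absurd diffusivity -> admissible dt below 0.02
    with pytest.raises(StabilityError) as err:
        pace(sheet, PacingProtocol(n_beats=0), edge_band_nodes(sheet))
    assert err.value.dt_admissible < 0.02


def test_resting_tissue_is_stable_for_one_second():
    sheet = make_sheet(10, 10, 0.5, d_base=0.2)
    proto = PacingProtocol(pcl=1000.0, stim_amplitude=-1e-12, n_beats=0)
    res = pace(sheet, proto, edge_band_nodes(sheet),
               record_duration=1000.0)
    v0 = resting_state()[0]
    assert np.abs(res.vm_field - v0).max() < 0.5
    assert not res.meta["capture"]


def test_pacing_site_in_scar_rejected(baseline_study):
    sheet = apply_scar(make_sheet(30, 30, 0.5), ScarSpec((15.0, 15.0), 9.0))
    inside = disc_nodes(sheet, (15.0, 15.0), 1.0)
    with pytest.raises(ConfigurationError):
        pace(sheet, PacingProtocol(), inside)


def test_activation_time_increases_with_distance(baseline_study):
    act = baseline_study.result.activation_times
    tissue = baseline_study.tissue
    x = tissue.nodes[:, 0]
    mid = np.abs(tissue.nodes[:, 1] - 20.0) < 0.1
    order = np.argsort(x[mid])
    times = act[mid][order]
    assert np.all(np.diff(times) >= 0)


def test_activation_delay_matches_cv(baseline_study, cv_calibration_05):
    _, cv = cv_calibration_05
    tissue = baseline_study.tissue
    act = baseline_study.result.activation_times
    a = tissue.nearest_node([12.0, 20.0, 0.0])
    b = tissue.nearest_node([28.0, 20.0, 0.0])
    measured = 16.0 / (act[b] - act[a])
    assert measured == pytest.approx(cv, rel=0.05)


def test_point_stimulus_activation_is_symmetric():
    sheet = make_sheet(20, 20, 0.5, d_base=0.2)
    centre = disc_nodes(sheet, (10.0, 10.0), 1.0)
    res = pace(sheet, PacingProtocol(n_beats=4), centre,
               record_duration=120.0)
    ny, nx = sheet.grid_shape
    act = res.activation_times.reshape(ny, nx)
    assert np.nanmax(np.abs(act - act[::-1, :])) <= 1.0
    assert np.nanmax(np.abs(act - act[:, ::-1])) <= 1.0
    assert np.nanmax(np.abs(act - act.T)) <= 1.0


class TestConductionVelocity:
    def test_baseline_cv_hits_target(self, cv_calibration_05):
        _, cv = cv_calibration_05
        assert cv == pytest.approx(0.48, abs=0.01)

    def test_cv_scales_as_sqrt_of_diffusivity(self, cv_calibration_025):
        # measured on a finely resolved strip, where lattice slowing of the
        # narrow upstroke no longer distorts the continuum scaling law
        d, _ = cv_calibration_025
        base = measure_planar_cv(make_sheet(40, 0.75, 0.125, d_base=d),
                                 dt=0.005, expected_cv=0.4)
        quad = measure_planar_cv(make_sheet(40, 0.75, 0.125, d_base=4 * d),
                                 dt=0.005, expected_cv=0.9)
        assert quad / base == pytest.approx(2.0, abs=0.1)

    def test_calibrated_cv_is_spacing_independent(self, cv_calibration_05,
                                                  cv_calibration_025):
        # the calibration absorbs lattice effects: the realized wave speed
        # is the same after halving the node spacing
        _, cv_coarse = cv_calibration_05
        _, cv_fine = cv_calibration_025
        assert abs(cv_fine - cv_coarse) / cv_coarse < 0.03

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_cv(2.0)


class TestScar:
    def test_scar_nodes_never_activate(self, scar_studies):
        study = scar_studies[9.0]
        act = study.result.activation_times
        assert np.all(np.isnan(act[study.tissue.scar_mask]))

    def test_scar_nodes_hold_resting_potential(self, scar_studies):
        # uncoupled scar nodes never depolarize; they may relax by a couple
        # of mV from the rate-adapted initial state toward quiescent rest
        study = scar_studies[9.0]
        vm_scar = study.result.vm_field[:, study.tissue.scar_mask]
        assert np.abs(vm_scar - vm_scar[0]).max() < 2.0
        assert vm_scar.max() < -70.0

    def test_wave_detours_around_scar(self, baseline_study, scar_studies):
        # activation behind the scar is later than in the scar-free sheet
        study = scar_studies[9.0]
        node = study.tissue.nearest_node([SCAR_CENTER[0] + 5.5,
                                          SCAR_CENTER[1], 0.0])
        t_scar = study.result.activation_times[node]
        t_free = baseline_study.result.activation_times[node]
        assert t_scar > t_free


def test_wave_propagates_on_curved_sheet():
    """A paced wave crosses a cylindrically curved patch; activation time
    grows with arc distance from the pacing edge."""
    sheet = make_sheet(20, 15, 0.5, curvature=15.0, d_base=0.2)
    res = pace(sheet, PacingProtocol(n_beats=2), edge_band_nodes(sheet),
               record_duration=120.0)
    act = res.activation_times
    assert np.isfinite(act).all()
    from biegm.geometry import sheet_coordinates
    uv = sheet_coordinates(sheet)
    mid = np.abs(uv[:, 1] - 7.5) < 0.1
    order = np.argsort(uv[mid, 0])
    assert np.all(np.diff(act[mid][order]) >= 0)


def test_af_induction_fails_with_long_apd_on_small_sheet():
    """With the unscaled (long-APD) membrane the re-entrant wavelength far
    exceeds a small sheet, so cross-field stimulation cannot start AF."""
    from biegm.errors import InductionError
    from biegm.ionic import IonicParams
    from biegm.tissue import AfConfig, induce_af

    sheet = make_sheet(20, 20, 0.5, d_base=0.2)
    cfg = AfConfig(record_duration=1500.0, s2_offsets_ms=(0.0, 20.0))
    with pytest.raises(InductionError):
        induce_af(sheet, IonicParams(), config=cfg)
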