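"""Shared fixtures: calibrations and tissue studies are expensive, so each is
computed once per session and reused by unit, property, and acceptance tests.
"""

import numpy as np
import pytest

from biegm.experiments import SheetStudy, af_study
from biegm.geometry import ScarSpec
from biegm.ionic import IonicParams, PacingProtocol, calibrate_apd
from biegm.tissue import calibrate_cv

SEED = 20260920
SCAR_CENTER = (20.0, 20.0)

# study conditions: cycle length 600 ms, baseline CV 0.48 m/s and slow CV
# 0.13 m/s, APD90 settings 223 (baseline) / 180 ms; sheets are 40 x 40 mm at
# 0.5 mm spacing (0.25 mm for the slow-CV condition, which needs the finer
# grid to resolve its narrow upstroke)
PCL = 600.0
CV_BASE = 0.48
CV_SLOW = 0.13
APD_BASE = 223.0
APD_SHORT = 180.0
AF_CV = 0.30
AF_APD = 120.0


@pytest.fixture(scope="session")
def apd_scales_223():
    return calibrate_apd(APD_BASE, PacingProtocol(pcl=PCL, n_beats=20))


@pytest.fixture(scope="session")
def apd_scales_180():
    return calibrate_apd(APD_SHORT, PacingProtocol(pcl=PCL, n_beats=20))


@pytest.fixture(scope="session")
def baseline_params(apd_scales_223):
    return IonicParams(scale_kr=apd_scales_223[0], scale_ks=apd_scales_223[1])


@pytest.fixture(scope="session")
def cv_calibration_05(baseline_params):
    """(d_base, measured cv) for 0.48 m/s at 0.5 mm spacing."""
    return calibrate_cv(CV_BASE, spacing=0.5, params=baseline_params,
                        full_output=True)


@pytest.fixture(scope="session")
def cv_calibration_025(baseline_params):
    return calibrate_cv(CV_BASE, spacing=0.25, params=baseline_params,
                        full_output=True)


@pytest.fixture(scope="session")
def cv_slow_calibration_025(baseline_params):
    return calibrate_cv(CV_SLOW, spacing=0.25, params=baseline_params,
                        full_output=True)


@pytest.fixture(scope="session")
def baseline_study(cv_calibration_05, apd_scales_223):
    """Homogeneous 40x40 sheet, planar wave at baseline CV and APD."""
    d, _ = cv_calibration_05
    return SheetStudy.paced_sheet(cv=CV_BASE, d_base=d,
                                  apd_scales=apd_scales_223, pcl=PCL)


@pytest.fixture(scope="session")
def slow_cv_study(cv_slow_calibration_025, apd_scales_223):
    d, _ = cv_slow_calibration_025
    return SheetStudy.paced_sheet(cv=CV_SLOW, d_base=d, spacing=0.25,
                                  apd_scales=apd_scales_223, pcl=PCL)


@pytest.fixture(scope="session")
def short_apd_study(cv_calibration_05, apd_scales_180):
    d, _ = cv_calibration_05
    return SheetStudy.paced_sheet(cv=CV_BASE, d_base=d,
                                  apd_scales=apd_scales_180, pcl=PCL)


@pytest.fixture(scope="session")
def scar_studies(baseline_study, cv_calibration_05, apd_scales_223):
    """Scar-diameter series 0/5/7/9 mm on the same sheet/calibration."""
    d, _ = cv_calibration_05
    out = {0.0: baseline_study}
    for diameter in (5.0, 7.0, 9.0):
        out[diameter] = SheetStudy.paced_sheet(
            cv=CV_BASE, d_base=d, apd_scales=apd_scales_223, pcl=PCL,
            scar=ScarSpec(SCAR_CENTER, diameter))
    return out


@pytest.fixture(scope="session")
def af_recording():
    """Self-sustained fibrillation recording on a remodelled 40x40 sheet."""
    return af_study(cv=AF_CV, apd90=AF_APD)


@pytest.fixture(scope="session")
def replicate_sites(baseline_study):
    from biegm.experiments import sample_sites

    return sample_sites(baseline_study.tissue, 10, seed=SEED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
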