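import numpy as np
import pytest

import myoperf as mp


@pytest.fixture(scope="session")
def ref_geom():
    """Reference annulus: 23 mm cavity radius, 8 mm wall."""
    return mp.make_geometry(0.023, 0.008)


@pytest.fixture(scope="session")
def tissue():
    return mp.TissueParams()


@pytest.fixture(scope="session")
def drive_rest():
    """Rest drive of the rest/stress MDCT calibration."""
    return mp.DriveParams(q0=2.5e-9, delta=3.0, T=60 / 58)


@pytest.fixture(scope="session")
def healthy_coeffs(ref_geom, tissue, drive_rest):
    return mp.healthy_coefficients(ref_geom, tissue, drive_rest, M=50)


@pytest.fixture(scope="session")
def healthy_field(ref_geom, tissue, drive_rest):
    return mp.HealthyField(ref_geom, tissue, drive_rest, M=50, mode="exact")


@pytest.fixture(scope="session")
def cx_spec():
    """72-degree circumflex-territory sector at 55% residual inflow."""
    return mp.StenosisSpec(theta_s=np.radians(72), xi=0.55, t0=0.0)


@pytest.fixture(scope="session")
def cx_coeffs(ref_geom, tissue, drive_rest, cx_spec):
    return mp.stenotic_coefficients(ref_geom, tissue, drive_rest, drive_rest,
                                    cx_spec, N=40, M=50)


@pytest.fixture(scope="session")
def linde_cal():
    return mp.calibrate(mp.LINDE)


@pytest.fixture(scope="session")
def george_cal():
    return mp.calibrate(mp.GEORGE)
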