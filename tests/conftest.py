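import numpy as np
import pytest

import renal_mps_pbpk as r
from renal_mps_pbpk import parameters as P


@pytest.fixture(scope="session")
def geometry():
    return r.DeviceGeometry()


@pytest.fixture(scope="session")
def kidney():
    """Frozen (calibrated) default kidney physiology."""
    return r.default_kidney_physiology()


@pytest.fixture(scope="session")
def body():
    return r.default_body_physiology()


@pytest.fixture(scope="session")
def morphine_renal():
    return r.drug_from_sheet(P.MORPHINE)


@pytest.fixture(scope="session")
def m6g_renal():
    return r.drug_from_sheet(P.M6G)


@pytest.fixture(scope="session")
def morphine_model(body):
    return r.build_drug_model(P.MORPHINE, body=body)


@pytest.fixture(scope="session")
def m6g_model(body):
    return r.build_drug_model(P.M6G, body=body)


@pytest.fixture
def noise_free_truth():
    """A donor whose clearances are exactly recoverable (no noise)."""
    return r.MpsGroundTruth(
        cl_app_transport=3.0, cl_app_passive=1.0, vascular_conc_in=1000.0,
        flow_tubular=60.0, flow_vascular=60.0, noise_cv=0.0, seed=7,
    )


def make_profile(times, conc, analyte="x", site="arm_vein", **meta):
    return r.PKProfile(analyte=analyte, site=site, times=np.asarray(times),
                       conc=np.asarray(conc), metadata=meta)
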