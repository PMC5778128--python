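import pytest

from permaom import CoreProfile, HorizonRecord, generate_core
from permaom.synthetic import bk2_like, c2_like


def make_profile(rows, core_id="test"):
    """rows: iterable of dicts of HorizonRecord kwargs."""
    return CoreProfile.from_records(core_id, [HorizonRecord(**r) for r in rows])


@pytest.fixture
def simple_profile():
    """Three-horizon profile with an oxidized layer above a source layer."""
    return make_profile(
        [
            {"depth_mbsf": 50.0, "d13c_ch4": -37.0 + 1e-9, "ch4": 10.0},
            {"depth_mbsf": 51.0, "d13c_ch4": -45.0, "ch4": 100.0},
            {"depth_mbsf": 52.0, "d13c_ch4": -72.0, "ch4": 990.0},
        ]
    )


@pytest.fixture(scope="session")
def c2_noiseless():
    params = c2_like(seed=7, noise_sd_delta=0.0, noise_sd_conc=0.0)
    profile, truth = generate_core(params)
    return params, profile, truth


@pytest.fixture(scope="session")
def bk2_noiseless():
    params = bk2_like(seed=7, noise_sd_delta=0.0, noise_sd_conc=0.0)
    profile, truth = generate_core(params)
    return params, profile, truth
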