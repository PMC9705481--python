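import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dwiharm.core import SiteProfile, TissueMap, TissueSpec
from dwiharm.synthdata import generate_site_manifest, generate_study

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def manifest7():
    return generate_site_manifest(7, seed=1)


@pytest.fixture(scope="session")
def phantom_study(manifest7):
    return generate_study(manifest7, "phantom", seed=11)


@pytest.fixture(scope="session")
def traveling_study(manifest7):
    return generate_study(manifest7, "traveling_volunteer", seed=7)


@pytest.fixture(scope="session")
def test_retest_study(manifest7):
    return generate_study(manifest7, "test_retest", seed=13)


@pytest.fixture()
def clean_site():
    """A site with no gain/noise/bias distortions."""
    return SiteProfile("clean")


def uniform_tissue_map(adc=1600.0, s0=1000.0, f=0.0, d_star=0.0,
                       shape=(8, 8, 4), spacing=(2.0, 2.0, 5.0)):
    spec = TissueSpec("phantom", adc_true=adc, s0=s0, perfusion_fraction=f,
                      pseudo_diffusion=d_star)
    labels = np.ones(shape, dtype=np.int16)
    return TissueMap.from_labels(labels, {1: spec}, spacing, seed=0)


@pytest.fixture()
def uniform_map():
    return uniform_tissue_map()
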