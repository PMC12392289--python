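import numpy as np
import pytest

from visrsim import (AcousticsSpec, PhantomSpec, TrackingSequenceSpec,
                     double_push_schedule, make_phantom, tracking_times)

# desk-scale grid shared by image-level tests: 40 mm depth on 256 rows
GRID = (256, 40)
DZ = 0.15625
DX = 0.5
SPACINGS = (DZ, DX)


@pytest.fixture(scope="session")
def seq():
    return TrackingSequenceSpec()


@pytest.fixture(scope="session")
def schedule(seq):
    return double_push_schedule(seq)


@pytest.fixture(scope="session")
def sample_times(seq):
    return tracking_times(seq)[1]


@pytest.fixture(scope="session")
def ac_clean():
    """No attenuation, no RF noise: isolates the estimation chain."""
    return AcousticsSpec(attenuation_db_cm_mhz=0.0)


def small_spec(**kw):
    """A lesion phantom on the desk-scale grid."""
    defaults = dict(grid_shape=GRID, axial_spacing=DZ, lateral_spacing=DX,
                    lesion_axes=(6.0, 4.0), lesion_E=7.5, lesion_mu=1.5,
                    heterogeneity_cv=0.0, seed=0)
    defaults.update(kw)
    return PhantomSpec(**defaults)


def tiny_rf_spec(**kw):
    """A short homogeneous phantom cheap enough for RF synthesis."""
    defaults = dict(grid_shape=(128, 3), axial_spacing=0.1,
                    lateral_spacing=0.5, lesion_center=(0.5, 6.4),
                    lesion_axes=(0.4, 0.3), lesion_E=3.0, lesion_mu=0.6,
                    background_E=3.0, background_mu=0.6,
                    heterogeneity_cv=0.0, scatterers_per_mm=60.0, seed=2)
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def tiny_rf_phantom():
    return make_phantom(tiny_rf_spec())
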