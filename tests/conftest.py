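import numpy as np
import pytest

from laminarq import AcquisitionParams, EffectConfig, build_t1_lookup
from laminarq.phantom import generate_cohort, make_cortical_phantom


@pytest.fixture(scope="session")
def params():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def lut(params):
    return build_t1_lookup(params)


@pytest.fixture(scope="session")
def hc_phantom():
    """Noise-free healthy-control slab phantom (default geometry)."""
    eff = EffectConfig(noise_sd=0.0)
    spec = generate_cohort(1, 1, eff, master_seed=42)[1]  # the HC subject
    spec = type(spec)(**{**spec.__dict__, "t1_profile_shift": 0.0})
    return make_cortical_phantom(spec=spec, effects=eff)


@pytest.fixture(scope="session")
def small_undulated_phantom():
    """32^3 undulated slab for brute-force geometry oracles."""
    return make_cortical_phantom(
        grid_shape=(32, 32, 32),
        ribbon_thickness_mm=8.4,
        undulation_amp_mm=1.4,
        undulation_period_mm=11.2,
    )


def planar_labels(shape=(16, 16, 21), wm_top=8, gm_top=13):
    """Hand-built planar slab: WM below, GM band, CSF above along axis 2."""
    from laminarq.phantom import CSF, GM, WM

    labels = np.full(shape, CSF, dtype=np.int8)
    labels[:, :, :wm_top] = WM
    labels[:, :, wm_top:gm_top] = GM
    return labels
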