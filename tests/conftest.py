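import numpy as np
import pytest
from hypothesis import settings

from sepmap.forward import SolverConfig, assemble_spfd
from sepmap.leadfield import build_leadfield_direct, build_leadfield_reciprocity
from sepmap.phantom import PhantomSpec, build_layered_sphere, place_electrodes
from sepmap.pipeline import build_study

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_layer_vol():
    """16^3 two-layer sphere at 2 mm: the small forward/lead-field testbed."""
    spec = PhantomSpec(
        layer_radii=(10.0, 13.0),
        layer_conductivities=(0.33, 0.1),
        grid_shape=(16, 16, 16),
        spacing_mm=2.0,
        gm_shell_frac=(0.2, 0.85),
    )
    return build_layered_sphere(spec)


@pytest.fixture(scope="session")
def two_layer_system(two_layer_vol):
    return assemble_spfd(two_layer_vol)


@pytest.fixture(scope="session")
def electrodes8(two_layer_vol):
    return place_electrodes(two_layer_vol, "fibonacci", n_electrodes=8)


@pytest.fixture(scope="session")
def mask_voxels20(two_layer_vol):
    vox = np.argwhere(two_layer_vol.gray_matter_mask)
    rng = np.random.default_rng(7)
    return vox[rng.choice(len(vox), size=20, replace=False)]


@pytest.fixture(scope="session")
def tight_config():
    return SolverConfig(tolerance=1e-8)


@pytest.fixture(scope="session")
def L_recip(two_layer_vol, electrodes8, mask_voxels20, tight_config, two_layer_system):
    return build_leadfield_reciprocity(
        two_layer_vol, electrodes8, mask_voxels20, tight_config, system=two_layer_system
    )


@pytest.fixture(scope="session")
def L_direct(two_layer_vol, electrodes8, mask_voxels20, tight_config, two_layer_system):
    return build_leadfield_direct(
        two_layer_vol, electrodes8, mask_voxels20, tight_config, system=two_layer_system
    )


@pytest.fixture(scope="session")
def study():
    """Desk-scale 3-layer study model with its reciprocity lead field."""
    return build_study()


@pytest.fixture(scope="session")
def sloreta_testbed():
    """Small two-layer phantom (<500 mask voxels) with a 1e-8 lead field."""
    spec = PhantomSpec(
        layer_radii=(10.0, 12.0),
        layer_conductivities=(0.33, 0.1),
        grid_shape=(14, 14, 14),
        spacing_mm=2.0,
        gm_shell_frac=(0.0, 0.9),
    )
    vol = build_layered_sphere(spec)
    el = place_electrodes(vol, "fibonacci", n_electrodes=16)
    L = build_leadfield_reciprocity(vol, el, config=SolverConfig(tolerance=1e-8))
    return vol, el, L
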