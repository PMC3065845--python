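import numpy as np
import pytest

import lamina3d as l3


@pytest.fixture(scope="session")
def optics():
    return l3.OpticsConfig()


@pytest.fixture(scope="session")
def sphere_spec():
    """Spherical-shell phantom, radius 20 voxels at 60 nm isotropic spacing."""
    return l3.PhantomSpec(
        semi_axes=(1200.0, 1200.0, 1200.0),
        shell_thickness=60.0,
        spacing=(60.0, 60.0, 60.0),
        base_photons=1000.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def sphere_truth(sphere_spec):
    return l3.render_shell(sphere_spec)


@pytest.fixture(scope="session")
def standard_phantom():
    """The ellipsoidal "standard phantom": anisotropic sampling, one hotspot,
    one invagination, Poisson noise — used by segmentation stability tests."""
    spec = l3.PhantomSpec(
        seed=5,
        hotspots=(l3.Hotspot((0.2, 0.6, 0.77), 1.6, 0.4),),
        invaginations=(l3.Invagination((0.0, 1.0, 0.0), 500.0, 500.0),),
    )
    stack = l3.image_phantom(l3.render_shell(spec), spec)
    return spec, stack


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
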