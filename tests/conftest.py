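import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nemaiq.geometry import ActivityConfig, CylinderBody, PhantomDefinition, SphereSpec
from nemaiq.simulate import GridSpec, ReconPreset, apply_recon_signature, rasterize_truth
from nemaiq.study import build_phantom

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def nema8():
    """Full six-sphere phantom filled at the 8:1 contrast level."""
    return build_phantom("8:1")


@pytest.fixture(scope="session")
def default_grid():
    from nemaiq.simulate import DEFAULT_GRID

    return DEFAULT_GRID


@pytest.fixture(scope="session")
def truth8(nema8, default_grid):
    return rasterize_truth(nema8, default_grid, supersample=4)


@pytest.fixture(scope="session")
def blurred8(truth8):
    """Noiseless volumes at the resolution levels exercised throughout."""
    return {
        blur: apply_recon_signature(truth8, ReconPreset(name=f"blur{blur}", blur_fwhm=blur))
        for blur in (3.7, 4.2, 5.2, 8.2)
    }


def make_single_sphere_phantom(
    inner_radius=8.5,
    wall=1.06,
    sphere_ac=24.4,
    background_ac=3.1,
    center=(0.0, 0.0, 0.0),
    body_radius=40.0,
    body_length=120.0,
    voi_center=(0.0, 0.0, 35.0),
):
    return PhantomDefinition(
        spheres=[SphereSpec(label="17", inner_radius=inner_radius, wall_thickness=wall,
                            center=center)],
        body=CylinderBody(radius=body_radius, length=body_length),
        activity=ActivityConfig(sphere_ac=sphere_ac, background_ac=background_ac),
        background_voi_center=voi_center,
    )


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec.centered((48, 48, 48), (2.73, 2.73, 2.78))


@pytest.fixture(scope="session")
def sphere17_phantom():
    return make_single_sphere_phantom()


@pytest.fixture(scope="session")
def sphere17_truth(sphere17_phantom, small_grid):
    return rasterize_truth(sphere17_phantom, small_grid, supersample=4)


@pytest.fixture(scope="session")
def sphere17_blurred(sphere17_truth):
    return apply_recon_signature(sphere17_truth, ReconPreset(name="b42", blur_fwhm=4.2))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
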