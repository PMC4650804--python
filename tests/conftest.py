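import numpy as np
import pytest

from vesselseg import PhantomSpec, make_vessel_phantom


@pytest.fixture(scope="session")
def small_spec():
    """A compact noisy phantom exercising every tissue feature."""
    return PhantomSpec(image_shape=(8, 192, 192), lumen_radius_vox=28.0,
                       n_lamellae=4, adventitia_thickness_vox=18.0,
                       pore_count=4, pore_radius_range_vox=(3.0, 4.0), seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_vessel_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_circular_phantom():
    """Noiseless circular phantom at the default wall geometry."""
    spec = PhantomSpec(image_shape=(6, 256, 256), ripple_amplitude_vox=0.0,
                       waviness_amplitude_vox=0.0, pore_count=0, noise_sd=0.0,
                       seed=2)
    return spec, make_vessel_phantom(spec)


def make_annulus(shape=(128, 128), r_inner=40.0, r_outer=55.0, inner_level=10.0,
                 wall_level=200.0, outer_level=10.0, wobble=None):
    """Synthetic annulus slice: dark interior, bright wall, dark outside."""
    yy, xx = np.indices(shape, dtype=float)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    th = np.arctan2(yy - cy, xx - cx)
    ri = r_inner + (wobble(th) if wobble else 0.0)
    img = np.full(shape, outer_level, dtype=float)
    img[r < r_outer] = wall_level
    img[r < ri] = inner_level
    return img, (cx, cy)
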