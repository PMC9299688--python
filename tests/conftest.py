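"""Shared fixtures: random parameter sets, profile factories, phantoms."""

import numpy as np
import pytest

from bonemap.model import CorticalModelParams, eval_blurred
from bonemap.profiles import DensityProfile


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_valid_params(rng, *, sigma_range=(0.3, 1.5)):
    """One random parameter set satisfying the model invariants."""
    x0 = rng.uniform(-1.0, 1.0)
    w1 = rng.uniform(0.05, 2.0)
    w2 = rng.uniform(0.0, 1.5)
    return CorticalModelParams(
        x0=x0, x1=x0 + w1, x2=x0 + w1 + w2,
        y_bg=rng.uniform(0.0, 100.0),
        y_c=rng.uniform(600.0, 1200.0),
        y_t=rng.uniform(0.0, 400.0),
        sigma=rng.uniform(*sigma_range),
    )


def make_profile(params, *, spacing=0.2, depth_out=4.0, depth_in=8.0,
                 noise_sd=0.0, rng=None, vertex_id=-1):
    pos = np.arange(-depth_out, depth_in + 0.5 * spacing, spacing)
    vals = eval_blurred(params, pos)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, pos.shape)
    return DensityProfile(pos, vals, spacing, vertex_id=vertex_id)


@pytest.fixture()
def profile_factory():
    return make_profile


@pytest.fixture(scope="session")
def small_phantom():
    """One small uniform-truth 3-D shell phantom (shared; ~5 s to build)."""
    from bonemap.synthetic import PhantomSpec, gen_shell_phantom

    spec = PhantomSpec(semi_axes=(12.0, 10.0, 8.0), ct_th=0.9, ec_th=0.1,
                       y_c=790.0, y_t=113.0, sigma_inplane=0.8,
                       sigma_slice=1.0, noise_sd=25.0, voxel=(0.6, 0.6, 1.0),
                       fine_step=0.2, subdivisions=2, seed=7)
    volume, mesh, truth = gen_shell_phantom(spec)
    return spec, volume, mesh, truth
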