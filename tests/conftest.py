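import dataclasses

import numpy as np
import pytest

from aaaquant import phantom, segmentation


@pytest.fixture(scope="session")
def small_spec() -> phantom.PhantomSpec:
    """A reduced phantom for fast unit tests (same physics, smaller grid)."""
    return phantom.PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size_mm=0.5,
        neck_radius_mm=9.0,
        max_sac_radius_mm=13.0,
        wall_thickness_mm=4.0,
        mesh_thickness_mm=1.5,
        bulge_center_z_mm=10.0,
        bulge_sigma_mm=4.0,
        landmark_z_mm={"HRA": 28.0, "LRA": 25.0, "MIRA": 19.0, "MAS": 10.0},
        rng_seed=7,
    ).validate()


@pytest.fixture(scope="session")
def small_geometry(small_spec):
    labels, mesh = phantom.generate_geometry(small_spec, n_theta=32, n_z=48)
    return labels, mesh


@pytest.fixture(scope="session")
def small_segmentation(small_spec, small_geometry):
    labels, _ = small_geometry
    return segmentation.segment(labels, small_spec.landmark_z_mm,
                                slab_halfwidth_mm=1.5, erosion_radius_mm=1.5)


@pytest.fixture(scope="session")
def clean_spec(small_spec) -> phantom.PhantomSpec:
    """Noiseless, unblurred variant: downstream statistics become exact."""
    return dataclasses.replace(small_spec, psf_sigma_mm=0.0, noise_sd=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
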