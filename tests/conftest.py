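"""Shared fixtures: desk-scale phantom runs reused across test modules.

Full pipeline runs are the expensive part of the suite, so every result that
more than one test needs is computed once per session.  Phantoms are sampled
at 5 mm pitch with a reduced 3x3 ICP restart grid; the boundary-image pixel
matches the sampling pitch so silhouette columns have no sampling gaps.
"""

from __future__ import annotations

import numpy as np
import pytest

from backsym import ICPConfig, RunConfig, TorsoSpec, generate_scan, run_pipeline
from backsym.geometry import PointCloud, estimate_normals_and_curvature

PHANTOM_PITCH = 5.0


def desk_config(**overrides) -> RunConfig:
    """Pipeline configuration for desk-scale phantom experiments."""
    defaults = dict(
        icp=ICPConfig(perturbation_range=2.5, perturbation_interval=2.5),
        compute_colormap=False,
        image_dx=PHANTOM_PITCH,
        image_dy=PHANTOM_PITCH,
    )
    defaults.update(overrides)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def fast_config() -> RunConfig:
    return desk_config()


@pytest.fixture(scope="session")
def symmetric_spec() -> TorsoSpec:
    return TorsoSpec(pitch=PHANTOM_PITCH, hump_amplitude=0.0, noise_sigma=0.0)


@pytest.fixture(scope="session")
def symmetric_result(symmetric_spec, fast_config):
    return run_pipeline(generate_scan(symmetric_spec), fast_config)


@pytest.fixture(scope="session")
def hump_results(symmetric_result, fast_config):
    """Asymmetry results for hump amplitudes 0, 3, 6, 9 mm (noiseless)."""
    out = {0.0: symmetric_result}
    for a in (3.0, 6.0, 9.0):
        scan = generate_scan(TorsoSpec(pitch=PHANTOM_PITCH, hump_amplitude=a))
        out[a] = run_pipeline(scan, fast_config)
    return out


@pytest.fixture(scope="session")
def wavy_surface() -> PointCloud:
    """A smooth doubly-curved surface patch that pins all six rigid DOF."""
    gx, gy = np.meshgrid(np.arange(-100, 101, 4.0), np.arange(-100, 101, 4.0), indexing="ij")
    z = 30.0 * np.sin(gx / 40.0) * np.cos(gy / 50.0)
    cloud = PointCloud(np.column_stack([gx.ravel(), gy.ravel(), z.ravel()]))
    return estimate_normals_and_curvature(cloud, radius=12.0)
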