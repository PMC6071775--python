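"""Shared fixtures: small phantom scenes generated at test time."""

import numpy as np
import pytest

from nemorph.core import LabelVolume
from nemorph.synthetic import SceneSpec, make_pore_volume, make_telophase_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact telophase scene: 2 gaps, 25 vesicles, 4.5 nm voxels."""
    spec = SceneSpec(
        volume_shape=(60, 90, 220),
        voxel_size=(10.0, 4.5, 4.5),
        vesicle_count=25,
        vesicle_distance_range=(60.0, 160.0),
        gap_specs=[(100.0, 140.0, (300.0, 450.0)), (60.0, 300.0, (150.0, 120.0))],
        seed=3,
    )
    return spec, *make_telophase_scene(spec)


@pytest.fixture(scope="session")
def pore_phantom_26():
    """Single-pore phantom at the 3 nm working grid, moderate tilt."""
    spec = SceneSpec(
        volume_shape=(81, 81, 81),
        voxel_size=(3.0, 3.0, 3.0),
        pore_specs=[(26.0, 80.0, 30.0, 0.0)],
        noise_sd=0.05,
        seed=5,
    )
    return spec, *make_pore_volume(spec)


def digital_sphere_labels(diameters, centers, shape, voxel, label=2):
    """Rasterize filled spheres as a LabelVolume (centers/diameters in nm)."""
    labels = np.zeros(shape, dtype=np.int32)
    coords = [np.arange(n) * v for n, v in zip(shape, voxel)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    for d, (cz, cy, cx) in zip(diameters, centers):
        r2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        labels[r2 <= (d / 2.0) ** 2] = label
    return LabelVolume(labels, voxel, {label: "vesicle"})
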