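import numpy as np
import pytest

from nucmorph import FieldSpec, VoxelGrid, make_nucleus_field


@pytest.fixture
def sphere_field():
    """One sphere, r = 5 um, 0.2 um isotropic voxels: the analytic benchmark
    (V = 523.599 um^3, S = 314.159 um^2)."""
    spec = FieldSpec(
        n_nuclei=1,
        radii_dist={"name": "constant", "value": 5.0},
        extent_um=(14, 14, 14),
        voxel_size_um=(0.2, 0.2, 0.2),
        noise_sigma=3.0,
        seed=1,
    )
    return make_nucleus_field(spec)


@pytest.fixture
def ellipsoid_field():
    """One 7 x 5.5 x 4.5 um ellipsoid on 0.2 um voxels (line-scan geometry)."""
    spec = FieldSpec(
        n_nuclei=1,
        radii_dist={"name": "constant", "value": [7.0, 5.5, 4.5]},
        extent_um=(24, 20, 16),
        voxel_size_um=(0.2, 0.2, 0.2),
        noise_sigma=3.0,
        seed=3,
    )
    return make_nucleus_field(spec)


def grid_from(data, voxel=1.0, bit_depth=None):
    data = np.asarray(data)
    return VoxelGrid(data, (voxel,) * data.ndim if np.isscalar(voxel) else voxel, bit_depth)
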