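"""Detection chain: smoothing, thresholding, labelling (vs a flood-fill
oracle) and the object-filter rules."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucmorph import (
    FieldSpec,
    SegmentationParams,
    VoxelGrid,
    filter_objects,
    label_components,
    make_nucleus_field,
    rasterize_truth,
    segment,
    smooth,
    threshold,
)

from conftest import grid_from


def flood_fill_labels(mask, full_connectivity=False):
    """Independent BFS connected-component labelling."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    if full_connectivity:
        offs = [d for d in np.ndindex(*(3,) * mask.ndim) if any(x != 1 for x in d)]
        offs = [tuple(x - 1 for x in d) for d in offs]
    else:
        offs = []
        for ax in range(mask.ndim):
            for s in (-1, 1):
                d = [0] * mask.ndim
                d[ax] = s
                offs.append(tuple(d))
    nxt = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            p = stack.pop()
            for d in offs:
                q = tuple(a + b for a, b in zip(p, d))
                if all(0 <= x < n for x, n in zip(q, mask.shape)) and mask[q] and not labels[q]:
                    labels[q] = nxt
                    stack.append(q)
    return labels


def same_partition(a, b):
    """Two labelings describe the same partition of foreground voxels."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a > 0, b > 0):
        return False
    pairs = set(zip(a[a > 0].ravel(), b[b > 0].ravel()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


class TestSmooth:
    def test_sigma_zero_is_identity(self):
        g = grid_from(np.random.default_rng(0).integers(0, 255, (8, 8, 8)))
        assert np.array_equal(smooth(g, 0.0).data, g.data)

    def test_constant_image_unchanged(self):
        g = grid_from(np.full((10, 10, 10), 42.0))
        assert np.allclose(smooth(g, 2.0).data, 42.0)

    def test_impulse_mass_preserved(self):
        # direct summation: reflective-boundary Gaussian keeps total mass
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 100.0
        g = VoxelGrid(data, (0.5, 0.5, 0.5))
        sm = smooth(g, 1.0)
        assert sm.data.sum() == pytest.approx(100.0, abs=1e-6)

    def test_anisotropic_voxels_smooth_isotropically(self):
        data = np.zeros((21, 41, 41))
        data[10, 20, 20] = 1.0
        g = VoxelGrid(data, (1.0, 0.5, 0.5))  # dz twice dx
        sm = smooth(g, 2.0).data
        # physical symmetry: 4 um along z is 4 voxels, along x is 8 voxels
        assert sm[14, 20, 20] == pytest.approx(sm[10, 20, 28], rel=1e-6)


class TestThreshold:
    def test_auto_separates_bimodal_synthetic_field(self):
        spec = FieldSpec(n_nuclei=4, radii_dist={"name": "uniform", "low": 3.0, "high": 4.0},
                         min_spacing_um=10.0, extent_um=(40, 40, 12),
                         voxel_size_um=(0.25, 0.25, 0.25),
                         background=10, foreground=200, noise_sigma=5.0, seed=4)
        grid, truth = make_nucleus_field(spec)
        mask, value = threshold(smooth(grid, 0.3))
        gt = rasterize_truth(truth, grid.shape, grid.voxel_size) > 0
        assert mask.sum() == pytest.approx(gt.sum(), rel=0.05)

    def test_manual_zero_all_foreground(self):
        g = grid_from(np.random.default_rng(0).integers(1, 255, (6, 6)).astype(np.uint8),
                      bit_depth=8)
        with pytest.warns(UserWarning, match="all-foreground"):
            mask, _ = threshold(g, 0)
        assert mask.all()

    def test_manual_above_max_empty(self):
        g = grid_from(np.random.default_rng(0).integers(0, 100, (6, 6)).astype(np.uint8),
                      bit_depth=8)
        with pytest.warns(UserWarning, match="empty"):
            mask, _ = threshold(g, 200)
        assert not mask.any()


class TestLabelComponents:
    def test_two_disjoint_cubes(self):
        m = np.zeros((10, 10, 10), bool)
        m[1:3, 1:3, 1:3] = True
        m[6:9, 6:9, 6:9] = True
        assert label_components(m, (1, 1, 1)).n_labels == 2

    def test_vertex_touching_cubes_connectivity(self):
        m = np.zeros((4, 4, 4), bool)
        m[0:2, 0:2, 0:2] = True
        m[2:4, 2:4, 2:4] = True
        assert label_components(m, (1, 1, 1), "face").n_labels == 2
        assert label_components(m, (1, 1, 1), "full").n_labels == 1

    @pytest.mark.parametrize("connectivity", ["face", "full"])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(50):
            mask = rng.random((10, 10, 5)) < 0.35
            ours = label_components(mask, (1, 1, 1), connectivity).labels
            oracle = flood_fill_labels(mask, full_connectivity=(connectivity == "full"))
            assert same_partition(ours, oracle)


class TestFilterObjects:
    def make_sized_components(self):
        # interior bars of 30, 50 and 120 voxels
        m = np.zeros((12, 40, 10), np.int32)
        m[2:5, 1:11, 1:2] = 1      # 30 voxels
        m[2:7, 13:23, 1:2] = 2     # 50 voxels
        m[2:8, 25:35, 1:3] = 3     # 120 voxels
        from nucmorph.grids import LabelMap
        return LabelMap(m, (1, 1, 1))

    def test_min_size_inclusive(self):
        lm = self.make_sized_components()
        out = filter_objects(lm, SegmentationParams(min_size=50, exclude_border=False))
        assert out.n_labels == 2
        assert out.provenance["removed_small"] == 1

    def test_border_touching_removed(self):
        m = np.zeros((8, 8, 8), np.int32)
        m[0:3, 2:5, 2:5] = 1   # touches z=0 face
        m[4:7, 2:5, 2:5] = 2   # interior
        from nucmorph.grids import LabelMap
        out = filter_objects(LabelMap(m, (1, 1, 1)),
                             SegmentationParams(min_size=1, exclude_border=True))
        assert out.n_labels == 1
        assert out.provenance["removed_border"] == 1

    def test_interior_object_unchanged(self):
        m = np.zeros((10, 10, 10), np.int32)
        m[3:7, 3:7, 3:7] = 1
        from nucmorph.grids import LabelMap
        out = filter_objects(LabelMap(m, (1, 1, 1)), SegmentationParams(min_size=1))
        assert np.array_equal(out.labels, m)

    def test_idempotent(self):
        lm = self.make_sized_components()
        params = SegmentationParams(min_size=50, exclude_border=True)
        once = filter_objects(lm, params)
        twice = filter_objects(once, params)
        assert np.array_equal(once.labels, twice.labels)

    @given(min_a=st.integers(1, 80), min_b=st.integers(1, 80))
    @settings(max_examples=20, deadline=None)
    def test_raising_min_size_is_monotone(self, min_a, min_b):
        lm = self.make_sized_components()
        na = filter_objects(lm, SegmentationParams(min_size=min_a, exclude_border=False)).n_labels
        nb = filter_objects(lm, SegmentationParams(min_size=min_b, exclude_border=False)).n_labels
        if min_a <= min_b:
            assert na >= nb

    def test_solidity_rule_drops_aggregate(self):
        # a plus-shape (low solidity) and a solid cube
        m = np.zeros((14, 14, 14), np.int32)
        m[2:4, 4:10, 6:8] = 1
        m[2:4, 6:8, 2:12] = 1
        m[8:12, 8:12, 8:12] = 2
        from nucmorph.grids import LabelMap
        out = filter_objects(
            LabelMap(m, (1, 1, 1)),
            SegmentationParams(min_size=1, exclude_border=False, max_solidity_deficit=0.2),
        )
        assert out.n_labels == 1
        assert out.provenance["removed_aggregate"] == 1


def test_count_recovery_on_random_fields():
    """With spacing that prevents merges, the pipeline finds exactly n nuclei."""
    hits = 0
    for seed in range(100):
        spec = FieldSpec(n_nuclei=4, radii_dist={"name": "uniform", "low": 2.0, "high": 3.0},
                         min_spacing_um=8.0, extent_um=(32, 32, 10),
                         voxel_size_um=(0.4, 0.4, 0.4), seed=seed)
        grid, _ = make_nucleus_field(spec)
        lab = segment(grid, SegmentationParams(smooth_sigma_um=0.4, min_size=50))
        hits += lab.provenance["n_objects"] == 4
    assert hits == 100
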