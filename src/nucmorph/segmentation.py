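"""Nucleus detection: smoothing, thresholding, labelling and object filtering.

The detection chain mirrors the common fluorescence workflow: Gaussian
smoothing to normalise heterogeneous staining, a global intensity threshold
(automatic between-class-variance, i.e. Otsu, or a manual value), connected
component labelling, and filtering of small objects, border-clipped
("partial") nuclei and, optionally, low-solidity aggregates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .grids import LabelMap, VoxelGrid

__all__ = ["SegmentationParams", "smooth", "threshold", "label_components", "filter_objects", "segment"]


@dataclass
class SegmentationParams:
    """Knobs of the detection chain.

    ``smooth_sigma_um`` is a physical sigma converted per axis to voxels, so
    anisotropic stacks are smoothed isotropically in um-space. ``min_size`` is
    an inclusive voxel-count threshold (an object of exactly ``min_size``
    voxels survives). ``exclude_border`` drops components touching any lattice
    boundary (partial nuclei). ``max_solidity_deficit`` > 0 additionally drops
    components whose solidity falls below 1 - deficit (aggregates); off by
    default since aggregates are usually curated manually.
    """

    smooth_sigma_um: float = 0.5
    threshold_mode: str | float = "auto"  # "auto" or a manual numeric value
    connectivity: str = "face"  # "face" | "full"
    min_size: int = 50
    exclude_border: bool = True
    max_solidity_deficit: float = 0.0

    def __post_init__(self):
        if self.smooth_sigma_um < 0:
            raise ValueError("smooth_sigma_um must be >= 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.connectivity not in ("face", "full"):
            raise ValueError("connectivity must be 'face' or 'full'")
        if not (0.0 <= self.max_solidity_deficit <= 1.0):
            raise ValueError("max_solidity_deficit must be in [0, 1]")


def smooth(grid: VoxelGrid, sigma_um: float) -> VoxelGrid:
    """Gaussian smoothing with sigma given in um (isotropic in physical space)."""
    if sigma_um < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_um == 0:
        return grid.copy_with(grid.data.copy())
    sigma_vox = [sigma_um / v for v in grid.voxel_size]
    out = ndimage.gaussian_filter(grid.data.astype(np.float64), sigma=sigma_vox, mode="reflect")
    return grid.copy_with(out, bit_depth=None)


def threshold(grid: VoxelGrid, mode="auto"):
    """Binary foreground mask, ``intensities >= value`` (inclusive).

    ``mode="auto"`` picks the value by Otsu's between-class-variance criterion;
    a numeric mode is used verbatim (manual thresholding parity). Returns
    ``(mask, value)``; an empty or all-foreground mask warns but is returned.
    """
    data = grid.data
    if mode == "auto":
        value = float(threshold_otsu(data))
    else:
        value = float(mode)
        if grid.bit_depth is not None and not (0 <= value <= 2**grid.bit_depth - 1):
            raise ValueError(f"manual threshold {value} outside {grid.bit_depth}-bit range")
    mask = data >= value
    if mask.all() or not mask.any():
        warnings.warn(
            f"threshold {value} produced an {'all-foreground' if mask.all() else 'empty'} mask",
            stacklevel=2,
        )
    return mask, value


def _structure(ndim: int, connectivity: str):
    return ndimage.generate_binary_structure(ndim, 1 if connectivity == "face" else ndim)


def label_components(mask, voxel_size, connectivity="face", provenance=None) -> LabelMap:
    """Connected-component labelling of a boolean mask (labels 1..K).

    ``connectivity="face"`` is 6-connectivity in 3D / 4 in 2D; ``"full"``
    additionally joins edge and vertex neighbours.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, _ = ndimage.label(mask, structure=_structure(mask.ndim, connectivity))
    prov = dict(provenance or {})
    prov["connectivity"] = connectivity
    return LabelMap(labels.astype(np.int32), tuple(voxel_size), prov)


def _border_labels(labels: np.ndarray):
    hit = set()
    for ax in range(labels.ndim):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=ax)
            hit.update(np.unique(face[face > 0]).tolist())
    return hit


def filter_objects(labmap: LabelMap, params: SegmentationParams) -> LabelMap:
    """Apply size / border / solidity rules and relabel contiguously.

    Removal counts per rule are recorded in provenance, so the written report
    can state how many objects each rule discarded.
    """
    labels = labmap.labels
    n = labmap.n_labels
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    sizes = np.bincount(labels.ravel(), minlength=n + 1)

    too_small = (sizes < params.min_size) & keep
    keep &= ~too_small

    n_border = 0
    if params.exclude_border:
        border = _border_labels(labels)
        for lab in border:
            if keep[lab]:
                keep[lab] = False
                n_border += 1

    n_aggregate = 0
    if params.max_solidity_deficit > 0:
        min_solidity = 1.0 - params.max_solidity_deficit
        for rp in regionprops(labels):
            if keep[rp.label]:
                try:
                    sol = rp.solidity
                except Exception:  # degenerate hulls (e.g. coplanar voxels)
                    continue
                if sol < min_solidity:
                    keep[rp.label] = False
                    n_aggregate += 1

    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    out = remap[labels]

    prov = dict(labmap.provenance)
    prov.update(
        min_size=params.min_size,
        exclude_border=params.exclude_border,
        max_solidity_deficit=params.max_solidity_deficit,
        removed_small=int(too_small.sum()),
        removed_border=n_border,
        removed_aggregate=n_aggregate,
        n_objects=int(keep.sum()),
    )
    return LabelMap(out, labmap.voxel_size, prov)


def segment(grid: VoxelGrid, params: SegmentationParams | None = None) -> LabelMap:
    """Full chain: smooth -> threshold -> label -> filter."""
    params = params or SegmentationParams()
    sm = smooth(grid, params.smooth_sigma_um)
    mask, value = threshold(sm, params.threshold_mode)
    labmap = label_components(
        mask,
        grid.voxel_size,
        params.connectivity,
        provenance={"threshold_value": value, "threshold_mode": str(params.threshold_mode),
                    "smooth_sigma_um": params.smooth_sigma_um},
    )
    return filter_objects(labmap, params)
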