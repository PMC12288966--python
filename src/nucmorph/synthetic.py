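"""Ground-truthed synthetic microscopy and biochemistry data.

The generators here emulate the raw material of a nuclear-morphometry study:

* DAPI-like z-stacks of ellipsoidal nuclei with controllable size
  distributions and a two-population median shift (the oncogene analogue),
* a nuclear-membrane channel whose peripheral enrichment is an exact,
  requested quantity,
* 2D "optical density" planes standing in for stained tissue sections,
* exponential protein-decay time courses with multiplicative noise
  (cycloheximide-chase analogue).

Every output ships with an analytic ground-truth table so downstream
measurements can be validated against closed forms rather than against
other image-analysis code.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import VoxelGrid, xyz_to_axis_order

__all__ = [
    "FieldSpec",
    "MembraneSpec",
    "DecaySpec",
    "DecayCourse",
    "CrowdedFieldError",
    "make_nucleus_field",
    "make_membrane_channel",
    "make_plane_field",
    "make_decay_course",
    "ellipsoid_volume",
    "ellipsoid_surface_area",
    "rasterize_truth",
    "save_truth",
]

KNUD_THOMSEN_P = 1.6075


class CrowdedFieldError(RuntimeError):
    """Raised when rejection sampling cannot place all nuclei."""


def ellipsoid_volume(a, b, c):
    """Analytic ellipsoid volume 4/3*pi*a*b*c (um^3)."""
    return 4.0 / 3.0 * np.pi * np.asarray(a) * np.asarray(b) * np.asarray(c)


def ellipsoid_surface_area(a, b, c, p=KNUD_THOMSEN_P):
    """Knud Thomsen surface-area approximation (relative error < 1.1%)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ap, bp, cp = a**p, b**p, c**p
    return 4.0 * np.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p)


@dataclass
class FieldSpec:
    """Recipe for a field of ellipsoidal nuclei.

    ``radii_dist`` names the per-axis semi-axis distribution (um):
    ``{"name": "constant", "value": r}``, ``{"name": "uniform", "low": .., "high": ..}``
    or ``{"name": "lognormal", "median_um": .., "cv": ..}``.

    ``median_scale`` != 1 turns the field into a matched-pair two-population
    design: each base shape is instantiated once unscaled (population 0) and
    once with all semi-axes multiplied by ``median_scale`` (population 1), so
    the ground-truth median-volume ratio between populations is exactly
    ``median_scale**3``. ``size_scale`` instead multiplies *every* nucleus and
    is used to build separate experimental conditions.
    """

    n_nuclei: int = 40
    radii_dist: dict = field(default_factory=lambda: {"name": "lognormal", "median_um": 4.5, "cv": 0.10})
    median_scale: float = 1.0
    size_scale: float = 1.0
    min_spacing_um: float = 12.0
    extent_um: tuple = (60.0, 60.0, 18.0)  # (x, y, z)
    voxel_size_um: tuple = (0.25, 0.25, 0.25)  # (dx, dy, dz)
    background: float = 10.0
    foreground: float = 200.0
    noise_sigma: float = 5.0
    bit_depth: int = 8
    placement: str = "random"  # "random" | "hex" (hex: 2D planes only)
    border_pad_um: float = 1.0  # minimum gap between any nucleus surface and the field edge
    max_attempts: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.median_scale <= 0 or self.size_scale <= 0:
            raise ValueError("scale multipliers must be > 0")
        if self.min_spacing_um <= 0:
            raise ValueError("min_spacing_um must be > 0")
        if any(e <= 0 for e in self.extent_um) or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("extents and voxel sizes must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.median_scale != 1.0 and self.n_nuclei % 2:
            raise ValueError("two-population fields (median_scale != 1) need an even n_nuclei")


def _sample_semiaxes(dist: dict, n: int, ndim: int, rng) -> np.ndarray:
    """n rows of per-axis semi-axes (um), columns ordered (x, y, z)[:ndim]."""
    name = dist.get("name", "lognormal")
    if name == "constant":
        val = dist["value"]
        arr = np.broadcast_to(np.atleast_1d(np.asarray(val, float)), (n, ndim)).copy()
    elif name == "uniform":
        arr = rng.uniform(dist["low"], dist["high"], size=(n, ndim))
    elif name == "lognormal":
        med, cv = float(dist["median_um"]), float(dist.get("cv", 0.1))
        sigma = np.sqrt(np.log1p(cv**2))
        arr = med * np.exp(rng.normal(0.0, sigma, size=(n, ndim)))
    else:
        raise ValueError(f"unknown radii distribution {name!r}")
    if np.any(arr <= 0):
        raise ValueError("sampled semi-axes must be positive")
    return arr


def _place_centers(semiaxes, extent, min_spacing, max_attempts, rng, hex_spacing=None, pad=1.0):
    """Centers (um, xyz order) keeping each ellipsoid inside the extent (with a
    ``pad`` um gap to the edge) and pairwise center distances >= min_spacing.
    Rejection sampling with a hard cap."""
    n, ndim = semiaxes.shape
    if hex_spacing is not None:
        if ndim != 2:
            raise ValueError("hex placement is defined for planes only")
        return _hex_centers(n, extent, hex_spacing, semiaxes)
    centers = np.empty((n, ndim))
    for i in range(n):
        lo = semiaxes[i] + pad
        hi = np.asarray(extent[:ndim]) - semiaxes[i] - pad
        if np.any(hi <= lo):
            raise CrowdedFieldError(
                f"nucleus with semi-axes {semiaxes[i]} does not fit extent {extent}"
            )
        for attempt in range(max_attempts):
            c = rng.uniform(lo, hi)
            if i == 0 or np.all(np.linalg.norm(centers[:i] - c, axis=1) >= min_spacing):
                centers[i] = c
                break
        else:
            raise CrowdedFieldError(
                f"field too crowded: failed to place nucleus {i + 1}/{n} after "
                f"{max_attempts} attempts (min_spacing={min_spacing} um, extent={extent} um)"
            )
    return centers


def _hex_centers(n, extent, spacing, semiaxes):
    """First n sites of a triangular (hexagonal) lattice, row by row."""
    margin = float(semiaxes.max())
    dy = spacing * np.sqrt(3.0) / 2.0
    pts = []
    j = 0
    while len(pts) < n:
        y = margin + j * dy
        if y > extent[1] - margin:
            raise CrowdedFieldError("hex lattice does not fit the requested extent")
        x0 = margin + (spacing / 2.0 if j % 2 else 0.0)
        x = x0
        while x <= extent[0] - margin and len(pts) < n:
            pts.append((x, y))
            x += spacing
        j += 1
    return np.asarray(pts)


def _paint_ellipsoids(shape_axis, voxel_axis, centers_xyz, semiaxes_xyz, out, value_fn):
    """Set voxels whose centers fall inside each ellipsoid. Bounding-box local work."""
    ndim = len(shape_axis)
    vox = np.asarray(voxel_axis)  # array-axis order
    for idx in range(len(centers_xyz)):
        c_axis = centers_xyz[idx][::-1]  # -> (z,y,x)[:ndim]
        r_axis = semiaxes_xyz[idx][::-1]
        lo = np.maximum(0, np.floor((c_axis - r_axis) / vox - 1).astype(int))
        hi = np.minimum(shape_axis, np.ceil((c_axis + r_axis) / vox + 1).astype(int))
        grids = np.meshgrid(
            *[(np.arange(lo[k], hi[k]) + 0.5) * vox[k] - c_axis[k] for k in range(ndim)],
            indexing="ij",
        )
        q = sum((g / r) ** 2 for g, r in zip(grids, r_axis))
        sel = tuple(slice(lo[k], hi[k]) for k in range(ndim))
        inside = q <= 1.0
        value_fn(out, sel, inside, idx)


def _truth_table(centers, semiaxes, populations, ndim):
    cols = {"id": np.arange(1, len(centers) + 1)}
    for k, ax in enumerate("xyz"[:ndim]):
        cols[f"c{ax}_um"] = centers[:, k]
    names = ["a_um", "b_um", "c_um"][:ndim]
    for k, nm in enumerate(names):
        cols[nm] = semiaxes[:, k]
    if ndim == 3:
        cols["volume_um3"] = ellipsoid_volume(semiaxes[:, 0], semiaxes[:, 1], semiaxes[:, 2])
        cols["surface_area_um2"] = ellipsoid_surface_area(
            semiaxes[:, 0], semiaxes[:, 1], semiaxes[:, 2]
        )
    else:
        cols["area_um2"] = np.pi * semiaxes[:, 0] * semiaxes[:, 1]
    cols["population"] = populations
    return pd.DataFrame(cols)


def _render(spec: FieldSpec, ndim: int, hex_spacing=None, dark=False):
    rng = np.random.default_rng(spec.seed)
    extent = spec.extent_um[:ndim]
    voxel_axis = xyz_to_axis_order(spec.voxel_size_um, ndim)
    shape = tuple(int(round(e / v)) for e, v in zip(extent[::-1], voxel_axis))

    n = spec.n_nuclei
    if spec.median_scale != 1.0:
        base = _sample_semiaxes(spec.radii_dist, n // 2, ndim, rng)
        semiaxes = np.vstack([base, base * spec.median_scale]) * spec.size_scale
        populations = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    else:
        semiaxes = _sample_semiaxes(spec.radii_dist, n, ndim, rng) * spec.size_scale
        populations = np.zeros(n, int)

    if n:
        centers = _place_centers(
            semiaxes, extent, spec.min_spacing_um, spec.max_attempts, rng,
            hex_spacing, pad=spec.border_pad_um,
        )
    else:
        centers = np.empty((0, ndim))

    img = np.full(shape, float(spec.background))
    fg = float(spec.foreground)

    def setval(out, sel, inside, idx):
        region = out[sel]
        region[inside] = fg
        out[sel] = region

    _paint_ellipsoids(shape, voxel_axis, centers, semiaxes, img, setval)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=shape)
    lim = 2**spec.bit_depth - 1
    if dark:
        img = lim - img
    img = np.clip(np.rint(img), 0, lim).astype(np.uint8 if spec.bit_depth == 8 else np.uint16)

    grid = VoxelGrid(img, voxel_axis, bit_depth=spec.bit_depth)
    truth = _truth_table(centers, semiaxes, populations, ndim)
    return grid, truth


def make_nucleus_field(spec: FieldSpec):
    """Render a 3D DAPI-like stack of ellipsoidal nuclei.

    Returns
    -------
    (VoxelGrid, DataFrame)
        Calibrated intensity volume and the exact per-nucleus ground truth
        (centers, semi-axes, analytic volume and Knud-Thomsen surface area,
        population label). Deterministic for identical (spec, seed).
    """
    return _render(spec, ndim=3)


def make_plane_field(spec: FieldSpec, hex_spacing_um=None, dark_nuclei=False):
    """2D analogue of :func:`make_nucleus_field` (histology-plane stand-in).

    ``hex_spacing_um`` places nuclei on a triangular lattice with that pitch
    (useful as a geometric oracle for crowding statistics). ``dark_nuclei``
    inverts the contrast, emulating optical-density detection on brightfield
    stains where nuclei are darker than background.
    """
    return _render(spec, ndim=2, hex_spacing=hex_spacing_um, dark=dark_nuclei)


def rasterize_truth(truth: pd.DataFrame, shape, voxel_size_axis) -> np.ndarray:
    """Ground-truth label image: voxel centers inside nucleus i get label i (id).

    Later nuclei overwrite earlier ones on (unexpected) overlap.
    """
    ndim = len(shape)
    labels = np.zeros(shape, dtype=np.int32)
    if not len(truth):
        return labels
    centers = truth[[f"c{ax}_um" for ax in "xyz"[:ndim]]].to_numpy()
    semi = truth[["a_um", "b_um", "c_um"][:ndim]].to_numpy()
    ids = truth["id"].to_numpy()

    def setval(out, sel, inside, idx):
        region = out[sel]
        region[inside] = ids[idx]
        out[sel] = region

    _paint_ellipsoids(shape, voxel_size_axis, centers, semi, labels, setval)
    return labels


@dataclass
class MembraneSpec:
    """Recipe for a nuclear-membrane channel with known peripheral enrichment.

    ``rim_fraction`` (rho) is the requested peripheral share; ``None`` renders
    a uniform fill (no enrichment). Two exact calibrations are offered:

    ``calibration="mass"``
        Fraction rho of each nucleus's total voxel signal lies in the rim
        shell (Euclidean depth <= ``rim_width_um`` from the rendered surface);
        the remainder is uniform over the interior. This is the 3D mass
        semantics, verifiable by voxel summation.

    ``calibration="linescan"``
        Zone intensity levels are solved per nucleus so that an ideal
        continuous line scan along the in-plane long axis, scored with the
        assay's ``margin_um`` edge margin, yields exactly rho. This is the
        ground-truth counterpart of the measured peripheral percentage; a 1D
        line scan cannot in general recover the 3D mass fraction because it
        weights zones by length along the axis rather than by shell volume.
    """

    rim_fraction: float | None = 0.72
    rim_width_um: float = 1.0
    interior_level: float = 0.0
    calibration: str = "mass"
    margin_um: float = 3.0
    brightness: float = 100.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.rim_fraction is not None and not (0.0 <= self.rim_fraction <= 1.0):
            raise ValueError("rim_fraction must be in [0, 1]")
        if self.rim_width_um <= 0:
            raise ValueError("rim_width_um must be > 0")
        if self.calibration not in ("mass", "linescan"):
            raise ValueError("calibration must be 'mass' or 'linescan'")
        if self.margin_um <= 0:
            raise ValueError("margin_um must be > 0")


def _zone_levels_linescan(rho, L, w, d):
    """Intensity levels (rim, mid, core) so a continuous long-axis line scan
    with margin d reads exactly rho.

    The line of length L crosses rim (depth <= w) for 2w, the rest of the
    margin zone (w < depth <= d) for 2(d - w), and the core for L - 2d.
    """
    if L <= 2 * d:
        return 1.0, 1.0, 1.0  # span smaller than twice the margin: fraction is 1 regardless
    if rho >= 1:
        return 1.0, 0.0, 0.0
    if rho <= 0:
        return 0.0, 0.0, 1.0
    c_r = (rho * (L - 2 * w) - 2 * (d - w)) / (2 * w * (1.0 - rho))
    if c_r >= 0.0:
        return float(c_r), 1.0, 1.0
    # rho below the uniform margin share: rim dark, dim the rest of the margin zone
    c_m = rho * (L - 2 * d) / (2 * (d - w) * (1.0 - rho)) if d > w else 0.0
    return 0.0, float(c_m), 1.0


def make_membrane_channel(truth: pd.DataFrame, mspec: MembraneSpec, shape, voxel_size_axis) -> VoxelGrid:
    """Render the membrane channel for nuclei in ``truth`` on the given lattice.

    The rim shell is defined by Euclidean distance-to-surface computed on the
    rendered voxel mask (matching what a line scan actually samples), not
    analytically.
    """
    if len(truth):
        min_semi = truth[["a_um", "b_um", "c_um"][: len(shape)]].to_numpy().min()
        if mspec.rim_width_um >= min_semi:
            raise ValueError(
                f"rim_width_um={mspec.rim_width_um} must be smaller than the smallest "
                f"nuclear semi-axis ({min_semi:.3f} um)"
            )
    ndim = len(shape)
    labels = rasterize_truth(truth, shape, voxel_size_axis)
    out = np.zeros(shape, dtype=np.float64)
    sampling = tuple(voxel_size_axis)
    w, d = mspec.rim_width_um, mspec.margin_um

    objects = ndimage.find_objects(labels)
    for _, row in truth.iterrows():
        nid = int(row["id"])
        # local bounding box with 1-voxel pad so the EDT sees the surface
        if nid > len(objects) or objects[nid - 1] is None:
            continue
        sel = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, n))
            for s, n in zip(objects[nid - 1], shape)
        )
        mask = labels[sel] == nid
        depth = ndimage.distance_transform_edt(mask, sampling=sampling)
        rim = mask & (depth <= w)
        interior = mask & ~rim
        local = np.zeros(mask.shape)
        if mspec.rim_fraction is None:
            local[mask] = 1.0
        elif mspec.calibration == "mass":
            rho = mspec.rim_fraction
            n_rim, n_int = int(rim.sum()), int(interior.sum())
            if n_rim:
                local[rim] = rho / n_rim
            if n_int:
                local[interior] = (1.0 - rho) / n_int
            elif n_rim:  # no interior voxels: everything is rim
                local[rim] = 1.0 / n_rim
        else:  # linescan calibration
            semi = row[["a_um", "b_um", "c_um"][:ndim]].to_numpy(dtype=float)
            L = 2.0 * float(max(semi[0], semi[1]) if ndim >= 2 else semi[0])
            c_r, c_m, c_c = _zone_levels_linescan(mspec.rim_fraction, L, w, d)
            mid = interior & (depth <= d)
            core = interior & (depth > d)
            local[rim] = c_r
            local[mid] = c_m
            local[core] = c_c
        tot = local.sum()
        if tot > 0:
            local *= mspec.brightness / tot
        if mspec.interior_level:
            local[interior] += mspec.interior_level
        out[sel] += local

    if mspec.noise_sigma > 0:
        rng = np.random.default_rng(mspec.seed)
        out = np.clip(out + rng.normal(0.0, mspec.noise_sigma, size=shape), 0.0, None)
    return VoxelGrid(out, tuple(voxel_size_axis), bit_depth=None)


@dataclass
class DecaySpec:
    """Exponential protein-decay time course (cycloheximide-chase analogue).

    ``rate_per_h`` is the first-order decay constant k (1/h); half-life is
    ln2/k. ``noise_cv`` is the coefficient of variation of multiplicative
    lognormal noise (mean-one).
    """

    initial_level: float = 1.0
    rate_per_h: float = np.log(2.0) / 6.0
    timepoints_h: tuple = (0.0, 6.0, 12.0)
    noise_cv: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.rate_per_h < 0:
            raise ValueError("rate_per_h must be >= 0")
        tp = np.asarray(self.timepoints_h, dtype=float)
        if tp.size == 0 or np.any(tp < 0) or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be nonnegative and strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.initial_level <= 0:
            raise ValueError("initial_level must be > 0")


@dataclass
class DecayCourse:
    """Replicate x timepoint table of protein levels."""

    timepoints_h: np.ndarray
    levels: np.ndarray  # shape (replicates, timepoints)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, columns=[f"t{t:g}h" for t in self.timepoints_h])
        df.insert(0, "replicate", np.arange(1, len(df) + 1))
        return df

    def normalized_to_t0(self) -> "DecayCourse":
        """Each replicate divided by its own t=0 level (self-normalization)."""
        return DecayCourse(self.timepoints_h, self.levels / self.levels[:, :1])


def make_decay_course(dspec: DecaySpec) -> DecayCourse:
    """levels = initial * exp(-k t) * noise, noiseless when noise_cv = 0."""
    rng = np.random.default_rng(dspec.seed)
    t = np.asarray(dspec.timepoints_h, dtype=float)
    clean = dspec.initial_level * np.exp(-dspec.rate_per_h * t)
    levels = np.tile(clean, (dspec.replicates, 1))
    if dspec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(dspec.noise_cv**2))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=levels.shape))
        levels = levels * noise
    return DecayCourse(t, levels)


def save_truth(truth: pd.DataFrame, path) -> Path:
    """Ground truth CSV, one row per nucleus, with a versioned header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# nucmorph ground-truth table v1; lengths um, volumes um^3, areas um^2\n")
        truth.to_csv(fh, index=False)
    return path
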