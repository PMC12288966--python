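"""Line scans, densitometry and decay-course summarisation.

The line-scan assay draws a segment through the long axis of a nucleus on the
middle z-plane, samples the membrane channel along it, and reports the
peripheral fraction: the share of the trans-nuclear signal lying within a
fixed margin (3 um by convention) of the two nuclear edges. Densitometry
reduces a blot lane profile to a background-subtracted AUC normalised to a
loading control; decay summarisation turns cycloheximide-chase tables into
per-timepoint means with per-timepoint tests and an optional half-life fit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import VoxelGrid
from .synthetic import DecayCourse

__all__ = [
    "LineProfile",
    "PeripheralFraction",
    "LaneDensitometry",
    "long_axis",
    "sample_profile",
    "peripheral_fraction",
    "lane_auc",
    "summarize_decay",
]


@dataclass
class LineProfile:
    """Calibrated 1D intensity trace along a nucleus's long axis."""

    positions_um: np.ndarray
    intensities: np.ndarray
    edge_left_um: float
    edge_right_um: float
    z_plane: int | None = None

    def __post_init__(self):
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_um.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not (self.edge_left_um < self.edge_right_um):
            raise ValueError("edge_left must be < edge_right")

    @property
    def span_um(self) -> float:
        return self.edge_right_um - self.edge_left_um


@dataclass
class PeripheralFraction:
    value: float
    margin_um: float
    flagged: bool = False  # True when the margin covers the whole span


@dataclass
class LaneDensitometry:
    auc: float
    background_mode: str
    normalized: float | None = None


def long_axis(mask2d, pixel_size, overshoot_um=2.0):
    """Endpoints (um, (x, y)) of a segment through the mask's long axis.

    The direction is the principal axis of the mask's pixel coordinates; for
    round masks (aspect ~1) the tie is broken toward the image x-axis. The
    segment runs through the centroid, is clipped to the mask, then extended
    by ``overshoot_um`` on each side so the profile samples across both edges.
    """
    mask = np.asarray(mask2d, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_comp = ndimage.label(mask)[1]
    if n_comp != 1:
        raise ValueError(f"mask must be a single connected component (found {n_comp})")
    vox = np.asarray(pixel_size, dtype=float)  # (dy, dx)
    iy, ix = np.nonzero(mask)
    pts = np.stack([(ix + 0.5) * vox[1], (iy + 0.5) * vox[0]], axis=1)  # (x, y) um
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T) if len(pts) > 1 else np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[-1] / max(evals[0], 1e-30) < 1.05:
        direction = np.array([1.0, 0.0])  # near-isotropic: x-axis tie-break
    else:
        direction = evecs[:, -1]
        if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
            direction = -direction

    # march outwards from the centroid until the ray leaves the mask
    step = 0.25 * float(vox.min())
    span = mask.shape[0] * vox[0] + mask.shape[1] * vox[1]

    def reach(sign):
        t, t_in = 0.0, 0.0
        while t < span:
            p = centroid + sign * t * direction
            j = int(p[0] / vox[1])
            i = int(p[1] / vox[0])
            if i < 0 or j < 0 or i >= mask.shape[0] or j >= mask.shape[1] or not mask[i, j]:
                break
            t_in = t
            t += step
        return t_in

    t_plus, t_minus = reach(+1), reach(-1)
    p0 = centroid - (t_minus + overshoot_um) * direction
    p1 = centroid + (t_plus + overshoot_um) * direction
    return p0, p1


def sample_profile(channel: VoxelGrid, segment, mask, step_um=0.1, z_plane=None,
                   clip_to_bounds=False) -> LineProfile:
    """Bilinear profile of ``channel`` along ``segment`` on one z-plane.

    ``segment`` is (p0, p1) in um (x, y); ``mask`` is the nucleus mask on the
    same plane, used to locate the two nuclear-edge crossings. For 3D
    channels, ``z_plane`` defaults to the middle plane of the stack. A segment
    leaving the image raises, unless ``clip_to_bounds`` trims the overshoot
    (the trans-nuclear part must still be inside).
    """
    if step_um <= 0:
        raise ValueError("step_um must be > 0")
    if channel.is_3d:
        if z_plane is None:
            z_plane = channel.shape[0] // 2
        plane = channel.data[z_plane]
        vox = channel.voxel_size[1:]
    else:
        plane = channel.data
        vox = channel.voxel_size
        z_plane = None
    p0, p1 = (np.asarray(p, dtype=float) for p in segment)
    if clip_to_bounds:
        hi = np.array([plane.shape[1] * vox[1], plane.shape[0] * vox[0]])
        direction = (p1 - p0) / np.linalg.norm(p1 - p0)
        t0, t1 = 0.0, float(np.linalg.norm(p1 - p0))
        for k in range(2):
            if abs(direction[k]) > 1e-12:
                ta, tb = sorted([(0.0 - p0[k]) / direction[k], (hi[k] - p0[k]) / direction[k]])
                t0, t1 = max(t0, ta), min(t1, tb)
        eps = 1e-9
        p0, p1 = p0 + (t0 + eps) * direction, p0 + (t1 - eps) * direction
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.floor(length / step_um)) + 1, 2)
    t = np.linspace(0.0, length, n)
    pts = p0[None, :] + (p1 - p0)[None, :] / length * t[:, None]
    # physical (x, y) -> fractional array indices (voxel centers at (i+0.5)*v)
    idx = np.stack([pts[:, 1] / vox[0] - 0.5, pts[:, 0] / vox[1] - 0.5])
    if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
            or pts[:, 0].max() > plane.shape[1] * vox[1]
            or pts[:, 1].max() > plane.shape[0] * vox[0]):
        raise ValueError("segment exits the image bounds")
    values = ndimage.map_coordinates(np.asarray(plane, dtype=float), idx, order=1, mode="nearest")
    inside = ndimage.map_coordinates(np.asarray(mask, dtype=float), idx, order=1, mode="constant") >= 0.5
    if not inside.any():
        raise ValueError("segment does not cross the nucleus mask")
    first, last = np.nonzero(inside)[0][[0, -1]]
    return LineProfile(t, values, float(t[first]), float(t[last]), z_plane=z_plane)


def _trapz_between(x, y, lo, hi):
    """Trapezoidal integral of the sampled curve over [lo, hi], interpolating
    at the cut points so partial end intervals are weighted exactly."""
    if hi <= lo:
        return 0.0
    cuts = np.unique(np.concatenate([x[(x > lo) & (x < hi)], [lo, hi]]))
    return float(np.trapezoid(np.interp(cuts, x, y), cuts))


def peripheral_fraction(profile: LineProfile, margin_um=3.0) -> PeripheralFraction:
    """Share of the trans-nuclear signal within ``margin_um`` of either edge.

    Signal outside the nuclear span is excluded from both numerator and
    denominator. When the two margins cover the whole span the fraction is
    trivially 1 and the result is flagged.
    """
    if margin_um <= 0:
        raise ValueError("margin_um must be > 0")
    pl, pr = profile.edge_left_um, profile.edge_right_um
    x, y = profile.positions_um, profile.intensities
    total = _trapz_between(x, y, pl, pr)
    if total <= 0:
        raise ValueError("no signal on line")
    if profile.span_um <= 2 * margin_um:
        return PeripheralFraction(1.0, margin_um, flagged=True)
    peri = _trapz_between(x, y, pl, pl + margin_um) + _trapz_between(x, y, pr - margin_um, pr)
    return PeripheralFraction(min(peri / total, 1.0), margin_um)


def lane_auc(profile, positions=None, background_mode="zero", control_auc=None) -> LaneDensitometry:
    """Densitometric AUC of a blot-lane profile.

    ``background_mode``: "zero" (no baseline), "min" (flat baseline at the
    profile minimum) or "linear" (straight line between the endpoint values,
    a rolling-ball-style local base). Negative excursions after subtraction
    are clipped to zero. ``control_auc`` normalises to a loading control.
    """
    y = np.asarray(profile, dtype=float)
    if y.size == 0:
        raise ValueError("empty profile")
    x = np.arange(y.size, dtype=float) if positions is None else np.asarray(positions, dtype=float)
    if background_mode == "zero":
        base = np.zeros_like(y)
    elif background_mode == "min":
        base = np.full_like(y, y.min())
    elif background_mode == "linear":
        base = np.interp(x, [x[0], x[-1]], [y[0], y[-1]])
    else:
        raise ValueError("background_mode must be 'zero', 'min' or 'linear'")
    auc = float(np.trapezoid(np.clip(y - base, 0.0, None), x))
    norm = None
    if control_auc is not None:
        if control_auc <= 0:
            raise ValueError("control AUC must be > 0 for normalization")
        norm = auc / control_auc
    return LaneDensitometry(auc, background_mode, normalized=norm)


def fit_half_life(course: DecayCourse) -> float:
    """Half-life (h) from a log-linear least-squares fit over all replicates.

    This pools replicate x timepoint levels, regresses log(level) on time and
    returns ln2 / k_hat. Reported as an extension beyond per-timepoint testing.
    """
    t = np.repeat(course.timepoints_h, course.levels.shape[0])
    y = course.levels.T.ravel()
    if np.any(y <= 0):
        raise ValueError("nonpositive levels: cannot log-fit decay")
    slope = np.polyfit(t, np.log(y), 1)[0]
    if slope >= 0:
        return float("inf")
    return float(np.log(2.0) / -slope)


def summarize_decay(course: DecayCourse, other: DecayCourse | None = None,
                    fit=True) -> pd.DataFrame:
    """Per-timepoint mean +/- SEM, optionally with a second condition.

    With ``other`` given, a per-timepoint two-sided Student's t test compares
    the two conditions (the convention for chase assays). The returned frame
    carries ``half_life_h`` (and ``half_life_h_other``) as attrs when
    ``fit=True``; the fit is labelled an extension of the per-timepoint view.
    """
    if course.levels.shape[0] < 2:
        raise ValueError("need >= 2 replicates for SEM")
    rows = {
        "timepoint_h": course.timepoints_h,
        "mean": course.levels.mean(axis=0),
        "sem": stats.sem(course.levels, axis=0),
        "n": course.levels.shape[0],
    }
    if other is not None:
        if not np.array_equal(other.timepoints_h, course.timepoints_h):
            raise ValueError("conditions must share timepoints")
        rows["mean_other"] = other.levels.mean(axis=0)
        rows["sem_other"] = stats.sem(other.levels, axis=0)
        pvals = [
            stats.ttest_ind(course.levels[:, k], other.levels[:, k]).pvalue
            if (np.ptp(course.levels[:, k]) > 0 or np.ptp(other.levels[:, k]) > 0) else 1.0
            for k in range(len(course.timepoints_h))
        ]
        rows["t_test_p"] = pvals
    df = pd.DataFrame(rows)
    if fit:
        df.attrs["half_life_h"] = fit_half_life(course)
        df.attrs["half_life_note"] = "log-linear LS fit; extension beyond per-timepoint tests"
        if other is not None:
            df.attrs["half_life_h_other"] = fit_half_life(other)
    return df
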