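"""ROI tiling and Delaunay internuclear-distance / crowding statistics.

"Internuclear distance" is the centroid-to-centroid length of Delaunay edges.
The crowding index divides each nucleus's mean (or median) incident edge
length by its equivalent diameter, which makes the statistic invariant under
joint scaling of positions and sizes — the property that removes nuclear-size
confounding from packing density.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

__all__ = ["RoiSpec", "DelaunayGraph", "tile_rois", "delaunay_graph", "crowding_indices"]


@dataclass
class RoiSpec:
    """Random placement of square analysis boxes on a large plane.

    Boxes are axis-aligned, ``box_size_um`` on a side (half-open in um
    coordinates), non-overlapping, and fully outside the exclusion mask when
    one is provided (regions such as stroma or islets that the analysis
    should avoid).
    """

    box_size_um: float = 1500.0
    n_boxes: int = 8
    max_attempts: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.box_size_um <= 0 or self.n_boxes < 1 or self.max_attempts < 1:
            raise ValueError("invalid RoiSpec")


def tile_rois(extent_um, spec: RoiSpec, exclusion_mask=None, mask_pixel_um=None):
    """Sample ``n_boxes`` boxes inside ``extent_um`` = (width, height) um.

    Returns a list of (x0, y0, x1, y1) um tuples. Deterministic given
    ``spec.seed``. If non-overlap cannot be achieved within ``max_attempts``
    draws per box, overlap is permitted with a warning; boxes intersecting
    the exclusion mask are never accepted and exhaustion raises.
    """
    w, h = float(extent_um[0]), float(extent_um[1])
    s = spec.box_size_um
    if s > w or s > h:
        raise ValueError(f"box size {s} um does not fit extent {extent_um} um")
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if mask_pixel_um is None:
            mask_pixel_um = (w / exclusion_mask.shape[1], h / exclusion_mask.shape[0])

    rng = np.random.default_rng(spec.seed)
    boxes: list[tuple] = []

    def hits_mask(x0, y0):
        if exclusion_mask is None:
            return False
        px, py = mask_pixel_um
        j0, j1 = int(np.floor(x0 / px)), int(np.ceil((x0 + s) / px))
        i0, i1 = int(np.floor(y0 / py)), int(np.ceil((y0 + s) / py))
        return bool(exclusion_mask[i0:i1, j0:j1].any())

    def overlaps(x0, y0):
        return any(x0 < bx1 and x0 + s > bx0 and y0 < by1 and y0 + s > by0
                   for bx0, by0, bx1, by1 in boxes)

    for b in range(spec.n_boxes):
        placed = False
        allow_overlap = False
        for attempt in range(2 * spec.max_attempts):
            if attempt == spec.max_attempts and not allow_overlap:
                allow_overlap = True
                warnings.warn(
                    f"ROI box {b + 1}: could not avoid overlap within "
                    f"{spec.max_attempts} attempts; permitting overlap",
                    stacklevel=2,
                )
            x0 = rng.uniform(0.0, w - s)
            y0 = rng.uniform(0.0, h - s)
            if hits_mask(x0, y0):
                continue
            if not allow_overlap and overlaps(x0, y0):
                continue
            boxes.append((x0, y0, x0 + s, y0 + s))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place ROI box {b + 1}/{spec.n_boxes}: exclusion mask too "
                f"restrictive for {s} um boxes in extent {extent_um} um"
            )
    return boxes


@dataclass
class DelaunayGraph:
    """2D Delaunay triangulation as an edge list with physical lengths."""

    points: np.ndarray          # (n, 2) um
    edges: np.ndarray           # (m, 2) int vertex indices, i < j
    lengths: np.ndarray         # (m,) um
    degenerate: bool = False    # True when a nearest-neighbour chain replaced qhull

    def incident_lengths(self, summary="mean") -> np.ndarray:
        """Per-node summary of incident edge lengths; NaN for isolated nodes."""
        n = len(self.points)
        if summary not in ("mean", "median"):
            raise ValueError("summary must be 'mean' or 'median'")
        buckets: list[list[float]] = [[] for _ in range(n)]
        for (i, j), ln in zip(self.edges, self.lengths):
            buckets[i].append(ln)
            buckets[j].append(ln)
        fn = np.mean if summary == "mean" else np.median
        return np.array([fn(b) if b else np.nan for b in buckets])


def _chain_graph(pts):
    """Fallback for collinear input: chain consecutive points along the line."""
    if len(pts) < 2:
        return DelaunayGraph(pts, np.empty((0, 2), int), np.empty(0), degenerate=True)
    d = pts - pts.mean(axis=0)
    # principal direction of the (degenerate) scatter
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    order = np.argsort(d @ vt[0])
    edges = np.stack([order[:-1], order[1:]], axis=1)
    edges = np.sort(edges, axis=1)
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    return DelaunayGraph(pts, edges, lengths, degenerate=True)


def delaunay_graph(points_um) -> DelaunayGraph:
    """Delaunay triangulation of 2D centroids; edges carry lengths in um.

    Fewer than 2 points give an empty graph; collinear inputs fall back to a
    nearest-neighbour chain flagged ``degenerate``.
    """
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        return DelaunayGraph(pts, np.empty((0, 2), int), np.empty(0), degenerate=True)
    if len(pts) == 2:
        return _chain_graph(pts)
    try:
        tri = Delaunay(pts)
    except QhullError:
        warnings.warn("collinear points: using nearest-neighbour chain fallback", stacklevel=2)
        return _chain_graph(pts)
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            pairs.add((min(i, j), max(i, j)))
    edges = np.array(sorted(pairs), dtype=int)
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    return DelaunayGraph(pts, edges, lengths)


def crowding_indices(graph: DelaunayGraph, records: pd.DataFrame, summary="mean") -> pd.DataFrame:
    """Per-nucleus crowding: incident-edge-length summary / equivalent diameter.

    ``records`` must carry one row per graph node, in node order, with columns
    ``id`` and ``equivalent_diameter_um``. Nuclei with no Delaunay neighbours
    or missing diameters are flagged and carry NaN indices.
    """
    if len(records) != len(graph.points):
        raise ValueError(
            f"records ({len(records)}) and graph nodes ({len(graph.points)}) disagree"
        )
    mean_edge = graph.incident_lengths(summary=summary)
    diam = records["equivalent_diameter_um"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        index = mean_edge / diam
    return pd.DataFrame(
        {
            "id": records["id"].to_numpy(),
            "mean_edge_um": mean_edge,
            "equivalent_diameter_um": diam,
            "crowding_index": index,
            "flagged": ~np.isfinite(index),
            "edge_summary": summary,
        }
    )
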