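"""Pixel-space ROI geometry: polygons, annuli, and rasterization.

Conventions
-----------
* Coordinates are 0-based ``(row, col)`` floats; pixel centers sit at integer
  coordinates, so pixel ``(i, j)`` covers ``[i-0.5, i+0.5] x [j-0.5, j+0.5]``.
* A pixel belongs to a polygon iff its *center* is inside under the even-odd
  (crossing-number) rule; a center lying exactly on an edge is included.

The rasterization rule is the measurement primitive of this package: every
intensity quantity downstream (unit PS intensity, relative PS and Ca levels)
is a sum over the pixels this module selects, so the rule is implemented
explicitly here rather than delegated to a drawing library with an
unspecified boundary convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "Polygon",
    "AnnulusROI",
    "polygon_mask",
    "disk_polygon",
    "ring_annulus",
    "background_disk",
]

_EDGE_EPS = 1e-9


def _points_in_polygon(vertices: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Even-odd test for points ``(rows, cols)``; on-edge points count as inside."""
    inside = np.zeros(rows.shape, dtype=bool)
    on_edge = np.zeros(rows.shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        # crossing number against a ray cast in the +col direction
        straddles = (r1 > rows) != (r2 > rows)
        if r1 != r2:
            c_int = (c2 - c1) * (rows - r1) / (r2 - r1) + c1
            inside ^= straddles & (cols < c_int)
        # on-segment check: collinear and within the segment's bounding box
        cross = (r2 - r1) * (cols - c1) - (c2 - c1) * (rows - r1)
        seg_len = np.hypot(r2 - r1, c2 - c1)
        if seg_len > 0:
            near = np.abs(cross) <= _EDGE_EPS * max(seg_len, 1.0)
            within = (
                (rows >= min(r1, r2) - _EDGE_EPS)
                & (rows <= max(r1, r2) + _EDGE_EPS)
                & (cols >= min(c1, c2) - _EDGE_EPS)
                & (cols <= max(c1, c2) + _EDGE_EPS)
            )
            on_edge |= near & within
    return inside | on_edge


def polygon_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the pixels whose centers fall inside the polygon."""
    vertices = np.asarray(vertices, dtype=float)
    rmin = max(int(np.floor(vertices[:, 0].min())), 0)
    rmax = min(int(np.ceil(vertices[:, 0].max())), shape[0] - 1)
    cmin = max(int(np.floor(vertices[:, 1].min())), 0)
    cmax = min(int(np.ceil(vertices[:, 1].max())), shape[1] - 1)
    mask = np.zeros(shape, dtype=bool)
    if rmax < rmin or cmax < cmin:
        return mask
    rows, cols = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    mask[rmin : rmax + 1, cmin : cmax + 1] = _points_in_polygon(
        vertices, rows.astype(float), cols.astype(float)
    )
    return mask


@dataclass(frozen=True)
class Polygon:
    """A closed, simple polygon outlining a cell body or background region.

    Parameters
    ----------
    vertices : (n, 2) array-like
        Ordered ``(row, col)`` vertex coordinates; the outline closes back to
        the first vertex implicitly.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a polygon needs >= 3 (row, col) vertices")
        if not np.isfinite(v).all():
            raise ValueError("polygon vertices must be finite")
        shp = _ShapelyPolygon(v)
        if not shp.is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if shp.area <= 0:
            raise ValueError("polygon has zero area")
        object.__setattr__(self, "vertices", v)

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return polygon_mask(self.vertices, shape)

    def bounds(self) -> tuple[float, float, float, float]:
        v = self.vertices
        return v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max()

    def within_image(self, shape: tuple[int, int]) -> bool:
        rmin, cmin, rmax, cmax = self.bounds()
        return rmin >= -0.5 and cmin >= -0.5 and rmax <= shape[0] - 0.5 and cmax <= shape[1] - 0.5


@dataclass(frozen=True)
class AnnulusROI:
    """Donut region between two nested polygons (outer minus inner).

    Used for the membrane-bound PS reporter, which forms a ring at the cell
    boundary: the outer polygon hugs the outside of the ring, the inner one
    its inside. The inner polygon must lie strictly inside the outer;
    partially overlapping outlines are rejected rather than clipped.
    """

    outer: Polygon
    inner: Polygon

    def __post_init__(self) -> None:
        if not self.outer.shapely.contains(self.inner.shapely):
            raise ValueError("annulus inner polygon must lie strictly inside the outer polygon")

    def masks(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        return self.outer.mask(shape), self.inner.mask(shape)


def disk_polygon(center: tuple[float, float], radius: float, n_vertices: int = 64) -> Polygon:
    """Regular-polygon approximation of a disk of the given radius (pixels)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    rows = center[0] + radius * np.sin(theta)
    cols = center[1] + radius * np.cos(theta)
    return Polygon(np.column_stack([rows, cols]))


def ring_annulus(
    center: tuple[float, float], inner_radius: float, width: float, n_vertices: int = 96
) -> AnnulusROI:
    """Annulus ROI matched to a circular ring of known radii.

    For a ring occupying distances ``(inner_radius, inner_radius + width]``
    from the center, the inner polygon circumscribes the inner circle and
    the outer polygon is inscribed in the outer circle, so every pixel the
    annulus selects lies inside the true ring — boundary pixels carrying
    non-ring signal are excluded rather than diluted into the measurement.
    """
    inner = disk_polygon(center, inner_radius / np.cos(np.pi / n_vertices), n_vertices)
    outer = disk_polygon(center, inner_radius + width, n_vertices)
    return AnnulusROI(outer=outer, inner=inner)


def background_disk(
    reference: Polygon,
    offset: tuple[float, float],
    area_tol: float = 0.05,
    n_vertices: int = 64,
) -> Polygon:
    """Build a nearby background disk of (approximately) matched area.

    Background-relative quantification divides the signal in the cell ROI by
    the signal in an equal-area region nearby; this helper constructs that
    region as a disk whose area matches ``reference`` within ``area_tol``
    (relative), centered at the reference centroid plus ``offset``.
    """
    target = reference.shapely.area
    centroid = reference.shapely.centroid
    center = (centroid.x + offset[0], centroid.y + offset[1])
    # exact-area radius for the inscribed regular n-gon
    radius = np.sqrt(2.0 * target / (n_vertices * np.sin(2.0 * np.pi / n_vertices)))
    disk = disk_polygon(center, radius, n_vertices)
    rel_err = abs(disk.shapely.area - target) / target
    if rel_err > area_tol:
        raise ValueError(f"matched-area disk misses target area by {rel_err:.3f} (> {area_tol})")
    return disk
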