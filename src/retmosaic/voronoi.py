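"""Voronoi tessellation domain analysis.

Each location in the window is assigned to the domain of its nearest cell;
the spread of domain areas measures mosaic regularity.  The headline
statistic is the variance-to-mean ratio (VMR, µm²) of domain areas; the
dimensionless variance/mean² (CV²) is reported alongside, since the VMR
still carries units of area and is only density-controlling up to scale.
Cells whose domain touches the window boundary are excluded from the
statistic (their areas are truncated by the field of view); the exclusion
count is always reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, box

from .io import PointPattern

__all__ = ["VoronoiResult", "compute_domains", "domain_vmr"]

_BOUNDARY_TOL = 1e-9


@dataclass
class VoronoiResult:
    areas: np.ndarray        # µm², one per retained (interior) cell
    all_areas: np.ndarray    # µm², clipped areas of every cell (partition of window)
    n_excluded: int          # boundary-affected cells
    mean_area: float
    variance_area: float     # sample variance (n−1)
    vmr: float               # variance / mean, µm²
    cv2: float               # variance / mean², dimensionless


def compute_domains(pattern: PointPattern) -> VoronoiResult:
    """Planar Voronoi tessellation clipped to the window.

    Requires ≥ 3 non-collinear, duplicate-free points.  The clipped domains
    partition the window exactly; domains touching the border are excluded
    from the area statistics but included in ``all_areas``.
    """
    pts = pattern.points
    if len(pts) < 3:
        raise ValueError("Voronoi domain analysis needs at least 3 points")
    # duplicates collapse domains; collinear inputs have a degenerate diagram
    _, idx, counts = np.unique(pts, axis=0, return_index=True, return_counts=True)
    if (counts > 1).any():
        dup = pts[idx[counts > 1][0]]
        raise ValueError(f"duplicate points at {tuple(dup)}")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise ValueError("all points are collinear; tessellation is degenerate")

    window = box(*pattern.window)
    cells = shapely.voronoi_polygons(MultiPoint(pts), extend_to=window)
    clipped = [poly.intersection(window) for poly in cells.geoms]

    # map polygons back to their seed points (voronoi_polygons does not
    # preserve input order)
    tree = shapely.STRtree(clipped)
    areas = np.full(len(pts), np.nan)
    touches = np.zeros(len(pts), dtype=bool)
    boundary = window.exterior
    for i, p in enumerate(pts):
        seed = Point(p)
        for j in tree.query(seed, predicate="intersects"):
            if clipped[j].covers(seed):
                areas[i] = clipped[j].area
                touches[i] = clipped[j].distance(boundary) < _BOUNDARY_TOL
                break
    if np.isnan(areas).any():
        raise RuntimeError("failed to assign a Voronoi domain to every point")

    retained = areas[~touches]
    n_excluded = int(touches.sum())
    if len(retained) >= 2:
        mean = float(retained.mean())
        var = float(retained.var(ddof=1))
        vmr = var / mean
        cv2 = var / mean**2
    elif len(retained) == 1:
        mean, var, vmr, cv2 = float(retained[0]), np.nan, np.nan, np.nan
    else:
        mean = var = vmr = cv2 = np.nan
    return VoronoiResult(
        areas=retained,
        all_areas=areas,
        n_excluded=n_excluded,
        mean_area=mean,
        variance_area=var,
        vmr=vmr,
        cv2=cv2,
    )


def domain_vmr(result: VoronoiResult) -> float:
    """Variance-to-mean ratio of the retained domain areas (µm²)."""
    if len(result.areas) < 2:
        raise ValueError("VMR needs at least 2 interior domains")
    return result.vmr
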