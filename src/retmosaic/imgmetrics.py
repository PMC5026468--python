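"""Threshold-based area, two-channel overlap, and line-profile measurements.

These reproduce the three image measurements used to grade projection and
protein-level phenotypes on already-projected 2D images: percent area above
each of several intensity thresholds, the overlap-to-marker area ratio for
two thresholded channels (mask intersection, the deterministic equivalent of
a threshold-and-multiply colocalization workflow), and the mean fluorescence
along a short line segment (default use case: a 10 µm line projecting into
the IPL perpendicular to the INL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .io import IntensityImage

__all__ = [
    "ThresholdAreaResult",
    "percent_area_above",
    "overlap_ratio",
    "line_profile_mean",
]


@dataclass
class ThresholdAreaResult:
    thresholds: tuple[float, ...]
    percent_area: tuple[float, ...]   # % of pixels strictly above each threshold
    pixel_counts: tuple[int, ...]


def percent_area_above(image: IntensityImage, thresholds) -> ThresholdAreaResult:
    """Percent of pixels strictly above each threshold (single channel).

    A pure histogram statistic: invariant under pixel permutation, and
    non-increasing as the threshold rises.
    """
    if image.n_channels != 1:
        raise ValueError("percent_area_above expects a single-channel image")
    px = image.pixels
    if px.size == 0:
        raise ValueError("empty image")
    thresholds = tuple(float(t) for t in np.atleast_1d(thresholds))
    counts = tuple(int((px > t).sum()) for t in thresholds)
    percent = tuple(100.0 * c / px.size for c in counts)
    return ThresholdAreaResult(thresholds=thresholds, percent_area=percent,
                               pixel_counts=counts)


def overlap_ratio(image: IntensityImage, t_a: float, t_b: float) -> float:
    """Ratio of the two-channel overlap area to the channel-b (marker) area.

    Masks are pixels strictly above ``t_a`` (channel 0, the reference stain)
    and ``t_b`` (channel 1, the marker); the returned fraction is
    |mask_a ∧ mask_b| / |mask_b|.  Swapping the channels changes the
    denominator — the ratio is deliberately asymmetric.
    """
    if image.n_channels != 2:
        raise ValueError("overlap_ratio expects a two-channel image")
    mask_a = image.channel(0) > t_a
    mask_b = image.channel(1) > t_b
    n_b = int(mask_b.sum())
    if n_b == 0:
        raise ValueError("marker mask is empty; overlap ratio undefined")
    return float((mask_a & mask_b).sum()) / n_b


def line_profile_mean(
    image: IntensityImage,
    start: tuple[float, float],
    direction: tuple[float, float],
    length: float = 10.0,
    channel: int = 0,
) -> float:
    """Mean intensity along a line segment, sampled at pixel pitch.

    ``start`` is (x, y) in µm with x along columns and y along rows (pixel
    centres at integer pixel coordinates); ``direction`` is normalized
    internally; ``length`` is in µm.  Intensities are sampled every
    ``image.scale`` µm (endpoints inclusive) with bilinear interpolation.
    The whole segment must lie inside the image.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    d = np.asarray(direction, dtype=float)
    norm = np.hypot(*d)
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    d = d / norm
    start = np.asarray(start, dtype=float)

    n_steps = max(1, int(round(length / image.scale)))
    t = np.linspace(0.0, length, n_steps + 1)
    xy = start[None, :] + t[:, None] * d[None, :]
    colrow = xy / image.scale  # µm -> pixel coordinates

    px = image.channel(channel)
    n_rows, n_cols = px.shape
    cols, rows_f = colrow[:, 0], colrow[:, 1]
    eps = 1e-9
    if (cols.min() < -eps or rows_f.min() < -eps
            or cols.max() > n_cols - 1 + eps or rows_f.max() > n_rows - 1 + eps):
        raise ValueError("line segment exits the image")
    samples = map_coordinates(px, [rows_f, cols], order=1, mode="nearest")
    return float(samples.mean())
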