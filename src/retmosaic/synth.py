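"""Synthetic point patterns, rater-choice logs and test images.

These generators emulate the three spatial regimes a retinal mosaic analysis
must distinguish — exclusion-zone (mosaic), uniform random, and clustered
arrangements — plus latent-quality-driven forced-choice rater behaviour and
thresholdable images with known area fractions.  Every generator is
deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .io import ComparisonRecord, IntensityImage, PointPattern

__all__ = [
    "gen_random",
    "gen_hex_lattice",
    "gen_dmin",
    "gen_clustered",
    "gen_comparisons",
    "gen_test_image",
]

Window = tuple[float, float, float, float]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_random(n: int, window: Window, seed=0, **meta) -> PointPattern:
    """``n`` points i.i.d. uniform on the window (binomial point process)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = _rng(seed)
    x0, y0, x1, y1 = window
    pts = rng.uniform((x0, y0), (x1, y1), size=(n, 2))
    return PointPattern(points=pts, window=window, **meta)


def gen_hex_lattice(
    spacing: float, window: Window, jitter_sd: float = 0.0, seed=0, **meta
) -> PointPattern:
    """Triangular lattice clipped to the window, with optional Gaussian jitter.

    With ``jitter_sd=0`` every interior point's nearest neighbour sits at
    exactly ``spacing``; the lattice density is 2/(√3·spacing²).  Jittered
    points are clipped back to the window.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = _rng(seed)
    x0, y0, x1, y1 = window
    row_h = spacing * np.sqrt(3.0) / 2.0
    rows = np.arange(y0, y1 + 1e-9, row_h)
    pts = []
    for i, y in enumerate(rows):
        offset = 0.0 if i % 2 == 0 else spacing / 2.0
        xs = np.arange(x0 + offset, x1 + 1e-9, spacing)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    pts = np.concatenate(pts) if pts else np.empty((0, 2))
    if jitter_sd > 0 and len(pts):
        pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
        pts[:, 0] = np.clip(pts[:, 0], x0, x1)
        pts[:, 1] = np.clip(pts[:, 1], y0, y1)
    if len(pts) < 3:
        import warnings

        warnings.warn(
            f"spacing {spacing} yields only {len(pts)} lattice points in the window",
            stacklevel=2,
        )
    return PointPattern(points=pts, window=window, **meta)


def gen_dmin(
    n: int,
    window: Window,
    dmin: float,
    seed=0,
    max_tries: int | None = None,
    **meta,
) -> PointPattern:
    """Simple sequential inhibition: uniform candidates accepted only when at
    least ``dmin`` from every previously accepted point.

    This is the minimal process with the exclusion-zone signature the density
    recovery profile detects: all bins below ``dmin`` are empty.  Raises if
    ``max_tries`` candidates (default ``10**5 * n``) are exhausted before
    ``n`` acceptances, reporting the count achieved.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if dmin < 0:
        raise ValueError("dmin must be non-negative")
    rng = _rng(seed)
    x0, y0, x1, y1 = window
    if max_tries is None:
        max_tries = 100_000 * max(n, 1)
    accepted = np.empty((n, 2))
    count = 0
    tries = 0
    d2 = dmin * dmin
    while count < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"sequential inhibition infeasible: accepted {count}/{n} points "
                f"after {tries} candidates (dmin={dmin})"
            )
        cand = rng.uniform((x0, y0), (x1, y1))
        tries += 1
        if count == 0 or (((accepted[:count] - cand) ** 2).sum(axis=1) >= d2).all():
            accepted[count] = cand
            count += 1
    return PointPattern(points=accepted, window=window, **meta)


def gen_clustered(
    n_parents: int,
    offspring_mean: float,
    cluster_sd: float,
    window: Window,
    seed=0,
    **meta,
) -> PointPattern:
    """Neyman–Scott process: uniform parents, Poisson(offspring_mean)
    offspring per parent displaced by an isotropic Gaussian(cluster_sd),
    clipped to the window.  Parents themselves are not retained."""
    if n_parents <= 0 or offspring_mean <= 0 or cluster_sd < 0:
        raise ValueError("parameters must be positive (cluster_sd may be 0)")
    rng = _rng(seed)
    x0, y0, x1, y1 = window
    parents = rng.uniform((x0, y0), (x1, y1), size=(n_parents, 2))
    counts = rng.poisson(offspring_mean, size=n_parents)
    pts = np.repeat(parents, counts, axis=0)
    if len(pts):
        pts = pts + rng.normal(0.0, cluster_sd, size=pts.shape)
        pts[:, 0] = np.clip(pts[:, 0], x0, x1)
        pts[:, 1] = np.clip(pts[:, 1], y0, y1)
    return PointPattern(points=pts, window=window, **meta)


def gen_comparisons(
    latent_scores: dict[str, float],
    n_matchups: int,
    n_raters: int = 6,
    noise_scale: float = 1.0,
    seed=0,
) -> list[ComparisonRecord]:
    """Simulate forced-choice matchups under a Bradley–Terry model.

    Pairs of distinct images are drawn uniformly; image *a* beats *b* with
    probability 1/(1+exp(−(q_a−q_b)/noise_scale)).  ``noise_scale → 0``
    makes the higher-latent image win deterministically.  Rater ids are
    assigned round-robin.
    """
    ids = list(latent_scores)
    if len(ids) < 2:
        raise ValueError("need at least 2 images to compare")
    if n_matchups < 1:
        raise ValueError("n_matchups must be >= 1")
    rng = _rng(seed)
    q = np.array([latent_scores[i] for i in ids], dtype=float)
    records = []
    for m in range(n_matchups):
        ia, ib = rng.choice(len(ids), size=2, replace=False)
        gap = q[ia] - q[ib]
        if noise_scale <= 0:
            p_a = 0.5 if gap == 0 else float(gap > 0)
        else:
            p_a = 1.0 / (1.0 + np.exp(-gap / noise_scale))
        winner = ids[ia] if rng.random() < p_a else ids[ib]
        records.append(
            ComparisonRecord(
                image_a=ids[ia],
                image_b=ids[ib],
                winner=winner,
                rater=f"rater{m % n_raters}",
            )
        )
    return records


def gen_test_image(
    shape: tuple[int, int],
    target_fraction: float,
    overlap_fraction: float | None = None,
    seed=0,
    scale: float = 1.0,
    foreground: float = 255.0,
) -> tuple[IntensityImage, dict]:
    """Binary-valued image(s) with an exactly known foreground fraction.

    Single channel (``overlap_fraction is None``): exactly
    ``round(target_fraction · n_pixels)`` pixels at ``foreground``, rest 0.

    Two channels: channel 1 plays the reference (stain of interest), channel
    2 the marker; channel 2 has ``round(target_fraction · n_pixels)``
    foreground pixels of which ``round(overlap_fraction · |ch2|)`` are also
    foreground in channel 1.  Channel 1 additionally gets the same number of
    foreground pixels outside channel 2 when space allows, so the masks are
    asymmetric.  Returns the image plus a ground-truth dict.
    """
    if not 0 <= target_fraction <= 1:
        raise ValueError("target_fraction must be in [0, 1]")
    if overlap_fraction is not None and not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = _rng(seed)
    rows, cols = shape
    n_pix = rows * cols
    order = rng.permutation(n_pix)
    n_fg = round(target_fraction * n_pix)

    if overlap_fraction is None:
        img = np.zeros(n_pix)
        img[order[:n_fg]] = foreground
        truth = {"target_fraction": n_fg / n_pix, "n_foreground": n_fg}
        return IntensityImage(pixels=img.reshape(shape), scale=scale), truth

    n_overlap = round(overlap_fraction * n_fg)
    ch2 = np.zeros(n_pix)
    ch2[order[:n_fg]] = foreground
    ch1 = np.zeros(n_pix)
    ch1[order[:n_overlap]] = foreground  # inside ch2
    n_outside = min(n_fg, n_pix - n_fg)
    ch1[order[n_fg : n_fg + n_outside]] = foreground  # outside ch2
    img = np.stack([ch1.reshape(shape), ch2.reshape(shape)])
    truth = {
        "target_fraction": n_fg / n_pix,
        "overlap_fraction": (n_overlap / n_fg) if n_fg else 0.0,
        "n_ch2_foreground": n_fg,
        "n_overlap": n_overlap,
    }
    return IntensityImage(pixels=img, scale=scale), truth
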