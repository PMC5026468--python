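"""Input/output and core domain containers.

Coordinate tables follow the ImageJ export convention: origin at the top-left
of the image, x increasing rightward, y increasing downward.  All geometry in
this package is orientation-agnostic, so the convention only matters for
plotting.  Internally every length is in micrometres; pixel-unit inputs are
converted once at read time via the ``scale`` argument.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PointPattern",
    "IntensityImage",
    "ComparisonRecord",
    "GROUP_TABLE_COLUMNS",
    "validate_group_table",
    "read_points_table",
    "read_comparisons",
    "read_image",
    "write_results",
    "read_results",
]

#: Canonical column order of a group table: one row per retina per metric.
GROUP_TABLE_COLUMNS = ("retina_id", "genotype", "metric_name", "value")


@dataclass(frozen=True)
class PointPattern:
    """Cell-body positions inside a rectangular observation window.

    Parameters
    ----------
    points
        ``(n, 2)`` array of (x, y) positions in µm.
    window
        ``(x_min, y_min, x_max, y_max)`` in µm; must have positive width
        and height, and contain every point (boundary included).
    image_id, retina_id, genotype
        Metadata labels carried through to group-level statistics.
    """

    points: np.ndarray
    window: tuple[float, float, float, float]
    image_id: str = ""
    retina_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        x0, y0, x1, y1 = (float(v) for v in self.window)
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"window must have positive extent, got {self.window}")
        object.__setattr__(self, "window", (x0, y0, x1, y1))
        if pts.size and not np.isfinite(pts).all():
            raise ValueError("non-finite coordinates in point pattern")
        if pts.size:
            inside = (
                (pts[:, 0] >= x0) & (pts[:, 0] <= x1)
                & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
            )
            if not inside.all():
                bad = int(np.flatnonzero(~inside)[0])
                raise ValueError(
                    f"point {bad} at {tuple(pts[bad])} lies outside window {self.window}"
                )

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def window_area(self) -> float:
        x0, y0, x1, y1 = self.window
        return (x1 - x0) * (y1 - y0)

    def rescaled(self, factor: float) -> "PointPattern":
        """Uniformly rescale coordinates and window by ``factor``."""
        x0, y0, x1, y1 = self.window
        return dataclasses.replace(
            self,
            points=self.points * factor,
            window=(x0 * factor, y0 * factor, x1 * factor, y1 * factor),
        )


@dataclass(frozen=True)
class IntensityImage:
    """One- or two-channel non-negative intensity grid with a pixel scale.

    ``pixels`` has shape ``(rows, cols)`` for a single channel or
    ``(2, rows, cols)`` for two channels.  ``scale`` is µm per pixel.
    """

    pixels: np.ndarray
    scale: float = 1.0
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            pass
        elif px.ndim == 3 and px.shape[0] in (1, 2):
            if px.shape[0] == 1:
                px = px[0]
        else:
            raise ValueError(
                f"expected (rows, cols) or (2, rows, cols) pixels, got shape {px.shape}"
            )
        if not np.isfinite(px).all():
            raise ValueError("non-finite pixel intensities")
        if (px < 0).any():
            raise ValueError("negative pixel intensities")
        if not self.scale > 0:
            raise ValueError("scale must be positive (µm per pixel)")
        object.__setattr__(self, "pixels", px)
        names = tuple(self.channel_names) or tuple(
            f"ch{i}" for i in range(self.n_channels_of(px))
        )
        object.__setattr__(self, "channel_names", names)

    @staticmethod
    def n_channels_of(px: np.ndarray) -> int:
        return 1 if px.ndim == 2 else px.shape[0]

    @property
    def n_channels(self) -> int:
        return self.n_channels_of(self.pixels)

    def channel(self, i: int) -> np.ndarray:
        if self.n_channels == 1:
            if i != 0:
                raise IndexError("single-channel image")
            return self.pixels
        return self.pixels[i]


@dataclass(frozen=True)
class ComparisonRecord:
    """One forced-choice matchup between two images by one rater."""

    image_a: str
    image_b: str
    winner: str
    rater: str = ""

    def __post_init__(self) -> None:
        if self.image_a == self.image_b:
            raise ValueError(f"self-comparison: {self.image_a!r} vs itself")
        if self.winner not in (self.image_a, self.image_b):
            raise ValueError(
                f"winner {self.winner!r} is neither {self.image_a!r} nor {self.image_b!r}"
            )


def validate_group_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the group-table contract: required columns, finite values,
    one row per (retina, metric).  Returns the table with canonical columns
    first."""
    missing = [c for c in GROUP_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"group table missing columns: {missing}")
    if len(table) and not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValueError("group table contains non-finite values")
    dup = table.duplicated(subset=["retina_id", "metric_name"])
    if dup.any():
        pair = table.loc[dup.idxmax(), ["retina_id", "metric_name"]].tolist()
        raise ValueError(f"duplicate (retina, metric) row: {pair}")
    rest = [c for c in table.columns if c not in GROUP_TABLE_COLUMNS]
    return table[list(GROUP_TABLE_COLUMNS) + rest]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def read_points_table(
    path: str | Path,
    scale: float = 1.0,
    metadata: Mapping[str, Mapping[str, object]] | None = None,
) -> list[PointPattern]:
    """Read an ImageJ-style XY table into one :class:`PointPattern` per image.

    The file must contain ``x`` and ``y`` columns (case-insensitive; extra
    columns such as ``Slice`` are ignored).  Coordinates are multiplied by
    ``scale`` (µm per pixel).  An optional ``image_id`` column splits rows
    into several patterns; otherwise the file is a single image named after
    ``metadata`` or the file stem.

    ``metadata`` maps image_id to a dict with optional keys ``retina_id``,
    ``genotype`` and ``window`` (``(x_min, y_min, x_max, y_max)`` in µm).
    Without a declared window the tight bounding box of the points is used
    and a warning is emitted, because edge correction depends on it.
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    df = _read_table(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ValueError(f"{path}: table must contain x and y columns, has {list(df.columns)}")
    for axis in ("x", "y"):
        raw = pd.to_numeric(df[cols[axis]], errors="coerce")
        bad = raw.isna() & df[cols[axis]].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"{path}: non-numeric {axis} coordinate in data row {row}")
        df[cols[axis]] = raw
    metadata = metadata or {}

    if "image_id" in cols:
        groups = [(str(k), g) for k, g in df.groupby(df[cols["image_id"]].astype(str), sort=False)]
    else:
        default_id = next(iter(metadata), Path(path).stem)
        groups = [(str(default_id), df)]

    patterns = []
    for image_id, sub in groups:
        pts = sub[[cols["x"], cols["y"]]].dropna().to_numpy(dtype=float) * scale
        meta = dict(metadata.get(image_id, {}))
        window = meta.get("window")
        if window is None:
            if len(pts):
                x0, y0 = pts.min(axis=0)
                x1, y1 = pts.max(axis=0)
            else:
                x0 = y0 = 0.0
                x1 = y1 = 1.0
            if x1 <= x0:
                x1 = x0 + 1.0
            if y1 <= y0:
                y1 = y0 + 1.0
            window = (x0, y0, x1, y1)
            warnings.warn(
                f"{image_id}: no window declared; using the bounding box of the "
                "points — edge correction near the border will be approximate",
                stacklevel=2,
            )
            logger.warning("%s: window defaulted to point bounding box %s", image_id, window)
        patterns.append(
            PointPattern(
                points=pts,
                window=tuple(float(v) for v in window),
                image_id=image_id,
                retina_id=str(meta.get("retina_id", "")),
                genotype=str(meta.get("genotype", "")),
            )
        )
    return patterns


def read_comparisons(path: str | Path) -> list[ComparisonRecord]:
    """Read a pairwise-comparison log CSV (image_a, image_b, winner, rater)."""
    df = _read_table(path)
    required = {"image_a", "image_b", "winner"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: comparison log needs columns {sorted(required)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ComparisonRecord(
                    image_a=str(row["image_a"]),
                    image_b=str(row["image_b"]),
                    winner=str(row["winner"]),
                    rater=str(row.get("rater", "")),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return records


def read_image(path: str | Path, scale: float = 1.0) -> IntensityImage:
    """Read an 8/16-bit grayscale TIFF or PNG (1 or 2 channels)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (1, 2) and arr.shape[0] not in (1, 2):
        arr = np.moveaxis(arr, -1, 0)  # (rows, cols, ch) -> (ch, rows, cols)
    return IntensityImage(pixels=arr, scale=scale)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

class _ResultEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_results(obj, path: str | Path) -> Path:
    """Write a DataFrame as CSV or any (possibly nested) result as JSON.

    Tables round-trip losslessly through :func:`read_results`; dataclass
    results (e.g. a DRP result) serialize with all array fields as lists.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            json.dump(obj, fh, cls=_ResultEncoder, indent=2)
            fh.write("\n")
    return path


def read_results(path: str | Path):
    """Inverse of :func:`write_results` (CSV → DataFrame, JSON → dict/list)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    with open(path) as fh:
        return json.load(fh)
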