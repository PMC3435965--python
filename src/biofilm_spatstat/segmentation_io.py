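"""Micrograph segmentation and per-cell feature extraction.

Reads 8-bit grayscale or RGB micrographs with a spatial calibration
(um/pixel), segments foreground cells (intensity threshold or red/green
color dominance), labels connected objects and extracts one record per cell:
centroid in a Cartesian frame whose origin is the image's lower-left corner,
area (um^2), pixel count, channel tag and mean 8-bit luminosity.

Coordinate convention: pixel centers sit at (col + 0.5, row + 0.5); the
Cartesian y coordinate is (image_height_px - row_center) * calibration so
that y increases upward from the lower-left origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

from .point_pattern import PointPattern

__all__ = [
    "CalibratedImage",
    "ObjectTable",
    "read_image",
    "write_label_image",
    "segment_binary",
    "segment_color",
    "extract_objects",
    "read_object_csv",
    "write_object_csv",
]

OBJECT_COLUMNS = ["id", "x_um", "y_um", "area_um2", "pixel_count",
                  "channel", "mean_luminosity"]


@dataclass(frozen=True)
class CalibratedImage:
    """8-bit image plus its spatial calibration in um per pixel."""

    pixels: np.ndarray  # (H, W) grayscale or (H, W, 3) RGB, uint8 range
    calibration: float
    name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError("pixels must be (H, W) grayscale or (H, W, 3) RGB")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        if not self.calibration > 0:
            raise ValueError("calibration (um/pixel) must be positive")

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def window_um(self) -> tuple[float, float]:
        h, w = self.shape_px
        return w * self.calibration, h * self.calibration


@dataclass
class ObjectTable:
    """Per-cell records with the observation window they came from.

    ``df`` has columns id, x_um, y_um, area_um2, pixel_count, channel,
    mean_luminosity (area/pixel_count/luminosity may be NaN for coordinate
    tables read from plain CSVs).
    """

    df: pd.DataFrame
    window: tuple[float, float]
    source_image: str = ""

    def __post_init__(self) -> None:
        for col in ("id", "x_um", "y_um"):
            if col not in self.df.columns:
                raise ValueError(f"object table is missing column {col!r}")
        for col in OBJECT_COLUMNS:
            if col not in self.df.columns:
                self.df[col] = np.nan
        self.df = self.df[OBJECT_COLUMNS].reset_index(drop=True)
        if self.df["id"].duplicated().any():
            raise ValueError("object ids must be unique")

    def __len__(self) -> int:
        return len(self.df)

    def to_point_pattern(self) -> PointPattern:
        return PointPattern(self.df[["x_um", "y_um"]].to_numpy(float),
                            self.window)


def read_image(path: str | Path, calibration: float,
               name: str | None = None) -> CalibratedImage:
    """Read a TIFF/PNG micrograph (8-bit gray or RGB; alpha dropped)."""
    import imageio.v3 as iio

    px = np.asarray(iio.imread(path))
    if px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    if px.dtype != np.uint8:
        if px.max() > 255:
            px = (px.astype(float) / px.max() * 255).round()
        px = px.astype(np.uint8)
    return CalibratedImage(px, calibration, name or Path(path).stem)


def write_label_image(labels: np.ndarray, path: str | Path) -> None:
    """Write a label image as 16-bit TIFF."""
    import tifffile

    tifffile.imwrite(str(path), labels.astype(np.uint16))


def _label_mask(mask: np.ndarray, min_pixels: int,
                connectivity: int) -> np.ndarray:
    if not mask.any():
        warnings.warn("empty foreground: no objects segmented", stacklevel=3)
        return np.zeros(mask.shape, dtype=np.int32)
    labels = measure.label(mask, connectivity=connectivity)
    if min_pixels > 1:
        counts = np.bincount(labels.ravel())
        keep = counts >= min_pixels
        keep[0] = False
        labels = measure.label(keep[labels], connectivity=connectivity)
    if labels.max() == 0:
        warnings.warn("empty foreground after size filtering", stacklevel=3)
    return labels.astype(np.int32)


def segment_binary(img: CalibratedImage, threshold: float | str = "otsu",
                   min_pixels: int = 5, connectivity: int = 2) -> np.ndarray:
    """Threshold a grayscale micrograph and label connected cells.

    ``threshold`` is an intensity in [0, 255] or "otsu"; pixels strictly
    above it are foreground.  Components smaller than ``min_pixels`` are
    discarded (debris filter).  ``connectivity`` 1 = 4-neighborhood,
    2 = 8-neighborhood (default: bacterial cells are compact).
    Returns a label image with objects 1..K; an empty foreground yields an
    all-zero labeling with a warning, not a failure.
    """
    if img.is_rgb:
        raise ValueError("segment_binary requires a grayscale image")
    px = img.pixels
    if threshold == "otsu":
        if px.min() == px.max():
            warnings.warn("constant image: empty foreground", stacklevel=2)
            return np.zeros(px.shape, dtype=np.int32)
        thr = threshold_otsu(px)
    else:
        thr = float(threshold)
    return _label_mask(px > thr, min_pixels, connectivity)


def segment_color(img: CalibratedImage, channel: str, margin: int = 30,
                  min_pixels: int = 5, connectivity: int = 2) -> np.ndarray:
    """Segment the red or green reporter channel of an RGB micrograph.

    A pixel belongs to a channel when that plane dominates both others by
    at least ``margin`` intensity levels (dominance rule).  Labeling and
    size filtering as in :func:`segment_binary`.
    """
    if not img.is_rgb:
        raise ValueError("color segmentation requires RGB")
    planes = {"red": 0, "green": 1}
    if channel not in planes:
        raise ValueError(f"channel must be 'red' or 'green', got {channel!r}")
    k = planes[channel]
    px = img.pixels.astype(np.int16)
    others = np.max(np.delete(px, k, axis=2), axis=2)
    mask = (px[:, :, k] - others) >= margin
    return _label_mask(mask, min_pixels, connectivity)


def extract_objects(labels: np.ndarray, img: CalibratedImage,
                    channel: str = "fg") -> ObjectTable:
    """Extract one record per labeled object.

    Centroids are arithmetic means of member pixel centers, converted to um
    in the lower-left-origin frame; mean luminosity is taken from the plane
    named by ``channel`` ("fg" = the grayscale image itself or the RGB
    luminance, "red"/"green" = that plane).
    """
    if labels.shape != img.shape_px:
        raise ValueError("label image does not align with the micrograph")
    if channel == "fg":
        if img.is_rgb:
            intensity = np.round(img.pixels.astype(float).mean(axis=2))
        else:
            intensity = img.pixels.astype(float)
    elif channel in ("red", "green"):
        if not img.is_rgb:
            raise ValueError(f"channel {channel!r} requires an RGB image")
        intensity = img.pixels[:, :, 0 if channel == "red" else 1].astype(float)
    else:
        raise ValueError(f"unknown channel {channel!r}")

    h_px = img.shape_px[0]
    cal = img.calibration
    rows = []
    for i, prop in enumerate(measure.regionprops(labels,
                                                 intensity_image=intensity),
                             start=1):
        r_c, c_c = prop.centroid  # pixel-index coordinates
        x_um = (c_c + 0.5) * cal
        y_um = (h_px - (r_c + 0.5)) * cal
        rows.append({
            "id": i,
            "x_um": x_um,
            "y_um": y_um,
            "area_um2": prop.area * cal ** 2,
            "pixel_count": int(prop.area),
            "channel": channel,
            "mean_luminosity": float(prop.intensity_mean),
        })
    df = pd.DataFrame(rows, columns=OBJECT_COLUMNS)
    return ObjectTable(df, window=img.window_um, source_image=img.name)


def write_object_csv(table: ObjectTable, path: str | Path) -> None:
    """Write an object table to CSV (full precision round trip)."""
    table.df.to_csv(path, index=False, float_format="%.17g")


def read_object_csv(path: str | Path,
                    window: tuple[float, float] | None = None) -> ObjectTable:
    """Read an object table CSV (header ``id,x_um,y_um[,...]``).

    When ``window`` is not given, it is inferred as the ceiling of the
    maximum coordinates.  Missing coordinate columns and non-numeric
    coordinates raise informative errors.
    """
    df = pd.read_csv(path)
    for col in ("x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header = row 1
            raise ValueError(
                f"non-numeric value in column {col!r} at row {row} of {path}")
        df[col] = coerced
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(1, len(df) + 1))
    if window is None:
        if len(df):
            window = (float(np.ceil(df["x_um"].max())) or 1.0,
                      float(np.ceil(df["y_um"].max())) or 1.0)
        else:
            window = (1.0, 1.0)
    return ObjectTable(df, window=window, source_image=str(path))
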