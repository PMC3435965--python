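"""Dual-reporter analysis of cell-to-cell communication.

Source cells (red fluorescent) produce a diffusible signal (e.g. an
N-acylhomoserine lactone); sensor cells (green fluorescent) respond by
expressing GFP.  The analysis measures, for every sensor cell, the
"calling distance" — the shortest in-situ distance to its nearest source
cell — and the per-cell mean luminosity of the expression response, then
summarizes both as frequency distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .segmentation_io import CalibratedImage, ObjectTable

__all__ = [
    "calling_distances",
    "calling_summary",
    "expression_histogram",
    "apply_roi_mask",
]

CALLING_COLUMNS = ["sensor_id", "source_id", "calling_distance_um",
                   "sensor_mean_luminosity"]


def apply_roi_mask(table: ObjectTable, roi_mask: np.ndarray,
                   calibration: float) -> ObjectTable:
    """Drop objects whose centroid falls outside a binary ROI mask.

    The mask is in pixel space (row-major, same orientation as the source
    image); it excludes manually flagged regions such as root hairs or
    cells off the optical section.
    """
    mask = np.asarray(roi_mask).astype(bool)
    n_rows = mask.shape[0]
    cols = np.floor(table.df["x_um"].to_numpy() / calibration).astype(int)
    rows = np.floor(n_rows - table.df["y_um"].to_numpy() / calibration
                    ).astype(int)
    cols = np.clip(cols, 0, mask.shape[1] - 1)
    rows = np.clip(rows, 0, n_rows - 1)
    keep = mask[rows, cols]
    return ObjectTable(table.df[keep].copy(), window=table.window,
                       source_image=table.source_image)


def calling_distances(sources: ObjectTable, sensors: ObjectTable,
                      mode: str = "centroid",
                      roi_mask: np.ndarray | None = None,
                      calibration: float | None = None,
                      source_labels: np.ndarray | None = None,
                      sensor_labels: np.ndarray | None = None
                      ) -> pd.DataFrame:
    """Nearest-source calling distance for every sensor cell.

    ``mode="centroid"`` (default) measures centroid-to-centroid distances;
    ``mode="boundary"`` measures minimum pixel-to-pixel distances and
    requires the source/sensor label images plus the calibration.  An ROI
    mask, when given, excludes objects from both tables before matching.
    Returns a DataFrame with columns sensor_id, source_id,
    calling_distance_um, sensor_mean_luminosity.
    """
    if roi_mask is not None:
        if calibration is None:
            raise ValueError("roi_mask requires the calibration (um/px)")
        sources = apply_roi_mask(sources, roi_mask, calibration)
        sensors = apply_roi_mask(sensors, roi_mask, calibration)
    if len(sources) == 0:
        raise ValueError("no source cells")
    if len(sensors) == 0:
        return pd.DataFrame(columns=CALLING_COLUMNS)

    if mode == "centroid":
        src_xy = sources.df[["x_um", "y_um"]].to_numpy(float)
        sen_xy = sensors.df[["x_um", "y_um"]].to_numpy(float)
        tree = cKDTree(src_xy)
        dist, idx = tree.query(sen_xy, k=1)
        source_ids = sources.df["id"].to_numpy()[idx]
    elif mode == "boundary":
        if source_labels is None or sensor_labels is None or calibration is None:
            raise ValueError(
                "boundary mode requires source_labels, sensor_labels and "
                "calibration")
        from scipy import ndimage

        edt, (ri, ci) = ndimage.distance_transform_edt(
            source_labels == 0, return_indices=True)
        dist = np.empty(len(sensors))
        source_ids = np.empty(len(sensors), dtype=sources.df["id"].dtype)
        for j, sensor_id in enumerate(sensors.df["id"]):
            pix = sensor_labels == _label_of(sensors, sensor_id)
            if not pix.any():
                raise ValueError(f"sensor {sensor_id} not found in labels")
            d_here = edt[pix]
            k = int(np.argmin(d_here))
            rows, cols = np.nonzero(pix)
            dist[j] = d_here[k] * calibration
            nearest_label = source_labels[ri[rows[k], cols[k]],
                                          ci[rows[k], cols[k]]]
            source_ids[j] = _id_of(sources, nearest_label)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return pd.DataFrame({
        "sensor_id": sensors.df["id"].to_numpy(),
        "source_id": source_ids,
        "calling_distance_um": np.asarray(dist, dtype=float),
        "sensor_mean_luminosity": sensors.df["mean_luminosity"].to_numpy(),
    })


def _label_of(table: ObjectTable, obj_id) -> int:
    # ids assigned by extract_objects enumerate labels 1..K in order
    return int(obj_id)


def _id_of(table: ObjectTable, label: int):
    return table.df["id"].iloc[int(label) - 1]


def calling_summary(records: pd.DataFrame, bin_width: float = 1.0) -> dict:
    """Frequency distribution of calling distances.

    1-um bins by default; reports the bin edges, counts, the modal bin and
    the maximum distance.  Counts sum to the number of sensors.
    """
    if len(records) == 0:
        raise ValueError("need at least one calling record")
    d = records["calling_distance_um"].to_numpy(float)
    top = float(np.ceil(max(d.max(), bin_width) / bin_width)) * bin_width
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    mode_i = int(np.argmax(counts))
    return {
        "bin_edges_um": edges,
        "counts": counts,
        "mode_bin_um": (float(edges[mode_i]), float(edges[mode_i + 1])),
        "max_distance_um": float(d.max()),
        "n_sensors": int(len(d)),
    }


def expression_histogram(sensors: ObjectTable, bin_width: float = 16.0
                         ) -> dict:
    """Histogram of per-sensor mean luminosity over the 8-bit range.

    Reports counts per bin over [0, 256), the number of occupied (non-empty)
    bins, and the luminosity of local maxima after 3-bin moving-average
    smoothing (modality flags for multi-modal expression).
    """
    lum = sensors.df["mean_luminosity"].to_numpy(float)
    if np.isnan(lum).any():
        raise ValueError("sensors must have mean_luminosity populated")
    edges = np.arange(0.0, 256.0 + bin_width / 2, bin_width)
    if edges[-1] < 256.0:
        edges = np.append(edges, 256.0)
    counts, _ = np.histogram(lum, bins=edges)
    occupied = int(np.sum(counts > 0))
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    is_peak = np.zeros(len(counts), dtype=bool)
    for i in range(len(counts)):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < len(counts) - 1 else -np.inf
        is_peak[i] = smooth[i] > 0 and smooth[i] >= left and smooth[i] > right
    return {
        "bin_edges": edges,
        "counts": counts,
        "occupied_bins": occupied,
        "peak_bins": np.flatnonzero(is_peak),
        "n_sensors": int(len(lum)),
    }
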