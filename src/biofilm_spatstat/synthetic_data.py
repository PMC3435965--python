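"""Ground-truthed synthetic scenes for every analysis stage.

Generators for the three canonical point-process conditions — complete
spatial randomness (homogeneous Poisson), aggregation (Thomas cluster
process) and regularity (hard-core inhibition) — plus renderers that turn
point patterns into binary "biofilm" micrographs of disk-shaped cells and
two-channel (red source / green sensor) communication scenes in which
sensor luminosity decays exponentially with distance to the nearest source.
Every generator is seed-deterministic and returns its parameters alongside
the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .point_pattern import PointPattern
from .segmentation_io import OBJECT_COLUMNS, CalibratedImage, ObjectTable

__all__ = [
    "gen_poisson",
    "gen_thomas",
    "gen_hardcore",
    "render_cells",
    "RenderedScene",
    "gen_communication_scene",
    "CommunicationScene",
    "SceneTruth",
]


def gen_poisson(window: tuple[float, float], n: int | None = None,
                intensity: float | None = None,
                seed: int | np.random.Generator | None = None,
                inset: float = 0.0) -> PointPattern:
    """Homogeneous Poisson (CSR) pattern in a rectangular window.

    Pass ``n`` for a conditional (fixed-n) pattern — the convention for
    simulation batteries where the sample size must be constant — or
    ``intensity`` (points per um^2) for the unconditional process.
    ``inset`` keeps points at least that far from the window edge (e.g. one
    cell radius, so rendered cells are never clipped by the field of view).
    """
    w, h = window
    if w <= 0 or h <= 0:
        raise ValueError("window area must be positive")
    rng = np.random.default_rng(seed)
    if n is None:
        if intensity is None:
            raise ValueError("give either n or intensity")
        n = rng.poisson(intensity * w * h)
    pts = rng.uniform([inset, inset], [w - inset, h - inset],
                      size=(int(n), 2))
    return PointPattern(pts, window)


def gen_thomas(kappa: float, mu: float, sigma: float,
               window: tuple[float, float],
               seed: int | np.random.Generator | None = None,
               min_separation: float = 0.0) -> PointPattern:
    """Thomas cluster process: an aggregated pattern.

    Poisson parents with intensity ``kappa`` (per um^2); each parent spawns
    Poisson(``mu``) offspring displaced by an isotropic Gaussian with sd
    ``sigma`` um; offspring falling outside the window are dropped.  Parents
    are drawn from the window dilated by 3 sigma so edge clusters are not
    under-represented; the expected count in the window is ~kappa*area*mu.

    ``min_separation`` > 0 applies a sequential hard-core thinning (points
    closer than that to an already-kept point are removed), emulating the
    physical exclusion between cell bodies; it caps the per-cell cluster
    index at 1/min_separation.
    """
    if kappa <= 0 or mu <= 0 or sigma <= 0:
        raise ValueError("kappa, mu and sigma must be positive")
    w, h = window
    rng = np.random.default_rng(seed)
    ext = 3.0 * sigma
    n_par = rng.poisson(kappa * (w + 2 * ext) * (h + 2 * ext))
    parents = rng.uniform([-ext, -ext], [w + ext, h + ext], size=(n_par, 2))
    chunks = []
    for px, py in parents:
        k = rng.poisson(mu)
        if k == 0:
            continue
        off = rng.normal([px, py], sigma, size=(k, 2))
        inside = ((off[:, 0] >= 0) & (off[:, 0] <= w)
                  & (off[:, 1] >= 0) & (off[:, 1] <= h))
        if inside.any():
            chunks.append(off[inside])
    pts = np.vstack(chunks) if chunks else np.empty((0, 2))
    if min_separation > 0 and len(pts) > 1:
        order = rng.permutation(len(pts))
        tree_pts: list[np.ndarray] = []
        kept = []
        for i in order:
            cand = pts[i]
            if tree_pts:
                d2 = np.sum((np.asarray(tree_pts) - cand) ** 2, axis=1)
                if d2.min() < min_separation ** 2:
                    continue
            tree_pts.append(cand)
            kept.append(i)
        pts = pts[np.sort(kept)]
    return PointPattern(pts, window)


def gen_hardcore(n: int, r_min: float, window: tuple[float, float],
                 seed: int | np.random.Generator | None = None,
                 max_tries: int = 100_000, inset: float = 0.0) -> PointPattern:
    """Sequential-inhibition (hard-core) pattern: a regular/uniform layout.

    Uniform proposals are rejected within ``r_min`` of accepted points;
    ``inset`` keeps points away from the window edge.  Raises when the
    packing is infeasible or ``max_tries`` is exhausted.
    """
    w, h = window
    if r_min > 0 and n * np.pi * (r_min / 2) ** 2 >= 0.5 * w * h:
        raise ValueError("packing infeasible: n*pi*(r_min/2)^2 >= area/2")
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"packing infeasible: {max_tries} proposals exhausted at "
                f"{len(pts)}/{n} points")
        cand = rng.uniform([inset, inset], [w - inset, h - inset], size=2)
        tries += 1
        if r_min > 0 and pts:
            d2 = np.sum((np.asarray(pts) - cand) ** 2, axis=1)
            if d2.min() < r_min ** 2:
                continue
        pts.append(cand)
    return PointPattern(np.asarray(pts), window)


def _paint_disks(img: np.ndarray, pts_um: np.ndarray, radius_um: np.ndarray,
                 calibration: float, value) -> None:
    """Fill disks (no anti-aliasing) into ``img`` (2-D, or 3-D with value
    being an RGB triple per point)."""
    n_rows = img.shape[0]
    r_px = np.asarray(radius_um, dtype=float) / calibration
    values = np.asarray(value)
    for i, (x, y) in enumerate(pts_um):
        cc = x / calibration
        rr = n_rows - y / calibration
        rp = r_px[i] if r_px.ndim else float(r_px)
        c0, c1 = int(np.floor(cc - rp - 1)), int(np.ceil(cc + rp + 1))
        r0, r1 = int(np.floor(rr - rp - 1)), int(np.ceil(rr + rp + 1))
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, img.shape[0]), min(c1, img.shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disk = ((xx + 0.5 - cc) ** 2 + (yy + 0.5 - rr) ** 2) <= rp ** 2
        val = values[i] if values.ndim > img.ndim - 2 else values
        img[r0:r1, c0:c1][disk] = val


@dataclass(frozen=True)
class RenderedScene:
    """A rendered binary biofilm image with its ground truth."""

    image: CalibratedImage
    truth: ObjectTable           # intended cells (true centroids)
    merged_object_count: int     # connected objects after rendering
    params: dict


def render_cells(p: PointPattern, radius: float | np.ndarray,
                 calibration: float, intensity: int = 255,
                 name: str = "rendered") -> RenderedScene:
    """Render a point pattern as filled disks on a black background.

    Disks closer than two radii merge into one connected object; the truth
    table keeps the intended per-cell centroids while
    ``merged_object_count`` records the connected-object count of the
    rendered image.
    """
    radius_arr = np.broadcast_to(np.asarray(radius, dtype=float), (p.n,))
    if p.n and radius_arr.min() < calibration:
        raise ValueError("cell radius must be at least one pixel")
    w_um, h_um = p.window
    shape = (int(round(h_um / calibration)), int(round(w_um / calibration)))
    img = np.zeros(shape, dtype=np.uint8)
    _paint_disks(img, p.points, radius_arr, calibration, intensity)
    cal_img = CalibratedImage(img, calibration, name)
    df = pd.DataFrame({
        "id": np.arange(1, p.n + 1),
        "x_um": p.points[:, 0],
        "y_um": p.points[:, 1],
        "area_um2": np.pi * radius_arr ** 2,
        "pixel_count": np.nan,
        "channel": "fg",
        "mean_luminosity": float(intensity),
    }, columns=OBJECT_COLUMNS)
    truth = ObjectTable(df, window=p.window, source_image=name)
    from skimage import measure
    merged = int(measure.label(img > 0, connectivity=2).max())
    return RenderedScene(cal_img, truth, merged,
                         params={"radius_um": float(np.mean(radius_arr)),
                                 "calibration": calibration,
                                 "intensity": intensity, "n": p.n})


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth of a two-channel communication scene."""

    source_points: np.ndarray
    sensor_points: np.ndarray
    nearest_source_distance: np.ndarray
    nearest_source_index: np.ndarray
    true_luminosity: np.ndarray
    active: np.ndarray
    params: dict = field(default_factory=dict)
    seed: int | None = None


@dataclass(frozen=True)
class CommunicationScene:
    image: CalibratedImage
    truth: SceneTruth


def gen_communication_scene(n_source: int = 40, n_sensor: int = 80,
                            window: tuple[float, float] = (200.0, 200.0),
                            l_max: float = 255.0, d0: float = 20.0,
                            d_thresh: float = 60.0,
                            baseline_luminosity: int = 2,
                            radius: float = 1.0, calibration: float = 0.2,
                            seed: int | None = None) -> CommunicationScene:
    """Two-channel scene: red source disks, green sensor disks.

    Sensor luminosity follows L(d) = round(l_max * exp(-d / d0)) where d is
    the distance to the nearest source; sensors beyond ``d_thresh`` are
    inactive and rendered at ``baseline_luminosity`` (basal expression).
    Cells are placed with a hard-core separation of 2*radius + 2 pixels so
    rendered cells never merge and segmentation recovers every cell.
    """
    if min(n_source, n_sensor) < 1 or min(l_max, d0, d_thresh, radius) <= 0:
        raise ValueError("all scene parameters must be positive")
    rng = np.random.default_rng(seed)
    sep = 2 * radius + 2 * calibration
    all_pts = gen_hardcore(n_source + n_sensor, sep, window, seed=rng,
                           max_tries=1_000_000,
                           inset=radius + calibration)
    src = all_pts.points[:n_source]
    sen = all_pts.points[n_source:]
    from scipy.spatial import cKDTree
    d, idx = cKDTree(src).query(sen, k=1)
    active = d <= d_thresh
    lum = np.where(active,
                   np.round(l_max * np.exp(-d / d0)),
                   float(baseline_luminosity)).astype(int)
    lum = np.clip(lum, baseline_luminosity, 255)

    w_um, h_um = window
    shape = (int(round(h_um / calibration)), int(round(w_um / calibration)), 3)
    img = np.zeros(shape, dtype=np.uint8)
    red = np.tile([255, 0, 0], (n_source, 1))
    _paint_disks(img, src, np.full(n_source, radius), calibration, red)
    green = np.column_stack([np.zeros(n_sensor, int), lum,
                             np.zeros(n_sensor, int)])
    _paint_disks(img, sen, np.full(n_sensor, radius), calibration, green)
    cal_img = CalibratedImage(img, calibration, "communication_scene")
    truth = SceneTruth(
        source_points=src, sensor_points=sen,
        nearest_source_distance=d, nearest_source_index=idx,
        true_luminosity=lum.astype(float), active=active,
        params={"n_source": n_source, "n_sensor": n_sensor,
                "window": window, "l_max": l_max, "d0": d0,
                "d_thresh": d_thresh,
                "baseline_luminosity": baseline_luminosity,
                "radius": radius, "calibration": calibration},
        seed=seed if isinstance(seed, int) else None)
    return CommunicationScene(cal_img, truth)
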