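"""Nearest-neighbor geometry and tests of complete spatial randomness (CSR).

A :class:`PointPattern` holds the calibrated centroids of surface-attached
cells inside a rectangular observation window.  The module implements the
classical nearest-neighbor battery used to decide whether a biofilm's
colonization pattern is aggregated, random or uniform:

* per-cell 1st/2nd nearest-neighbor distances and the cluster index
  (1/NND1, in 1/um) — a local sensor of crowding,
* the empirical distribution function of NND1 with a Monte-Carlo CSR
  envelope,
* the Holgate, Russ, Clark & Evans and Hopkins & Skellam indices with the
  conventional decision rules (aggregated when >0.5, <1.0, <1.0 and >1.0
  respectively),
* spatial density (cells/mm^2) and the box-count fractal dimension of a
  binary image,
* a 1-D classifier binning cells by any per-cell feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "PointPattern",
    "CsrTestResult",
    "EdfCurve",
    "neighbor_table",
    "edf_curve",
    "clark_evans",
    "hopkins_skellam",
    "holgate",
    "russ_randomness",
    "spatial_density",
    "fractal_dimension",
    "classify_1d",
    "render_classification",
    "DEFAULT_CLUSTER_INDEX_EDGES",
]

#: Default bin edges (1/um) for the cluster-index 1-D classifier; 0.4 is the
#: conventional divide between dispersed and aggregated cells.
DEFAULT_CLUSTER_INDEX_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4)


@dataclass(frozen=True)
class PointPattern:
    """Planar point pattern in a rectangular window [0, W] x [0, H] (um)."""

    points: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        w, h = float(self.window[0]), float(self.window[1])
        object.__setattr__(self, "window", (w, h))
        if w <= 0 or h <= 0:
            raise ValueError("window dimensions must be positive")
        if pts.size and (
            pts[:, 0].min() < 0 or pts[:, 1].min() < 0
            or pts[:, 0].max() > w or pts[:, 1].max() > h
        ):
            raise ValueError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        return self.window[0] * self.window[1]

    @property
    def intensity(self) -> float:
        """Points per um^2."""
        return self.n / self.area


@dataclass(frozen=True)
class CsrTestResult:
    """Outcome of one CSR test: the index value, significance and verdict."""

    name: str
    value: float
    p_value: float
    verdict: str  # aggregated | random | uniform
    z: float | None = None
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EdfCurve:
    """Empirical G(r) of NND1 against its CSR reference, with MC envelope."""

    r: np.ndarray
    g_emp: np.ndarray
    g_csr: np.ndarray
    max_abs_dev: float
    p_value: float
    env_lo: np.ndarray
    env_hi: np.ndarray
    n_sim: int


def _nnd12(points: np.ndarray, window: tuple[float, float] | None = None,
           torus: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """1st/2nd NN distances and ids; torus=True wraps distances periodically."""
    n = len(points)
    if torus:
        w, h = window
        # boxsize requires coordinates strictly inside [0, box)
        pts = np.remainder(points, [w, h])
        tree = cKDTree(pts, boxsize=[w, h])
    else:
        tree = cKDTree(points)
    k = min(n, 4)
    dist, idx = tree.query(points, k=k)
    # self appears at distance 0; with coincident points it may not be first,
    # so drop each row's own index explicitly and tie-break by lowest id.
    nnd = np.empty((n, 2))
    nnid = np.empty((n, 2), dtype=int)
    self_first = (idx[:, 0] == np.arange(n))
    if self_first.all():
        nnd[:] = dist[:, 1:3]
        nnid[:] = idx[:, 1:3]
    else:
        for i in range(n):
            mask = idx[i] != i
            d, j = dist[i][mask], idx[i][mask]
            order = np.lexsort((j, d))
            nnd[i] = d[order[:2]]
            nnid[i] = j[order[:2]]
    return nnd, nnid


def neighbor_table(p: PointPattern, *, calibration: float | None = None,
                   edge_correction: str = "none") -> pd.DataFrame:
    """Per-cell 1st/2nd nearest-neighbor distances and cluster index.

    Returns a DataFrame with columns ``nnd1, nnd2, nn1_id, nn2_id,
    cluster_index``; ``cluster_index = 1/nnd1`` (1/um).  Coincident centroids
    (nnd1 = 0) would make the cluster index infinite; they are clamped to
    half the pixel calibration (default 0.05 um when no calibration is
    known) with a warning.

    Parameters
    ----------
    edge_correction : "none" or "torus"
        "torus" measures distances periodically in the window (edge-free;
        used by the simulation-based tests).
    """
    if p.n < 3:
        raise ValueError("need >=3 points to define 1st and 2nd neighbors")
    if edge_correction not in ("none", "torus"):
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    nnd, nnid = _nnd12(p.points, p.window, torus=(edge_correction == "torus"))
    nnd1 = nnd[:, 0]
    clamp = (calibration / 2.0) if calibration else 0.05
    if np.any(nnd1 <= 0):
        warnings.warn(
            f"{int(np.sum(nnd1 <= 0))} coincident centroid(s): nnd1 clamped "
            f"to {clamp} um for the cluster index", stacklevel=2)
    ci = 1.0 / np.maximum(nnd1, clamp)
    return pd.DataFrame({
        "nnd1": nnd1,
        "nnd2": nnd[:, 1],
        "nn1_id": nnid[:, 0],
        "nn2_id": nnid[:, 1],
        "cluster_index": ci,
    })


def _empirical_g(nnd1_sorted: np.ndarray, r: np.ndarray) -> np.ndarray:
    return np.searchsorted(nnd1_sorted, r, side="right") / len(nnd1_sorted)


def edf_curve(p: PointPattern, n_sim: int = 99,
              seed: int | np.random.Generator | None = None) -> EdfCurve:
    """Empirical distribution function of NND1 vs the CSR reference.

    The CSR reference is G0(r) = 1 - exp(-lambda*pi*r^2).  The returned
    envelope is simultaneous: G0 +/- d*, where d* is the 95th percentile of
    the maximum absolute deviation over ``n_sim`` CSR simulations, so a CSR
    pattern falls entirely inside it with probability ~0.95.  The p-value is
    the Monte-Carlo rank of the observed maximum deviation.
    """
    if p.area <= 0:
        raise ValueError("window has zero area")
    if p.n < 3:
        raise ValueError("need >=3 points")
    rng = np.random.default_rng(seed)
    lam = p.intensity
    nnd, _ = _nnd12(p.points)
    r = np.sort(nnd[:, 0])
    g_emp = np.arange(1, p.n + 1) / p.n
    g_csr = 1.0 - np.exp(-lam * np.pi * r ** 2)
    obs_dev = float(np.max(np.abs(g_emp - g_csr)))

    w, h = p.window
    sim_devs = np.empty(n_sim)
    for s in range(n_sim):
        pts = rng.uniform(0, [w, h], size=(p.n, 2))
        snn, _ = _nnd12(pts)
        sr = np.sort(snn[:, 0])
        sg = np.arange(1, p.n + 1) / p.n
        sim_devs[s] = np.max(np.abs(sg - (1 - np.exp(-lam * np.pi * sr ** 2))))
    p_value = (1 + np.sum(sim_devs >= obs_dev)) / (n_sim + 1)
    d_star = float(np.quantile(sim_devs, 0.95))
    return EdfCurve(r=r, g_emp=g_emp, g_csr=g_csr, max_abs_dev=obs_dev,
                    p_value=float(p_value),
                    env_lo=np.clip(g_csr - d_star, 0, 1),
                    env_hi=np.clip(g_csr + d_star, 0, 1), n_sim=n_sim)


def _verdict(value: float, p_value: float, alpha: float,
             aggregated_when: str) -> str:
    """Map an index and its significance onto aggregated/random/uniform."""
    if p_value > alpha:
        return "random"
    if aggregated_when == "greater":
        return "aggregated" if value > 0 else "uniform"
    raise AssertionError(aggregated_when)


def clark_evans(p: PointPattern, edge_correction: str = "donnelly",
                alpha: float = 0.05) -> CsrTestResult:
    """Clark & Evans nearest-neighbor dispersion index.

    R = mean(nnd1) / (0.5/sqrt(lambda)); R < 1 indicates aggregation,
    R > 1 uniformity.  Significance via the normal test with
    SE = 0.26136/sqrt(n*lambda); the Donnelly edge correction (default)
    adjusts the CSR expectation and SE for the window perimeter, "torus"
    measures distances periodically instead, "none" applies no correction.
    """
    if p.n < 3:
        raise ValueError("need >=3 points")
    lam = p.intensity
    w, h = p.window
    torus = edge_correction == "torus"
    nnd, _ = _nnd12(p.points, p.window, torus=torus)
    mean_d = float(np.mean(nnd[:, 0]))
    e_csr = 0.5 / np.sqrt(lam)
    if mean_d == 0.0:
        return CsrTestResult("clark_evans", 0.0, 0.0, "aggregated", z=-np.inf)
    if edge_correction == "donnelly":
        perim = 2 * (w + h)
        n = p.n
        e_d = e_csr + (0.0514 + 0.041 / np.sqrt(n)) * perim / n
        var = 0.0703 * p.area / n ** 2 + 0.037 * perim * np.sqrt(p.area / n ** 5)
        se = np.sqrt(var)
    elif edge_correction in ("torus", "none"):
        e_d = e_csr
        se = 0.26136 / np.sqrt(p.n * lam)
    else:
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    z = (mean_d - e_d) / se
    p_value = 2 * stats.norm.sf(abs(z))
    R = mean_d / e_csr
    if p_value <= alpha:
        verdict = "aggregated" if R < 1 else "uniform"
    else:
        verdict = "random"
    return CsrTestResult("clark_evans", float(R), float(p_value), verdict,
                         z=float(z),
                         extras={"edge_correction": edge_correction,
                                 "mean_nnd1": mean_d})


def hopkins_skellam(p: PointPattern, m: int | None = None,
                    seed: int | np.random.Generator | None = None,
                    edge_correction: str = "none",
                    alpha: float = 0.05) -> CsrTestResult:
    """Hopkins & Skellam aggregation index.

    h = sum(x_i^2) / sum(r_i^2), where x_i is the distance from each of m
    uniformly random sampling locations to its nearest cell and r_i is the
    NND1 of m randomly chosen cells.  Under CSR h ~ F(2m, 2m); h > 1 marks
    aggregation, h < 1 uniformity.  The default m = clip(n//10, 10, 100)
    keeps the sampled distances nearly independent so the F reference is
    calibrated.
    """
    if p.n < 3:
        raise ValueError("need >=3 points")
    if m is None:
        m = int(np.clip(p.n // 10, 10, min(100, p.n)))
    if not 1 <= m <= p.n:
        raise ValueError(f"m={m} must satisfy 1 <= m <= n={p.n}")
    rng = np.random.default_rng(seed)
    w, h_win = p.window
    torus = edge_correction == "torus"
    sample = rng.uniform(0, [w, h_win], size=(m, 2))
    if torus:
        tree = cKDTree(np.remainder(p.points, [w, h_win]), boxsize=[w, h_win])
    else:
        tree = cKDTree(p.points)
    x, _ = tree.query(sample, k=1)
    nnd, _ = _nnd12(p.points, p.window, torus=torus)
    r = nnd[rng.choice(p.n, size=m, replace=False), 0]
    denom = float(np.sum(r ** 2))
    if denom == 0.0:
        return CsrTestResult("hopkins_skellam", np.inf, 0.0, "aggregated")
    h = float(np.sum(x ** 2) / denom)
    p_value = float(2 * min(stats.f.sf(h, 2 * m, 2 * m),
                            stats.f.cdf(h, 2 * m, 2 * m)))
    if p_value <= alpha:
        verdict = "aggregated" if h > 1 else "uniform"
    else:
        verdict = "random"
    return CsrTestResult("hopkins_skellam", h, p_value, verdict,
                         extras={"m": m, "edge_correction": edge_correction})


def _simulate_csr_stat(statistic, n: int, window: tuple[float, float],
                       n_sim: int, rng: np.random.Generator) -> np.ndarray:
    w, h = window
    out = np.empty(n_sim)
    for s in range(n_sim):
        pts = rng.uniform(0, [w, h], size=(n, 2))
        out[s] = statistic(pts)
    return out


def _mc_p(observed: float, null: np.ndarray) -> float:
    """Two-sided Monte-Carlo rank p-value."""
    n_sim = len(null)
    n_ge = np.sum(null >= observed)
    n_le = np.sum(null <= observed)
    return float(min(1.0, 2 * (1 + min(n_ge, n_le)) / (n_sim + 1)))


def holgate(p: PointPattern, alpha: float = 0.05, p_method: str = "mc",
            n_sim: int = 99, edge_correction: str = "none",
            method: str = "sample_point", m: int | None = None,
            seed: int | np.random.Generator | None = None) -> CsrTestResult:
    """Holgate aggregation index from 1st & 2nd nearest-neighbor distances.

    The classical form (``method="sample_point"``) measures, from each of
    ``m`` uniformly random sampling locations, the distances d1 and d2 to
    the nearest and second-nearest cell and averages the squared ratio
    A = mean(d1^2 / d2^2).  Under CSR the ratio is exactly uniform on
    (0, 1), so E[A] = 0.5; in aggregated patterns sampling locations fall
    in gaps where both distances point at the same cluster, pushing the
    ratio toward 1, so A > 0.5 marks aggregation and A < 0.5 regularity.
    ``method="event"`` uses each cell's own nnd1/nnd2 instead (a locally
    scale-free ratio; near 0.5 whenever clusters are internally
    Poisson-like, so it has little power against cluster processes).

    The normal score z = (A - 0.5)*sqrt(12 m) is always reported; the
    default verdict p-value comes from a Monte-Carlo rank test
    (``p_method="mc"``), the normal approximation via ``p_method="normal"``.
    """
    if p.n < 3:
        raise ValueError("need >=3 points")
    torus = edge_correction == "torus"
    rng = np.random.default_rng(seed)
    if m is None:
        m = p.n
    w, h = p.window

    if method == "sample_point":
        def _stat(pts: np.ndarray) -> float:
            sample = rng.uniform(0, [w, h], size=(m, 2))
            if torus:
                tree = cKDTree(np.remainder(pts, [w, h]), boxsize=[w, h])
            else:
                tree = cKDTree(pts)
            d, _ = tree.query(sample, k=2)
            d2 = d[:, 1]
            ok = d2 > 0
            return float(np.mean(d[ok, 0] ** 2 / d2[ok] ** 2))
    elif method == "event":
        def _stat(pts: np.ndarray) -> float:
            nnd, _ = _nnd12(pts, p.window, torus=torus)
            nnd2 = nnd[:, 1]
            ok = nnd2 > 0
            if not ok.all():
                warnings.warn("points with nnd2 = 0 excluded from Holgate A",
                              stacklevel=3)
            return float(np.mean(nnd[ok, 0] ** 2 / nnd2[ok] ** 2))
    else:
        raise ValueError(f"unknown method {method!r}")

    A = _stat(p.points)
    z = (A - 0.5) * np.sqrt(12 * m)
    if p_method == "normal":
        p_value = float(2 * stats.norm.sf(abs(z)))
    elif p_method == "mc":
        null = _simulate_csr_stat(_stat, p.n, p.window, n_sim, rng)
        p_value = _mc_p(A, null)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    if p_value <= alpha:
        verdict = "aggregated" if A > 0.5 else "uniform"
    else:
        verdict = "random"
    return CsrTestResult("holgate", A, p_value, verdict, z=float(z),
                         extras={"p_method": p_method, "method": method,
                                 "m": m})


def russ_randomness(p: PointPattern, alpha: float = 0.05, n_sim: int = 99,
                    edge_correction: str = "none",
                    seed: int | np.random.Generator | None = None
                    ) -> CsrTestResult:
    """Russ randomness index from 1st & 2nd NND.

    Mean over k in {1, 2} of mean(nnd_k) / E_CSR[nnd_k], with CSR
    expectations 0.5/sqrt(lambda) and 0.75/sqrt(lambda).  Equals 1 under
    CSR; < 1 marks aggregation, > 1 uniformity.  Significance by a
    two-sided Monte-Carlo rank test (``n_sim`` CSR simulations).
    """
    if p.n < 3:
        raise ValueError("need >=3 points")
    lam = p.intensity
    e1, e2 = 0.5 / np.sqrt(lam), 0.75 / np.sqrt(lam)
    torus = edge_correction == "torus"

    def _stat(pts: np.ndarray) -> float:
        nnd, _ = _nnd12(pts, p.window, torus=torus)
        return float(0.5 * (np.mean(nnd[:, 0]) / e1 + np.mean(nnd[:, 1]) / e2))

    value = _stat(p.points)
    rng = np.random.default_rng(seed)
    null = _simulate_csr_stat(_stat, p.n, p.window, n_sim, rng)
    p_value = _mc_p(value, null)
    if p_value <= alpha:
        verdict = "aggregated" if value < 1 else "uniform"
    else:
        verdict = "random"
    return CsrTestResult("russ_randomness", value, p_value, verdict,
                         extras={"n_sim": n_sim})


def spatial_density(p: PointPattern) -> float:
    """Cells per mm^2 (window area is in um^2; 1 mm^2 = 1e6 um^2)."""
    if p.area <= 0:
        raise ValueError("window has zero area")
    return p.n / p.area * 1e6


def fractal_dimension(binary: np.ndarray) -> tuple[float, float]:
    """Box-count fractal dimension of a binary image.

    Counts foreground-occupied boxes over a geometric ladder of box sizes
    (powers of 2 from 2 px up to a quarter of the smaller image side) and
    fits log(count) against log(1/size) by least squares.  Returns
    ``(dimension, fit_r2)``.  D ~ 2 for a plane-filling mass, ~1 for a
    curve; values above 1 indicate aggregated, scale-dependent structure.
    """
    img = np.asarray(binary).astype(bool)
    if img.ndim != 2:
        raise ValueError("binary image must be 2-D")
    n_fg = img.sum()
    if n_fg == 0:
        raise ValueError("image has no foreground pixels")
    if n_fg == 1:
        return 0.0, 1.0
    short = min(img.shape)
    sizes = []
    s = 2
    while s <= max(2, short // 4):
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        return 0.0, 1.0
    counts = []
    for s in sizes:
        hh = int(np.ceil(img.shape[0] / s)) * s
        ww = int(np.ceil(img.shape[1] / s)) * s
        padded = np.zeros((hh, ww), dtype=bool)
        padded[:img.shape[0], :img.shape[1]] = img
        blocks = padded.reshape(hh // s, s, ww // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    x = np.log(1.0 / np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else 1.0
    return float(slope), float(r2)


def classify_1d(values: Sequence[float] | pd.Series,
                bin_edges: Sequence[float] = DEFAULT_CLUSTER_INDEX_EDGES
                ) -> tuple[np.ndarray, np.ndarray]:
    """Sort cells into bins by a single feature (the 1-D classifier).

    Bin b covers the interval (edges[b], edges[b+1]]; values above the top
    edge are assigned the (open-ended) top bin with a warning, matching the
    "+" class of the pseudocolor ramp.  Returns ``(bin_index, counts)``
    where counts has ``len(bin_edges) - 1`` entries summing to n.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    v = np.asarray(values, dtype=float)
    n_bins = len(edges) - 1
    idx = np.searchsorted(edges, v, side="left") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    if np.any(v > edges[-1]):
        warnings.warn(
            f"{int(np.sum(v > edges[-1]))} value(s) above the top edge "
            f"assigned to the open-ended top bin", stacklevel=2)
    counts = np.bincount(idx, minlength=n_bins)
    return idx, counts


def render_classification(p: PointPattern, bin_index: np.ndarray,
                          bin_edges: Sequence[float], path=None,
                          marker_size: float = 12.0):
    """Pseudocolor overlay of classifier bins at each cell position.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n_bins = len(bin_edges) - 1
    cmap = plt.get_cmap("turbo", n_bins)
    fig, ax = plt.subplots(figsize=(6, 6 * p.window[1] / p.window[0]))
    sc = ax.scatter(p.points[:, 0], p.points[:, 1], c=bin_index, cmap=cmap,
                    vmin=-0.5, vmax=n_bins - 0.5, s=marker_size)
    cb = fig.colorbar(sc, ax=ax, ticks=range(n_bins))
    cb.ax.set_yticklabels(
        [f"({bin_edges[i]:g}, {bin_edges[i+1]:g}]" for i in range(n_bins - 1)]
        + [f"> {bin_edges[-2]:g}"])
    ax.set_xlim(0, p.window[0]); ax.set_ylim(0, p.window[1])
    ax.set_xlabel("x (um)"); ax.set_ylabel("y (um)")
    ax.set_aspect("equal")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
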