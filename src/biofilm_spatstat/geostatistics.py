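"""Geostatistics of a regionalized per-cell variable (the "Z-variate").

Given cell locations and a continuously distributed per-cell quantity (for
biofilms, typically the cluster index), this module estimates the isotropic
empirical semivariogram, fits permissible variogram models (spherical,
exponential, gaussian, linear) by pair-count-weighted least squares, reports
the effective range (the lag at which the model reaches 95% of its
asymptote — the radius of spatial autocorrelation), computes Moran's I with
a randomization z-score, and produces ordinary-kriging interpolation maps
with isopleth contours and kriging variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GeoSample",
    "Variogram",
    "VariogramModel",
    "KrigingGrid",
    "empirical_variogram",
    "fit_variogram",
    "morans_i",
    "ordinary_kriging",
    "isopleth_contours",
    "loo_cross_validation",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("spherical", "exponential", "gaussian", "linear")

# 95% point of the unit spherical correlation shape 1.5x - 0.5x^3
_SPHERICAL_95 = optimize.brentq(lambda x: 1.5 * x - 0.5 * x ** 3 - 0.95, 0, 1)


@dataclass(frozen=True)
class GeoSample:
    """Cell locations (um) with one Z-variate value per cell."""

    locations: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=float).reshape(-1, 2)
        z = np.asarray(self.z, dtype=float).ravel()
        if len(loc) != len(z):
            raise ValueError("locations and z must have the same length")
        object.__setattr__(self, "locations", loc)
        object.__setattr__(self, "z", z)

    @property
    def n(self) -> int:
        return len(self.z)


@dataclass(frozen=True)
class Variogram:
    """Binned empirical semivariogram."""

    lag_centers: np.ndarray
    semivariance: np.ndarray  # NaN where a bin holds no pairs
    pair_counts: np.ndarray
    active_lag_max: float
    n_lags: int
    sample_variance: float


@dataclass(frozen=True)
class VariogramModel:
    """Fitted variogram model gamma(h)."""

    family: str
    nugget: float          # c0
    sill: float            # c0 + c (total)
    range_param: float     # a
    effective_range: float  # lag at 95% of the asymptote
    fit_r2: float
    no_structure: bool = False

    @property
    def partial_sill(self) -> float:
        return self.sill - self.nugget

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        c0, c, a = self.nugget, self.partial_sill, self.range_param
        out = _gamma(self.family, h, c0, c, a)
        return np.where(h == 0, 0.0, out)


def _gamma(family: str, h: np.ndarray, c0: float, c: float,
           a: float) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if family == "spherical":
        x = np.minimum(h / a, 1.0)
        return c0 + c * (1.5 * x - 0.5 * x ** 3)
    if family == "exponential":
        return c0 + c * (1.0 - np.exp(-h / a))
    if family == "gaussian":
        return c0 + c * (1.0 - np.exp(-((h / a) ** 2)))
    if family == "linear":
        # c is the slope; a (fixed at active_lag_max) only sets the scale
        return c0 + c * h / a
    raise ValueError(f"unknown variogram family {family!r}")


def _effective_range(family: str, a: float) -> float:
    if family == "exponential":
        return a * np.log(20.0)
    if family == "gaussian":
        return a * np.sqrt(np.log(20.0))
    if family == "spherical":
        return a * _SPHERICAL_95
    if family == "linear":
        return 0.95 * a
    raise ValueError(family)


def empirical_variogram(g: GeoSample, n_lags: int = 12,
                        active_lag_max: float | None = None) -> Variogram:
    """Isotropic empirical semivariogram over equal-width lag bins.

    gamma(h) = (1 / 2N(h)) * sum over pairs in lag bin h of (z_i - z_j)^2.
    ``active_lag_max`` defaults to half the diagonal of the sample's
    bounding box.  Bins without pairs carry NaN semivariance and are
    excluded from fitting.
    """
    if g.n < 2:
        raise ValueError("variogram estimation requires n >= 2")
    d = pdist(g.locations)
    dz2 = pdist(g.z[:, None], metric="sqeuclidean")
    if active_lag_max is None:
        span = g.locations.max(axis=0) - g.locations.min(axis=0)
        active_lag_max = float(np.hypot(*span) / 2.0)
    edges = np.linspace(0.0, active_lag_max, n_lags + 1)
    idx = np.digitize(d, edges) - 1
    ok = (idx >= 0) & (idx < n_lags)
    counts = np.bincount(idx[ok], minlength=n_lags)
    sums = np.bincount(idx[ok], weights=dz2[ok], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Variogram(lag_centers=centers, semivariance=gamma,
                     pair_counts=counts, active_lag_max=active_lag_max,
                     n_lags=n_lags, sample_variance=float(np.var(g.z)))


def fit_variogram(v: Variogram,
                  families: tuple[str, ...] = MODEL_FAMILIES
                  ) -> VariogramModel:
    """Fit candidate variogram families by weighted least squares.

    Weights are pair counts; the best family minimizes the weighted
    residual sum of squares.  When the fitted spatial structure is
    negligible (partial sill below 1% of the total sill), the model is
    flagged ``no_structure`` and the effective range reported as 0.
    A non-convergent fit falls back to the linear model with a warning.
    """
    ok = (v.pair_counts > 0) & np.isfinite(v.semivariance)
    h = v.lag_centers[ok]
    y = v.semivariance[ok]
    w = v.pair_counts[ok].astype(float)
    if len(h) < 4:
        raise ValueError("need >= 4 usable lags to fit a variogram model")
    sigma = 1.0 / np.sqrt(w)
    y_w_mean = np.average(y, weights=w)
    tss = float(np.sum(w * (y - y_w_mean) ** 2))

    best: VariogramModel | None = None
    best_rss = np.inf
    for family in families:
        try:
            if family == "linear":
                a_fix = v.active_lag_max

                def f(hh, c0, c):
                    return _gamma("linear", hh, c0, c, a_fix)

                p0 = [max(y.min(), 0.0), max(y.max() - y.min(), 1e-9)]
                bounds = ([0, 0], [np.inf, np.inf])
                popt, _ = optimize.curve_fit(f, h, y, p0=p0, sigma=sigma,
                                             bounds=bounds, maxfev=10000)
                c0, c = popt
                a = a_fix
            else:
                def f(hh, c0, c, a, fam=family):
                    return _gamma(fam, hh, c0, c, a)

                # a is not identifiable beyond the sampled lags; cap it
                p0 = [max(y.min(), 0.0), max(y.max() - y.min(), 1e-9),
                      v.active_lag_max / 3.0]
                bounds = ([0, 0, 1e-9],
                          [np.inf, np.inf, v.active_lag_max])
                popt, _ = optimize.curve_fit(f, h, y, p0=p0, sigma=sigma,
                                             bounds=bounds, maxfev=10000)
                c0, c, a = popt
        except (RuntimeError, ValueError):
            continue
        resid = y - _gamma(family, h, c0, c, a)
        rss = float(np.sum(w * resid ** 2))
        if rss < best_rss:
            best_rss = rss
            r2 = 1.0 - rss / tss if tss > 0 else 1.0
            sill = c0 + c
            # pure-nugget data: negligible partial sill or a fit that
            # explains no more of the binned variance than a flat line
            no_structure = sill <= 0 or (c <= 0.01 * sill) or r2 < 0.3
            eff = 0.0 if no_structure else _effective_range(family, a)
            best = VariogramModel(family=family, nugget=float(c0),
                                  sill=float(sill), range_param=float(a),
                                  effective_range=float(eff),
                                  fit_r2=float(r2),
                                  no_structure=bool(no_structure))
    if best is None:
        warnings.warn("no variogram model converged; falling back to a flat "
                      "linear model", stacklevel=2)
        c0 = float(np.average(y, weights=w))
        return VariogramModel("linear", c0, c0, v.active_lag_max, 0.0, 0.0,
                              no_structure=True)
    return best


def morans_i(g: GeoSample, weights: str = "inverse_distance",
             bandwidth: float | None = None, cutoff: float | None = None,
             alpha: float = 0.05) -> dict:
    """Moran's I spatial autocorrelation of the Z-variate.

    I = (n/W) * sum_ij w_ij (z_i - zbar)(z_j - zbar) / sum_i (z_i - zbar)^2
    with E[I] = -1/(n-1) and the randomization variance for the z-score.
    ``weights``: "inverse_distance" (w = 1/d, optionally zeroed beyond
    ``cutoff``) or "binary" (w = 1 within ``bandwidth``).
    Returns a dict with I, expected_i, z_score, p_value, verdict.
    """
    if g.n < 10:
        raise ValueError("Moran's I requires n >= 10")
    z = g.z
    dev = z - z.mean()
    m2 = np.sum(dev ** 2)
    if m2 == 0:
        raise ValueError("zero variance: Moran's I undefined")
    d = squareform(pdist(g.locations))
    np.fill_diagonal(d, np.inf)
    if weights == "inverse_distance":
        wmat = 1.0 / d
        if cutoff is not None:
            wmat[d > cutoff] = 0.0
    elif weights == "binary":
        if bandwidth is None:
            raise ValueError("binary weights require a bandwidth")
        wmat = (d <= bandwidth).astype(float)
    else:
        raise ValueError(f"unknown weights scheme {weights!r}")
    W = wmat.sum()
    if W == 0:
        raise ValueError("total spatial weight is zero")
    n = g.n
    I = (n / W) * float(dev @ wmat @ dev) / m2
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((wmat + wmat.T) ** 2)
    s2 = np.sum((wmat.sum(axis=1) + wmat.sum(axis=0)) ** 2)
    b2 = n * np.sum(dev ** 4) / m2 ** 2
    num = (n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * W ** 2)
           - b2 * ((n ** 2 - n) * s1 - 2 * n * s2 + 6 * W ** 2))
    var_i = num / ((n - 1) * (n - 2) * (n - 3) * W ** 2) - e_i ** 2
    zsc = (I - e_i) / np.sqrt(var_i)
    p = 2 * stats.norm.sf(abs(zsc))
    if p <= alpha:
        verdict = "autocorrelated" if I > e_i else "dispersed"
    else:
        verdict = "independent"
    return {"I": float(I), "expected_i": float(e_i), "z_score": float(zsc),
            "p_value": float(p), "verdict": verdict, "weights": weights}


@dataclass(frozen=True)
class KrigingGrid:
    """Ordinary-kriging surface: predictions and kriging variances."""

    x: np.ndarray          # node x coordinates (nx,)
    y: np.ndarray          # node y coordinates (ny,)
    z: np.ndarray          # predictions (ny, nx)
    variance: np.ndarray   # kriging variance (ny, nx)
    model: VariogramModel
    isopleth_levels: np.ndarray = field(default_factory=lambda: np.array([]))


def ordinary_kriging(g: GeoSample, model: VariogramModel,
                     grid_spacing: float | None = None,
                     neighborhood: int = 16,
                     window: tuple[float, float] | None = None,
                     jitter: float = 0.05) -> KrigingGrid:
    """Ordinary kriging of the Z-variate on a regular grid.

    Per node, the kriging system is solved on the ``neighborhood`` nearest
    data (weights constrained to sum to 1 via a Lagrange multiplier).  With
    zero nugget the predictor is exact at data locations with zero kriging
    variance.  Duplicate locations are jittered by ``jitter`` um with a
    warning to keep the system nonsingular.
    """
    if model.sill <= 0:
        raise ValueError("kriging requires a fitted model with positive sill")
    loc = g.locations.copy()
    # jitter exact duplicates
    _, inv, cnt = np.unique(loc.round(9), axis=0, return_inverse=True,
                            return_counts=True)
    if (cnt > 1).any():
        warnings.warn("duplicate locations jittered for kriging",
                      stacklevel=2)
        rng = np.random.default_rng(0)
        dup = cnt[inv] > 1
        loc[dup] += rng.uniform(-jitter, jitter, size=(int(dup.sum()), 2))
    if window is None:
        window = (float(loc[:, 0].max()), float(loc[:, 1].max()))
    w_um, h_um = window
    if grid_spacing is None:
        grid_spacing = max(w_um, h_um) / 100.0
    xs = np.arange(0.0, w_um + grid_spacing / 2, grid_spacing)
    ys = np.arange(0.0, h_um + grid_spacing / 2, grid_spacing)
    k = min(neighborhood, g.n)
    tree = cKDTree(loc)
    zz = np.empty((len(ys), len(xs)))
    vv = np.empty_like(zz)
    for iy, yv in enumerate(ys):
        nodes = np.column_stack([xs, np.full_like(xs, yv)])
        dists, idxs = tree.query(nodes, k=k)
        if k == 1:
            dists, idxs = dists[:, None], idxs[:, None]
        for ix in range(len(xs)):
            nb = idxs[ix]
            pts = loc[nb]
            gam = model(squareform(pdist(pts)))
            a_mat = np.empty((k + 1, k + 1))
            a_mat[:k, :k] = gam
            a_mat[k, :] = 1.0
            a_mat[:, k] = 1.0
            a_mat[k, k] = 0.0
            rhs = np.empty(k + 1)
            rhs[:k] = model(dists[ix])
            rhs[k] = 1.0
            try:
                sol = np.linalg.solve(a_mat, rhs)
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(a_mat, rhs, rcond=None)[0]
            wgt, mu = sol[:k], sol[k]
            zz[iy, ix] = wgt @ g.z[nb]
            vv[iy, ix] = max(wgt @ rhs[:k] + mu, 0.0)
    levels = np.quantile(zz, [0.2, 0.4, 0.6, 0.8])
    return KrigingGrid(x=xs, y=ys, z=zz, variance=vv, model=model,
                       isopleth_levels=levels)


def isopleth_contours(kg: KrigingGrid,
                      levels: np.ndarray | None = None
                      ) -> list[tuple[float, np.ndarray]]:
    """Marching-squares isopleths of the kriged surface.

    Returns ``(level, polyline)`` pairs with polylines as (m, 2) arrays of
    (x, y) in um.  Default levels are the quintiles of the predicted
    surface; a constant surface yields no contours.
    """
    from skimage import measure

    if kg.z.shape[0] < 2 or kg.z.shape[1] < 2:
        raise ValueError("kriging grid must be at least 2x2")
    if levels is None:
        levels = kg.isopleth_levels
    out: list[tuple[float, np.ndarray]] = []
    zmin, zmax = kg.z.min(), kg.z.max()
    if zmax == zmin:
        return out
    dx = kg.x[1] - kg.x[0]
    dy = kg.y[1] - kg.y[0]
    for lev in np.atleast_1d(levels):
        if not zmin < lev < zmax:
            continue
        for contour in measure.find_contours(kg.z, lev):
            xy = np.column_stack([kg.x[0] + contour[:, 1] * dx,
                                  kg.y[0] + contour[:, 0] * dy])
            out.append((float(lev), xy))
    return out


def loo_cross_validation(g: GeoSample, model: VariogramModel,
                         neighborhood: int = 16) -> dict:
    """Leave-one-out kriging cross-validation.

    Returns predictions, kriging variances and the mean standardized
    squared error (MSSE); MSSE ~ 1 indicates well-calibrated kriging
    variances.
    """
    n = g.n
    k = min(neighborhood, n - 1)
    tree = cKDTree(g.locations)
    dists, idxs = tree.query(g.locations, k=k + 1)
    preds = np.empty(n)
    kvars = np.empty(n)
    for i in range(n):
        mask = idxs[i] != i
        nb = idxs[i][mask][:k]
        dd = dists[i][mask][:k]
        pts = g.locations[nb]
        gam = model(squareform(pdist(pts)))
        m = len(nb)
        a_mat = np.empty((m + 1, m + 1))
        a_mat[:m, :m] = gam
        a_mat[m, :] = 1.0
        a_mat[:, m] = 1.0
        a_mat[m, m] = 0.0
        rhs = np.empty(m + 1)
        rhs[:m] = model(dd)
        rhs[m] = 1.0
        sol = np.linalg.solve(a_mat, rhs)
        preds[i] = sol[:m] @ g.z[nb]
        kvars[i] = max(sol[:m] @ rhs[:m] + sol[m], 1e-12)
    msse = float(np.mean((g.z - preds) ** 2 / kvars))
    return {"predictions": preds, "variances": kvars, "msse": msse}
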