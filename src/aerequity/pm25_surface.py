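"""Hourly PM2.5 concentration surfaces.

The concentration model is a geographically weighted regression (GWR) of
station-observed PM2.5 on five covariates — aerosol optical depth (AOD),
population density, NDVI, road density and distance to the industrial
source::

    PM2.5_i = β0(u_i) + β1(u_i)·AOD_i + β2(u_i)·POP_i + β3(u_i)·NDVI_i
              + β4(u_i)·ROAD_i + β5(u_i)·NP_i + ε_i

with all coefficients varying over location u_i. At each calibration point
the coefficients solve a kernel-weighted least-squares problem (Gaussian
kernel by default; bandwidth by leave-one-out cross-validation). Local
coefficients are carried to the fishnet by inverse-distance-weighted
interpolation and dotted with the cell covariates; the predicted fishnet
values are then interpolated by ordinary kriging (exponential variogram by
default) and finally averaged to blocks by intersection area.

In the infinite-bandwidth limit GWR collapses to global OLS, and zero-nugget
ordinary kriging reproduces every datum exactly — both limits are used as
oracles in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

COVARIATES = ("aod", "pop", "ndvi", "road", "np_dist")


@dataclass
class GWRFit:
    x: np.ndarray  # calibration coordinates (n, 2)
    coefficients: np.ndarray  # (n, 1+p): intercept + slopes at each station
    fitted: np.ndarray
    residuals: np.ndarray
    bandwidth: float
    kernel_name: str
    r2: float
    covariate_names: tuple = COVARIATES


@dataclass
class VariogramModel:
    model_name: str  # exponential | spherical
    nugget: float
    sill: float  # total sill (nugget + partial sill)
    range_m: float

    def __post_init__(self):
        if self.nugget < 0 or self.sill < self.nugget or self.range_m <= 0:
            raise ValueError("invalid variogram parameters")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        if self.model_name == "exponential":
            g = psill * (1.0 - np.exp(-3.0 * h / self.range_m))
        elif self.model_name == "spherical":
            hr = np.minimum(h / self.range_m, 1.0)
            g = psill * (1.5 * hr - 0.5 * hr**3)
        else:
            raise ValueError(f"unknown variogram model {self.model_name!r}")
        return np.where(h > 0, self.nugget + g, 0.0)


@dataclass
class ConcentrationSurface:
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray  # (n_cells,) for one hour or (n_cells, n_hours)
    provenance: str  # gwr_predicted | kriged
    n_clamped: int = 0
    cell_id: np.ndarray | None = None


# ---------------------------------------------------------------------------
# GWR


def _kernel_weights(d: np.ndarray, bandwidth: float, kernel: str) -> np.ndarray:
    if kernel == "gaussian":
        return np.exp(-0.5 * (d / bandwidth) ** 2)
    if kernel == "bisquare":
        w = np.clip(1.0 - (d / bandwidth) ** 2, 0.0, None)
        return w**2
    raise ValueError(f"unknown kernel {kernel!r}")


def _local_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    XtX = Xw.T @ Xw
    Xty = Xw.T @ yw
    try:
        beta = np.linalg.solve(XtX, Xty)
        # guard against numerically singular but invertible systems
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular local design; ridge fallback", RuntimeWarning, stacklevel=2)
        lam = 1e-8 * np.trace(XtX) / XtX.shape[0]
        beta = np.linalg.solve(XtX + lam * np.eye(XtX.shape[0]), Xty)
    return beta


def _design(stations: pd.DataFrame, covariates) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coords = stations[["x", "y"]].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(stations))] + [stations[c].to_numpy(dtype=float) for c in covariates]
    )
    y = stations["pm25"].to_numpy(dtype=float)
    return coords, X, y


def fit_gwr(
    stations: pd.DataFrame,
    bandwidth: float | str = "cv",
    kernel: str = "gaussian",
    covariates=COVARIATES,
) -> GWRFit:
    """Fit GWR for one hour of station records.

    ``stations`` needs columns x, y, pm25 and the five covariates.
    ``bandwidth`` is a kernel scale in metres, or ``"cv"`` for leave-one-out
    cross-validation over a log-spaced candidate grid.
    """
    p = len(covariates)
    if len(stations) < p + 2:
        raise ValueError(f"need at least {p + 2} stations, got {len(stations)}")
    coords, X, y = _design(stations, covariates)
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    if np.any(d[np.isfinite(d)] == 0) or (d.min() == 0):
        raise ValueError("duplicate station coordinates")
    np.fill_diagonal(d, 0.0)

    if bandwidth == "cv":
        bandwidth = _cv_bandwidth(coords, X, y, d, kernel)
    bandwidth = float(bandwidth)

    n = len(y)
    betas = np.empty((n, X.shape[1]))
    for i in range(n):
        w = _kernel_weights(d[i], bandwidth, kernel)
        betas[i] = _local_wls(X, y, w)
    fitted = np.einsum("ij,ij->i", X, betas)
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return GWRFit(coords, betas, fitted, resid, bandwidth, kernel, r2, tuple(covariates))


def _cv_bandwidth(coords, X, y, d, kernel) -> float:
    span = float(d.max())
    candidates = np.geomspace(span / 16.0, span, 10)
    # identifiability floor: keep only bandwidths whose smallest effective
    # local sample (sum of kernel weights) supports the local regression
    p1 = X.shape[1]
    admissible = []
    for bw in candidates:
        n_eff = _kernel_weights(d, bw, kernel).sum(axis=1).min()
        if n_eff >= 3 * p1:
            admissible.append(bw)
    if admissible:
        candidates = np.asarray(admissible)
    else:
        candidates = candidates[-1:]
    best_bw, best_err = candidates[-1], np.inf
    n = len(y)
    for bw in candidates:
        sse = 0.0
        ok = True
        for i in range(n):
            w = _kernel_weights(d[i], bw, kernel)
            w = w.copy()
            w[i] = 0.0
            if w.sum() <= 0:
                ok = False
                break
            beta = _local_wls(X, y, w)
            sse += float((y[i] - X[i] @ beta) ** 2)
        if ok and sse < best_err:
            best_err, best_bw = sse, bw
    return float(best_bw)


def predict_grid(
    fit: GWRFit,
    grid: pd.DataFrame,
    coefficient_interpolation: str = "idw",
    idw_power: float = 2.0,
) -> ConcentrationSurface:
    """Predict the fitted GWR onto fishnet cells.

    Local coefficients are interpolated from the calibration locations to the
    cell centers (inverse-distance weighting, power 2, by default; a cell
    coincident with a station takes that station's coefficients), then dotted
    with the cell covariates. Negative predictions are clamped to zero and
    counted.
    """
    missing = [c for c in fit.covariate_names if c not in grid.columns]
    if missing:
        raise ValueError(f"grid missing covariate columns: {missing}")
    if coefficient_interpolation != "idw":
        raise ValueError(f"unknown coefficient interpolation {coefficient_interpolation!r}")

    targets = grid[["x", "y"]].to_numpy(dtype=float)
    d = cdist(targets, fit.x)
    betas = np.empty((len(grid), fit.coefficients.shape[1]))
    exact = d.min(axis=1) == 0.0
    if exact.any():
        betas[exact] = fit.coefficients[d[exact].argmin(axis=1)]
    inexact = ~exact
    if inexact.any():
        w = 1.0 / d[inexact] ** idw_power
        w /= w.sum(axis=1, keepdims=True)
        betas[inexact] = w @ fit.coefficients

    Xg = np.column_stack(
        [np.ones(len(grid))] + [grid[c].to_numpy(dtype=float) for c in fit.covariate_names]
    )
    vals = np.einsum("ij,ij->i", Xg, betas)
    n_clamped = int(np.sum(vals < 0))
    if n_clamped:
        log.info("clamped %d negative predictions to 0", n_clamped)
    vals = np.clip(vals, 0.0, None)
    cell_id = grid["cell_id"].to_numpy() if "cell_id" in grid.columns else None
    return ConcentrationSurface(
        targets[:, 0], targets[:, 1], vals, "gwr_predicted", n_clamped, cell_id
    )


# ---------------------------------------------------------------------------
# Variogram + ordinary kriging


def empirical_variogram(
    points: np.ndarray, values: np.ndarray, n_bins: int = 12, max_lag_m: float | None = None
) -> pd.DataFrame:
    """Binned empirical semivariances with pair counts."""
    d = cdist(points, points)
    iu = np.triu_indices_from(d, k=1)
    lags = d[iu]
    if max_lag_m is None:
        max_lag_m = float(lags.max()) / 2.0
    sq = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    keep = lags <= max_lag_m
    lags, sq = lags[keep], sq[keep]
    if len(lags) == 0:
        raise ValueError("max_lag smaller than the minimum pair distance: no pairs")
    edges = np.linspace(0.0, max_lag_m, n_bins + 1)
    idx = np.clip(np.digitize(lags, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        if m.sum() == 0:
            continue
        rows.append(
            {"lag": float(lags[m].mean()), "gamma": float(sq[m].mean()), "n_pairs": int(m.sum())}
        )
    return pd.DataFrame(rows)


def fit_variogram(
    points,
    values=None,
    n_bins: int = 12,
    max_lag_m: float | None = None,
    model: str = "exponential",
) -> VariogramModel:
    """Fit a variogram model to empirical semivariances.

    ``points`` may be an (n, 3) array of (x, y, value) or an (n, 2) array with
    ``values`` given separately. Parameters minimize pair-count-weighted least
    squares. Constant data yield the degenerate pure-nugget model
    (nugget = sill = 0).
    """
    pts = np.asarray(points, dtype=float)
    if values is None:
        if pts.shape[1] != 3:
            raise ValueError("expect (x, y, value) triples or separate values")
        values = pts[:, 2]
        pts = pts[:, :2]
    values = np.asarray(values, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 points to fit a variogram")
    if np.ptp(values) == 0:
        log.warning("constant field: pure-nugget variogram")
        return VariogramModel(model, 0.0, 0.0, 1.0)

    emp = empirical_variogram(pts, values, n_bins=n_bins, max_lag_m=max_lag_m)
    lag = emp["lag"].to_numpy()
    gam = emp["gamma"].to_numpy()
    w = np.sqrt(emp["n_pairs"].to_numpy(dtype=float))

    var = float(values.var())
    x0 = np.array([0.1 * var + 1e-12, var, max(lag.max() / 2.0, 1.0)])

    def resid(theta):
        nug, psill, rng = theta
        vm = VariogramModel(model, nug, nug + psill, rng)
        return w * (vm(lag) - gam)

    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 1e-12, 1e-6], [np.inf, np.inf, np.inf]),
        method="trf",
    )
    nug, psill, rng = sol.x
    return VariogramModel(model, float(nug), float(nug + psill), float(rng))


def krige(
    points,
    values,
    variogram: VariogramModel,
    targets,
) -> ConcentrationSurface:
    """Ordinary kriging of scattered data onto target locations.

    Solves the Lagrange-constrained system per target (weights sum to one);
    with a zero nugget the predictor is exact at data points. Duplicate data
    coordinates are collapsed to their mean value first.
    """
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    tgt = np.asarray(targets, dtype=float)

    # deduplicate coincident points with their mean (singular system otherwise)
    key = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "v": vals})
    agg = key.groupby(["x", "y"], as_index=False, sort=False)["v"].mean()
    if len(agg) < len(key):
        log.warning("collapsed %d duplicate points to means", len(key) - len(agg))
    pts = agg[["x", "y"]].to_numpy()
    vals = agg["v"].to_numpy()
    n = len(pts)

    gamma_pp = variogram(cdist(pts, pts))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma_pp
    A[n, :] = 1.0
    A[:, n] = 1.0
    A[n, n] = 0.0

    gamma_pt = variogram(cdist(pts, tgt))  # (n, m)
    B = np.vstack([gamma_pt, np.ones(tgt.shape[0])])
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(A, B, rcond=None)[0]
    weights = sol[:n, :]
    pred = weights.T @ vals
    return ConcentrationSurface(tgt[:, 0], tgt[:, 1], pred, "kriged")


def block_average(
    surface: ConcentrationSurface,
    blocks: pd.DataFrame,
    cell_geometries=None,
) -> pd.Series:
    """Area-weighted mean surface value per block polygon.

    ``cell_geometries`` is the sequence of cell polygons aligned with the
    surface values; when omitted, each surface point is treated as a point
    sample and a block averages the points it contains (nearest point
    fallback for empty blocks).
    """
    from shapely.geometry import Point
    from shapely.strtree import STRtree

    vals = np.atleast_1d(surface.values)
    out = {}
    if cell_geometries is not None:
        geoms = list(cell_geometries)
        tree = STRtree(geoms)
        for row in blocks.itertuples(index=False):
            idx = tree.query(row.geometry)
            wts, vv = [], []
            for i in idx:
                a = geoms[i].intersection(row.geometry).area
                if a > 0:
                    wts.append(a)
                    vv.append(vals[i])
            if wts:
                out[row.block_id] = float(np.average(vv, weights=wts))
            else:
                out[row.block_id] = _nearest_value(surface, row.geometry)
    else:
        pts = [Point(xx, yy) for xx, yy in zip(surface.x, surface.y)]
        tree = STRtree(pts)
        for row in blocks.itertuples(index=False):
            idx = [i for i in tree.query(row.geometry) if row.geometry.covers(pts[i])]
            if idx:
                out[row.block_id] = float(vals[list(idx)].mean())
            else:
                out[row.block_id] = _nearest_value(surface, row.geometry)
                log.warning("block %s intersects no cell; nearest-cell fallback", row.block_id)
    s = pd.Series(out, name="pm25")
    s.index.name = "block_id"
    return s


def _nearest_value(surface: ConcentrationSurface, geom) -> float:
    c = geom.centroid
    d = np.hypot(surface.x - c.x, surface.y - c.y)
    return float(np.atleast_1d(surface.values)[int(d.argmin())])


def hourly_surfaces(
    stations: pd.DataFrame,
    grid: pd.DataFrame,
    hours=None,
    hourly_covariates: pd.DataFrame | None = None,
    bandwidth: float | str = "cv",
    kernel: str = "gaussian",
    use_kriging: bool = False,
) -> tuple[pd.DataFrame, list[GWRFit]]:
    """Full per-hour pipeline: GWR fit → grid prediction → (optional) kriging.

    Returns (cell × hour concentration frame indexed by cell_id, fits).
    Bandwidth is cross-validated on the first processed hour and reused, since
    the station network does not move. Ordinary kriging is an exact
    interpolator, so kriging the fishnet predictions back onto the same
    lattice is the identity; it is therefore off by default here and applied
    through :func:`krige` when predicting onto finer or offset targets.
    """
    if hours is None:
        hours = sorted(stations["hour"].unique())
    fits = []
    cols = {}
    bw = bandwidth
    for h in hours:
        sub = stations[stations["hour"] == h]
        fit = fit_gwr(sub, bandwidth=bw, kernel=kernel)
        bw = fit.bandwidth
        fits.append(fit)
        if hourly_covariates is not None:
            cov_h = hourly_covariates[hourly_covariates["hour"] == h]
            grid_h = grid.drop(
                columns=[c for c in COVARIATES if c in grid.columns]
            ).merge(cov_h.drop(columns=["hour"]), on="cell_id")
        else:
            grid_h = grid
        surf = predict_grid(fit, grid_h)
        vals = surf.values
        if use_kriging:
            vg = fit_variogram(np.column_stack([surf.x, surf.y]), vals)
            if vg.sill > 0:
                kr = krige(np.column_stack([surf.x, surf.y]), vals, vg, np.column_stack([surf.x, surf.y]))
                vals = np.clip(kr.values, 0.0, None)
        cols[h] = vals
    out = pd.DataFrame(cols)
    out.index = grid["cell_id"].to_numpy() if "cell_id" in grid.columns else np.arange(len(grid))
    out.index.name = "cell_id"
    return out, fits
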