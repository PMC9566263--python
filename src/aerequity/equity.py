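"""Exposure-equity metrics: Lorenz/Gini and bivariate Moran / LISA.

The Gini coefficient measures how unequally the exposure burden
(concentration × head count) is spread over a vulnerable population:
units are sorted ascending by per-capita exposure, the Lorenz curve plots
cumulative population share against cumulative burden share, and
G = 1 − 2·∫y dx (trapezoid rule). G = 0 is perfect equality.

Bivariate spatial association between a variable x (weighted PM2.5) and the
spatial lag of a second variable y (vulnerable head count) follows the
Anselin formulation: with z-standardized variables and row-standardized
weights W,

    I = zₓᵀ W z_y / n,     Iᵢ = zₓ,ᵢ · (W z_y)ᵢ

Inference is by random permutation of y (global: full permutation; local:
conditional permutation holding unit i fixed), with two-sided pseudo
p-values (count(|I*| ≥ |I|) + 1) / (n_perm + 1). Significant units are
labeled HH/HL/LH/LL by the quadrant of (zₓ,ᵢ, lag of z_y).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class LorenzResult:
    x: np.ndarray  # cumulative population shares, starts 0 ends 1
    y: np.ndarray  # cumulative exposure-burden shares
    gini: float


@dataclass
class SpatialWeights:
    ids: list
    neighbors: dict  # id -> list of neighbor ids
    weights: dict  # id -> list of row-standardized weights

    @property
    def n(self) -> int:
        return len(self.ids)

    def matrix(self) -> np.ndarray:
        pos = {u: i for i, u in enumerate(self.ids)}
        W = np.zeros((self.n, self.n))
        for u in self.ids:
            for v, w in zip(self.neighbors[u], self.weights[u]):
                W[pos[u], pos[v]] = w
        return W

    @property
    def islands(self) -> list:
        return [u for u in self.ids if not self.neighbors[u]]


@dataclass
class BivariateMoranResult:
    I: float
    p_value: float
    z_score: float
    n_permutations: int
    seed: int
    local: pd.DataFrame  # unit_id, local_I, pseudo_p, cluster
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Lorenz / Gini


def lorenz_gini(exposure_per_unit, population_per_unit) -> LorenzResult:
    """Lorenz curve and Gini of exposure burden over a population.

    ``exposure_per_unit`` is the per-capita exposure (e.g. pod) of each unit;
    ``population_per_unit`` the vulnerable head count. The burden of a unit
    is exposure × population.
    """
    e = np.asarray(exposure_per_unit, dtype=float)
    p = np.asarray(population_per_unit, dtype=float)
    if np.any(e < 0) or np.any(p < 0):
        raise ValueError("inputs must be non-negative")
    if p.sum() <= 0:
        raise ValueError("total population must be positive")
    burden = e * p
    if burden.sum() == 0:
        x = np.concatenate([[0.0], np.cumsum(p) / p.sum()])
        return LorenzResult(x, x.copy(), 0.0)
    order = np.argsort(e, kind="stable")
    cp = np.concatenate([[0.0], np.cumsum(p[order])]) / p.sum()
    cb = np.concatenate([[0.0], np.cumsum(burden[order])]) / burden.sum()
    auc = float(np.trapezoid(cb, cp))
    return LorenzResult(cp, cb, 1.0 - 2.0 * auc)


def lorenz_top_share(result: LorenzResult, top_population_share: float) -> float:
    """Burden share borne by the most-exposed fraction of the population.

    Reporting view of the Lorenz curve read from the top (descending
    per-capita exposure): e.g. top 40% of a population holding 80% of the
    burden.
    """
    q = 1.0 - top_population_share
    return 1.0 - float(np.interp(q, result.x, result.y))


# ---------------------------------------------------------------------------
# Spatial weights


def build_weights(units: pd.DataFrame, scheme: str = "queen", k: int = 6) -> SpatialWeights:
    """Contiguity (queen/rook) or knn weights from unit polygons.

    Queen counts any shared boundary point as adjacency; rook requires a
    shared edge (positive-length boundary intersection). Rows are
    standardized to sum to one; islands keep empty rows (warned).
    """
    from shapely.strtree import STRtree

    ids = list(units["unit_id" if "unit_id" in units.columns else "community_id"])
    geoms = list(units["geometry"])
    nbrs: dict = {u: [] for u in ids}

    if scheme in ("queen", "rook"):
        tree = STRtree(geoms)
        for i, g in enumerate(geoms):
            for j in tree.query(g):
                j = int(j)
                if j == i:
                    continue
                inter = g.intersection(geoms[j])
                if inter.is_empty:
                    continue
                if scheme == "queen" or inter.length > 0:
                    nbrs[ids[i]].append(ids[j])
    elif scheme == "knn":
        cent = np.array([[g.centroid.x, g.centroid.y] for g in geoms])
        from scipy.spatial.distance import cdist

        d = cdist(cent, cent)
        np.fill_diagonal(d, np.inf)
        for i, u in enumerate(ids):
            nbrs[u] = [ids[j] for j in np.argsort(d[i])[:k]]
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")

    weights = {}
    for u in ids:
        nn = len(nbrs[u])
        weights[u] = [1.0 / nn] * nn if nn else []
        if nn == 0:
            warnings.warn(f"island unit {u!r}: no neighbors", RuntimeWarning, stacklevel=2)
    return SpatialWeights(ids, nbrs, weights)


# ---------------------------------------------------------------------------
# Bivariate Moran / LISA


def _zstd(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("constant variable: zero variance")
    return (v - v.mean()) / sd


def bivariate_moran(
    x,
    y,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    compute_local: bool = True,
) -> BivariateMoranResult:
    """Global and local bivariate Moran's I with permutation inference.

    x and y are aligned with ``W.ids`` (array-likes, or Series indexed by the
    unit ids). Global inference permutes y wholesale; local pseudo p-values
    use conditional permutation (unit i held fixed, its neighbors' y drawn
    from the remaining units).
    """
    if seed is None:
        raise ValueError("seed is required for permutation inference")
    if isinstance(x, pd.Series):
        x = x.loc[W.ids].to_numpy()
    if isinstance(y, pd.Series):
        y = y.loc[W.ids].to_numpy()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = W.n
    if len(x) != n or len(y) != n:
        raise ValueError("x, y must align with the weights' unit ids")
    if n < 10:
        raise ValueError("need at least 10 units")
    Wm = W.matrix()
    if np.all(Wm.sum(axis=1) == 0):
        raise ValueError("all-zero weight rows: degenerate weights")

    zx = _zstd(x)
    zy = _zstd(y)
    lag = Wm @ zy
    local = zx * lag
    I = float(zx @ lag / n)

    rng = np.random.default_rng(seed)
    # global: full permutations of y, vectorized
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Zp = zy[perm_idx]  # (n_perm, n)
    I_star = (Zp @ (Wm.T @ zx)) / n
    p_global = (np.count_nonzero(np.abs(I_star) >= abs(I)) + 1) / (n_perm + 1)
    mu, sd = I_star.mean(), I_star.std(ddof=0)
    z_score = (I - mu) / sd if sd > 0 else np.nan

    if not compute_local:
        local_df = pd.DataFrame(
            {"unit_id": W.ids, "local_I": local, "pseudo_p": np.nan, "cluster": "ns"}
        )
        return BivariateMoranResult(
            I, float(p_global), float(z_score), n_perm, seed, local_df, alpha
        )

    # local: conditional permutation, vectorized per unit
    pseudo_p = np.empty(n)
    pos = {u: i for i, u in enumerate(W.ids)}
    for i, u in enumerate(W.ids):
        nb = [pos[v] for v in W.neighbors[u]]
        ki = len(nb)
        if ki == 0:
            pseudo_p[i] = np.nan
            continue
        others = np.delete(zy, i)
        # n_perm draws of ki values without replacement from the others
        draw = np.argsort(rng.random((n_perm, n - 1)), axis=1)[:, :ki]
        lag_star = others[draw].mean(axis=1)  # row-standardized: mean of ki draws
        li_star = zx[i] * lag_star
        pseudo_p[i] = (np.count_nonzero(np.abs(li_star) >= abs(local[i])) + 1) / (n_perm + 1)

    cluster = np.where(
        pseudo_p <= alpha,
        np.where(zx > 0, np.where(lag > 0, "HH", "HL"), np.where(lag > 0, "LH", "LL")),
        "ns",
    )
    cluster = np.where(np.isnan(pseudo_p), "ns", cluster)
    local_df = pd.DataFrame(
        {"unit_id": W.ids, "local_I": local, "pseudo_p": pseudo_p, "cluster": cluster}
    )
    return BivariateMoranResult(I, float(p_global), float(z_score), n_perm, seed, local_df, alpha)


def lisa_clusters(result: BivariateMoranResult, alpha: float | None = None) -> pd.DataFrame:
    """Cluster labels per unit at significance ``alpha``; with counts.

    Returns the local frame relabeled at the requested alpha (``ns`` for
    non-significant units); attach counts via ``.attrs['counts']``.
    """
    df = result.local.copy()
    if alpha is not None and alpha != result.alpha:
        sig = df["pseudo_p"] <= alpha
        df.loc[~sig.fillna(False), "cluster"] = "ns"
    counts = df["cluster"].value_counts().to_dict()
    df.attrs["counts"] = counts
    return df
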