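"""Three-stage walkability index.

1. **Basic index**: the ten facility categories carry fixed importance
   weights summing to 16; for each category the nearest facility's distance
   sets a decay band (0–500 m: no attenuation; 500–1000 m: 25%; 1000–1500 m:
   88%; beyond 1500 m: full attenuation) and the surviving weights are summed.
2. **Single-point index**: the basic index is attenuated by street form —
   block length and intersection density each contribute up to 5% decay
   (10% combined maximum).
3. **Area index**: single-point indices of the fishnet cells intersecting a
   spatial unit are averaged with cell-population weights.

Distances are straight-line in projected metres; a user-supplied distance
function can replace them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_FACILITY_WEIGHTS = {
    "grocery": 3.0,
    "mall": 2.0,
    "restaurants": 3.0,
    "cafe": 2.0,
    "bookstore": 1.0,
    "park": 1.0,
    "entertainment": 1.0,
    "hospital": 1.0,
    "school": 1.0,
    "bank": 1.0,
}

SQMILE_PER_KM2 = 1.0 / 2.58999  # intersections/km² × 2.58999 = per sq mile


@dataclass(frozen=True)
class FacilityWeightTable:
    weights: dict = field(default_factory=lambda: dict(DEFAULT_FACILITY_WEIGHTS))

    @property
    def total(self) -> float:
        return float(sum(self.weights.values()))

    def __post_init__(self):
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("facility weights must be positive")


@dataclass(frozen=True)
class DistanceDecayPolicy:
    """Contiguous half-open distance bands [lo, hi) → attenuation fraction."""

    bands: tuple = (
        (0.0, 500.0, 0.0),
        (500.0, 1000.0, 0.25),
        (1000.0, 1500.0, 0.88),
        (1500.0, float("inf"), 1.0),
    )

    def __post_init__(self):
        prev_hi, prev_decay = 0.0, -1.0
        for lo, hi, decay in self.bands:
            if lo != prev_hi:
                raise ValueError(f"non-contiguous band starting at {lo}")
            if decay < prev_decay:
                raise ValueError("decay must be non-decreasing with distance")
            prev_hi, prev_decay = hi, decay
        if prev_hi != float("inf"):
            raise ValueError("bands must cover all distances")

    def decay(self, distance_m: float) -> float:
        for lo, hi, dec in self.bands:
            if lo <= distance_m < hi:
                return dec
        raise ValueError(f"negative distance {distance_m}")


# Table-driven street-form decay. Bands are (threshold, decay%) read
# top-down: block length uses "value < threshold" with the last band open
# above; intersection density uses "value > threshold" with the last band
# open below.
BLOCK_LENGTH_BANDS = ((120.0, 0), (150.0, 1), (165.0, 2), (180.0, 3), (195.0, 4), (None, 5))
INTERSECTION_BANDS = ((200.0, 0), (150.0, 1), (120.0, 2), (90.0, 3), (60.0, 4), (None, 5))


@dataclass(frozen=True)
class StreetFormDecay:
    block_length_bands: tuple = BLOCK_LENGTH_BANDS
    intersection_bands: tuple = INTERSECTION_BANDS

    def block_length_decay(self, length_m: float) -> float:
        if length_m < 0:
            raise ValueError("negative block length")
        for thr, pct in self.block_length_bands:
            if thr is not None and length_m < thr:
                return pct / 100.0
        return self.block_length_bands[-1][1] / 100.0

    def intersection_decay(self, density_per_sqmile: float) -> float:
        if density_per_sqmile < 0:
            raise ValueError("negative intersection density")
        for thr, pct in self.intersection_bands:
            if thr is not None and density_per_sqmile > thr:
                return pct / 100.0
        return self.intersection_bands[-1][1] / 100.0


def per_km2_to_per_sqmile(density_per_km2: float) -> float:
    """Convert an intersection density from per km² to per square mile."""
    return density_per_km2 * 2.58999


def base_index(
    origin_xy,
    facilities: pd.DataFrame,
    weights: FacilityWeightTable | None = None,
    decay: DistanceDecayPolicy | None = None,
) -> float:
    """Basic walkability index at one origin point.

    Only the nearest facility of each category contributes: its distance sets
    the decay band and the contribution is weight × (1 − decay).
    """
    weights = weights or FacilityWeightTable()
    decay = decay or DistanceDecayPolicy()
    unknown = set(facilities["category"].unique()) - set(weights.weights)
    if unknown:
        raise ValueError(
            f"unknown facility categories {sorted(unknown)}; known: {sorted(weights.weights)}"
        )
    ox, oy = float(origin_xy[0]), float(origin_xy[1])
    total = 0.0
    for cat, grp in facilities.groupby("category"):
        d = np.hypot(grp["x"].to_numpy() - ox, grp["y"].to_numpy() - oy)
        total += weights.weights[cat] * (1.0 - decay.decay(float(d.min())))
    return total


def point_index(
    base: float,
    block_length_m: float,
    intersection_density_per_sqmile: float,
    decay: StreetFormDecay | None = None,
) -> float:
    """Single-point index: basic index attenuated by street form (≤ 10%)."""
    if base < 0:
        raise ValueError("negative base index")
    decay = decay or StreetFormDecay()
    total = decay.block_length_decay(block_length_m) + decay.intersection_decay(
        intersection_density_per_sqmile
    )
    return base * (1.0 - total)


def area_index(point_indices, cell_populations) -> float:
    """Population-weighted mean of cell point-indices within one unit."""
    v = np.asarray(point_indices, dtype=float)
    w = np.asarray(cell_populations, dtype=float)
    if v.shape != w.shape or v.size == 0:
        raise ValueError("point indices and populations must align and be non-empty")
    if w.sum() <= 0:
        log.warning("zero cell population in unit; unweighted mean fallback")
        return float(v.mean())
    return float(np.average(v, weights=w))


def grid_walkscore(
    grid: pd.DataFrame,
    facilities: pd.DataFrame,
    weights: FacilityWeightTable | None = None,
    decay: DistanceDecayPolicy | None = None,
    street: StreetFormDecay | None = None,
) -> pd.DataFrame:
    """Basic and single-point indices at every fishnet cell center.

    Expects grid columns x, y, block_length_m, int_density_sqmi.
    """
    weights = weights or FacilityWeightTable()
    decay = decay or DistanceDecayPolicy()
    street = street or StreetFormDecay()
    unknown = set(facilities["category"].unique()) - set(weights.weights)
    if unknown:
        raise ValueError(f"unknown facility categories {sorted(unknown)}")

    gx = grid["x"].to_numpy(dtype=float)
    gy = grid["y"].to_numpy(dtype=float)
    base = np.zeros(len(grid))
    # vectorized nearest-facility distance per category
    for cat, grp in facilities.groupby("category"):
        fx = grp["x"].to_numpy(dtype=float)
        fy = grp["y"].to_numpy(dtype=float)
        d2 = (gx[:, None] - fx[None, :]) ** 2 + (gy[:, None] - fy[None, :]) ** 2
        dmin = np.sqrt(d2.min(axis=1))
        dec = np.array([decay.decay(v) for v in dmin])
        base += weights.weights[cat] * (1.0 - dec)

    pt = np.array(
        [
            point_index(b, bl, dens, street)
            for b, bl, dens in zip(
                base, grid["block_length_m"].to_numpy(), grid["int_density_sqmi"].to_numpy()
            )
        ]
    )
    out = grid[["cell_id"]].copy() if "cell_id" in grid.columns else pd.DataFrame(index=grid.index)
    out["base_index"] = base
    out["point_index"] = pt
    return out


def unit_walkscore(
    cell_scores: pd.DataFrame,
    cell_unit_ids,
    cell_populations,
) -> pd.Series:
    """Area walkability index per unit, population-weighting member cells."""
    df = cell_scores.copy()
    df["unit_id"] = np.asarray(cell_unit_ids)
    df["population"] = np.asarray(cell_populations, dtype=float)
    out = {}
    for uid, grp in df.groupby("unit_id"):
        out[uid] = area_index(grp["point_index"].to_numpy(), grp["population"].to_numpy())
    s = pd.Series(out, name="area_index")
    s.index.name = "unit_id"
    return s
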