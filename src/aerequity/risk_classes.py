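"""Risk classification machinery.

* Hourly tertile scoring: each hour's block exposure intensities are split
  into equal-count thirds scored 1/2/3 (one assignment per hour, 168 for a
  week), then summed per block and re-tertiled into a final low/medium/high
  exposure level.
* Jenks natural breaks: exact dynamic-programming minimization of the
  within-class sum of squared deviations, used for the walkability and
  age-proportion axes.
* Combined typologies: 3×3 label grids for blocks (exposure × walkability)
  and communities (weighted concentration × age-group proportion); all nine
  labels are emitted with their observed frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LEVELS = ("low", "medium", "high")


@dataclass
class RiskTypology:
    unit_id: object
    exposure_level: str
    second_axis_level: str

    @property
    def label(self) -> str:
        return f"{self.exposure_level}-{self.second_axis_level}"


def quantile_tertiles(values, ids=None) -> np.ndarray:
    """Equal-count tertile scores in {1, 2, 3}, lowest third scoring 1.

    For distinct values the counts differ by at most one, with remainder
    units going to the lower classes first. Equal values always share a
    class: a run of ties takes the class of its lowest-sorted member, so a
    constant vector scores all 1 and the assignment is invariant to input
    order.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError(f"need at least 3 values, got {n}")
    if ids is None:
        order = np.argsort(v, kind="stable")
    else:
        order = np.lexsort((np.asarray(ids), v))
    base, rem = divmod(n, 3)
    sizes = [base + (1 if k < rem else 0) for k in range(3)]
    sorted_scores = np.empty(n, dtype=int)
    start = 0
    for k, sz in enumerate(sizes, start=1):
        sorted_scores[start : start + sz] = k
        start += sz
    # ties share the lower class
    s = v[order]
    for i in range(1, n):
        if s[i] == s[i - 1]:
            sorted_scores[i] = sorted_scores[i - 1]
    scores = np.empty(n, dtype=int)
    scores[order] = sorted_scores
    return scores


def hourly_score_matrix(E_matrix: pd.DataFrame) -> pd.DataFrame:
    """Tertile-score every hourly column of a blocks × hours intensity matrix."""
    if E_matrix.isna().any().any():
        raise ValueError("missing hours in exposure-intensity matrix")
    scored = {h: quantile_tertiles(E_matrix[h].to_numpy()) for h in E_matrix.columns}
    return pd.DataFrame(scored, index=E_matrix.index)


def hourly_score_sum(E_matrix: pd.DataFrame) -> pd.DataFrame:
    """Sum the hourly tertile scores per block and tertile the sums.

    Returns a frame with columns score_sum (in [n_hours, 3·n_hours]) and
    exposure_level.
    """
    scores = hourly_score_matrix(E_matrix)
    sums = scores.sum(axis=1)
    levels = quantile_tertiles(sums.to_numpy())
    return pd.DataFrame(
        {"score_sum": sums, "exposure_level": [LEVELS[s - 1] for s in levels]},
        index=E_matrix.index,
    )


def jenks_breaks(values, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact Jenks natural-breaks classification.

    Dynamic programming over the sorted values minimizes the total
    within-class sum of squared deviations. Returns (breaks, classes) where
    ``breaks`` holds the k−1 upper boundaries of the lower classes (the max
    value in each) and ``classes`` the 0-based class of each input value.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n; got k={k}, n={n}")
    order = np.argsort(v, kind="stable")
    s = v[order]

    # prefix sums for O(1) within-class SSD of s[i..j]
    c1 = np.concatenate([[0.0], np.cumsum(s)])
    c2 = np.concatenate([[0.0], np.cumsum(s**2)])

    def ssd(i, j):  # inclusive 0-based range
        m = j - i + 1
        tot = c1[j + 1] - c1[i]
        return (c2[j + 1] - c2[i]) - tot * tot / m

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            best, arg = INF, kk - 1
            for i in range(kk - 1, j):
                c = cost[kk - 1, i] + ssd(i, j - 1)
                if c < best:
                    best, arg = c, i
            cost[kk, j] = best
            back[kk, j] = arg

    # recover class boundaries
    bounds = np.empty(k + 1, dtype=int)
    bounds[k] = n
    j = n
    for kk in range(k, 0, -1):
        j = back[kk, j]
        bounds[kk - 1] = j

    classes_sorted = np.empty(n, dtype=int)
    for kk in range(k):
        classes_sorted[bounds[kk] : bounds[kk + 1]] = kk
    classes = np.empty(n, dtype=int)
    classes[order] = classes_sorted
    breaks = np.array([s[bounds[kk] - 1] for kk in range(1, k)])
    return breaks, classes


def jenks_levels(values, k: int = 3) -> list[str]:
    """Jenks classes mapped onto low/medium/high names (k ≤ 3).

    A degenerate (constant) axis collapses to a single class.
    """
    v = np.asarray(values, dtype=float)
    k_eff = min(k, len(np.unique(v)))
    if k_eff < k:
        log.warning("degenerate axis: only %d distinct values for %d classes", k_eff, k)
    _, classes = jenks_breaks(v, k_eff)
    names = LEVELS[:k_eff] if k_eff == 3 else (["low"] if k_eff == 1 else ["low", "high"])
    return [names[c] for c in classes]


def combine_levels(
    ids, first_levels, second_levels
) -> pd.DataFrame:
    """3×3 combination of two level vectors into typology labels."""
    df = pd.DataFrame(
        {
            "unit_id": ids,
            "exposure_level": first_levels,
            "second_axis_level": second_levels,
        }
    )
    df["label"] = df["exposure_level"] + "-" + df["second_axis_level"]
    return df


def classify_blocks(
    exposure_levels: pd.Series, walk_index: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Combined block typology: tertiled exposure × Jenks-classed walkability.

    Blocks missing a walk index are excluded (logged). Returns (typology
    frame, observed label frequency table).
    """
    walk = walk_index.dropna()
    dropped = set(exposure_levels.index) - set(walk.index)
    if dropped:
        log.warning("excluding %d blocks without a walk index", len(dropped))
    ids = [i for i in exposure_levels.index if i in set(walk.index)]
    wlev = jenks_levels(walk.loc[ids].to_numpy(), 3)
    df = combine_levels(ids, exposure_levels.loc[ids].to_numpy(), wlev)
    freq = df["label"].value_counts().sort_index()
    return df, freq


def classify_communities(
    pod: pd.Series, age_proportion: pd.Series, group: str = ""
) -> tuple[pd.DataFrame, pd.Series]:
    """Community typology: Jenks 3-classing of pod × of the age proportion."""
    ids = pod.index.intersection(age_proportion.index)
    plev = jenks_levels(pod.loc[ids].to_numpy(), 3)
    alev = jenks_levels(age_proportion.loc[ids].to_numpy(), 3)
    df = combine_levels(list(ids), plev, alev)
    if group:
        df["group"] = group
    freq = df["label"].value_counts().sort_index()
    return df, freq
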