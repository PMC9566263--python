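"""Dynamic exposure statistics under hourly population mobility.

Two statistics are computed from hourly block/community PM2.5 and hourly
population fields:

* **Exposure intensity** ``E_j`` of a spatial unit: the sum over counted hours
  of concentration × population density, in µg·person/(m³·km²), together with
  ``NT``, the number of counted (polluted) hours. With no threshold every hour
  counts.

* **Time-activity-weighted concentration** (``pod``) of a community: the mean
  hourly PM2.5 its residents actually experience given their daily schedules —
  the elderly (65+) and children (0–6) stay in their home community all week;
  workers (19–59) are at their workplace community 8:00–18:00 Monday–Friday
  and at home otherwise. Each origin–destination (OD) group contributes in
  proportion to its head count.

The static baseline (residence-only time-mean concentration) is provided for
comparison; ignoring mobility understates exposure whenever commuting flows
point toward more polluted places.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("elderly_65p", "child_0_6", "worker_19_59")

#: hour-of-day bins counted as "at work" for the worker schedule, half-open
#: [h, h+1): 8:00–18:00 is bins 8..17 inclusive.
WORK_HOUR_BINS = tuple(range(8, 18))
#: weekday indices (day 0 = Monday) on which the work schedule applies.
WORK_DAYS = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class TimeActivitySchedule:
    """At-work hour bins for one age group, as (weekday, hour-of-day) pairs."""

    group: str
    at_work_hours: frozenset = field(default_factory=frozenset)

    def is_at_work(self, hour_index: int) -> bool:
        day, hod = divmod(hour_index, 24)
        return (day % 7, hod) in self.at_work_hours


def default_schedules() -> dict[str, TimeActivitySchedule]:
    """The three age-group schedules: only workers leave home."""
    work = frozenset((d, h) for d in WORK_DAYS for h in WORK_HOUR_BINS)
    return {
        "elderly_65p": TimeActivitySchedule("elderly_65p"),
        "child_0_6": TimeActivitySchedule("child_0_6"),
        "worker_19_59": TimeActivitySchedule("worker_19_59", work),
    }


def is_work_hour(hour_index: int) -> bool:
    """True if the worker schedule places workers at the workplace this hour."""
    day, hod = divmod(hour_index, 24)
    return day % 7 in WORK_DAYS and hod in WORK_HOUR_BINS


@dataclass
class ExposureIntensityResult:
    block_id: object
    E: float
    NT: int
    hourly_conc: np.ndarray
    hourly_density: np.ndarray


@dataclass
class WeightedConcentrationResult:
    community_id: object
    pod: float
    sum_home: float  # ΣCO: person-weighted home-hours concentration sum
    sum_work: float  # ΣCD: person-weighted work-hours concentration sum
    total_population: float  # ΣP


def exposure_intensity(
    block_conc, block_density, threshold: float | None = None, block_id=None
) -> ExposureIntensityResult:
    """Hourly-sum exposure intensity of one block.

    E = Σ_h conc_h × density_h over hours with conc_h > ``threshold``
    (all hours when ``threshold`` is None); NT = number of counted hours.
    """
    conc = np.asarray(block_conc, dtype=float)
    dens = np.asarray(block_density, dtype=float)
    if conc.shape != dens.shape:
        raise ValueError(f"length mismatch: conc {conc.shape} vs density {dens.shape}")
    if np.any(dens < 0):
        raise ValueError("negative population density")
    mask = np.ones_like(conc, dtype=bool) if threshold is None else conc > threshold
    E = float(np.sum(conc[mask] * dens[mask]))
    return ExposureIntensityResult(block_id, E, int(mask.sum()), conc, dens)


def weighted_concentration(
    od_groups: pd.DataFrame,
    conc: pd.DataFrame,
    schedules: dict[str, TimeActivitySchedule] | None = None,
    community_id=None,
) -> WeightedConcentrationResult:
    """Time-activity-weighted PM2.5 for one community's resident OD groups.

    Parameters
    ----------
    od_groups : frame with columns home_id, work_id, group, count — all rows
        sharing the same home community.
    conc : hourly concentrations, indexed by community id, one column per
        hour (0..n_hours-1).
    """
    if schedules is None:
        schedules = default_schedules()
    if od_groups.empty or od_groups["count"].sum() <= 0:
        raise ValueError("community has zero resident population; pod undefined")
    homes = od_groups["home_id"].unique()
    if community_id is None:
        if len(homes) != 1:
            raise ValueError("od_groups must share a single home community")
        community_id = homes[0]

    n_hours = conc.shape[1]
    if n_hours % 24:
        raise ValueError("concentration series must cover whole days")
    hour_cols = list(conc.columns)
    at_work = np.array(
        [schedules["worker_19_59"].is_at_work(h) for h in range(n_hours)]
    )

    sum_home = 0.0
    sum_work = 0.0
    total_p = 0.0
    weighted = 0.0
    for row in od_groups.itertuples(index=False):
        p = float(row.count)
        if p == 0:
            continue
        home_c = conc.loc[row.home_id, hour_cols].to_numpy(dtype=float)
        if row.group == "worker_19_59":
            work_id = row.work_id
            if work_id not in conc.index:
                # workplace outside the study region: fall back to home conc
                work_c = home_c
            else:
                work_c = conc.loc[work_id, hour_cols].to_numpy(dtype=float)
            co = float(home_c[~at_work].sum())
            cd = float(work_c[at_work].sum())
        else:
            co = float(home_c.sum())
            cd = 0.0
        sum_home += p * co
        sum_work += p * cd
        weighted += p * (co + cd)
        total_p += p

    pod = weighted / (total_p * n_hours)
    return WeightedConcentrationResult(community_id, pod, sum_home, sum_work, total_p)


def weighted_concentration_all(
    od_groups: pd.DataFrame,
    conc: pd.DataFrame,
    schedules: dict[str, TimeActivitySchedule] | None = None,
) -> pd.DataFrame:
    """pod for every home community present in ``od_groups``.

    Returns a frame indexed by community id with columns pod, sum_home,
    sum_work, population. Communities with zero population are excluded.
    """
    out = []
    for cid, grp in od_groups.groupby("home_id", sort=True):
        if grp["count"].sum() <= 0:
            continue
        r = weighted_concentration(grp, conc, schedules, community_id=cid)
        out.append(
            {
                "community_id": cid,
                "pod": r.pod,
                "sum_home": r.sum_home,
                "sum_work": r.sum_work,
                "population": r.total_population,
            }
        )
    return pd.DataFrame(out).set_index("community_id")


def hourly_community_population(
    residential: pd.Series, od_groups: pd.DataFrame, hour: int
) -> pd.Series:
    """Head count per community at one hour under the OD work schedules.

    ``residential`` is the night-time (all-home) population indexed by
    community id. During work hours commuting workers are moved from home to
    workplace; the regional total is conserved.
    """
    pop = residential.astype(float).copy()
    if is_work_hour(hour):
        workers = od_groups[
            (od_groups["group"] == "worker_19_59")
            & (od_groups["home_id"] != od_groups["work_id"])
        ]
        out = workers.groupby("home_id")["count"].sum()
        inn = workers.groupby("work_id")["count"].sum()
        pop = pop.sub(out, fill_value=0.0).add(inn, fill_value=0.0)
    return pop


def static_exposure(conc: pd.DataFrame) -> pd.Series:
    """Residence-only baseline: time-mean concentration per community."""
    return conc.mean(axis=1)


def regional_means(
    pod: pd.Series, static: pd.Series, population: pd.Series
) -> tuple[float, float]:
    """Population-weighted regional means of dynamic pod and static baseline."""
    idx = pod.index
    w = population.loc[idx].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError("total population is zero")
    dyn = float(np.average(pod.to_numpy(dtype=float), weights=w))
    sta = float(np.average(static.loc[idx].to_numpy(dtype=float), weights=w))
    return dyn, sta


def decile_exposure(
    communities: pd.DataFrame,
    group_prop_col: str,
    pod_col: str = "pod",
    weight_col: str | None = None,
) -> pd.DataFrame:
    """Decile table of pod by ascending age-group proportion.

    Communities are sorted ascending by ``group_prop_col`` and split into 10
    equal-count bins (remainder spread over the lowest deciles); each decile
    reports the population-weighted mean pod (weights from ``weight_col``,
    unweighted if None).
    """
    df = communities.dropna(subset=[pod_col, group_prop_col])
    if len(df) < 10:
        raise ValueError(f"need >= 10 communities, got {len(df)}")
    df = df.sort_values([group_prop_col], kind="stable")
    chunks = np.array_split(np.arange(len(df)), 10)
    rows = []
    for i, idx in enumerate(chunks, start=1):
        sub = df.iloc[idx]
        if weight_col is not None and sub[weight_col].sum() > 0:
            mean_pod = float(np.average(sub[pod_col], weights=sub[weight_col]))
        else:
            mean_pod = float(sub[pod_col].mean())
        rows.append({"decile": f"D{i}", "mean_pod": mean_pod, "n": len(sub)})
    return pd.DataFrame(rows)
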