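"""End-to-end orchestration: simulate → surface → exposure → walkscore →
classify → equity, driven by one config, with a reproducibility manifest.

All tabular artifacts are CSV, geometries GeoJSON; every stochastic stage
draws from a child stream of the single master seed, so re-running with the
same config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import equity as eq
from . import exposure as ex
from . import pm25_surface as ps
from . import risk_classes as rc
from . import walkscore as ws
from .geoio import geojson_to_frame
from .synthetic_city import AgeGradients, CityConfig, generate_city, write_city

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "surface", "exposure", "walkscore", "classify", "equity")

#: upstream artifacts each stage needs and the stage that produces them
STAGE_INPUTS = {
    "surface": {
        "stations.csv": "simulate",
        "grid.geojson": "simulate",
        "grid_covariates.csv": "simulate",
    },
    "exposure": {
        "block_pm25.csv": "surface",
        "community_pm25.csv": "surface",
        "od_groups.csv": "simulate",
        "communities.geojson": "simulate",
        "blocks.geojson": "simulate",
    },
    "walkscore": {"facilities.csv": "simulate", "grid.geojson": "simulate"},
    "classify": {
        "exposure_matrix.csv": "exposure",
        "walkscore_units.csv": "walkscore",
        "pod_communities.csv": "exposure",
        "communities.geojson": "simulate",
    },
    "equity": {"pod_communities.csv": "exposure", "communities.geojson": "simulate"},
}


@dataclass
class PipelineConfig:
    out_dir: str = "aerequity_run"
    seed: int = 7
    stages: tuple = ALL_STAGES
    # synthetic city
    extent_km: float = 24.0
    grid_res_m: float = 1000.0
    n_blocks: int = 144
    n_communities: int = 36
    n_stations: int = 10
    n_hours: int = 168
    noise_sd: float = 1.0
    commute_fraction: float = 0.6
    total_population: int = 500_000
    # surface
    bandwidth: object = "cv"
    kernel: str = "gaussian"
    variogram_model: str = "exponential"
    use_kriging: bool = False
    # exposure
    pollution_threshold: float | None = None
    # equity
    weights_scheme: str = "queen"
    n_perm: int = 999
    alpha: float = 0.05

    def city_config(self) -> CityConfig:
        return CityConfig(
            extent_km=self.extent_km,
            grid_res_m=self.grid_res_m,
            n_blocks=self.n_blocks,
            n_communities=self.n_communities,
            n_stations=self.n_stations,
            n_hours=self.n_hours,
            seed=int(np.random.SeedSequence(self.seed).generate_state(1)[0] % (2**31)),
            noise_sd=self.noise_sd,
            commute_fraction=self.commute_fraction,
            total_population=self.total_population,
            age_gradients=AgeGradients(),
        )


@dataclass
class RunManifest:
    config_hash: str
    stages_run: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    wall_clock_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(out: Path, stage: str) -> None:
    for fname, producer in STAGE_INPUTS.get(stage, {}).items():
        if not (out / fname).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs {fname}, produced by stage '{producer}' — "
                f"run that stage first"
            )


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, out: Path) -> list[str]:
    city = generate_city(cfg.city_config())
    paths = write_city(city, out)
    # cell-level residential population for the walkscore weights
    night = city.population_snapshot(3, level="community")
    cell_pop = (
        night.loc[city.grid["community_id"]].to_numpy()
        * (cfg.grid_res_m / 1000.0) ** 2
    )
    pd.DataFrame({"cell_id": city.grid["cell_id"], "population": cell_pop}).to_csv(
        out / "cell_population.csv", index=False
    )
    # hourly covariates on the fishnet (AOD daily, POP hourly, rest static)
    cov_frames = []
    for h in range(cfg.n_hours):
        cov = city.cell_covariates(h)[["cell_id", "aod", "pop", "ndvi", "road", "np_dist"]]
        cov.insert(1, "hour", h)
        cov_frames.append(cov)
    pd.concat(cov_frames).to_csv(out / "grid_covariates.csv", index=False)
    return [Path(p).name for p in paths.values()] + [
        "cell_population.csv",
        "grid_covariates.csv",
    ]


def stage_surface(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, "surface")
    stations = pd.read_csv(out / "stations.csv")
    grid = geojson_to_frame(out / "grid.geojson")
    covariates = pd.read_csv(out / "grid_covariates.csv")
    conc, fits = ps.hourly_surfaces(
        stations,
        grid,
        hourly_covariates=covariates,
        bandwidth=cfg.bandwidth,
        kernel=cfg.kernel,
        use_kriging=cfg.use_kriging,
    )
    long = conc.stack().rename("pm25").reset_index()
    long.columns = ["cell_id", "hour", "pm25"]
    long.to_csv(out / "surface.csv", index=False)
    # zonal means; cells nest exactly in blocks and communities here
    block = conc.groupby(grid["block_id"].to_numpy()).mean()
    block.index.name = "block_id"
    block.to_csv(out / "block_pm25.csv")
    comm = conc.groupby(grid["community_id"].to_numpy()).mean()
    comm.index.name = "community_id"
    comm.to_csv(out / "community_pm25.csv")
    pd.DataFrame(
        {
            "hour": sorted(stations["hour"].unique()),
            "r2": [f.r2 for f in fits],
            "bandwidth_m": [f.bandwidth for f in fits],
        }
    ).to_csv(out / "gwr_fit.csv", index=False)
    return ["surface.csv", "block_pm25.csv", "community_pm25.csv", "gwr_fit.csv"]


def stage_exposure(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, "exposure")
    block_conc = pd.read_csv(out / "block_pm25.csv", index_col=0)
    comm_conc = pd.read_csv(out / "community_pm25.csv", index_col=0)
    od = pd.read_csv(out / "od_groups.csv")
    comms = geojson_to_frame(out / "communities.geojson").set_index("community_id")
    blocks = geojson_to_frame(out / "blocks.geojson").set_index("block_id")
    comm_conc.columns = comm_conc.columns.astype(int)
    block_conc.columns = block_conc.columns.astype(int)
    n_hours = block_conc.shape[1]

    residential = comms["population"]
    dens_cols = {}
    for h in range(n_hours):
        pop = ex.hourly_community_population(residential, od, h)
        dens_c = pop / comms["area_km2"]
        dens_cols[h] = dens_c.loc[blocks["community_id"]].to_numpy()
    density = pd.DataFrame(dens_cols, index=blocks.index)

    rows = []
    E_matrix = pd.DataFrame(
        block_conc.to_numpy() * density.to_numpy(),
        index=block_conc.index,
        columns=block_conc.columns,
    )
    for bid in block_conc.index:
        r = ex.exposure_intensity(
            block_conc.loc[bid].to_numpy(),
            density.loc[bid].to_numpy(),
            threshold=cfg.pollution_threshold,
            block_id=bid,
        )
        rows.append({"block_id": bid, "E": r.E, "NT": r.NT})
    pd.DataFrame(rows).to_csv(out / "exposure_blocks.csv", index=False)
    E_matrix.to_csv(out / "exposure_matrix.csv")

    pods = ex.weighted_concentration_all(od, comm_conc)
    static = ex.static_exposure(comm_conc)
    pods["static_mean"] = static.loc[pods.index]
    for col in ("prop_0_6", "prop_19_59", "prop_65p"):
        pods[col] = comms[col].loc[pods.index]
    pods.to_csv(out / "pod_communities.csv")
    return ["exposure_blocks.csv", "exposure_matrix.csv", "pod_communities.csv"]


def stage_walkscore(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, "walkscore")
    grid = geojson_to_frame(out / "grid.geojson")
    facilities = pd.read_csv(out / "facilities.csv")
    cell_pop = pd.read_csv(out / "cell_population.csv").set_index("cell_id")["population"]
    scores = ws.grid_walkscore(grid, facilities)
    scores.to_csv(out / "walkscore_points.csv", index=False)
    units = ws.unit_walkscore(
        scores,
        grid["block_id"].to_numpy(),
        cell_pop.loc[scores["cell_id"]].to_numpy(),
    )
    units.to_frame().to_csv(out / "walkscore_units.csv")
    return ["walkscore_points.csv", "walkscore_units.csv"]


def stage_classify(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, "classify")
    E_matrix = pd.read_csv(out / "exposure_matrix.csv", index_col=0)
    E_matrix.columns = E_matrix.columns.astype(int)
    walk = pd.read_csv(out / "walkscore_units.csv", index_col=0)["area_index"]
    levels = rc.hourly_score_sum(E_matrix)
    typ, freq = rc.classify_blocks(levels["exposure_level"], walk)
    typ = typ.merge(
        levels["score_sum"], left_on="unit_id", right_index=True, how="left"
    )
    typ.to_csv(out / "block_typology.csv", index=False)

    pods = pd.read_csv(out / "pod_communities.csv", index_col=0)
    frames = []
    for group, col in (("elderly_65p", "prop_65p"), ("child_0_6", "prop_0_6")):
        t, _ = rc.classify_communities(pods["pod"], pods[col], group=group)
        frames.append(t)
    pd.concat(frames).to_csv(out / "community_typology.csv", index=False)
    return ["block_typology.csv", "community_typology.csv"]


def stage_equity(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, "equity")
    pods = pd.read_csv(out / "pod_communities.csv", index_col=0)
    comms = geojson_to_frame(out / "communities.geojson")
    W = eq.build_weights(comms, scheme=cfg.weights_scheme)
    pods = pods.loc[[i for i in W.ids if i in pods.index]]

    seed = int(np.random.SeedSequence([cfg.seed, 1]).generate_state(1)[0] % (2**31))
    results = {}
    lisa_frames = []
    for group, col in (("elderly", "prop_65p"), ("children", "prop_0_6")):
        count = pods[col] * pods["population"]
        lr = eq.lorenz_gini(pods["pod"].to_numpy(), count.to_numpy())
        x = pods["pod"].reindex(W.ids)
        y = count.reindex(W.ids)
        mor = eq.bivariate_moran(
            x, y, W, n_perm=cfg.n_perm, seed=seed, alpha=cfg.alpha
        )
        clusters = eq.lisa_clusters(mor)
        clusters["group"] = group
        lisa_frames.append(clusters)
        results[group] = {
            "gini": lr.gini,
            "moran_I": mor.I,
            "z_score": mor.z_score,
            "p_value": mor.p_value,
            "cluster_counts": clusters.attrs["counts"],
        }
    dyn, sta = ex.regional_means(pods["pod"], pods["static_mean"], pods["population"])
    results["regional"] = {"dynamic_mean": dyn, "static_mean": sta}
    (out / "equity.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    pd.concat(lisa_frames).to_csv(out / "lisa_clusters.csv", index=False)
    return ["equity.json", "lisa_clusters.csv"]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "surface": stage_surface,
    "exposure": stage_exposure,
    "walkscore": stage_walkscore,
    "classify": stage_classify,
    "equity": stage_equity,
}


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run the enabled stages in dependency order and write the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash)
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        log.info("running stage %s", stage)
        written = _STAGE_FUNCS[stage](cfg, out)
        manifest.wall_clock_s[stage] = round(time.perf_counter() - t0, 3)
        manifest.stages_run.append(stage)
        for fname in written:
            manifest.checksums[fname] = _sha256(out / fname)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# config file handling


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        log.warning("ignoring unknown config keys: %s", sorted(unknown))
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "stages" in kwargs:
        kwargs["stages"] = tuple(kwargs["stages"])
    return PipelineConfig(**kwargs)


def validate_config(path) -> dict:
    """Validate a YAML pipeline config; returns {'errors': [...], 'warnings': [...]}."""
    report = {"errors": [], "warnings": []}
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        report["errors"].append(f"unparseable config: {e}")
        return report
    if not isinstance(raw, dict):
        report["errors"].append("config must be a mapping")
        return report
    known = set(PipelineConfig.__dataclass_fields__)
    for k in sorted(set(raw) - known):
        report["warnings"].append(f"unknown key: {k}")
    cfg_kwargs = {k: v for k, v in raw.items() if k in known}
    if "stages" in cfg_kwargs:
        cfg_kwargs["stages"] = tuple(cfg_kwargs["stages"])
        for s in cfg_kwargs["stages"]:
            if s not in ALL_STAGES:
                report["errors"].append(f"unknown stage: {s}")
    try:
        cfg = PipelineConfig(**cfg_kwargs)
    except TypeError as e:
        report["errors"].append(str(e))
        return report
    stochastic = {"simulate", "equity"} & set(cfg.stages)
    if stochastic and raw.get("seed") is None and "seed" not in raw:
        report["warnings"].append("no explicit seed; default seed 7 will be used")
    try:
        cfg.city_config().validate()
    except ValueError as e:
        report["errors"].append(str(e))
    if not 0 < cfg.alpha < 1:
        report["errors"].append(f"alpha must be in (0,1), got {cfg.alpha}")
    if cfg.n_perm < 1:
        report["errors"].append("n_perm must be >= 1")
    return report
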