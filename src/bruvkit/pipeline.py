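"""Configuration-driven end-to-end pipeline runner.

Runs design -> simulate -> MaxN -> indices -> covariates -> spatial ->
models -> rarefaction on the synthetic seascape, with plain-file handoffs
between stages so each stage is independently testable and resumable, and
emits a machine-readable run report with a determinism hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._raster import read_ascii_grid
from . import synthetic, design, ingest, indices as idx_mod, covariates as cov_mod
from . import spatial, models as mod_mod, rarefaction as rare_mod

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "synthetic_lw_registry"]

STAGE_ORDER = ("seascape", "design", "simulate", "maxn", "indices",
               "covariates", "spatial", "models", "rarefaction")

RESPONSE_FAMILIES = {"richness": ("poisson", "log"),
                     "abundance": ("negbin", "log"),
                     "biomass_kg": ("gamma", "log")}


class PipelineError(RuntimeError):
    """A stage failed or a required upstream output is missing."""


@dataclass
class RunConfig:
    seed: int = 1
    output_dir: str = "bruvkit_out"
    stages: tuple[str, ...] = STAGE_ORDER
    extent: tuple[float, float, float, float] = (0., 0., 10_000., 10_000.)
    cell_size: float = 100.0
    n_islands: int = 5
    n_per_stratum: dict = field(default_factory=lambda: {"Reefs": 200,
                                                         "Sediments": 100})
    min_dist: float = 200.0
    depth_range: tuple[float, float] = (0.0, 40.0)
    n_species: int = 30
    n_frames: int = 100
    buffer_radius: float = 200.0
    r_max: float = 0.55
    vif_max: float = 5.0
    k_neighbours: int = 4
    hex_area: float = 1_000_000.0
    rarefaction_t_max: int = 1500
    bootstrap_B: int = 200
    responses: tuple[str, ...] = ("richness", "abundance", "biomass_kg")

    def __post_init__(self):
        for name, val in (("min_dist", self.min_dist),
                          ("buffer_radius", self.buffer_radius),
                          ("hex_area", self.hex_area),
                          ("cell_size", self.cell_size),
                          ("bootstrap_B", self.bootstrap_B)):
            if val <= 0 and name != "min_dist":
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text(encoding="utf-8"))
        flat = {}
        for section in raw.values() if all(isinstance(v, dict) for v in raw.values()) else [raw]:
            flat.update(section)
        known = {f for f in cls.__dataclass_fields__}
        cfg = {k: v for k, v in flat.items() if k in known}
        for key in ("stages", "extent", "depth_range", "responses"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


def synthetic_lw_registry(species_pool) -> pd.DataFrame:
    """Length-weight parameters for the synthetic species pool.

    Cube-law coefficients with group-specific condition factors, reference
    lengths taken from the generating length medians, and a family grouping
    so the family-mean proxy tier is exercised.
    """
    a_of = {"teleost": 1.0e-5, "elasmobranch": 3.0e-6, "crustacean": 2.0e-5,
            "other": 1.2e-5}
    rows = []
    for i, sp in enumerate(species_pool):
        rows.append({
            "taxon": sp.name,
            "a": a_of.get(sp.group, 1.0e-5),
            "b": 3.0,
            "reference_length_mm": sp.length_median_mm,
            "family": f"family_{i % 8}",
            "is_family_level": False,
        })
    return pd.DataFrame(rows)


def synthetic_traits(species_pool) -> pd.DataFrame:
    return pd.DataFrame({"taxon": [sp.name for sp in species_pool],
                         "guild": [sp.guild for sp in species_pool],
                         "group": [sp.group for sp in species_pool]})


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r} requires missing input {path.name}; "
            f"was its producing stage enabled?")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order and return the run report.

    Every intermediate table is written to ``config.output_dir``; any stage
    error halts the run naming the stage. The report includes versions,
    seeds, per-stage row counts, warnings, headline statistics and a hash
    over the deterministic content.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "bruvkit_version": __version__,
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "headline": {},
    }
    enabled = [s for s in STAGE_ORDER if s in config.stages]
    seascape = None
    pool = None

    for stage in enabled:
        t0 = time.perf_counter()
        try:
            if stage == "seascape":
                seascape = synthetic.generate_seascape(
                    config.seed, config.extent, config.cell_size,
                    n_islands=config.n_islands)
                seascape.bathymetry.write_ascii(out / "bathymetry.asc")
                seascape.habitat.write_ascii(out / "habitat.asc")
                synthetic.write_islands_geojson(seascape.islands,
                                                out / "islands.geojson")
                report["stages"][stage] = {
                    "cells": int(np.prod(seascape.bathymetry.shape)),
                    "islands": len(seascape.islands)}

            elif stage == "design":
                if seascape is None:
                    raise PipelineError("design requires the seascape stage")
                frame = design.frame_from_rasters(
                    seascape.habitat, seascape.bathymetry,
                    {c: synthetic.HABITAT_OF[n]
                     for c, n in synthetic.SUBHABITAT_NAMES.items()})
                plan = design.grts_sample(frame, config.n_per_stratum,
                                          config.min_dist, config.depth_range,
                                          seed=config.seed)
                plan.to_csv(out / "plan.csv", index=False)
                report["stages"][stage] = {"sites": len(plan)}

            elif stage == "simulate":
                plan = pd.read_csv(_require(out / "plan.csv", stage))
                pool = synthetic.default_species_pool(config.n_species,
                                                      seed=config.seed)
                deployments = synthetic.build_deployment_table(
                    plan, seascape, seed=config.seed)
                ann, truth = synthetic.simulate_annotations(
                    deployments, pool, n_frames=config.n_frames,
                    seed=config.seed)
                deployments.to_csv(out / "deployments.csv", index=False)
                ann.to_csv(out / "annotations.csv", index=False)
                synthetic_traits(pool).to_csv(out / "traits.csv", index=False)
                synthetic_lw_registry(pool).to_csv(out / "lw.csv", index=False)
                truth["latent_maxn"].to_csv(out / "truth_maxn.csv")
                report["stages"][stage] = {"annotation_rows": len(ann),
                                           "deployments": len(deployments),
                                           "species": len(pool)}

            elif stage == "maxn":
                ann, rep = ingest.read_annotations(
                    _require(out / "annotations.csv", stage))
                deployments = ingest.read_deployments(
                    _require(out / "deployments.csv", stage))
                maxn, maxn_times = ingest.compute_maxn(
                    ann, deployments["deployment_id"])
                maxn.to_csv(out / "maxn.csv")
                maxn_times.to_csv(out / "maxn_times.csv", index=False)
                traits = pd.read_csv(_require(out / "traits.csv", stage))
                demersal = ingest.filter_demersal(maxn, traits)
                demersal.to_csv(out / "maxn_demersal.csv")
                report["warnings"].extend(rep.warnings)
                report["stages"][stage] = {"deployments": len(maxn),
                                           "taxa": maxn.shape[1],
                                           "dropped_rows": rep.n_dropped}
                report["headline"]["total_individuals"] = int(maxn.to_numpy().sum())
                report["headline"]["total_species"] = int((maxn.sum(0) > 0).sum())
                report["headline"]["demersal_individuals"] = int(
                    demersal.to_numpy().sum())

            elif stage == "indices":
                ann, _ = ingest.read_annotations(
                    _require(out / "annotations.csv", stage))
                deployments = ingest.read_deployments(out / "deployments.csv")
                maxn = pd.read_csv(out / "maxn.csv", index_col=0)
                demersal = pd.read_csv(_require(out / "maxn_demersal.csv", stage),
                                       index_col=0)
                registry = idx_mod.validate_lw_registry(
                    pd.read_csv(_require(out / "lw.csv", stage)))
                lengths = idx_mod.accepted_lengths(ann, deployments)
                tab = idx_mod.compute_indices(demersal, deployments,
                                              lengths=lengths, registry=registry,
                                              diversity_maxn=maxn)
                tab.to_csv(out / "indices.csv", index=False)
                summary = idx_mod.habitat_summary(tab, deployments)
                report["stages"][stage] = {"rows": len(tab)}
                report["headline"]["mean_richness"] = float(tab["richness"].mean())
                report["headline"]["richness_dispersion"] = float(
                    idx_mod.dispersion_index(tab["richness"]))
                report["headline"]["abundance_dispersion"] = float(
                    idx_mod.dispersion_index(tab["abundance"]))
                mw = summary["tests"]["richness"].get("mann_whitney")
                if mw:
                    report["headline"]["richness_mann_whitney_W"] = mw["W"]

            elif stage == "covariates":
                deployments = ingest.read_deployments(
                    _require(out / "deployments.csv", stage))
                bathy = read_ascii_grid(_require(out / "bathymetry.asc", stage))
                islands = _read_islands(out / "islands.geojson")
                cov = cov_mod.compute_covariates(deployments, bathy, islands,
                                                 config.buffer_radius)
                cov.to_csv(out / "covariates.csv", index=False)
                screened, screen_report = cov_mod.collinearity_screen(
                    cov.drop(columns=["deployment_id"]),
                    r_max=config.r_max, vif_max=config.vif_max, auto_drop=True)
                report["stages"][stage] = {
                    "rows": len(cov), "retained": screened,
                    "flagged": screen_report["flagged"],
                    "dropped": screen_report["dropped"]}

            elif stage == "spatial":
                deployments = ingest.read_deployments(
                    _require(out / "deployments.csv", stage))
                tab = pd.read_csv(_require(out / "indices.csv", stage))
                merged = tab.merge(deployments[["deployment_id", "x", "y"]],
                                   on="deployment_id")
                grid = spatial.hex_aggregate(
                    merged[["x", "y"]],
                    merged[["richness", "abundance", "shannon", "biomass_kg"]],
                    cell_area=config.hex_area)
                spatial.write_hexgrid_geojson(grid, out / "hexgrid.geojson")
                coords = merged[["x", "y"]].to_numpy()
                spatial.write_weights_triplets(
                    coords, merged["deployment_id"].tolist(),
                    config.k_neighbours, out / "weights.csv")
                report["stages"][stage] = {
                    "hex_cells": len(grid),
                    "occupied_cells": int((grid["n_deployments"] > 0).sum())}

            elif stage == "models":
                data = _model_data(out, stage, config)
                ranking_summary = {}
                for response in config.responses:
                    family, link = RESPONSE_FAMILIES.get(response,
                                                         ("gaussian", "identity"))
                    lag = spatial.knn_lag(data[["x", "y"]].to_numpy(),
                                          data[response].to_numpy(),
                                          k=config.k_neighbours)
                    dat = data.assign(spatial_lag=lag)
                    if family == "gamma":
                        dat = dat[dat[response] > 0]
                        # year effect configured off for biomass (outliers)
                        mandatory = ("spatial_lag",)
                    else:
                        mandatory = ("C(year)", "spatial_lag")
                    cfg = mod_mod.CandidateConfig(mandatory=mandatory)
                    specs = mod_mod.build_candidate_set(
                        ["depth_m", "sst_c", "relief", "exposure_deg",
                         "remoteness_m"], response, family, link, cfg)
                    fits, rank = mod_mod.fit_and_rank(specs, dat)
                    rank.to_csv(out / f"ranks_{response}.csv", index=False)
                    best = rank.iloc[0]
                    ranking_summary[response] = {
                        "best": best["terms"], "aicc": float(best["aicc"]),
                        "weight": float(best["weight"]),
                        "pseudo_r2": float(best["pseudo_r2"]),
                        "n_models": len(rank)}
                report["stages"][stage] = ranking_summary

            elif stage == "rarefaction":
                maxn = pd.read_csv(_require(out / "maxn.csv", stage), index_col=0)
                curve = rare_mod.rarefaction_curve(
                    maxn, t_max=config.rarefaction_t_max,
                    B=config.bootstrap_B, seed=config.seed, step=10)
                curve.to_csv(out / "rarefaction.csv", index=False)
                report["stages"][stage] = {"S_obs": curve.attrs["S_obs"],
                                           "asymptote": curve.attrs["asymptote"],
                                           "asymptote_ci": list(curve.attrs["asymptote_ci"])}
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        report["stages"].setdefault(stage, {})
        report["stages"][stage]["seconds"] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage,
                    report["stages"][stage]["seconds"])

    report["hash"] = _report_hash(report)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                default=str), encoding="utf-8")
    return report


def _model_data(out: Path, stage: str, config: RunConfig) -> pd.DataFrame:
    tab = pd.read_csv(_require(out / "indices.csv", stage))
    cov = pd.read_csv(_require(out / "covariates.csv", stage))
    deployments = ingest.read_deployments(_require(out / "deployments.csv", stage))
    data = (tab.merge(cov.drop(columns=["depth_m", "sst_c", "relief"]),
                      on="deployment_id")
            .merge(deployments[["deployment_id", "x", "y", "year", "habitat",
                                "depth_m", "sst_c", "relief"]],
                   on="deployment_id"))
    return data


def _read_islands(path: Path):
    fc = json.loads(Path(path).read_text(encoding="utf-8"))
    return [tuple(f["geometry"]["coordinates"]) for f in fc["features"]]


def _report_hash(report: dict) -> str:
    """Hash over the deterministic report content (timings excluded)."""
    def strip(obj):
        if isinstance(obj, dict):
            return {k: strip(v) for k, v in sorted(obj.items())
                    if k != "seconds"}
        if isinstance(obj, (list, tuple)):
            return [strip(v) for v in obj]
        return obj
    blob = json.dumps(strip(report), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()
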