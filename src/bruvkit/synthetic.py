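"""Synthetic archipelago seascape and observation-process simulator.

Builds a seeded artificial survey area (bathymetry, benthic habitat strata,
inhabited-island points) and simulates the full observation chain — camera
deployments producing frame-level detections with body lengths — while
recording the generating parameters so downstream estimators can be tested
for recovery against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._raster import Raster

__all__ = [
    "CIRCALITTORAL", "INFRALITTORAL", "SEAGRASS", "SEDIMENTS",
    "SUBHABITAT_CODES", "SUBHABITAT_NAMES", "HABITAT_OF",
    "HabitatRule", "SpeciesTruth", "SeascapeTruth", "Seascape",
    "stage_seed", "generate_seascape", "default_species_pool",
    "build_deployment_table", "simulate_annotations",
    "write_islands_geojson",
]

# Sub-habitat integer codes used in the habitat raster.
CIRCALITTORAL = 1
INFRALITTORAL = 2
SEAGRASS = 3
SEDIMENTS = 4

SUBHABITAT_NAMES = {
    CIRCALITTORAL: "circalittoral rock",
    INFRALITTORAL: "infralittoral rock",
    SEAGRASS: "subtidal seagrass",
    SEDIMENTS: "subtidal sediments",
}
SUBHABITAT_CODES = {v: k for k, v in SUBHABITAT_NAMES.items()}

HABITAT_OF = {
    "circalittoral rock": "Reefs",
    "infralittoral rock": "Reefs",
    "subtidal seagrass": "Sediments",
    "subtidal sediments": "Sediments",
}

# Fixed ordering of pipeline stages for seed splitting: one root seed expands
# into per-stage child seeds so each stage is independently reproducible.
_STAGES = ("seascape", "design", "annotations", "covariates", "models",
           "rarefaction", "misc")


def stage_seed(root_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic child seed for a named pipeline stage."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    return np.random.SeedSequence([int(root_seed), _STAGES.index(stage)])


@dataclass
class HabitatRule:
    """Thresholds mapping (depth, noise) to sub-habitat codes.

    Rock cells shallower than ``rock_depth_threshold`` are infralittoral,
    deeper ones circalittoral. Soft-bottom cells shallower than
    ``seagrass_depth_threshold`` with favourable noise become seagrass.
    """

    rock_depth_threshold: float = 15.0
    seagrass_depth_threshold: float = 8.0
    rock_noise_quantile: float = 0.55
    seagrass_noise_quantile: float = 0.6


@dataclass
class SpeciesTruth:
    """Generating parameters of one simulated taxon."""

    name: str
    guild: str  # "demersal" | "pelagic"
    group: str = "teleost"  # teleost | elasmobranch | crustacean | other
    affinity: dict = field(default_factory=dict)  # sub-habitat -> multiplier
    base_log_abundance: float = 0.0
    depth_slope: dict = field(default_factory=dict)  # habitat -> per-m slope
    nb_k: float = 1.0
    shoaling: bool = False
    shoal_weight: float = 0.0
    shoal_mean: float = 0.0
    length_median_mm: float = 300.0
    length_sigma: float = 0.25
    length_depth_slope: float = 0.0     # per m, on log-length scale
    length_remoteness_slope: float = 0.0  # per km
    length_exposure_slope: float = 0.0  # per degree
    detectability: float = 1.0

    def __post_init__(self):
        if self.nb_k <= 0:
            raise ValueError(f"{self.name}: overdispersion k must be > 0")
        if any(m < 0 for m in self.affinity.values()):
            raise ValueError(f"{self.name}: habitat affinities must be >= 0")
        if not 0.0 <= self.detectability <= 1.0:
            raise ValueError(f"{self.name}: detectability must be in [0, 1]")
        if self.guild not in ("demersal", "pelagic"):
            raise ValueError(f"{self.name}: guild must be demersal or pelagic")


@dataclass
class SeascapeTruth:
    """Full generating configuration of a synthetic seascape."""

    seed: int
    extent: tuple[float, float, float, float]  # x0, y0, x1, y1 (m)
    depth_amplitude: float = 40.0
    depth_length_scale: float = 1500.0
    habitat_rule: HabitatRule = field(default_factory=HabitatRule)
    species_pool: list[SpeciesTruth] = field(default_factory=list)


@dataclass
class Seascape:
    bathymetry: Raster   # depth in m, positive down
    habitat: Raster      # integer sub-habitat codes
    islands: list[tuple[float, float]]
    truth: SeascapeTruth


def generate_seascape(seed: int,
                      extent: tuple[float, float, float, float] = (0., 0., 10_000., 10_000.),
                      cell_size: float = 100.0,
                      depth_amplitude: float = 40.0,
                      depth_length_scale: float = 1500.0,
                      habitat_rule: HabitatRule | None = None,
                      n_islands: int = 5) -> Seascape:
    """Generate bathymetry, habitat and island layers for a fixed seed.

    The depth field is smoothed random-field noise plus a radial offshore
    gradient centred on the archipelago, clipped to [0, 60] m. Habitat is a
    threshold rule on depth and a second smoothed noise field. Deterministic
    for a fixed seed.
    """
    x0, y0, x1, y1 = extent
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate extent: max must exceed min on both axes")
    rule = habitat_rule or HabitatRule()
    nx = int(round((x1 - x0) / cell_size))
    ny = int(round((y1 - y0) / cell_size))
    if nx < 2 or ny < 2:
        raise ValueError("extent too small for the requested cell size")

    rng = np.random.default_rng(stage_seed(seed, "seascape"))
    xs = x0 + (np.arange(nx) + 0.5) * cell_size
    ys = y0 + (np.arange(ny) + 0.5) * cell_size
    X, Y = np.meshgrid(xs, ys)
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    half_diag = float(np.hypot(x1 - x0, y1 - y0)) / 2.0

    sigma = max(depth_length_scale / cell_size, 1.0)
    noise = gaussian_filter(rng.standard_normal((ny, nx)), sigma, mode="nearest")
    noise /= max(noise.std(), 1e-12)
    radial = np.hypot(X - cx, Y - cy) / half_diag
    depth = depth_amplitude * radial + 0.35 * depth_amplitude * noise
    depth = np.clip(depth, 0.0, 60.0)

    hab_noise = gaussian_filter(rng.standard_normal((ny, nx)), sigma * 0.5,
                                mode="nearest")
    rock = hab_noise > np.quantile(hab_noise, rule.rock_noise_quantile)
    habitat = np.full((ny, nx), SEDIMENTS, dtype=float)
    habitat[rock & (depth <= rule.rock_depth_threshold)] = INFRALITTORAL
    habitat[rock & (depth > rule.rock_depth_threshold)] = CIRCALITTORAL
    soft_shallow = (~rock) & (depth <= rule.seagrass_depth_threshold)
    sg_noise = hab_noise < np.quantile(hab_noise, 1 - rule.seagrass_noise_quantile)
    habitat[soft_shallow & sg_noise] = SEAGRASS

    # Island points: shallowest cells near the archipelago centre, spaced out.
    flat = np.argsort(depth, axis=None)
    islands: list[tuple[float, float]] = []
    min_spacing = 8 * cell_size
    for idx in flat:
        r, c = divmod(int(idx), nx)
        pt = (float(xs[c]), float(ys[r]))
        if all(np.hypot(pt[0] - p[0], pt[1] - p[1]) >= min_spacing for p in islands):
            islands.append(pt)
        if len(islands) >= n_islands:
            break
    if not islands:  # pragma: no cover - flat ordering always yields >= 1
        islands = [(cx, cy)]

    truth = SeascapeTruth(seed=seed, extent=extent,
                          depth_amplitude=depth_amplitude,
                          depth_length_scale=depth_length_scale,
                          habitat_rule=rule)
    bathy = Raster(depth, x0, y0, cell_size)
    hab = Raster(habitat, x0, y0, cell_size)
    return Seascape(bathymetry=bathy, habitat=hab, islands=islands, truth=truth)


def default_species_pool(n_species: int = 30, seed: int = 0) -> list[SpeciesTruth]:
    """A reproducible species pool spanning the structures the pipeline must
    handle: habitat-specific depth effects, overdispersion, a rare
    hyperabundant shoaler, and partially unmeasurable taxa."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 917]))
    pool: list[SpeciesTruth] = []
    subhabs = list(SUBHABITAT_CODES)
    groups = ["teleost"] * 6 + ["elasmobranch", "crustacean", "other"]
    for i in range(n_species):
        guild = "pelagic" if i % 7 == 6 else "demersal"
        affinity = {h: float(rng.lognormal(0.0, 0.5)) for h in subhabs}
        if guild == "pelagic":
            affinity = {h: 1.0 for h in subhabs}
        slope = float(rng.normal(0.03, 0.015))
        depth_slope = {"Reefs": slope,
                       "Sediments": slope * float(rng.uniform(0.5, 1.5))}
        shoaling = i == 0
        pool.append(SpeciesTruth(
            name=f"species_{i:02d}",
            guild=guild,
            group=groups[i % len(groups)],
            affinity=affinity,
            base_log_abundance=float(rng.normal(-1.2, 0.8)),
            depth_slope=depth_slope,
            nb_k=float(rng.uniform(0.5, 3.0)),
            shoaling=shoaling,
            shoal_weight=0.1 if shoaling else 0.0,
            shoal_mean=60.0 if shoaling else 0.0,
            length_median_mm=float(rng.uniform(100, 700)),
            length_sigma=float(rng.uniform(0.15, 0.35)),
            length_depth_slope=float(rng.normal(0.004, 0.002)),
            length_remoteness_slope=float(rng.normal(0.02, 0.01)),
            length_exposure_slope=float(rng.normal(-0.0005, 0.0003)),
            detectability=float(rng.uniform(0.4, 1.0)) if i % 5 else 0.8,
        ))
    return pool


def build_deployment_table(plan: pd.DataFrame, seascape: Seascape,
                           seed: int, mono_fraction: float = 0.14) -> pd.DataFrame:
    """Attach environmental metadata to a deployment plan.

    Expects ``plan`` with columns site_id, x, y (and optionally depth_m);
    returns the deployment metadata table consumed by the ingest stage.
    """
    rng = np.random.default_rng(stage_seed(seed, "covariates"))
    n = len(plan)
    x = plan["x"].to_numpy(float)
    y = plan["y"].to_numpy(float)
    depth = (plan["depth_m"].to_numpy(float) if "depth_m" in plan
             else seascape.bathymetry.value_at(x, y))
    code = seascape.habitat.value_at(x, y).astype(int)
    subhab = np.array([SUBHABITAT_NAMES[c] for c in code])
    habitat = np.array([HABITAT_OF[s] for s in subhab])
    isl = np.asarray(seascape.islands, float)
    remoteness = np.min(np.hypot(x[:, None] - isl[None, :, 0],
                                 y[:, None] - isl[None, :, 1]), axis=1)
    relief = np.where(habitat == "Reefs",
                      rng.integers(2, 6, n), rng.integers(0, 3, n))
    out = pd.DataFrame({
        "deployment_id": plan["site_id"].astype(str).to_numpy(),
        "x": x, "y": y,
        "year": np.where(np.arange(n) % 2 == 0, 2022, 2023),
        "gear": np.where(rng.random(n) < mono_fraction, "mono", "stereo"),
        "depth_m": depth,
        "sst_c": np.round(14.0 + 0.08 * (y - y.mean()) / 1000.0
                          + rng.normal(0, 0.4, n), 2),
        "relief": relief,
        "habitat": habitat,
        "subhabitat": subhab,
        "remoteness_m": remoteness,
    })
    return out


def simulate_annotations(deployments: pd.DataFrame,
                         species_pool: list[SpeciesTruth],
                         n_frames: int = 100,
                         seed: int = 0,
                         window_s: float = 3600.0):
    """Simulate frame-level annotations for every deployment x species.

    For each pair a latent true MaxN is drawn from a log-linear negative
    binomial model (habitat affinity + habitat-specific depth slope, with an
    optional hyperabundant shoaling mixture). Frame counts are thinned from
    the latent MaxN with one frame forced to the maximum, so the MaxN
    statistic is exact by construction. Individual body lengths at the MaxN
    frame are lognormal with depth/remoteness/exposure effects; each is
    flagged measurable with the species' detectability (never measurable on
    mono gear).

    Returns ``(annotations, truth)`` where ``truth`` carries the latent MaxN
    matrix, per-species simulated mean lengths, and generator coefficients.
    """
    if not species_pool:
        raise ValueError("species pool is empty")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(stage_seed(seed, "annotations"))
    frame_times = np.round(np.linspace(0, window_s, n_frames, endpoint=False), 1)

    dep_ids = deployments["deployment_id"].astype(str).to_numpy()
    depth = deployments["depth_m"].to_numpy(float)
    subhab = deployments["subhabitat"].to_numpy()
    habitat = deployments["habitat"].to_numpy() if "habitat" in deployments else \
        np.array([HABITAT_OF[s] for s in subhab])
    remote_km = (deployments["remoteness_m"].to_numpy(float) / 1000.0
                 if "remoteness_m" in deployments else np.zeros(len(deployments)))
    exposure = (deployments["exposure_deg"].to_numpy(float)
                if "exposure_deg" in deployments else np.zeros(len(deployments)))
    gear = (deployments["gear"].to_numpy() if "gear" in deployments
            else np.full(len(deployments), "stereo"))

    rows = []
    latent = np.zeros((len(deployments), len(species_pool)), dtype=int)
    length_sums: dict[str, list[float]] = {sp.name: [] for sp in species_pool}
    for j, sp in enumerate(species_pool):
        aff = np.array([sp.affinity.get(s, 1.0) for s in subhab])
        slope = np.array([sp.depth_slope.get(h, 0.0) if isinstance(sp.depth_slope, dict)
                          else sp.depth_slope for h in habitat])
        with np.errstate(divide="ignore"):
            log_mu = sp.base_log_abundance + np.log(aff) + slope * depth
        mu = np.exp(log_mu)
        p = sp.nb_k / (sp.nb_k + mu)
        m = np.where(mu > 0, rng.negative_binomial(sp.nb_k, np.clip(p, 1e-12, 1.0)), 0)
        if sp.shoaling and sp.shoal_weight > 0:
            shoal = rng.random(len(m)) < sp.shoal_weight
            m = m + shoal * rng.poisson(sp.shoal_mean, len(m))
        latent[:, j] = m
        for i in np.nonzero(m)[0]:
            mi = int(m[i])
            counts = rng.binomial(mi, 0.5, n_frames)
            kmax = int(rng.integers(n_frames))
            counts[kmax] = mi
            mean_log = (np.log(sp.length_median_mm)
                        + sp.length_depth_slope * depth[i]
                        + sp.length_remoteness_slope * remote_km[i]
                        + sp.length_exposure_slope * exposure[i])
            lengths = np.exp(rng.normal(mean_log, sp.length_sigma, mi))
            length_sums[sp.name].extend(lengths.tolist())
            measurable = rng.random(mi) < sp.detectability
            if gear[i] == "mono":
                measurable[:] = False
            for k in range(n_frames):
                c = int(counts[k])
                if c == 0:
                    continue
                if k == kmax:
                    for ell, ok in zip(lengths, measurable):
                        rows.append((dep_ids[i], frame_times[k], sp.name, 1,
                                     round(float(ell), 1) if ok else np.nan,
                                     int(ok)))
                else:
                    rows.append((dep_ids[i], frame_times[k], sp.name, c,
                                 np.nan, 0))

    annotations = pd.DataFrame(
        rows, columns=["deployment_id", "time_s", "taxon", "count",
                       "length_mm", "measurable"],
    ).sort_values(["deployment_id", "time_s", "taxon"], kind="stable",
                  ignore_index=True)
    truth = {
        "latent_maxn": pd.DataFrame(latent, index=pd.Index(dep_ids, name="deployment_id"),
                                    columns=[sp.name for sp in species_pool]),
        "mean_length": {k: (float(np.mean(v)) if v else np.nan)
                        for k, v in length_sums.items()},
        "species_pool": species_pool,
    }
    return annotations, truth


def write_islands_geojson(islands, path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"island_id": i, "inhabited": True},
             "geometry": {"type": "Point", "coordinates": [float(x), float(y)]}}
            for i, (x, y) in enumerate(islands)
        ],
    }
    Path(path).write_text(json.dumps(fc, indent=1), encoding="utf-8")
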