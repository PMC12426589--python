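"""Per-deployment ecological indices.

Richness, relative abundance (summed MaxN), Shannon diversity (natural
log), variance-to-mean dispersion, and total biomass via length-weight
power-law conversion with a tiered proxy-length cascade for taxa without an
accepted measurement in the deployment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["PROXY_TIERS", "ProxyResolution", "validate_lw_registry",
           "richness", "shannon", "dispersion_index",
           "dispersion_from_moments", "accepted_lengths",
           "resolve_length", "biomass", "compute_indices", "habitat_summary",
           "dunn_test"]

PROXY_TIERS = ("measured-in-sample", "subhabitat-mean", "study-mean",
               "reference", "family-mean")


@dataclass
class ProxyResolution:
    """Provenance of the mean length used for one taxon in one deployment."""

    taxon: str
    deployment_id: str
    length_mm: float
    tier: str


def validate_lw_registry(registry: pd.DataFrame) -> pd.DataFrame:
    """Check a length-weight parameter registry.

    Required columns: taxon, a (g per mm^b), b; optional
    reference_length_mm, family, is_family_level.
    """
    for col in ("taxon", "a", "b"):
        if col not in registry.columns:
            raise ValueError(f"length-weight registry missing column {col!r}")
    if (registry["a"] <= 0).any():
        raise ValueError("length-weight parameter a must be positive")
    if ((registry["b"] <= 1) | (registry["b"] >= 5)).any():
        raise ValueError("length-weight exponent b must lie in (1, 5)")
    reg = registry.copy()
    if "reference_length_mm" not in reg.columns:
        reg["reference_length_mm"] = np.nan
    if "family" not in reg.columns:
        reg["family"] = reg["taxon"]
    if "is_family_level" not in reg.columns:
        reg["is_family_level"] = False
    return reg.set_index("taxon")


def richness(maxn_row: pd.Series | np.ndarray) -> int:
    """Number of taxa present (MaxN >= 1)."""
    return int(np.sum(np.asarray(maxn_row) >= 1))


def shannon(maxn_row: pd.Series | np.ndarray) -> float:
    """Shannon diversity H' in nats; NaN (with a warning) for all-zero rows."""
    v = np.asarray(maxn_row, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        logger.warning("Shannon index undefined for an all-zero row")
        return float("nan")
    p = v / v.sum()
    return float(-(p * np.log(p)).sum())


def dispersion_index(values) -> float:
    """Sample variance divided by sample mean; NaN when the mean is zero."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        logger.warning("dispersion index undefined: zero mean")
        return float("nan")
    return float(v.var(ddof=1) / m)


def dispersion_from_moments(mean: float, variance: float) -> float:
    """Dispersion index from summary moments (variance / mean), for checking
    reported values when only the moments are available."""
    if mean == 0:
        return float("nan")
    return variance / mean


def accepted_lengths(annotations: pd.DataFrame,
                     deployments: pd.DataFrame) -> pd.DataFrame:
    """Extract accepted length measurements at (or near) the MaxN frame.

    For each deployment x taxon, measurements are taken from the earliest
    frame whose total count is largest among frames carrying at least one
    measurable individual — the fallback to the next-highest-MaxN frame when
    nothing was measurable at the true MaxN frame.

    Returns long rows: deployment_id, taxon, subhabitat, length_mm.
    """
    meas = annotations[(annotations["measurable"] == 1)
                       & annotations["length_mm"].notna()]
    if meas.empty:
        return pd.DataFrame(columns=["deployment_id", "taxon", "subhabitat",
                                     "length_mm"])
    frame_totals = (annotations.groupby(["deployment_id", "taxon", "time_s"])
                    ["count"].sum().rename("frame_count"))
    meas = meas.join(frame_totals, on=["deployment_id", "taxon", "time_s"])
    best = (meas.sort_values(["frame_count", "time_s"],
                             ascending=[False, True], kind="stable")
            .groupby(["deployment_id", "taxon"], sort=False)["time_s"]
            .first().rename("best_time"))
    meas = meas.join(best, on=["deployment_id", "taxon"])
    meas = meas[meas["time_s"] == meas["best_time"]]
    sub = deployments.set_index("deployment_id")["subhabitat"]
    out = meas[["deployment_id", "taxon", "length_mm"]].copy()
    out["subhabitat"] = out["deployment_id"].map(sub)
    return out.reset_index(drop=True)[["deployment_id", "taxon", "subhabitat",
                                       "length_mm"]]


def resolve_length(taxon: str, deployment_id: str, lengths: pd.DataFrame,
                   subhabitat: str, registry: pd.DataFrame,
                   allow_in_sample: bool = True) -> ProxyResolution:
    """Resolve the mean length for one taxon in one deployment.

    First applicable rule wins: (0) mean of the taxon's accepted
    measurements in this deployment (skipped on mono gear via
    ``allow_in_sample=False``); (1) pooled mean over the same sub-habitat in
    the whole study; (2) study-wide species mean; (3) registry reference
    length. Family-level taxa resolve to the study-level family mean before
    falling back to the registry.
    """
    if taxon not in registry.index:
        raise KeyError(f"taxon {taxon!r} has no length-weight registry entry")
    entry = registry.loc[taxon]
    mine = lengths[lengths["taxon"] == taxon]

    if bool(entry["is_family_level"]):
        fam = entry["family"]
        members = registry.index[registry["family"] == fam]
        fam_lengths = lengths[lengths["taxon"].isin(members)]
        if len(fam_lengths):
            return ProxyResolution(taxon, deployment_id,
                                   float(fam_lengths["length_mm"].mean()),
                                   "family-mean")
    else:
        if allow_in_sample:
            own = mine[mine["deployment_id"] == deployment_id]
            if len(own):
                return ProxyResolution(taxon, deployment_id,
                                       float(own["length_mm"].mean()),
                                       "measured-in-sample")
        same_hab = mine[mine["subhabitat"] == subhabitat]
        if len(same_hab):
            return ProxyResolution(taxon, deployment_id,
                                   float(same_hab["length_mm"].mean()),
                                   "subhabitat-mean")
        if len(mine):
            return ProxyResolution(taxon, deployment_id,
                                   float(mine["length_mm"].mean()),
                                   "study-mean")
    ref = entry["reference_length_mm"]
    if pd.notna(ref):
        return ProxyResolution(taxon, deployment_id, float(ref), "reference")
    raise KeyError(f"no length rule applies for taxon {taxon!r} "
                   f"(never measured and no reference length)")


def biomass(maxn_row: pd.Series, resolutions: dict[str, ProxyResolution],
            registry: pd.DataFrame) -> float:
    """Total biomass (kg) of one deployment: sum of a * L^b * MaxN over taxa.

    Weight per individual is the power law a * L^b in grams with L the
    resolved mean length in mm.
    """
    total_g = 0.0
    missing = [t for t, n in maxn_row.items() if n > 0
               and (t not in resolutions or t not in registry.index)]
    if missing:
        raise KeyError(f"missing length resolution or LW entry for: {missing}")
    for taxon, n in maxn_row.items():
        if n <= 0:
            continue
        entry = registry.loc[taxon]
        L = resolutions[taxon].length_mm
        total_g += float(entry["a"]) * L ** float(entry["b"]) * float(n)
    return total_g / 1000.0


def compute_indices(maxn: pd.DataFrame, deployments: pd.DataFrame,
                    lengths: pd.DataFrame | None = None,
                    registry: pd.DataFrame | None = None,
                    diversity_maxn: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-deployment index table.

    Richness, relative abundance and biomass are computed on ``maxn``
    (typically the demersal subset); Shannon diversity on
    ``diversity_maxn`` when given (typically all species) else on ``maxn``.
    Biomass requires ``lengths`` (accepted measurements) and ``registry``;
    proxy tier usage is tallied per deployment.
    """
    div_tbl = maxn if diversity_maxn is None else diversity_maxn
    meta = deployments.set_index("deployment_id")
    rows = []
    for dep_id, row in maxn.iterrows():
        rec = {
            "deployment_id": dep_id,
            "richness": richness(row),
            "abundance": int(row.sum()),
            "shannon": (shannon(div_tbl.loc[dep_id])
                        if dep_id in div_tbl.index else np.nan),
        }
        if lengths is not None and registry is not None:
            subhab = meta.loc[dep_id, "subhabitat"]
            gear = meta.loc[dep_id, "gear"] if "gear" in meta.columns else "stereo"
            resolutions = {}
            tiers = dict.fromkeys(PROXY_TIERS, 0)
            for taxon in row.index[row > 0]:
                res = resolve_length(taxon, dep_id, lengths, subhab, registry,
                                     allow_in_sample=(gear != "mono"))
                resolutions[taxon] = res
                tiers[res.tier] += 1
            rec["biomass_kg"] = biomass(row, resolutions, registry)
            for tier in PROXY_TIERS:
                rec[f"tier_{tier.replace('-', '_')}"] = tiers[tier]
        rows.append(rec)
    return pd.DataFrame(rows)


def habitat_summary(index_table: pd.DataFrame, deployments: pd.DataFrame,
                    index_cols: tuple[str, ...] = ("richness", "abundance",
                                                   "biomass_kg")) -> dict:
    """Grouped mean +- SD per habitat and sub-habitat with rank tests.

    Returns a dict with 'habitat_means', 'subhabitat_means' tables and per
    index a Mann-Whitney contrast of the two main habitats, a
    Kruskal-Wallis across sub-habitats, and Dunn pairwise comparisons with
    Bonferroni adjustment. Contrasts with a group of fewer than two
    deployments are reported missing.
    """
    df = index_table.merge(deployments[["deployment_id", "habitat",
                                        "subhabitat"]], on="deployment_id")
    index_cols = [c for c in index_cols if c in df.columns]
    out: dict = {
        "habitat_means": df.groupby("habitat")[index_cols].agg(["mean", "std"]),
        "subhabitat_means": df.groupby("subhabitat")[index_cols].agg(["mean", "std"]),
        "tests": {},
    }
    habs = sorted(df["habitat"].unique())
    for col in index_cols:
        tests = {}
        if len(habs) == 2:
            a = df.loc[df["habitat"] == habs[0], col].dropna()
            b = df.loc[df["habitat"] == habs[1], col].dropna()
            if len(a) >= 2 and len(b) >= 2:
                mw = stats.mannwhitneyu(a, b, alternative="two-sided")
                tests["mann_whitney"] = {"W": float(mw.statistic),
                                         "p": float(mw.pvalue),
                                         "groups": habs}
            else:
                tests["mann_whitney"] = None
        groups = [g[col].dropna().to_numpy()
                  for _, g in df.groupby("subhabitat")]
        labels = [k for k, _ in df.groupby("subhabitat")]
        if all(len(g) >= 2 for g in groups) and len(groups) >= 2:
            kw = stats.kruskal(*groups)
            tests["kruskal_wallis"] = {"H": float(kw.statistic),
                                       "p": float(kw.pvalue)}
            tests["dunn"] = dunn_test(groups, labels)
        else:
            tests["kruskal_wallis"] = None
            tests["dunn"] = None
        out["tests"][col] = tests
    return out


def dunn_test(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's post hoc pairwise z tests on mean ranks, Bonferroni adjusted.

    Uses the tie-corrected large-sample z statistic; p-values are two-sided
    and multiplied by the number of pairs (capped at 1).
    """
    all_vals = np.concatenate(groups)
    N = len(all_vals)
    ranks = stats.rankdata(all_vals)
    split = np.cumsum([len(g) for g in groups])[:-1]
    group_ranks = np.split(ranks, split)
    mean_ranks = [r.mean() for r in group_ranks]
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_corr = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (N - 1))
    pairs = list(itertools.combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        ni, nj = len(groups[i]), len(groups[j])
        se = np.sqrt((N * (N + 1) / 12.0 - tie_corr) * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z,
                     "p_adj": min(p * len(pairs), 1.0) if np.isfinite(p) else np.nan})
    return pd.DataFrame(rows)
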