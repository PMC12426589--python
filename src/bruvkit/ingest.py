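"""Reading and validating frame-level annotation tables; MaxN computation.

The annotation dialect mirrors a video-annotation software export: one row
per frame-level observation with columns deployment_id, time_s, taxon,
count, length_mm (blank allowed) and measurable (0/1). Deployment metadata
carries location, environment and habitat labels.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ANNOTATION_COLUMNS", "DEPLOYMENT_COLUMNS", "IngestReport",
           "read_annotations", "read_deployments", "compute_maxn",
           "filter_demersal", "maxn_long"]

ANNOTATION_COLUMNS = ["deployment_id", "time_s", "taxon", "count",
                      "length_mm", "measurable"]
DEPLOYMENT_COLUMNS = ["deployment_id", "x", "y", "year", "gear", "depth_m",
                      "sst_c", "relief", "habitat", "subhabitat"]

#: Records past the standardized analysis window are dropped on ingest.
MAX_TIME_S = 3600.0


@dataclass
class IngestReport:
    n_rows: int = 0
    n_dropped: int = 0
    warnings: list[str] = field(default_factory=list)
    unmatched_taxa: list[str] = field(default_factory=list)


def _normalize_taxon(name: str) -> str:
    return re.sub(r"\s+", " ", str(name).strip()).lower()


def read_annotations(path: str | Path,
                     vocabulary: list[str] | None = None,
                     synonyms: dict[str, str] | None = None
                     ) -> tuple[pd.DataFrame, IngestReport]:
    """Read and validate an annotation table.

    Rows violating invariants (time outside [0, 3600] s, count < 1,
    non-positive length) are dropped with row-numbered diagnostics in the
    returned report. Taxon names are case/space-folded and mapped through
    the synonym table; names absent from ``vocabulary`` (when given) pass
    through flagged as unmatched.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file missing required columns: {missing}")
    report = IngestReport(n_rows=len(df))

    df["taxon"] = df["taxon"].map(_normalize_taxon)
    if synonyms:
        syn = {_normalize_taxon(k): _normalize_taxon(v)
               for k, v in synonyms.items()}
        df["taxon"] = df["taxon"].map(lambda t: syn.get(t, t))
    df["unmatched"] = False
    if vocabulary is not None:
        vocab = {_normalize_taxon(v) for v in vocabulary}
        unmatched = ~df["taxon"].isin(vocab)
        if unmatched.any():
            names = sorted(df.loc[unmatched, "taxon"].unique())
            report.unmatched_taxa = names
            msg = f"unknown taxa passed through flagged unmatched: {names}"
            report.warnings.append(msg)
            logger.warning(msg)
            df.loc[unmatched, "unmatched"] = True

    df["time_s"] = pd.to_numeric(df["time_s"], errors="coerce")
    df["count"] = pd.to_numeric(df["count"], errors="coerce")
    df["length_mm"] = pd.to_numeric(df["length_mm"], errors="coerce")
    df["measurable"] = pd.to_numeric(df["measurable"], errors="coerce").fillna(0).astype(int)

    bad_time = df["time_s"].isna() | (df["time_s"] < 0) | (df["time_s"] > MAX_TIME_S)
    bad_count = df["count"].isna() | (df["count"] < 1)
    bad_len = df["length_mm"].notna() & (df["length_mm"] <= 0)
    bad = bad_time | bad_count | bad_len
    for idx in df.index[bad]:
        reason = ("time outside [0, 3600] s" if bad_time[idx]
                  else "count < 1" if bad_count[idx] else "non-positive length")
        msg = f"row {idx + 2}: dropped ({reason})"  # +2: header + 1-based
        report.warnings.append(msg)
        logger.warning(msg)
    report.n_dropped = int(bad.sum())
    df = df[~bad].reset_index(drop=True)
    df["count"] = df["count"].astype(int)
    df["deployment_id"] = df["deployment_id"].astype(str)
    return df, report


def read_deployments(path: str | Path) -> pd.DataFrame:
    """Read deployment metadata, validating relief and habitat labels."""
    df = pd.read_csv(path)
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"deployment file missing required columns: {missing}")
    df["deployment_id"] = df["deployment_id"].astype(str)
    relief = pd.to_numeric(df["relief"], errors="coerce")
    if not relief.isin(range(6)).all():
        raise ValueError("relief scores must be integers in 0..5")
    if not df["habitat"].isin(["Reefs", "Sediments"]).all():
        raise ValueError("habitat must be 'Reefs' or 'Sediments'")
    return df


def compute_maxn(annotations: pd.DataFrame,
                 deployments: pd.Series | list | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per deployment x taxon MaxN and the frame time at which it occurred.

    MaxN is the maximum over frames of the summed count at that frame — the
    standard single-frame maximum that avoids double counting individuals
    seen across consecutive frames. Ties resolve to the earliest frame.

    Returns ``(maxn, maxn_times)``: a wide deployment x taxon integer table
    (absent taxa are 0) and a long table with the MaxN frame time per
    observed pair.
    """
    per_frame = (annotations.groupby(["deployment_id", "taxon", "time_s"],
                                     sort=True)["count"].sum().reset_index())
    idx = (per_frame.sort_values(["deployment_id", "taxon", "count", "time_s"],
                                 ascending=[True, True, False, True],
                                 kind="stable")
           .groupby(["deployment_id", "taxon"], sort=True).head(1))
    maxn_times = idx.rename(columns={"count": "maxn", "time_s": "maxn_time_s"})
    maxn = (maxn_times.pivot(index="deployment_id", columns="taxon",
                             values="maxn").fillna(0).astype(int))
    if deployments is not None:
        all_ids = pd.Index([str(d) for d in deployments], name="deployment_id")
        maxn = maxn.reindex(all_ids, fill_value=0)
    maxn.columns.name = "taxon"
    return maxn, maxn_times[["deployment_id", "taxon", "maxn", "maxn_time_s"]]


def maxn_long(maxn: pd.DataFrame) -> pd.DataFrame:
    """Wide MaxN table to long (deployment_id, taxon, maxn) rows, zeros kept."""
    return (maxn.stack().rename("maxn").reset_index())


def filter_demersal(maxn: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Subset a MaxN table to demersal/benthic-associated taxa.

    ``traits`` needs columns taxon and guild ('demersal' | 'pelagic').
    Reef/seabed-associated taxa that shoal are retained or dropped purely by
    their trait entry — nothing is hard-coded by name. Missing trait entries
    raise, listing the offending taxa.
    """
    traits = traits.copy()
    traits["taxon"] = traits["taxon"].map(_normalize_taxon)
    guild = traits.set_index("taxon")["guild"]
    missing = [t for t in maxn.columns if t not in guild.index]
    if missing:
        raise ValueError(f"no trait entry for taxa: {sorted(missing)}")
    keep = [t for t in maxn.columns if guild[t] == "demersal"]
    return maxn[keep]
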