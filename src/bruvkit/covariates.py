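"""Per-deployment environmental predictors from rasters and vector layers.

Terrain statistics (Horn 3x3 slope/aspect, depth-range ruggedness) within a
bounding buffer, exposure as angular distance from due west, remoteness as
minimum distance to an inhabited island, and a Pearson + VIF collinearity
screen.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._raster import Raster

logger = logging.getLogger(__name__)

__all__ = ["horn_slope_aspect", "terrain_stats", "exposure", "remoteness",
           "compute_covariates", "collinearity_screen"]


def horn_slope_aspect(raster: Raster) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell slope (deg) and downslope aspect (deg clockwise from north)
    using Horn's 3x3 finite-difference operators; edges use replicated
    padding. Flat cells get NaN aspect."""
    z = np.pad(raster.data, 1, mode="edge")
    c = raster.cell_size
    # neighbours: rows increase northward (row 0 = south edge)
    nw, n_, ne = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * c)
    dzdy = ((ne + 2 * n_ + nw) - (se + 2 * s_ + sw)) / (8.0 * c)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    with np.errstate(invalid="ignore"):
        aspect = (90.0 - np.degrees(np.arctan2(dzdy, -dzdx))) % 360.0
    aspect = np.where(slope > 0, aspect, np.nan)
    return slope, aspect


def terrain_stats(raster: Raster, point: tuple[float, float],
                  buffer_radius: float) -> tuple[float, float, float]:
    """(mean slope deg, ruggedness m, circular mean aspect deg) over cells
    whose centers fall within ``buffer_radius`` of ``point``.

    Ruggedness is the max-minus-min cell value within the buffer. Aspect is
    aggregated by circular (vector) mean and is NaN for flat buffers.
    """
    xs, ys = raster.cell_centers()
    X, Y = np.meshgrid(xs, ys)
    px, py = point
    inside = np.hypot(X - px, Y - py) <= buffer_radius
    if inside.sum() < 4:
        raise ValueError("buffer intersects fewer than 4 raster cells")
    slope, aspect = horn_slope_aspect(raster)
    slope_mean = float(slope[inside].mean())
    vals = raster.data[inside]
    ruggedness = float(vals.max() - vals.min())
    asp = aspect[inside]
    asp = asp[np.isfinite(asp)]
    if asp.size == 0:
        logger.warning("flat buffer at %s: aspect undefined", point)
        mean_aspect = float("nan")
    else:
        rad = np.radians(asp)
        mean_aspect = float(np.degrees(
            np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0)
    return slope_mean, ruggedness, mean_aspect


def exposure(mean_aspect: float) -> float:
    """Degrees from due west (270): circular absolute difference in [0, 180].

    0 = facing due west (most exposed to the prevailing westerlies),
    180 = facing due east. NaN aspect propagates to missing exposure.
    """
    if not np.isfinite(mean_aspect):
        return float("nan")
    d = abs(mean_aspect % 360.0 - 270.0)
    return float(min(d, 360.0 - d))


def remoteness(point: tuple[float, float], islands) -> float:
    """Minimum Euclidean distance (m) from ``point`` to any island geometry.

    Islands may be (x, y) tuples or shapely geometries (distance is then to
    the geometry boundary/point)."""
    if islands is None or len(islands) == 0:
        raise ValueError("island layer is empty")
    px, py = point
    dists = []
    for isl in islands:
        if hasattr(isl, "distance"):  # shapely geometry
            from shapely.geometry import Point
            dists.append(isl.distance(Point(px, py)))
        else:
            ix, iy = isl
            dists.append(float(np.hypot(px - ix, py - iy)))
    return float(min(dists))


def compute_covariates(deployments: pd.DataFrame, bathymetry: Raster,
                       islands, buffer_radius: float = 200.0) -> pd.DataFrame:
    """Covariate table: in-situ fields carried over from metadata plus
    terrain-derived exposure, remoteness, slope and ruggedness."""
    rows = []
    for _, d in deployments.iterrows():
        pt = (float(d["x"]), float(d["y"]))
        slope_mean, rugged, mean_aspect = terrain_stats(bathymetry, pt,
                                                        buffer_radius)
        rows.append({
            "deployment_id": d["deployment_id"],
            "depth_m": d.get("depth_m", np.nan),
            "sst_c": d.get("sst_c", np.nan),
            "relief": d.get("relief", np.nan),
            "exposure_deg": exposure(mean_aspect),
            "remoteness_m": remoteness(pt, islands),
            "slope_mean_deg": slope_mean,
            "ruggedness_m": rugged,
        })
    return pd.DataFrame(rows)


def collinearity_screen(table: pd.DataFrame, r_max: float = 0.55,
                        vif_max: float = 5.0, auto_drop: bool = False):
    """Pairwise Pearson r and per-variable VIF screen.

    VIF is 1/(1-R^2) from regressing each variable on all the others
    (complete cases); a perfectly collinear variable reports infinite VIF.
    Flagging is advisory; with ``auto_drop`` the flagged variable with the
    highest VIF is removed iteratively until all pass both thresholds.

    Returns ``(retained_columns, report)`` where the report carries the
    correlation matrix, VIF series, flags and any drops.
    """
    num = table.select_dtypes(include=[np.number])
    corr = num.corr(method="pearson")  # pairwise complete cases
    dropped: list[str] = []
    cols = list(num.columns)

    def _vifs(columns):
        cc = num[columns].dropna()
        out = {}
        X = cc.to_numpy(float)
        X = X - X.mean(axis=0)
        for i, col in enumerate(columns):
            yv = X[:, i]
            others = np.delete(X, i, axis=1)
            if others.shape[1] == 0 or np.allclose(yv, 0):
                out[col] = 1.0
                continue
            beta, *_ = np.linalg.lstsq(others, yv, rcond=None)
            resid = yv - others @ beta
            sst = float((yv ** 2).sum())
            r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 0.0
            out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    def _flags(columns, vifs):
        flagged = set()
        sub = corr.loc[columns, columns]
        for i, a in enumerate(columns):
            for b in columns[i + 1:]:
                if abs(sub.loc[a, b]) > r_max:
                    flagged.update((a, b))
        flagged.update(vifs.index[vifs > vif_max])
        return flagged

    vifs = _vifs(cols)
    flagged = _flags(cols, vifs)
    if auto_drop:
        while flagged:
            worst = vifs.loc[sorted(flagged)].idxmax()
            cols.remove(worst)
            dropped.append(worst)
            if len(cols) < 2:
                break
            vifs = _vifs(cols)
            flagged = _flags(cols, vifs)
    report = {
        "correlation": corr,
        "vif": _vifs(list(num.columns)),
        "flagged": sorted(_flags(list(num.columns), _vifs(list(num.columns)))),
        "dropped": dropped,
        "n_complete_cases": int(len(num.dropna())),
    }
    return cols, report
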