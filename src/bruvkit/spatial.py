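"""Hexagonal aggregation, k-nearest-neighbour spatial lag, and Moran's I.

The spatially lagged predictor is the equally weighted mean of the response
at each site's k nearest neighbours (k=4 default); Moran's I significance
comes from a seeded permutation test.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["hex_aggregate", "hex_polygon", "knn_neighbours", "knn_lag",
           "knn_weight_matrix", "morans_i", "write_hexgrid_geojson",
           "write_weights_triplets"]

_SQRT3 = math.sqrt(3.0)


def _hex_side(cell_area: float) -> float:
    # regular hexagon area = (3*sqrt(3)/2) * s^2
    return math.sqrt(2.0 * cell_area / (3.0 * _SQRT3))


def _axial_of_points(x, y, s):
    """Fractional flat-top axial coordinates, cube-rounded to cell indices."""
    qf = (2.0 / 3.0) * x / s
    rf = (-1.0 / 3.0 * x + _SQRT3 / 3.0 * y) / s
    # cube rounding
    xf, zf = qf, rf
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


def _hex_center(q, r, s):
    return 1.5 * s * q, _SQRT3 * s * (0.5 * q + r)


def hex_polygon(q: int, r: int, s: float, origin=(0.0, 0.0)):
    """Vertex ring of a flat-top hexagon cell (closed, 7 points)."""
    cx, cy = _hex_center(q, r, s)
    cx += origin[0]
    cy += origin[1]
    ang = np.radians(np.arange(0, 361, 60))
    return [(cx + s * math.cos(a), cy + s * math.sin(a)) for a in ang]


def hex_aggregate(points: pd.DataFrame, values: pd.DataFrame,
                  cell_area: float = 1_000_000.0,
                  origin: tuple[float, float] | None = None) -> pd.DataFrame:
    """Aggregate point values onto a flat-top hexagon tessellation.

    ``points`` needs x, y columns aligned row-wise with ``values``. Each
    point maps to exactly one cell; per-cell unweighted means of every value
    column are returned. Cells of the tessellation covering the point
    bounding box that contain no points carry NaN means. The grid origin is
    the extent minimum unless given.
    """
    s = _hex_side(cell_area)
    x = points["x"].to_numpy(float)
    y = points["y"].to_numpy(float)
    ox, oy = origin if origin is not None else (float(x.min()), float(y.min()))
    q, r = _axial_of_points(x - ox, y - oy, s)
    df = values.copy()
    df["_q"], df["_r"] = q, r
    grouped = df.groupby(["_q", "_r"]).agg(["mean", "size"])
    means = grouped.xs("mean", axis=1, level=1)
    count = grouped.xs("size", axis=1, level=1).iloc[:, 0].rename("n_deployments")

    # full tessellation covering the occupied axial range
    cells = []
    for qq in range(int(q.min()), int(q.max()) + 1):
        for rr in range(int(r.min()), int(r.max()) + 1):
            cells.append((qq, rr))
    idx = pd.MultiIndex.from_tuples(cells, names=["_q", "_r"])
    out = means.reindex(idx.union(means.index))
    out["n_deployments"] = count.reindex(out.index).fillna(0).astype(int)
    out = out.reset_index().rename(columns={"_q": "q", "_r": "r"})
    cx, cy = _hex_center(out["q"].to_numpy(), out["r"].to_numpy(), s)
    out.insert(2, "center_x", cx + ox)
    out.insert(3, "center_y", cy + oy)
    out.insert(0, "cell_id", [f"hex_{qq}_{rr}" for qq, rr in zip(out["q"], out["r"])])
    out.attrs["hex_side"] = s
    out.attrs["origin"] = (ox, oy)
    return out


def knn_neighbours(coords: np.ndarray, k: int = 4) -> np.ndarray:
    """Indices (n, k) of each site's k nearest other sites.

    Euclidean distance in the projected plane; ties broken deterministically
    by site index. Duplicate coordinates are allowed; n must exceed k.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if n <= k:
        raise ValueError(f"need more than k={k} sites, got {n}")
    d = np.hypot(coords[:, None, 0] - coords[None, :, 0],
                 coords[:, None, 1] - coords[None, :, 1])
    np.fill_diagonal(d, np.inf)
    ids = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((ids, d), axis=1)  # distance, then site id
    return order[:, :k]


def knn_lag(coords, values, k: int = 4) -> np.ndarray:
    """Spatially lagged variable: mean of ``values`` over k nearest sites."""
    nn = knn_neighbours(coords, k)
    v = np.asarray(values, float)
    return v[nn].mean(axis=1)


def knn_weight_matrix(coords, k: int = 4) -> np.ndarray:
    """Row-standardized (1/k) kNN spatial weight matrix, no self-neighbour."""
    nn = knn_neighbours(coords, k)
    n = len(nn)
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    W[rows, nn.ravel()] = 1.0 / k
    return W


def morans_i(values, weights: np.ndarray, n_perm: int = 999,
             seed: int = 0) -> tuple[float, float]:
    """Global Moran's I with a two-sided permutation p-value.

    I = (n/S0) * (z' W z)/(z' z) with z the centred values and S0 the total
    weight. The p-value compares |I - mean(I_perm)| against ``n_perm``
    random permutations of the values over sites.
    """
    v = np.asarray(values, float)
    n = len(v)
    if n < 8:
        raise ValueError("Moran's I requires at least 8 sites")
    z = v - v.mean()
    denom = float(z @ z)
    if denom == 0:
        logger.warning("Moran's I undefined: zero-variance values")
        return float("nan"), float("nan")
    S0 = float(weights.sum())
    I = n / S0 * float(z @ weights @ z) / denom

    rng = np.random.default_rng(seed)
    P = np.empty((n_perm, n))
    for b in range(n_perm):
        P[b] = z[rng.permutation(n)]
    numer = ((P @ weights) * P).sum(axis=1)
    I_perm = n / S0 * numer / denom
    center = I_perm.mean()
    p = (1.0 + np.sum(np.abs(I_perm - center) >= abs(I - center))) / (n_perm + 1.0)
    return float(I), float(min(p, 1.0))


def write_hexgrid_geojson(grid: pd.DataFrame, path: str | Path) -> None:
    s = grid.attrs.get("hex_side")
    origin = grid.attrs.get("origin", (0.0, 0.0))
    feats = []
    for _, row in grid.iterrows():
        props = {c: (None if pd.isna(row[c]) else
                     (row[c].item() if hasattr(row[c], "item") else row[c]))
                 for c in grid.columns if c not in ("q", "r")}
        ring = hex_polygon(int(row["q"]), int(row["r"]), s, origin)
        feats.append({"type": "Feature", "properties": props,
                      "geometry": {"type": "Polygon",
                                   "coordinates": [[list(p) for p in ring]]}})
    Path(path).write_text(json.dumps({"type": "FeatureCollection",
                                      "features": feats}), encoding="utf-8")


def write_weights_triplets(coords, site_ids, k: int, path: str | Path) -> None:
    """Sparse triplet text export: site_i, site_j, w per line."""
    nn = knn_neighbours(coords, k)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("site_i,site_j,w\n")
        for i, row in enumerate(nn):
            for j in row:
                fh.write(f"{site_ids[i]},{site_ids[j]},{1.0 / k}\n")
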