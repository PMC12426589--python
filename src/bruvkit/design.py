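"""Spatially balanced stratified survey design (GRTS on a discrete cell frame).

Implements generalized random tessellation stratified sampling over a frame
of labelled cells: quadrant-recursive hierarchical addresses with
independently randomized digit permutations per node, systematic selection
along the randomized address order (equal inclusion probability within
stratum), reverse hierarchical ordering of the draw, and a greedy
skip-and-replace rule for the minimum-spacing constraint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._raster import Raster

__all__ = ["InfeasibleDesignError", "frame_from_rasters", "grts_sample",
           "balance_metric"]


class InfeasibleDesignError(RuntimeError):
    """Raised when a stratum cannot host the requested sites at min_dist."""


def frame_from_rasters(habitat: Raster, bathymetry: Raster,
                       stratum_of: dict[int, str]) -> pd.DataFrame:
    """Build a sampling frame (one row per cell) from habitat/bathymetry
    rasters. ``stratum_of`` maps habitat codes to stratum labels; unmapped
    codes are excluded from the frame."""
    xs, ys = habitat.cell_centers()
    X, Y = np.meshgrid(xs, ys)
    codes = habitat.data.astype(int).ravel()
    frame = pd.DataFrame({
        "x": X.ravel(), "y": Y.ravel(),
        "depth_m": bathymetry.data.ravel(),
        "stratum": pd.Series(codes).map(stratum_of),
    })
    frame = frame.dropna(subset=["stratum"]).reset_index(drop=True)
    frame.insert(0, "cell_id", np.arange(len(frame)))
    return frame


def _hierarchical_order(x: np.ndarray, y: np.ndarray, levels: int,
                        rng: np.random.Generator):
    """Randomized quadrant-recursive ordering of points.

    Returns (order, addresses): ``order`` is the index array of points in
    randomized hierarchical address order; ``addresses`` the base-4 digit
    strings. Each internal node of the quadrant tree receives its own
    independent digit permutation.
    """
    n = len(x)
    res = 1 << levels
    bx0, bx1 = float(x.min()), float(x.max())
    by0, by1 = float(y.min()), float(y.max())
    eps = 1e-9
    ix = np.minimum(((x - bx0) / max(bx1 - bx0, eps) * res).astype(int), res - 1)
    iy = np.minimum(((y - by0) / max(by1 - by0, eps) * res).astype(int), res - 1)

    # Raw digit at each level: 2*y-bit + x-bit, most significant level first.
    digits = np.empty((levels, n), dtype=np.int64)
    for lev in range(levels):
        shift = levels - 1 - lev
        digits[lev] = 2 * ((iy >> shift) & 1) + ((ix >> shift) & 1)

    perms: dict[tuple, np.ndarray] = {}
    keys = np.zeros(n, dtype=np.int64)  # randomized prefix as base-4 integer
    rand_digits = np.empty((levels, n), dtype=np.int64)
    for lev in range(levels):
        raw = digits[lev]
        out = np.empty(n, dtype=np.int64)
        for key in np.unique(keys):
            mask = keys == key
            perm = perms.get((lev, key))
            if perm is None:
                perm = rng.permutation(4)
                perms[(lev, key)] = perm
            out[mask] = perm[raw[mask]]
        rand_digits[lev] = out
        keys = keys * 4 + out

    jitter = rng.random(n)  # tie-break for cells sharing an address
    order = np.lexsort((jitter, keys))
    addresses = np.array(["".join(str(d) for d in rand_digits[:, i])
                          for i in range(n)])
    return order, addresses, keys


def grts_sample(frame: pd.DataFrame, n_per_stratum: dict[str, int],
                min_dist: float = 0.0,
                depth_range: tuple[float, float] | None = None,
                seed: int = 0) -> pd.DataFrame:
    """Draw a spatially balanced stratified sample from a cell frame.

    Parameters
    ----------
    frame : DataFrame with columns cell_id, x, y, stratum, depth_m.
    n_per_stratum : stratum label -> number of sites.
    min_dist : minimum pairwise distance (m) between *all* plan sites.
    depth_range : (min, max) eligible depth envelope, inclusive.
    seed : root random seed; the draw is deterministic given the seed.

    Returns a DeploymentPlan table with columns site_id, stratum, x, y,
    address, order_rank, depth_m.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    accepted_xy: list[tuple[float, float]] = []
    records = []
    for stratum in sorted(n_per_stratum):
        n = int(n_per_stratum[stratum])
        sub = frame[frame["stratum"] == stratum]
        if depth_range is not None:
            lo, hi = depth_range
            sub = sub[(sub["depth_m"] >= lo) & (sub["depth_m"] <= hi)]
        if len(sub) < n:
            raise InfeasibleDesignError(
                f"stratum {stratum!r}: {len(sub)} eligible cells for {n} sites")
        x = sub["x"].to_numpy(float)
        y = sub["y"].to_numpy(float)
        N = len(sub)
        # Smallest level count giving >= 4x as many quadrants as sites.
        levels = 1
        while 4 ** levels < 4 * n:
            levels += 1
        order, addresses, _ = _hierarchical_order(x, y, levels, rng)

        # Systematic selection along the randomized order: each cell owns a
        # segment of length n/N; points u, u+1, ..., u+n-1 select cells.
        u = rng.random()
        cum = np.arange(1, N + 1) * (n / N)  # segment right edges in order
        hits = np.searchsorted(cum, u + np.arange(n), side="right")
        selected = order[np.minimum(hits, N - 1)]

        # Reverse hierarchical ordering of the selected sites.
        pos_in_order = np.empty(N, dtype=int)
        pos_in_order[order] = np.arange(N)
        rev_rank = np.argsort([_reverse_base4(addresses[i]) for i in selected],
                              kind="stable")
        draw_sequence = [selected[i] for i in rev_rank]

        taken = set(draw_sequence)
        for cand in draw_sequence:
            site = cand
            ok = _spaced(x[site], y[site], accepted_xy, min_dist)
            if not ok:
                # skip-and-replace: walk forward in address order
                start = pos_in_order[cand]
                site = -1
                for step in range(1, N):
                    alt = order[(start + step) % N]
                    if alt in taken:
                        continue
                    if _spaced(x[alt], y[alt], accepted_xy, min_dist):
                        site = alt
                        taken.add(alt)
                        break
                if site < 0:
                    raise InfeasibleDesignError(
                        f"stratum {stratum!r}: cannot place {n} sites "
                        f"with min_dist={min_dist}")
            accepted_xy.append((float(x[site]), float(y[site])))
            records.append({
                "stratum": stratum,
                "x": float(x[site]), "y": float(y[site]),
                "address": addresses[site],
                "depth_m": float(sub["depth_m"].to_numpy()[site]),
            })
    plan = pd.DataFrame.from_records(records)
    plan.insert(0, "site_id", [f"site_{i:04d}" for i in range(len(plan))])
    plan["order_rank"] = np.arange(len(plan))
    return plan[["site_id", "stratum", "x", "y", "address", "order_rank",
                 "depth_m"]]


def _reverse_base4(address: str) -> str:
    return address[::-1]


def _spaced(px: float, py: float, accepted, min_dist: float) -> bool:
    if min_dist <= 0 or not accepted:
        return True
    a = np.asarray(accepted)
    return bool(np.all(np.hypot(a[:, 0] - px, a[:, 1] - py) >= min_dist))


def balance_metric(plan: pd.DataFrame, frame: pd.DataFrame) -> float:
    """Spatial-balance diagnostic: variance of per-site Voronoi inclusion mass.

    Every frame cell carries equal inclusion mass summing to 1; each cell is
    assigned to its nearest plan site and the variance of the per-site mass
    totals is returned. 0 indicates a perfectly even partition. Single-site
    plans return 0 by convention.
    """
    if len(plan) == 0:
        raise ValueError("plan is empty")
    if len(plan) == 1:
        return 0.0
    fx = frame["x"].to_numpy(float)
    fy = frame["y"].to_numpy(float)
    sx = plan["x"].to_numpy(float)
    sy = plan["y"].to_numpy(float)
    d2 = (fx[:, None] - sx[None, :]) ** 2 + (fy[:, None] - sy[None, :]) ** 2
    nearest = np.argmin(d2, axis=1)
    mass = np.bincount(nearest, minlength=len(plan)) / len(frame)
    return float(np.var(mass))
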