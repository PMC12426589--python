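"""Sample-based (incidence) rarefaction and extrapolation of species richness.

Interpolation uses the hypergeometric expectation over subsets of sampling
units; extrapolation follows the Chao2-based asymptotic form; confidence
bands come from a seeded bootstrap over the estimated incidence-probability
assemblage (including estimated undetected species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = ["IncidenceData", "incidence_counts", "rarefy", "chao2",
           "extrapolate", "rarefaction_curve", "bootstrap_ci"]


@dataclass
class IncidenceData:
    """Incidence frequency summary of a deployment x species table.

    T: number of sampling units; S_obs: observed species; Q[k]: number of
    species found in exactly k units (index 0 unused). ``Y`` optionally
    keeps the per-species incidence counts for bootstrap resampling.
    """

    T: int
    S_obs: int
    Q: np.ndarray
    Y: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if int(self.Q[1:].sum()) != self.S_obs:
            raise ValueError("sum of incidence frequency counts != S_obs")

    @property
    def Q1(self) -> float:
        return float(self.Q[1]) if len(self.Q) > 1 else 0.0

    @property
    def Q2(self) -> float:
        return float(self.Q[2]) if len(self.Q) > 2 else 0.0

    @classmethod
    def from_incidence(cls, Y: np.ndarray, T: int) -> "IncidenceData":
        Y = np.asarray(Y, dtype=int)
        Y = Y[Y > 0]
        Q = np.bincount(Y, minlength=T + 1)[:T + 1]
        return cls(T=int(T), S_obs=int(len(Y)), Q=Q, Y=Y)


def incidence_counts(maxn: pd.DataFrame) -> IncidenceData:
    """Tally incidence (presence per deployment) from a MaxN table."""
    if len(maxn) == 0:
        raise ValueError("MaxN table is empty")
    Y = (maxn.to_numpy() >= 1).sum(axis=0)
    return IncidenceData.from_incidence(Y, T=len(maxn))


def rarefy(inc: IncidenceData, t: int) -> float:
    """Expected richness in t <= T units (hypergeometric interpolation).

    S(t) = S_obs - sum_k Q_k * C(T-k, t) / C(T, t).
    """
    T = inc.T
    if not 1 <= t <= T:
        raise ValueError(f"t={t} outside interpolation range [1, {T}]")
    ks = np.nonzero(inc.Q[1:])[0] + 1
    total = 0.0
    for k in ks:
        if T - k >= t:
            logratio = (gammaln(T - k + 1) - gammaln(T - k - t + 1)
                        - gammaln(T + 1) + gammaln(T - t + 1))
            total += inc.Q[k] * np.exp(logratio)
    return float(inc.S_obs - total)


def chao2(inc: IncidenceData) -> float:
    """Chao2 asymptotic richness (bias-corrected form when Q2 = 0)."""
    if inc.T < 2:
        raise ValueError("Chao2 requires at least 2 sampling units")
    q1, q2 = inc.Q1, inc.Q2
    mult = (inc.T - 1.0) / inc.T
    if q2 > 0:
        return float(inc.S_obs + mult * q1 * q1 / (2.0 * q2))
    return float(inc.S_obs + mult * q1 * (q1 - 1.0) / (2.0 * (q2 + 1.0)))


def extrapolate(inc: IncidenceData, t: int | float) -> float:
    """Expected richness beyond T units via the Chao2 asymptote.

    S(T + t*) = S_obs + Q0_hat * [1 - (1 - Q1/(Q1 + T*Q0_hat))^t*]. Flat at
    S_obs when Q1 = 0 (no undetected-species signal).
    """
    if t <= inc.T:
        raise ValueError(f"t={t} is not beyond T={inc.T}")
    q0 = chao2(inc) - inc.S_obs
    if inc.Q1 == 0 or q0 <= 0:
        return float(inc.S_obs)
    rate = inc.Q1 / (inc.Q1 + inc.T * q0)
    return float(inc.S_obs + q0 * (1.0 - (1.0 - rate) ** (t - inc.T)))


def _richness_at(inc: IncidenceData, t) -> float:
    return rarefy(inc, int(t)) if t <= inc.T else extrapolate(inc, t)


def bootstrap_ci(inc: IncidenceData, t_grid, B: int = 200, seed: int = 0,
                 level: float = 0.95) -> pd.DataFrame:
    """Percentile bootstrap confidence bands for S(t) and the asymptote.

    The estimated assemblage has each observed species present in a unit
    with probability Y_i/T and ``round(Q0_hat)`` undetected species at the
    equal incidence rate Q1/(Q1 + T*Q0_hat); each replicate resamples a
    T-unit incidence matrix and recomputes the whole curve.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if inc.Y is None:
        raise ValueError("bootstrap requires per-species incidence counts")
    rng = np.random.default_rng(seed)
    T = inc.T
    p = inc.Y / T
    q0 = max(chao2(inc) - inc.S_obs, 0.0)
    n0 = int(round(q0))
    if n0 > 0 and inc.Q1 > 0:
        p0 = inc.Q1 / (inc.Q1 + T * q0)
        p = np.concatenate([p, np.full(n0, p0)])
    t_grid = np.asarray(list(t_grid))
    curves = np.empty((B, len(t_grid)))
    asymptotes = np.empty(B)
    for b in range(B):
        pres = rng.random((T, len(p))) < p[None, :]
        Yb = pres.sum(axis=0)
        if (Yb > 0).sum() == 0:
            curves[b] = 0.0
            asymptotes[b] = 0.0
            continue
        ib = IncidenceData.from_incidence(Yb, T)
        curves[b] = [_richness_at(ib, t) for t in t_grid]
        asymptotes[b] = chao2(ib)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    out = pd.DataFrame({
        "t": t_grid,
        "lower": np.quantile(curves, lo, axis=0),
        "upper": np.quantile(curves, hi, axis=0),
    })
    out.attrs["asymptote_ci"] = (float(np.quantile(asymptotes, lo)),
                                 float(np.quantile(asymptotes, hi)))
    return out


def rarefaction_curve(maxn: pd.DataFrame, t_max: int | None = None,
                      B: int = 200, seed: int = 0,
                      step: int = 1) -> pd.DataFrame:
    """Full interpolated + extrapolated richness curve from a MaxN table.

    Returns columns t, richness, lower, upper, regime; the Chao2 asymptote
    and its CI ride along in ``attrs``. S(T) equals S_obs exactly and the
    curve is continuous and non-decreasing across the T boundary.
    """
    inc = incidence_counts(maxn)
    t_max = t_max or inc.T
    t_grid = np.arange(1, t_max + 1, step)
    if t_grid[-1] != t_max:
        t_grid = np.append(t_grid, t_max)
    rich = np.array([_richness_at(inc, t) for t in t_grid])
    ci = bootstrap_ci(inc, t_grid, B=B, seed=seed)
    out = pd.DataFrame({
        "t": t_grid,
        "richness": rich,
        "lower": ci["lower"].to_numpy(),
        "upper": ci["upper"].to_numpy(),
        "regime": np.where(t_grid <= inc.T, "interpolated", "extrapolated"),
    })
    out.attrs["S_obs"] = inc.S_obs
    out.attrs["T"] = inc.T
    out.attrs["asymptote"] = chao2(inc)
    out.attrs["asymptote_ci"] = ci.attrs["asymptote_ci"]
    return out
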