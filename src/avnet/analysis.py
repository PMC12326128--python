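"""Reaction-time distribution analytics.

Cumulative distribution functions of RTs per condition, the independent-race
prediction for bimodal responses (the probability that either unisensory
channel alone has responded, P_A + P_V - P_A*P_V), and area measures of the
redundant-signals effect: the empirical benefit (area between the bimodal CDF
and the faster unisensory envelope) and the multisensory gain (area between
the bimodal CDF and the race prediction, whose positivity marks a race-model
violation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RtCdf",
    "pooled_percentile_grid",
    "empirical_cdf",
    "raab_race_cdf",
    "benefit_area",
    "multisensory_gain",
    "switch_cost",
]


@dataclass(frozen=True)
class RtCdf:
    """Empirical cumulative RT distribution sampled on a fixed grid [ms]."""

    grid_ms: np.ndarray
    prob: np.ndarray
    n: int

    def __post_init__(self) -> None:
        g = np.asarray(self.grid_ms, dtype=float)
        p = np.asarray(self.prob, dtype=float)
        if g.shape != p.shape or g.ndim != 1:
            raise ValueError("grid and probabilities must be 1-D arrays of equal length")
        if np.any(np.diff(g) < 0):
            raise ValueError("grid must be non-decreasing")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12) or np.any(np.diff(p) < -1e-12):
            raise ValueError("probabilities must be non-decreasing within [0, 1]")
        object.__setattr__(self, "grid_ms", g)
        object.__setattr__(self, "prob", p)


def pooled_percentile_grid(*rt_samples, step_pct: float = 5.0) -> np.ndarray:
    """Quantile grid over the pooled samples (5th-100th percentile by default).

    The standard grid for RT CDF comparisons: percentiles of the pooled
    distribution of all conditions, so every condition is evaluated at common
    time points.
    """
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in rt_samples])
    if pooled.size == 0:
        raise ValueError("no RTs to build a grid from")
    q = np.arange(step_pct, 100.0 + step_pct / 2, step_pct)
    return np.percentile(pooled, q)


def empirical_cdf(rts, grid_ms) -> RtCdf:
    """Proportion of RTs at or below each grid point."""
    rts = np.sort(np.asarray(rts, dtype=float))
    if rts.size == 0:
        raise ValueError("empirical_cdf requires at least one RT")
    grid = np.asarray(grid_ms, dtype=float)
    prob = np.searchsorted(rts, grid, side="right") / rts.size
    return RtCdf(grid_ms=grid, prob=prob, n=int(rts.size))


def raab_race_cdf(cdf_a: RtCdf, cdf_v: RtCdf) -> RtCdf:
    """Independent-race prediction P_A + P_V - P_A * P_V on the shared grid."""
    if not np.array_equal(cdf_a.grid_ms, cdf_v.grid_ms):
        raise ValueError("race prediction requires CDFs on a shared grid")
    pa, pv = cdf_a.prob, cdf_v.prob
    return RtCdf(grid_ms=cdf_a.grid_ms, prob=pa + pv - pa * pv, n=min(cdf_a.n, cdf_v.n))


def _area_above(upper: RtCdf, lower_prob: np.ndarray) -> float:
    diff = np.clip(upper.prob - lower_prob, 0.0, None)
    return float(np.trapezoid(diff, upper.grid_ms))


def benefit_area(cdf_upper: RtCdf, cdf_a: RtCdf, cdf_v: RtCdf) -> float:
    """Area between an upper CDF and the faster-unisensory envelope.

    The envelope is the pointwise maximum of the A and V CDFs; negative
    differences are clamped to zero.  Units: probability x ms.
    """
    for c in (cdf_a, cdf_v):
        if not np.array_equal(cdf_upper.grid_ms, c.grid_ms):
            raise ValueError("benefit_area requires CDFs on a shared grid")
    envelope = np.maximum(cdf_a.prob, cdf_v.prob)
    return _area_above(cdf_upper, envelope)


def multisensory_gain(cdf_av: RtCdf, race_cdf: RtCdf) -> float:
    """Area between the bimodal CDF and the race prediction (clamped at zero).

    Strictly positive gain indicates a race-model violation: bimodal responses
    faster than any independent-channels account allows.
    """
    if not np.array_equal(cdf_av.grid_ms, race_cdf.grid_ms):
        raise ValueError("multisensory_gain requires CDFs on a shared grid")
    return _area_above(cdf_av, race_cdf.prob)


def switch_cost(records: pd.DataFrame) -> float:
    """Unisensory switch cost: mean(Sw) - mean(Rp) per modality, averaged A, V.

    Expects a record table with ``label`` and ``rt_ms`` columns; anticipatory
    and missing responses are excluded if flagged.
    """
    ok = records.dropna(subset=["rt_ms"])
    for flag in ("anticipatory", "no_response"):
        if flag in ok.columns:
            ok = ok[~ok[flag].astype(bool)]
    means = ok.groupby("label")["rt_ms"].mean()
    costs = []
    for m in ("A", "V"):
        if f"Sw{m}" not in means or f"Rp{m}" not in means:
            raise ValueError(f"records lack Sw{m}/Rp{m} trials")
        costs.append(means[f"Sw{m}"] - means[f"Rp{m}"])
    return float(np.mean(costs))
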