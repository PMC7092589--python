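"""Replication kinetics: cumulative curves, logistic T_rep/T_width fits,
TTR fork-speed estimation and the weighted early/late RT score.

The 16 fractions slice an S phase of ``s_duration`` hours (default 10)
into equal windows. A bin's cumulative curve (column-wise running sum of
its normalised heatmap values, ending at 100) approximates the fraction
of cells that have replicated the bin by the END of each window, so the
cumulative value of fraction ``f`` carries the time coordinate
``f/16 * s_duration`` (window midpoints describe the per-window
increments, not the running sum). A logistic

    F(t) = 100 / (1 + exp(-k (t - t0)))

is least-squares fitted to the 16 (time, cumulative) points. T_rep = t0 is
the 50 %-replicated time, and T_width = 2 ln 3 / k is the 25 %->75 % time
spread, a cell-to-cell variability measure (the identity follows from the
logistic quantile function). A non-parametric quantile oracle
(:func:`quantile_twidth`) interpolates the 25/50/75 crossing times
directly and is used for fit initialisation and cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import (
    N_FRACTIONS,
    BinIndex,
    BinnedTrack,
    FeatureCall,
    Heatmap,
    KineticsRecord,
    RepliSeqError,
)

LN3 = math.log(3.0)


@dataclass(frozen=True)
class CumulativeProfile:
    """Column-wise cumulative replication percentage (16 x N), with the
    S-phase duration in hours that maps fractions to times."""

    index: BinIndex
    cum: np.ndarray
    mask: np.ndarray
    s_duration: float = 10.0

    @property
    def times_mid(self) -> np.ndarray:
        """Window-midpoint time (hours) of each fraction."""
        return (np.arange(1, N_FRACTIONS + 1) - 0.5) / N_FRACTIONS * self.s_duration

    @property
    def times_end(self) -> np.ndarray:
        """Window-end time (hours) of each fraction."""
        return np.arange(1, N_FRACTIONS + 1) / N_FRACTIONS * self.s_duration


@dataclass(frozen=True)
class SpeedEstimate:
    """Fork speed inferred from one TTR: size (kb) divided by the S-phase
    time it traverses. ``speed == size / (fractions_spanned/16 * s_minutes)``
    holds exactly."""

    ttr: FeatureCall
    size: float  # kb
    fractions_spanned: float
    speed: float  # kb/min

    def __post_init__(self):
        if self.speed <= 0:
            raise RepliSeqError("fork speed must be positive")


def cumulative_profile(heatmap: Heatmap, s_duration: float = 10.0) -> CumulativeProfile:
    """Column-wise cumulative sum of the normalised heatmap.

    Unmasked columns are non-decreasing and end at 100 (by column scaling).
    """
    if heatmap.stage != "normalized":
        raise RepliSeqError("cumulative_profile requires a normalized heatmap")
    return CumulativeProfile(
        heatmap.index, np.cumsum(heatmap.matrix, axis=0), heatmap.mask, s_duration
    )


def quantile_twidth(cum: CumulativeProfile, bin: int) -> tuple:
    """(t25, t50, t75) in hours by linear interpolation of the crossing
    times of the cumulative curve (anchored at (t=0, 0), window-end times).
    """
    col = cum.cum[:, bin]
    if np.any(np.diff(col) < -1e-9):
        raise RepliSeqError("cumulative column is not non-decreasing")
    x = np.concatenate([[0.0], col])
    t = np.concatenate([[0.0], cum.times_end])
    out = []
    for q in (25.0, 50.0, 75.0):
        idx = int(np.searchsorted(x, q, side="left"))
        if idx >= len(x):
            out.append(float("nan"))
            continue
        if idx == 0 or x[idx] == x[idx - 1]:
            out.append(float(t[idx]))
        else:
            frac = (q - x[idx - 1]) / (x[idx] - x[idx - 1])
            out.append(float(t[idx - 1] + frac * (t[idx] - t[idx - 1])))
    return tuple(out)


def _logistic(t, k, t0):
    return 100.0 / (1.0 + np.exp(-np.clip(k * (t - t0), -500, 500)))


def _logistic_jac(t, k, t0):
    z = np.clip(k * (t - t0), -500, 500)
    e = np.exp(-z)
    s = 100.0 * e / (1.0 + e) ** 2
    return np.column_stack([s * (t - t0), -s * k])


def fit_sigmoid(
    cum: CumulativeProfile,
    bin: int,
    rmse_cap: float = 5.0,
    max_restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> KineticsRecord:
    """Fit the logistic to one bin's cumulative curve.

    Initialised from the quantile oracle (t0 from t50, k from the 25->75
    spread); bounded k in (0, 50] per hour, t0 in [0, s_duration]; restarts
    with jittered initial values on non-convergence. Fits that fail or
    exceed ``rmse_cap`` percentage points of residual are flagged, never
    raised.
    """
    col = cum.cum[:, bin]
    t = cum.times_end
    if len(np.unique(np.round(col, 9))) < 2:
        return KineticsRecord(bin, float("nan"), float("nan"), float("nan"),
                              float("inf"), flagged=True)
    t25, t50, t75 = quantile_twidth(cum, bin)
    if not np.isfinite(t50):
        t50 = cum.s_duration  # curve does not reach 50 % within S
    if not (np.isfinite(t25) and np.isfinite(t75)):
        t25, t75 = t50 - 1.0, t50 + 1.0
    width0 = max(t75 - t25, cum.s_duration / N_FRACTIONS / 2)
    p0 = np.array(
        [
            float(np.clip(2 * LN3 / width0, 1e-3, 50.0)),
            float(np.clip(t50, 0.0, cum.s_duration)),
        ]
    )
    rng = rng or np.random.default_rng(0)
    bounds = ([1e-3, 0.0], [50.0, cum.s_duration])
    best = None
    for attempt in range(max_restarts + 1):
        # least_squares keeps the best point even when the flat near-step
        # surface never satisfies the convergence tolerances
        fit = least_squares(
            lambda p: _logistic(t, p[0], p[1]) - col,
            x0=p0,
            jac=lambda p: _logistic_jac(t, p[0], p[1]),
            bounds=bounds,
            max_nfev=400,
        )
        k, t0 = float(fit.x[0]), float(fit.x[1])
        rmse = float(np.sqrt(np.mean(fit.fun**2)))
        if best is None or rmse < best[2]:
            best = (k, t0, rmse)
        if rmse <= rmse_cap:
            break
        p0 = np.array(
            [
                float(np.clip(p0[0] * rng.uniform(0.5, 2.0), 1e-3, 50.0)),
                float(np.clip(p0[1] + rng.uniform(-1, 1), 0, cum.s_duration)),
            ]
        )
    k, t0, rmse = best
    return KineticsRecord(bin, t0, 2 * LN3 / k, k, rmse, flagged=rmse > rmse_cap)


def fit_all(
    cum: CumulativeProfile, bins: Sequence[int] | None = None, rmse_cap: float = 5.0
) -> list:
    """Fit every requested unmasked bin (defaults to all unmasked bins)."""
    if bins is None:
        bins = np.flatnonzero(~cum.mask)
    return [fit_sigmoid(cum, int(b), rmse_cap=rmse_cap) for b in bins]


def trep_array(cum: CumulativeProfile, records: Sequence[KineticsRecord]) -> np.ndarray:
    """Per-bin t_rep (hours) from fit records; NaN where flagged/missing."""
    out = np.full(cum.index.n_bins, np.nan)
    for r in records:
        if not r.flagged:
            out[r.bin] = r.t_rep
    return out


def _breakage_free_chains(features: Sequence[FeatureCall]) -> list:
    """Group TTR calls into breakage-free slopes.

    Same-direction TTR pieces that are separated only by adjacent breakage
    calls belong to one uni-directional fork traversal; each chain yields
    the list of its TTR (not breakage) feature calls.
    """
    ordered = sorted(
        (f for f in features
         if f.feature_class in ("TTR_left", "TTR_right", "breakage")),
        key=lambda f: (f.chrom, f.start),
    )
    chains: list = []
    current: list = []
    direction = None
    last_end = None
    last_chrom = None
    for f in ordered:
        adjacent = f.chrom == last_chrom and f.start == last_end
        if f.feature_class == "breakage":
            if not adjacent:
                current, direction = [], None
        else:
            if adjacent and direction in (None, f.feature_class) and current:
                current.append(f)
                direction = f.feature_class
            else:
                current = [f]
                direction = f.feature_class
                chains.append(current)
        last_end, last_chrom = f.end, f.chrom
    return [c for c in chains if c]


def ttr_speed(
    features: Sequence[FeatureCall],
    trep: np.ndarray,
    index: BinIndex,
    s_duration: float = 10.0,
    min_fraction_span: float = 0.5,
    merge_across_breakages: bool = True,
) -> list:
    """Fork speed per breakage-free TTR.

    Breakages mark small internal initiation zones that locally flatten a
    slope, so same-direction TTR pieces separated only by breakages are
    treated as one fork traversal and the breakage bins are excluded from
    the estimate (set ``merge_across_breakages=False`` to score each TTR
    call separately). The speed is the inverse slope of an ordinary
    least-squares regression of t_rep (minutes) on bin-centre position
    (kb) over the TTR bins — identical to dividing the TTR size by the
    time it traverses, but unbiased for short TTRs since bin-centre times
    span one bin less than the interval. Estimates whose time span falls
    below ``min_fraction_span`` fraction widths, whose slope sign
    contradicts the TTR direction, or that lack >= 2 fitted bins are
    dropped (flagged), not emitted.
    """
    s_minutes = s_duration * 60.0
    frac_minutes = s_minutes / N_FRACTIONS
    centres_kb = index.centres() / 1000.0
    if merge_across_breakages:
        groups = _breakage_free_chains(features)
    else:
        groups = [
            [f] for f in features
            if f.feature_class in ("TTR_left", "TTR_right")
        ]
    out = []
    for group in groups:
        bins: list = []
        for f in group:
            i0 = index.bin_of(f.chrom, f.start)
            i1 = index.bin_of(f.chrom, f.end - 1)
            bins.extend(range(i0, i1 + 1))
        idx = np.array(bins)
        y = trep[idx] * 60.0  # minutes
        ok = np.isfinite(y)
        if ok.sum() < 2:
            continue
        x = centres_kb[idx][ok]
        y = y[ok]
        slope = float(np.polyfit(x, y, 1)[0])  # min per kb
        direction = group[0].feature_class
        if direction == "TTR_left":
            slope = -slope  # leftward fork: time decreases with position
        if slope <= 0:
            continue
        speed = 1.0 / slope
        size_kb = sum(f.end - f.start for f in group) / 1000.0
        span = FeatureCall(
            group[0].chrom, group[0].start, group[-1].end, direction
        )
        fractions_spanned = size_kb / speed / frac_minutes
        if fractions_spanned < min_fraction_span:
            continue
        out.append(SpeedEstimate(span, size_kb, fractions_spanned, speed))
    return out


def summarize_speeds(estimates: Sequence[SpeedEstimate]) -> dict:
    speeds = np.array([e.speed for e in estimates])
    if len(speeds) == 0:
        return {"n": 0, "median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    return {
        "n": len(speeds),
        "median": float(np.median(speeds)),
        "q1": float(np.percentile(speeds, 25)),
        "q3": float(np.percentile(speeds, 75)),
    }


def weighted_rt_score(heatmap: Heatmap, epsilon: float = 0.01) -> BinnedTrack:
    """Weighted early/late replication-timing score per bin:

    log2( (S1*8 + S2*7 + ... + S8*1 + eps) / (S9*1 + S10*2 + ... + S16*8 + eps) )

    Positive = early replicating, negative = late; ``epsilon`` keeps bins
    with all mass on one side finite. Masked bins score 0.
    """
    if heatmap.stage != "normalized":
        raise RepliSeqError("weighted_rt_score requires a normalized heatmap")
    w_early = np.arange(8, 0, -1)  # 8..1 for S1..S8
    w_late = np.arange(1, 9)  # 1..8 for S9..S16
    num = w_early @ heatmap.matrix[:8] + epsilon
    den = w_late @ heatmap.matrix[8:] + epsilon
    score = np.log2(num / den)
    score[heatmap.mask] = 0.0
    return BinnedTrack(heatmap.index, score)


def rt_difference(score_a: BinnedTrack, score_b: BinnedTrack) -> BinnedTrack:
    """Element-wise RT-score difference a - b (e.g. one allele minus the
    other); the two tracks must share a BinIndex."""
    if score_a.index != score_b.index:
        raise RepliSeqError("RT score tracks are on different bin grids")
    return BinnedTrack(score_a.index, score_a.values - score_b.values)
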