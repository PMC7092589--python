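"""Raw fraction counts -> normalised 16 x N Repli-Seq heatmap.

The stages mirror the standard high-resolution Repli-Seq processing:

1. per-track RPM (reads per million, G1 included);
2. log2(S/G1) mappability correction with clipping of negative values to
   zero and masking of low-G1 (unmappable) bins;
3. 2-D Gaussian smoothing (sigma = 1 bin, 3 x 3 truncated kernel, i.e. the
   8 neighbouring bins), with replicate padding of the first/last fraction
   rows and of chromosome-terminal bins;
4. column scaling so that every unmasked 16-value column sums to 100.

Masked bins are excluded from neighbour sums with kernel-weight
renormalisation, so mask borders do not dip artificially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Heatmap, BinnedTrack, FractionStack, N_FRACTIONS, RepliSeqError


@dataclass(frozen=True)
class SmoothingKernel:
    """Truncated, normalised 2-D Gaussian kernel.

    Weights follow w(x, y) ~ exp(-(x^2 + y^2) / (2 sigma^2)) on the
    (fraction, bin) lattice and are renormalised to sum to one; the 1/(2 pi
    sigma^2) prefactor of the continuous Gaussian does not normalise a
    truncated discrete kernel, and the later column scaling makes any
    constant factor irrelevant.
    """

    sigma: float = 1.0
    radius: int = 1

    def __post_init__(self):
        if self.radius < 1:
            raise RepliSeqError("kernel radius must be >= 1")
        if self.sigma <= 0:
            raise RepliSeqError("kernel sigma must be > 0")

    @property
    def weights(self) -> np.ndarray:
        r = self.radius
        y, x = np.mgrid[-r : r + 1, -r : r + 1]
        w = np.exp(-(x**2 + y**2) / (2.0 * self.sigma**2))
        return w / w.sum()


def compute_rpm(stack: FractionStack) -> FractionStack:
    """Scale every track (S1..S16 and G1) to reads per million independently."""
    totals = stack.counts.sum(axis=1)
    if np.any(totals <= 0) or stack.g1.sum() <= 0:
        bad = [f"S{i + 1}" for i in np.flatnonzero(totals <= 0)]
        if stack.g1.sum() <= 0:
            bad.append("G1")
        raise RepliSeqError(f"all-zero track(s): {', '.join(bad)}")
    counts = stack.counts / totals[:, None] * 1e6
    g1 = stack.g1 / stack.g1.sum() * 1e6
    return FractionStack(stack.index, counts, g1)


def g1_correct(stack_rpm: FractionStack, g1_floor: float = 0.1) -> Heatmap:
    """log2(S/G1) per fraction, clipped at zero, with mappability masking.

    Bins whose G1 RPM is zero or below ``g1_floor`` times the genome-wide
    median G1 RPM are masked (the bins "filtered out by mappability
    normalisation"); the ratio is never evaluated there.
    """
    if not (0 <= g1_floor < 1):
        raise RepliSeqError("g1_floor must be in [0, 1)")
    g1 = stack_rpm.g1
    mask = (g1 <= 0) | (g1 < g1_floor * np.median(g1))
    matrix = np.zeros_like(stack_rpm.counts)
    ok = ~mask
    with np.errstate(divide="ignore"):
        ratio = np.log2(stack_rpm.counts[:, ok] / g1[ok])
    matrix[:, ok] = np.maximum(0.0, np.where(np.isfinite(ratio), ratio, -np.inf))
    return Heatmap(stack_rpm.index, matrix, mask, "clipped")


def gaussian_smooth(
    heatmap: Heatmap, kernel: SmoothingKernel | None = None
) -> Heatmap:
    """2-D Gaussian smoothing over (fraction, bin).

    The fraction axis is padded by replicating the S1 row above and the
    S16 row below; the bin axis by edge replication. Masked columns are
    dropped from neighbour sums with weight renormalisation (normalised
    convolution), and stay masked and zero in the output.
    """
    if heatmap.stage not in ("raw_log2", "clipped"):
        raise RepliSeqError(f"cannot smooth heatmap at stage {heatmap.stage!r}")
    kernel = kernel or SmoothingKernel()
    w = kernel.weights
    ok = heatmap.unmasked.astype(float)
    out = np.zeros_like(heatmap.matrix)
    # chromosomes are smoothed independently: a fork cannot cross a
    # chromosome boundary, so neither should the kernel
    for sl in heatmap.index.chrom_slices().values():
        v = heatmap.matrix[:, sl] * ok[None, sl]
        support = np.ascontiguousarray(
            np.broadcast_to(ok[sl], v.shape), dtype=float
        )
        # 'nearest' replicates edges: first/last fraction rows, terminal bins
        num = ndimage.convolve(v, w, mode="nearest")
        den = ndimage.convolve(support, w, mode="nearest")
        out[:, sl] = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out *= heatmap.unmasked[None, :]
    return heatmap.with_(matrix=out, stage="smoothed")


def scale_columns(heatmap: Heatmap) -> Heatmap:
    """Assign every unmasked column a total mass of 100.

    Columns whose mass is zero (nothing replicated in any fraction) become
    masked. Smoothing may be skipped upstream: 'clipped' input is accepted
    and scaled as-is.
    """
    if heatmap.stage not in ("clipped", "smoothed"):
        raise RepliSeqError(f"cannot scale heatmap at stage {heatmap.stage!r}")
    sums = heatmap.matrix.sum(axis=0)
    mask = heatmap.mask | (sums <= 0)
    ok = ~mask
    matrix = np.zeros_like(heatmap.matrix)
    matrix[:, ok] = heatmap.matrix[:, ok] / sums[ok] * 100.0
    return heatmap.with_(matrix=matrix, mask=mask, stage="normalized")


def normalize_stack(
    stack: FractionStack,
    g1_floor: float = 0.1,
    sigma: float = 1.0,
    smooth: bool = True,
) -> Heatmap:
    """Full normalisation pipeline: RPM -> G1 correction -> smoothing -> scaling.

    ``smooth=False`` (or ``sigma=0``) skips the Gaussian stage, which is
    useful when downstream kinetics should not absorb the kernel's ~0.74
    fraction widths of temporal blur.
    """
    hm = g1_correct(compute_rpm(stack), g1_floor=g1_floor)
    if smooth and sigma > 0:
        hm = gaussian_smooth(hm, SmoothingKernel(sigma=sigma))
    return scale_columns(hm)


def qc_edge_noise(
    heatmap: Heatmap,
    rt_score: BinnedTrack,
    decile: float = 0.10,
    edge_window: int = 4,
) -> tuple:
    """Residual edge noise of the normalised heatmap.

    Returns ``(pct_late_in_earliest, pct_early_in_latest)``: the mean
    summed normalised signal (percentage points, columns sum to 100) in the
    last ``edge_window`` fractions over the top ``decile`` earliest bins by
    ``rt_score`` (higher score = earlier), and the symmetric quantity for
    the latest bins. Values well below a few percent indicate that
    non-specific signal at the extremes of S phase is negligible.
    """
    if heatmap.stage != "normalized":
        raise RepliSeqError("qc_edge_noise requires a normalized heatmap")
    if not 0 < decile <= 0.5:
        raise RepliSeqError("decile must be in (0, 0.5]")
    if not 1 <= edge_window < N_FRACTIONS:
        raise RepliSeqError("edge_window out of range")
    ok = np.flatnonzero(heatmap.unmasked)
    if len(ok) < 10:
        raise RepliSeqError("fewer than 10 unmasked bins")
    scores = rt_score.values[ok]
    n_top = max(1, int(round(decile * len(ok))))
    order = np.argsort(scores, kind="mergesort")
    earliest = ok[order[-n_top:]]
    latest = ok[order[:n_top]]
    pct_late = float(heatmap.matrix[-edge_window:, earliest].sum(axis=0).mean())
    pct_early = float(heatmap.matrix[:edge_window, latest].sum(axis=0).mean())
    return pct_late, pct_early
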