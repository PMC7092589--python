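"""Detection and classification of biphasically replicating regions.

A bin replicates biphasically when its 16-fraction profile (the increments
of the cumulative curve) carries two distinct temporal modes: two local
maxima, each holding at least ``peak_min`` percentage points of column
mass, separated by a temporal interval in which replication of neither
mode is detected (a run of at least ``min_gap`` intermediate fractions all
at or below ``trough_max``). Contiguous biphasic bins merge into one
region. Paired allele heatmaps then distinguish allele-dependent
asynchrony (each allele unimodal, one per pooled peak) from
allele-independent asynchrony (the biphasic pattern is retained within
each allele).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .core import BinIndex, Heatmap, N_FRACTIONS, RepliSeqError
from .kinetics import CumulativeProfile, cumulative_profile, quantile_twidth


@dataclass(frozen=True)
class BiphasicRegion:
    """A merged run of biphasic bins with its two replication modes."""

    chrom: str
    start: int
    end: int
    early_peak_fraction: int
    late_peak_fraction: int
    trough_fraction: int
    early_mass: float
    late_mass: float

    def __post_init__(self):
        if not (self.early_peak_fraction + 1 < self.late_peak_fraction):
            raise RepliSeqError("peaks must be separated by >= 1 fraction")
        if not (
            self.early_peak_fraction < self.trough_fraction < self.late_peak_fraction
        ):
            raise RepliSeqError("trough must lie between the peaks")


def _column_biphasic(
    profile: np.ndarray, peak_min: float, trough_max: float, min_gap: int
):
    """Classify one 16-value column. Returns (early, late, trough) 1-based
    fraction indices, or None if not biphasic."""
    v = profile
    n = len(v)
    peaks = [
        i
        for i in range(n)
        if v[i] >= peak_min
        and (i == 0 or v[i] >= v[i - 1])
        and (i == n - 1 or v[i] >= v[i + 1])
    ]
    best = None
    for a in range(len(peaks)):
        for b in range(len(peaks) - 1, a, -1):
            i, j = peaks[a], peaks[b]
            if j - i - 1 < min_gap:
                continue
            between = v[i + 1 : j]
            # longest run of consecutive quiet fractions between the peaks
            run = best_run = 0
            for x in between:
                run = run + 1 if x <= trough_max else 0
                best_run = max(best_run, run)
            if best_run >= min_gap:
                if best is None or (j - i) > (best[1] - best[0]):
                    trough = i + 1 + int(np.argmin(between))
                    best = (i, j, trough)
    if best is None:
        return None
    return best[0] + 1, best[1] + 1, best[2] + 1


def detect_biphasic(
    heatmap: Heatmap,
    peak_min: float = 20.0,
    trough_max: float = 5.0,
    min_gap: int = 1,
) -> list:
    """Find biphasic regions on a normalised heatmap.

    Per-bin detection as in :func:`_column_biphasic`; contiguous biphasic
    bins merge into one region whose peak fractions are the modal per-bin
    peaks and whose early/late masses are the mean column mass on each side
    of the trough. Detected regions are disjoint by construction.
    """
    if heatmap.stage != "normalized":
        raise RepliSeqError("detect_biphasic requires a normalized heatmap")
    flags = np.zeros(heatmap.index.n_bins, dtype=bool)
    peaks = {}
    for j in np.flatnonzero(heatmap.unmasked):
        res = _column_biphasic(heatmap.matrix[:, j], peak_min, trough_max, min_gap)
        if res is not None:
            flags[j] = True
            peaks[j] = res
    regions = []
    index = heatmap.index
    for chrom, sl in index.chrom_slices().items():
        j = sl.start
        while j < sl.stop:
            if not flags[j]:
                j += 1
                continue
            k = j
            while k + 1 < sl.stop and flags[k + 1]:
                k += 1
            bins = list(range(j, k + 1))
            early = _mode([peaks[b][0] for b in bins])
            late = _mode([peaks[b][1] for b in bins])
            trough = _mode([peaks[b][2] for b in bins])
            trough = int(np.clip(trough, early + 1, late - 1))
            sub = heatmap.matrix[:, bins]
            early_mass = float(sub[: trough - 1].sum(axis=0).mean())
            late_mass = float(sub[trough:].sum(axis=0).mean())
            regions.append(
                BiphasicRegion(
                    chrom,
                    int(index.starts[j]),
                    int(index.ends[k]),
                    int(early),
                    int(late),
                    trough,
                    early_mass,
                    late_mass,
                )
            )
            j = k + 1
    return regions


def _mode(values):
    vals, counts = np.unique(values, return_counts=True)
    return int(vals[counts.argmax()])


def region_bins(region: BiphasicRegion, index: BinIndex) -> np.ndarray:
    i0 = index.bin_of(region.chrom, region.start)
    i1 = index.bin_of(region.chrom, region.end - 1)
    return np.arange(i0, i1 + 1)


# ---------------------------------------------------------------------------
# Annotation overlap


def overlap_annotation(
    regions: Sequence[BiphasicRegion],
    annotation: Sequence[tuple],
    index: BinIndex,
) -> list:
    """Flag regions with >= 50 % of their bins fully contained in a single
    annotation interval (e.g. one fragile site or one long gene)."""
    flags = []
    for region in regions:
        bins = region_bins(region, index)
        starts = index.starts[bins]
        ends = index.ends[bins]
        best = 0
        for chrom, a_start, a_end, *_ in annotation:
            if chrom != region.chrom:
                continue
            contained = int(((starts >= a_start) & (ends <= a_end)).sum())
            best = max(best, contained)
        flags.append(best * 2 >= len(bins))
    return flags


@dataclass(frozen=True)
class ShuffleTestResult:
    observed_sizes: np.ndarray  # sizes of genes hit by observed regions
    shuffled_sizes: list  # one array per shuffle
    u_statistic: float
    p_value: float  # Mann-Whitney U, observed > shuffled
    empirical_p: float  # rank of observed median among shuffle medians
    defined: bool


def shuffle_overlap_test(
    regions: Sequence[BiphasicRegion],
    annotation: Sequence[tuple],
    index: BinIndex,
    n_shuffles: int = 200,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> ShuffleTestResult:
    """Are genes hit by biphasic regions larger than chance?

    Length-matched segments are placed uniformly (without overlap) over the
    unmasked genome ``n_shuffles`` times; the size distributions of
    annotation intervals overlapped by observed vs shuffled segments are
    compared by a Mann-Whitney U rank test, plus an empirical rank p of the
    observed median among shuffle medians.
    """
    if n_shuffles < 100:
        raise RepliSeqError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    observed = _hit_sizes(
        [(r.chrom, r.start, r.end) for r in regions], annotation
    )
    if len(annotation) == 0:
        return ShuffleTestResult(
            observed, [], float("nan"), float("nan"), float("nan"), defined=False
        )
    lengths = [r.end - r.start for r in regions]
    slices = index.chrom_slices()
    chrom_spans = {
        c: (int(index.starts[sl][0]), int(index.ends[sl][-1]))
        for c, sl in slices.items()
    }
    shuffled_sizes = []
    for _ in range(n_shuffles):
        placements = _place_segments(lengths, chrom_spans, rng)
        shuffled_sizes.append(_hit_sizes(placements, annotation))
    pooled = np.concatenate([s for s in shuffled_sizes if len(s)] or [np.array([])])
    if len(observed) == 0 or len(pooled) == 0:
        return ShuffleTestResult(
            observed, shuffled_sizes, float("nan"), float("nan"), float("nan"),
            defined=False,
        )
    u, p = mannwhitneyu(observed, pooled, alternative="greater")
    obs_median = np.median(observed)
    medians = np.array(
        [np.median(s) if len(s) else 0.0 for s in shuffled_sizes]
    )
    emp_p = float((1 + (medians >= obs_median).sum()) / (1 + n_shuffles))
    return ShuffleTestResult(
        observed, shuffled_sizes, float(u), float(p), emp_p, defined=True
    )


def _hit_sizes(segments, annotation) -> np.ndarray:
    sizes = []
    for chrom, a_start, a_end, *_ in annotation:
        for s_chrom, s_start, s_end in segments:
            if s_chrom == chrom and s_start < a_end and a_start < s_end:
                sizes.append(a_end - a_start)
                break
    return np.array(sizes, dtype=float)


def _place_segments(lengths, chrom_spans, rng, max_tries: int = 1000):
    """Uniform non-overlapping placement of length-matched segments."""
    chroms = list(chrom_spans)
    weights = np.array([chrom_spans[c][1] - chrom_spans[c][0] for c in chroms], float)
    weights /= weights.sum()
    placed = []
    for L in sorted(lengths, reverse=True):
        for attempt in range(max_tries):
            c = chroms[rng.choice(len(chroms), p=weights)]
            lo, hi = chrom_spans[c]
            if hi - lo < L:
                continue
            s = int(rng.integers(lo, hi - L + 1))
            if all(
                not (pc == c and s < pe and ps < s + L) for pc, ps, pe in placed
            ):
                placed.append((c, s, s + L))
                break
        else:
            raise RepliSeqError("genome too small to place shuffled segments")
    return placed


# ---------------------------------------------------------------------------
# Allele classification


def allele_classify(
    h_allele1: Heatmap,
    h_allele2: Heatmap,
    regions: Sequence[BiphasicRegion],
    peak_min: float = 20.0,
    trough_max: float = 5.0,
    min_gap: int = 1,
    trep_gap_fractions: float = 2.0,
) -> list:
    """Label each pooled biphasic region as allele_dependent,
    allele_independent, or unresolved.

    allele_independent: both allele heatmaps are themselves biphasic over
    the region. allele_dependent: each allele is unimodal, their t_rep
    differ by >= ``trep_gap_fractions`` fraction widths, and one allele
    peak matches each pooled peak (within one fraction). Anything else is
    unresolved.
    """
    if h_allele1.index != h_allele2.index:
        raise RepliSeqError("allele heatmaps are on different bin grids")
    index = h_allele1.index
    regs1 = detect_biphasic(h_allele1, peak_min, trough_max, min_gap)
    regs2 = detect_biphasic(h_allele2, peak_min, trough_max, min_gap)
    labels = []
    for region in regions:
        bins = region_bins(region, index)
        bi1 = _any_overlap(region, regs1)
        bi2 = _any_overlap(region, regs2)
        if bi1 and bi2:
            labels.append("allele_independent")
            continue
        if bi1 or bi2:
            labels.append("unresolved")
            continue
        stats = []
        for hm in (h_allele1, h_allele2):
            sub = hm.matrix[:, bins]
            usable = sub.sum(axis=0) > 0
            if not usable.any():
                stats.append(None)
                continue
            prof = sub[:, usable].mean(axis=1)
            prof = prof / prof.sum() * 100.0
            peak = int(prof.argmax()) + 1
            cum = np.cumsum(prof)
            t50_frac = float(np.searchsorted(cum, 50.0) + 1)
            stats.append((peak, t50_frac))
        if any(s is None for s in stats):
            labels.append("unresolved")
            continue
        (p1, t1), (p2, t2) = stats
        gap_ok = abs(t1 - t2) >= trep_gap_fractions
        pe, pl = region.early_peak_fraction, region.late_peak_fraction
        match = (abs(p1 - pe) <= 1 and abs(p2 - pl) <= 1) or (
            abs(p2 - pe) <= 1 and abs(p1 - pl) <= 1
        )
        labels.append("allele_dependent" if gap_ok and match else "unresolved")
    return labels


def _any_overlap(region: BiphasicRegion, others: Sequence[BiphasicRegion]) -> bool:
    return any(
        o.chrom == region.chrom and o.start < region.end and region.start < o.end
        for o in others
    )
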