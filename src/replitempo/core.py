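"""Shared domain types for 16-fraction Repli-Seq analysis.

All genomic coordinates are 0-based half-open (BED convention). Tracks and
heatmaps are defined on a :class:`BinIndex` of fixed-width bins (50 kb by
default); the last bin of a chromosome may be shorter than ``bin_size`` and
is kept with its true end coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

N_FRACTIONS = 16
DEFAULT_BIN_SIZE = 50_000

FRACTION_NAMES = tuple(f"S{i}" for i in range(1, N_FRACTIONS + 1))

FEATURE_CLASSES = (
    "IZ",
    "TTR_left",
    "TTR_right",
    "breakage",
    "termination_small",
    "late_CTR",
)

TIMING_CLASSES = ("early", "early_mid", "late_mid", "late", "NA")

#: Sex chromosomes are excluded from all analyses by construction.
SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "chrW", "chrZ", "X", "Y"})

HEATMAP_STAGES = ("raw_log2", "clipped", "smoothed", "normalized")


class RepliSeqError(ValueError):
    """Raised on malformed inputs or violated preconditions."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise RepliSeqError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class BinIndex:
    """Ordered fixed-width genomic bins shared by every track and heatmap.

    Parameters
    ----------
    chroms : per-bin chromosome names (sorted, grouped).
    starts, ends : per-bin 0-based half-open coordinates.
    bin_size : nominal bin width in bp; every non-terminal bin has
        ``end - start == bin_size``.
    """

    chroms: tuple
    starts: np.ndarray
    ends: np.ndarray
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "chroms", tuple(self.chroms))
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if not (len(self.chroms) == len(starts) == len(ends)):
            raise RepliSeqError("BinIndex fields have unequal lengths")
        if np.any(ends <= starts):
            raise RepliSeqError("BinIndex has empty or inverted bins")
        for c in set(self.chroms):
            if c in SEX_CHROMOSOMES:
                raise RepliSeqError(f"sex chromosome {c!r} not allowed in BinIndex")
        # sorted, non-overlapping, fixed width for non-terminal bins
        prev = None
        for i, chrom in enumerate(self.chroms):
            if prev is not None and chrom == prev:
                if starts[i] < ends[i - 1]:
                    raise RepliSeqError("BinIndex bins overlap or are unsorted")
                if ends[i - 1] - starts[i - 1] != self.bin_size:
                    raise RepliSeqError(
                        "non-terminal bin width differs from bin_size at "
                        f"{chrom}:{starts[i - 1]}"
                    )
            prev = chrom

    @classmethod
    def from_chrom_sizes(
        cls, chrom_sizes: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE
    ) -> "BinIndex":
        """Tile each autosome into ``bin_size`` bins (terminal bin may be short).

        Sex chromosomes present in ``chrom_sizes`` are silently dropped.
        """
        chroms, starts, ends = [], [], []
        for chrom in sorted(chrom_sizes):
            if chrom in SEX_CHROMOSOMES:
                continue
            size = int(chrom_sizes[chrom])
            for s in range(0, size, bin_size):
                chroms.append(chrom)
                starts.append(s)
                ends.append(min(s + bin_size, size))
        if not chroms:
            raise RepliSeqError("no autosomes in chrom_sizes")
        return cls(tuple(chroms), np.array(starts), np.array(ends), bin_size)

    @property
    def n_bins(self) -> int:
        return len(self.chroms)

    def __len__(self) -> int:
        return self.n_bins

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinIndex)
            and self.bin_size == other.bin_size
            and self.chroms == other.chroms
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def __hash__(self):
        return hash((self.chroms, self.bin_size, self.starts.tobytes()))

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> slice of contiguous bin rows."""
        out = {}
        start = 0
        for i in range(1, self.n_bins + 1):
            if i == self.n_bins or self.chroms[i] != self.chroms[start]:
                out[self.chroms[start]] = slice(start, i)
                start = i
        return out

    def centres(self) -> np.ndarray:
        """Bin centre coordinates in bp."""
        return (self.starts + self.ends) / 2.0

    def bin_of(self, chrom: str, pos: int) -> int:
        """Index of the bin containing ``pos`` on ``chrom``."""
        sl = self.chrom_slices().get(chrom)
        if sl is None:
            raise RepliSeqError(f"chromosome {chrom!r} not in index")
        j = sl.start + int(np.searchsorted(self.ends[sl], pos, side="right"))
        if j >= sl.stop or self.starts[j] > pos:
            raise RepliSeqError(f"position {chrom}:{pos} outside index")
        return j


@dataclass(frozen=True)
class BinnedTrack:
    """One finite real value per bin (reads, RPM, or arbitrary signal)."""

    index: BinIndex
    values: np.ndarray

    def __post_init__(self):
        vals = _as_float_array(self.values, "BinnedTrack.values")
        object.__setattr__(self, "values", vals)
        if len(vals) != self.index.n_bins:
            raise RepliSeqError("track length does not match BinIndex")


@dataclass(frozen=True)
class FractionStack:
    """Sixteen S-phase fraction tracks (S1..S16) plus the G1 control.

    ``counts`` is a 16 x N matrix, row ``i`` holding fraction ``S{i+1}``.
    """

    index: BinIndex
    counts: np.ndarray
    g1: np.ndarray

    def __post_init__(self):
        counts = _as_float_array(self.counts, "FractionStack.counts")
        g1 = _as_float_array(self.g1, "FractionStack.g1")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "g1", g1)
        if counts.shape != (N_FRACTIONS, self.index.n_bins):
            raise RepliSeqError(
                f"counts must be {N_FRACTIONS} x {self.index.n_bins}, "
                f"got {counts.shape}"
            )
        if g1.shape != (self.index.n_bins,):
            raise RepliSeqError("g1 length does not match BinIndex")

    def fraction(self, name: str) -> BinnedTrack:
        if name == "G1":
            return BinnedTrack(self.index, self.g1)
        if name not in FRACTION_NAMES:
            raise RepliSeqError(f"unknown fraction {name!r}")
        return BinnedTrack(self.index, self.counts[FRACTION_NAMES.index(name)])


@dataclass(frozen=True)
class Heatmap:
    """16 x N fraction-by-bin matrix with a per-bin filter mask.

    ``mask[j] == True`` means bin ``j`` was filtered out (e.g. by the
    mappability/G1 filter); masked columns carry zeros and are excluded
    from all downstream computation. ``stage`` tracks processing state.
    """

    index: BinIndex
    matrix: np.ndarray
    mask: np.ndarray
    stage: str

    def __post_init__(self):
        mat = _as_float_array(self.matrix, "Heatmap.matrix")
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "mask", mask)
        if self.stage not in HEATMAP_STAGES:
            raise RepliSeqError(f"unknown heatmap stage {self.stage!r}")
        if mat.shape != (N_FRACTIONS, self.index.n_bins):
            raise RepliSeqError("heatmap matrix shape mismatch")
        if mask.shape != (self.index.n_bins,):
            raise RepliSeqError("heatmap mask shape mismatch")
        if self.stage != "raw_log2" and mat[:, ~mask].size and mat[:, ~mask].min() < 0:
            raise RepliSeqError(f"negative entries in stage {self.stage!r}")

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def with_(self, **kw) -> "Heatmap":
        return replace(self, **kw)


@dataclass(frozen=True)
class FeatureCall:
    """A labelled, bin-aligned genomic interval of one replication feature."""

    chrom: str
    start: int
    end: int
    feature_class: str
    timing_class: str = "NA"
    peak_fraction: int | None = None

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise RepliSeqError(f"unknown feature class {self.feature_class!r}")
        if self.timing_class not in TIMING_CLASSES:
            raise RepliSeqError(f"unknown timing class {self.timing_class!r}")
        if self.end <= self.start:
            raise RepliSeqError("empty feature interval")
        if self.timing_class != "NA" and self.feature_class != "IZ":
            raise RepliSeqError("timing_class is only defined for IZs")

    def n_bins(self, bin_size: int = DEFAULT_BIN_SIZE) -> int:
        return max(1, round((self.end - self.start) / bin_size))


@dataclass(frozen=True)
class KineticsRecord:
    """Per-bin logistic replication-kinetics fit.

    ``t_rep`` is the midpoint (50 %-replicated) time in hours into S phase,
    ``t_width`` the 25->75 % time spread in hours, ``k`` the logistic rate
    (per hour); ``t_width == 2 ln 3 / k`` by the algebraic identity of the
    logistic. ``rmse`` is in percentage points of cumulative replication.
    """

    bin: int
    t_rep: float
    t_width: float
    k: float
    rmse: float
    flagged: bool = False

    def __post_init__(self):
        if not self.flagged:
            if self.t_width < 0:
                raise RepliSeqError("t_width must be non-negative")
            expected = 2.0 * np.log(3.0) / self.k
            if abs(self.t_width - expected) > 1e-9 * max(1.0, abs(expected)):
                raise RepliSeqError("t_width inconsistent with 2 ln3 / k")


def features_to_label_array(
    features: Sequence[FeatureCall], index: BinIndex
) -> np.ndarray:
    """Per-bin feature label ('unlabelled' where no call covers the bin).

    Raises if two calls claim the same bin.
    """
    labels = np.full(index.n_bins, "unlabelled", dtype=object)
    for f in features:
        i0 = index.bin_of(f.chrom, f.start)
        i1 = index.bin_of(f.chrom, f.end - 1)
        seg = labels[i0 : i1 + 1]
        if np.any(seg != "unlabelled"):
            raise RepliSeqError(
                f"overlapping feature calls at {f.chrom}:{f.start}-{f.end}"
            )
        labels[i0 : i1 + 1] = f.feature_class
    return labels
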