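"""Forward simulator of the replication programme.

A population of cells replicates a binned genome from a set of origins:
each origin fires per cell with its efficiency, at a time drawn from a
Normal(mean, sd) clipped to [0, S]; bidirectional forks move at constant
speed; the replication time of a position is the minimum over fired
origins of (firing time + distance / speed), so passive replication
emerges from the minimum. Cells with no fired origin on a chromosome
redraw until at least one fires (chromosomes must finish replicating).
FACS sorting is emulated by slicing S phase into 16 equal windows and
counting, per bin and window, the cells that replicate the bin there;
sequencing is Poisson noise around that occupancy scaled by read depth and
a per-bin mappability multiplier, and the G1 control is Poisson around
depth x mappability. Loci can be made biphasic by drawing the local
origin's firing time from a two-mode mixture, tied to a fixed allele
(allele-dependent asynchrony) or to a per-cell coin flip
(allele-independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (
    DEFAULT_BIN_SIZE,
    N_FRACTIONS,
    BinIndex,
    FractionStack,
    RepliSeqError,
)


@dataclass(frozen=True)
class OriginSpec:
    """One replication origin (or sub-50-kb origin cluster)."""

    chrom: str
    position: int  # bp
    mean_time: float  # minutes into S
    sd_time: float = 0.0  # minutes
    efficiency: float = 1.0  # firing probability per cell

    def __post_init__(self):
        if self.sd_time < 0:
            raise RepliSeqError("sd_time must be >= 0")
        if not (0 < self.efficiency <= 1):
            raise RepliSeqError("efficiency must be in (0, 1]")


@dataclass(frozen=True)
class BimodalLocus:
    """Interval whose origin fires from a two-mode firing-time mixture."""

    chrom: str
    start: int
    end: int
    mode2_time: float  # minutes
    weight: float = 0.5  # share of cells using mode 2
    allele_linked: bool = False


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated experiment."""

    chrom_sizes: dict
    origins: tuple
    fork_speed: float = 1.8  # kb/min
    s_duration: float = 600.0  # minutes (10-h S phase)
    n_cells: int = 1000
    read_depth: float = 200.0  # expected reads per bin summed over fractions
    g1_depth: float = 200.0
    background: float = 0.0  # expected non-specific reads per bin per fraction
    mappability: np.ndarray | None = None
    bimodal_loci: tuple = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "origins", tuple(self.origins))
        object.__setattr__(self, "bimodal_loci", tuple(self.bimodal_loci))
        if self.fork_speed <= 0:
            raise RepliSeqError("fork_speed must be > 0")
        if self.n_cells < 1:
            raise RepliSeqError("n_cells must be >= 1")
        for chrom in {o.chrom for o in self.origins}:
            if chrom not in self.chrom_sizes:
                raise RepliSeqError(f"origin on unknown chromosome {chrom!r}")
        for chrom in self.chrom_sizes:
            if not any(o.chrom == chrom for o in self.origins):
                raise RepliSeqError(f"chromosome {chrom!r} has no origin")
        for o in self.origins:
            if not (0 <= o.mean_time <= self.s_duration):
                raise RepliSeqError("origin mean_time outside S phase")

    def bin_index(self, bin_size: int = DEFAULT_BIN_SIZE) -> BinIndex:
        return BinIndex.from_chrom_sizes(self.chrom_sizes, bin_size)

    def mappability_for(self, index: BinIndex) -> np.ndarray:
        if self.mappability is None:
            return np.ones(index.n_bins)
        m = np.asarray(self.mappability, dtype=float)
        if m.shape != (index.n_bins,):
            raise RepliSeqError("mappability length does not match BinIndex")
        if m.min() < 0 or m.max() > 1:
            raise RepliSeqError("mappability must lie in [0, 1]")
        return m


@dataclass(frozen=True)
class SimResult:
    """Per-cell, per-bin replication times (minutes; inf = never within S)."""

    times: np.ndarray  # (n_cells, n_bins)
    alleles: np.ndarray  # (n_cells,), 0 or 1


@dataclass(frozen=True)
class TruthSet:
    """Machine-readable ground truth for one simulated experiment."""

    origin_bins: np.ndarray
    iz_intervals: list  # (chrom, start, end) around origin clusters
    ttr_spans: list  # (chrom, start_bin, end_bin) strictly monotone runs
    termination_bins: np.ndarray
    t_deterministic: np.ndarray  # per-bin noiseless replication time (min)
    quantiles: np.ndarray | None  # (4, n_bins): mean, q25, q50, q75 (min)
    bimodal_labels: list  # (chrom, start, end, allele_linked)


def simulate_replication_times(
    config: SimConfig, index: BinIndex, rng: np.random.Generator | None = None
) -> SimResult:
    """Draw per-cell replication times for every bin centre."""
    rng = rng or np.random.default_rng(config.seed)
    n_cells = config.n_cells
    alleles = np.arange(n_cells) % 2
    centres = index.centres()
    times = np.full((n_cells, index.n_bins), np.inf)
    slices = index.chrom_slices()
    v = config.fork_speed  # kb/min
    reach_bp = config.s_duration * v * 1000.0
    for chrom, sl in slices.items():
        origins = [o for o in config.origins if o.chrom == chrom]
        t_fire = np.empty((n_cells, len(origins)))
        for k, o in enumerate(origins):
            mean = np.full(n_cells, o.mean_time)
            locus = _bimodal_for(config, o)
            if locus is not None:
                if locus.allele_linked:
                    mode2 = alleles == 1
                else:
                    mode2 = rng.random(n_cells) < locus.weight
                mean = np.where(mode2, locus.mode2_time, mean)
            t_fire[:, k] = np.clip(
                rng.normal(mean, o.sd_time), 0.0, config.s_duration
            )
        fired = rng.random((n_cells, len(origins))) < np.array(
            [o.efficiency for o in origins]
        )
        # every chromosome must finish: redraw firing for origin-less cells
        while True:
            lacking = np.flatnonzero(~fired.any(axis=1))
            if len(lacking) == 0:
                break
            fired[lacking] = rng.random((len(lacking), len(origins))) < np.array(
                [o.efficiency for o in origins]
            )
        t_eff = np.where(fired, t_fire, np.inf)
        for k, o in enumerate(origins):
            near = np.flatnonzero(
                np.abs(centres[sl] - o.position) <= reach_bp
            )
            if len(near) == 0:
                continue
            cols = sl.start + near
            travel = np.abs(centres[cols] - o.position) / 1000.0 / v
            cand = t_eff[:, k, None] + travel[None, :]
            times[:, cols] = np.minimum(times[:, cols], cand)
    return SimResult(times, alleles)


def _bimodal_for(config: SimConfig, origin: OriginSpec):
    for locus in config.bimodal_loci:
        if (
            locus.chrom == origin.chrom
            and locus.start <= origin.position < locus.end
        ):
            return locus
    return None


def fractionate(
    result: SimResult,
    config: SimConfig,
    index: BinIndex,
    rng: np.random.Generator | None = None,
    cells: np.ndarray | None = None,
    noiseless: bool = False,
) -> FractionStack:
    """FACS-slice replication times into 16 windows and sequence them.

    ``cells`` optionally restricts to a boolean subset (e.g. one allele).
    ``noiseless`` returns the expected read mass instead of Poisson draws
    (the infinite-depth limit up to scale).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    times = result.times if cells is None else result.times[cells]
    n_sel = times.shape[0]
    if n_sel == 0:
        raise RepliSeqError("no cells selected")
    window = config.s_duration / N_FRACTIONS
    occ = np.zeros((N_FRACTIONS, index.n_bins))
    in_s = times < config.s_duration + 1e-9
    f_idx = np.minimum(
        (times[in_s] / window).astype(int), N_FRACTIONS - 1
    )
    bin_idx = np.broadcast_to(np.arange(index.n_bins), times.shape)[in_s]
    np.add.at(occ, (f_idx, bin_idx), 1.0)
    occ /= n_sel
    mapp = config.mappability_for(index)
    expected = config.read_depth * mapp[None, :] * occ + config.background
    g1_expected = config.g1_depth * mapp
    if noiseless:
        return FractionStack(index, expected, g1_expected)
    return FractionStack(
        index,
        rng.poisson(expected).astype(float),
        rng.poisson(g1_expected).astype(float),
    )


def make_truth(
    config: SimConfig,
    index: BinIndex,
    n_mc: int = 10_000,
    with_quantiles: bool = True,
) -> TruthSet:
    """Ground truth: origin bins, expected IZ/TTR/termination geometry from
    the deterministic (mean-time, all-fire) limit, and per-bin replication
    time quantiles (closed form when all sd are zero, else Monte Carlo)."""
    centres = index.centres()
    slices = index.chrom_slices()
    v = config.fork_speed
    t_det = np.full(index.n_bins, np.inf)
    origin_bins = []
    for o in config.origins:
        origin_bins.append(index.bin_of(o.chrom, o.position))
        sl = slices[o.chrom]
        travel = np.abs(centres[sl] - o.position) / 1000.0 / v
        np.minimum(t_det[sl], o.mean_time + travel, out=t_det[sl])
    origin_bins = np.array(sorted(set(origin_bins)))

    iz_intervals = []
    for chrom, sl in slices.items():
        obs = sorted(
            index.bin_of(o.chrom, o.position)
            for o in config.origins
            if o.chrom == chrom
        )
        merged = []
        for b in obs:
            lo = max(b - 1, sl.start)
            hi = min(b + 1, sl.stop - 1)
            if merged and lo <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], hi)
            else:
                merged.append((lo, hi))
        for lo, hi in merged:
            iz_intervals.append(
                (chrom, int(index.starts[lo]), int(index.ends[hi]))
            )

    ttr_spans = []
    term_bins = []
    for chrom, sl in slices.items():
        t = t_det[sl]
        n = len(t)
        d = np.sign(np.diff(t))
        # strictly monotone maximal runs
        i = 0
        while i < n - 1:
            if d[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < n - 1 and d[j + 1] == d[i]:
                j += 1
            ttr_spans.append((chrom, sl.start + i, sl.start + j + 1))
            i = j + 1
        for b in range(n):
            left_lower = b == 0 or t[b - 1] < t[b]
            right_lower = b == n - 1 or t[b + 1] < t[b]
            if left_lower and right_lower and not (b == 0 and b == n - 1):
                term_bins.append(sl.start + b)

    quantiles = None
    if with_quantiles:
        deterministic = all(o.sd_time == 0 for o in config.origins) and all(
            o.efficiency == 1 for o in config.origins
        ) and not config.bimodal_loci
        if deterministic:
            quantiles = np.vstack([t_det] * 4)
        else:
            mc_cfg = replace(config, n_cells=n_mc)
            res = simulate_replication_times(
                mc_cfg, index, np.random.default_rng(config.seed + 977)
            )
            finite = np.where(np.isfinite(res.times), res.times, np.nan)
            with np.errstate(invalid="ignore"):
                quantiles = np.vstack(
                    [
                        np.nanmean(finite, axis=0),
                        np.nanpercentile(finite, 25, axis=0),
                        np.nanpercentile(finite, 50, axis=0),
                        np.nanpercentile(finite, 75, axis=0),
                    ]
                )

    return TruthSet(
        origin_bins=origin_bins,
        iz_intervals=iz_intervals,
        ttr_spans=ttr_spans,
        termination_bins=np.array(term_bins),
        t_deterministic=t_det,
        quantiles=quantiles,
        bimodal_labels=[
            (l.chrom, l.start, l.end, l.allele_linked) for l in config.bimodal_loci
        ],
    )


def iz_recall_precision(
    called_izs: Sequence, truth: TruthSet, index: BinIndex, tol_bins: int = 1
) -> tuple:
    """(recall, precision) of called IZs against true origin bins.

    An origin is recalled if a called IZ comes within ``tol_bins`` bins of
    it; a call is a true positive if it comes within ``tol_bins`` bins of
    some origin.
    """
    call_spans = []
    for f in called_izs:
        if f.feature_class != "IZ":
            continue
        i0 = index.bin_of(f.chrom, f.start)
        i1 = index.bin_of(f.chrom, f.end - 1)
        call_spans.append((i0, i1))
    if not call_spans or len(truth.origin_bins) == 0:
        return 0.0, 0.0
    recalled = sum(
        any(i0 - tol_bins <= b <= i1 + tol_bins for i0, i1 in call_spans)
        for b in truth.origin_bins
    )
    true_pos = sum(
        any(i0 - tol_bins <= b <= i1 + tol_bins for b in truth.origin_bins)
        for i0, i1 in call_spans
    )
    return recalled / len(truth.origin_bins), true_pos / len(call_spans)


# ---------------------------------------------------------------------------
# Canned scenarios

SCENARIOS = (
    "well_separated_izs",
    "pure_ttr",
    "breakage_in_ttr",
    "late_ctr_tandem",
    "biphasic_allelic",
    "biphasic_random",
    "edge_noise",
)

_B = DEFAULT_BIN_SIZE


def _bin_centre(b: int) -> int:
    return b * _B + _B // 2


def scenario_library(name: str, seed: int | None = None) -> SimConfig:
    """Parameterised canned scenarios with fixed default seeds.

    The parameter choices are the simulator's stated study conditions;
    see docs/methods.md for the reasoning behind each.
    """
    if name == "well_separated_izs":
        # 20 origins, 16-bin (800 kb) spacing, firing times zig-zagging
        # through S so every neighbouring pair differs by exactly 120 min
        # (>= 2 fraction widths) and terminations fall mid-gap; a 2-bin
        # mappability hole away from any origin exercises the mask path.
        times = [60.0, 180.0, 300.0, 420.0, 300.0, 180.0]
        origins = tuple(
            OriginSpec("chr1", _bin_centre(8 + 16 * k), times[k % 6], 15.0, 1.0)
            for k in range(20)
        )
        mapp = np.ones(320)
        mapp[100:102] = 0.05
        return SimConfig(
            chrom_sizes={"chr1": 320 * _B},
            origins=origins,
            mappability=mapp,
            seed=11 if seed is None else seed,
        )
    if name == "pure_ttr":
        # one edge origin per 1-Mb chromosome: a single uni-directional
        # fork traverses the remaining 19 bins within the 10-h S phase
        # (reaching ~S15); a tiny very-late chromosome keeps S16 populated
        # genome-wide so the per-fraction RPM step stays well defined
        origins = tuple(
            OriginSpec(f"chr{c + 1}", _bin_centre(0), 20.0, 5.0, 1.0)
            for c in range(6)
        ) + (OriginSpec("chr7", _bin_centre(0), 555.0, 10.0, 1.0),)
        sizes = {f"chr{c + 1}": 20 * _B for c in range(6)}
        sizes["chr7"] = 4 * _B
        return SimConfig(
            chrom_sizes=sizes,
            origins=origins,
            seed=12 if seed is None else seed,
        )
    if name == "breakage_in_ttr":
        # weak (30 %-efficiency) origin mid-slope: a small inefficient IZ
        # that locally flattens the TTR
        origins = (
            OriginSpec("chr1", _bin_centre(2), 30.0, 5.0, 1.0),
            OriginSpec("chr1", _bin_centre(12), 230.0, 10.0, 0.3),
        )
        return SimConfig(
            chrom_sizes={"chr1": 22 * _B},
            origins=origins,
            seed=13 if seed is None else seed,
        )
    if name == "late_ctr_tandem":
        # many near-synchronous late origins in tandem between two early
        # flanking origins -> a broad late plateau (late CTR)
        origins = (
            OriginSpec("chr1", _bin_centre(2), 60.0, 10.0, 1.0),
            OriginSpec("chr1", _bin_centre(57), 60.0, 10.0, 1.0),
        ) + tuple(
            OriginSpec("chr1", _bin_centre(b), 480.0, 10.0, 0.9)
            for b in range(22, 39, 2)
        )
        return SimConfig(
            chrom_sizes={"chr1": 60 * _B},
            origins=origins,
            seed=14 if seed is None else seed,
        )
    if name in ("biphasic_allelic", "biphasic_random"):
        # chr1 carries the bimodal locus between two mid-S flanking
        # origins; chr2 is a sawtooth context whose forks sweep S phase
        # uniformly, so every fraction receives comparable genome-wide
        # signal (as in a real genome) and the per-fraction RPM scaling
        # does not skew the two modes against each other
        origins = (
            OriginSpec("chr1", _bin_centre(2), 170.0, 8.0, 1.0),
            OriginSpec("chr1", _bin_centre(38), 170.0, 8.0, 1.0),
            OriginSpec("chr1", _bin_centre(20), 125.0, 8.0, 1.0),
            OriginSpec("chr2", _bin_centre(0), 15.0, 8.0, 1.0),
            OriginSpec("chr2", _bin_centre(68), 15.0, 8.0, 1.0),
            OriginSpec("chr2", _bin_centre(135), 15.0, 8.0, 1.0),
        )
        locus = BimodalLocus(
            "chr1",
            18 * _B,
            23 * _B,
            mode2_time=425.0,
            weight=0.5,
            allele_linked=(name == "biphasic_allelic"),
        )
        return SimConfig(
            chrom_sizes={"chr1": 40 * _B, "chr2": 136 * _B},
            origins=origins,
            fork_speed=3.0,
            n_cells=2000,
            bimodal_loci=(locus,),
            seed=(15 if name == "biphasic_allelic" else 16)
            if seed is None
            else seed,
        )
    if name == "edge_noise":
        # early and late domains plus a small non-specific background floor
        origins = tuple(
            OriginSpec("chr1", _bin_centre(b), 80.0, 15.0, 1.0)
            for b in (5, 15, 25)
        ) + tuple(
            OriginSpec("chr1", _bin_centre(b), 480.0, 15.0, 1.0)
            for b in (40, 50)
        )
        return SimConfig(
            chrom_sizes={"chr1": 60 * _B},
            origins=origins,
            background=0.25,
            seed=17 if seed is None else seed,
        )
    raise RepliSeqError(f"unknown scenario {name!r}")


def run_scenario(
    name_or_config, seed: int | None = None, noiseless: bool = False
):
    """Simulate a scenario end to end.

    Returns a dict with the SimConfig, BinIndex, SimResult, pooled
    FractionStack, per-allele FractionStacks (when bimodal loci exist) and
    the TruthSet.
    """
    config = (
        scenario_library(name_or_config, seed)
        if isinstance(name_or_config, str)
        else name_or_config
    )
    if seed is not None and not isinstance(name_or_config, str):
        config = replace(config, seed=seed)
    index = config.bin_index()
    rng = np.random.default_rng(config.seed)
    result = simulate_replication_times(config, index, rng)
    stack = fractionate(result, config, index, rng, noiseless=noiseless)
    allele_stacks = None
    if config.bimodal_loci:
        allele_stacks = tuple(
            fractionate(
                result, config, index, rng, cells=result.alleles == a,
                noiseless=noiseless,
            )
            for a in (0, 1)
        )
    truth = make_truth(config, index, with_quantiles=False)
    return {
        "config": config,
        "index": index,
        "result": result,
        "stack": stack,
        "allele_stacks": allele_stacks,
        "truth": truth,
    }
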