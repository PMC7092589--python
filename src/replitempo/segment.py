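"""Clustering-based segmentation of the replication-timing landscape.

Bins (16-value normalised columns) are clustered with BIRCH; cluster
centroids are ranked temporally (earliest = rank 1); the per-bin rank
profile is then interpreted by run-length rules into the five replication
features:

* **IZ** — a same-rank run flanked on both sides by later (higher-rank)
  bins: replication starts here before its surroundings.
* **TTR_right / TTR_left** — a maximal monotone stretch of single-bin rank
  steps: a uni-directional fork moving right (ranks increasing) or left.
* **breakage** — a same-rank plateau inside a monotone stretch (earlier on
  one side, later on the other): a small/inefficient initiation zone that
  locally flattens a TTR.
* **termination_small** — a 1-2 bin run flanked by earlier bins on both
  sides (<= 100 kb at 50-kb bins): opposing forks fuse here.
* **late_CTR** — the same flanking pattern over > 2 bins: a large late
  plateau that must contain internal origins.

Rank-interpretation conventions (where the flanking rules alone are
ambiguous): plateau rules (IZ / termination / late CTR) take priority and
are evaluated per run first; the remaining runs — earlier on one flank and
later on the other — form "slope" chains that are automatically monotone.
A chain is labelled only if it spans at least ``min_ttr_bins`` bins in
total (breakages included); single-bin runs at a chain boundary at the
very start/end of a contiguous segment join the chain, while every other
run that touches a segment end stays unlabelled (no flank is invented).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering, Birch

from .core import (
    DEFAULT_BIN_SIZE,
    N_FRACTIONS,
    BinIndex,
    BinnedTrack,
    FeatureCall,
    Heatmap,
    RepliSeqError,
)

MASKED_RANK = -1


@dataclass(frozen=True)
class CentroidModel:
    """BIRCH clustering of bin profiles with a temporal centroid ranking.

    ``rank_of_cluster`` maps cluster id -> rank (1 = earliest); ``bin_rank``
    holds the rank of each bin's cluster (MASKED_RANK for filtered bins).
    ``cf_params`` records the CF-tree stage (threshold, branching factor).
    """

    n_clusters: int
    centroids: np.ndarray
    labels: np.ndarray
    cf_params: tuple
    seed: int
    rank_of_cluster: np.ndarray | None = None
    bin_rank: np.ndarray | None = None

    def __post_init__(self):
        if self.centroids.shape != (self.n_clusters, N_FRACTIONS):
            raise RepliSeqError("centroid matrix shape mismatch")
        if self.centroids.size and self.centroids.min() < 0:
            raise RepliSeqError("centroid rows must be non-negative")
        if self.rank_of_cluster is not None:
            if sorted(self.rank_of_cluster) != list(range(1, self.n_clusters + 1)):
                raise RepliSeqError("ranks must be a permutation of 1..n_clusters")


@dataclass(frozen=True)
class RankProfile:
    """Per-bin temporal rank (MASKED_RANK where the bin is filtered out)."""

    index: BinIndex
    rank: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rank", np.asarray(self.rank, dtype=int))
        if self.rank.shape != (self.index.n_bins,):
            raise RepliSeqError("rank profile length mismatch")


def cluster_profiles(
    heatmap: Heatmap,
    n_clusters: int = 50,
    seed: int = 0,
    cf_threshold: float = 0.5,
    branching_factor: int = 50,
) -> CentroidModel:
    """Assign every unmasked bin profile to one of ``n_clusters`` centroids.

    A CF-tree (BIRCH: subclusters summarised by (N, LS, SS) triples) is
    built first; its subcluster centroids are then globally agglomerated to
    the requested cluster count, and each bin inherits the cluster of its
    subcluster. Deterministic for fixed input; ``seed`` is recorded for
    provenance. If the CF stage yields fewer subclusters than requested the
    cluster count is capped rather than failing.
    """
    if n_clusters < 2:
        raise RepliSeqError("n_clusters must be >= 2")
    if heatmap.stage != "normalized":
        raise RepliSeqError("cluster_profiles requires a normalized heatmap")
    cols = np.flatnonzero(heatmap.unmasked)
    if len(cols) < n_clusters:
        raise RepliSeqError(
            f"{len(cols)} unmasked columns < n_clusters={n_clusters}"
        )
    X = heatmap.matrix[:, cols].T
    birch = Birch(
        threshold=cf_threshold, branching_factor=branching_factor, n_clusters=None
    ).fit(X)
    sub_centers = birch.subcluster_centers_
    sub_of_point = birch.predict(X)
    k = int(min(n_clusters, len(sub_centers)))
    if k < len(sub_centers):
        agg = AgglomerativeClustering(n_clusters=k).fit(sub_centers)
        cluster_of_sub = agg.labels_
    else:
        cluster_of_sub = np.arange(len(sub_centers))
    point_labels = cluster_of_sub[sub_of_point]
    # relabel to the set of clusters that actually received points
    used = np.unique(point_labels)
    remap = {old: new for new, old in enumerate(used)}
    point_labels = np.array([remap[l] for l in point_labels])
    k = len(used)
    centroids = np.vstack(
        [X[point_labels == c].mean(axis=0) for c in range(k)]
    )
    labels = np.full(heatmap.index.n_bins, MASKED_RANK, dtype=int)
    labels[cols] = point_labels
    return CentroidModel(
        n_clusters=k,
        centroids=np.maximum(centroids, 0.0),
        labels=labels,
        cf_params=(cf_threshold, branching_factor),
        seed=seed,
    )


def rank_centroids(model: CentroidModel) -> CentroidModel:
    """Rank centroids temporally: primary key = fraction of maximum
    replication (ascending, early first); secondary = peak magnitude
    (descending — a sharper peak means more synchronous, hence earlier
    among ties). Stable and idempotent."""
    argmaxes = model.centroids.argmax(axis=1)
    peaks = model.centroids.max(axis=1)
    order = np.lexsort((-peaks, argmaxes))
    rank_of_cluster = np.empty(model.n_clusters, dtype=int)
    rank_of_cluster[order] = np.arange(1, model.n_clusters + 1)
    bin_rank = np.where(
        model.labels == MASKED_RANK, MASKED_RANK, rank_of_cluster[model.labels]
    )
    return replace(model, rank_of_cluster=rank_of_cluster, bin_rank=bin_rank)


def rank_profile(model: CentroidModel, index: BinIndex) -> RankProfile:
    if model.bin_rank is None:
        model = rank_centroids(model)
    return RankProfile(index, model.bin_rank)


# ---------------------------------------------------------------------------
# Rank-profile interpretation


def _rle(seq: np.ndarray):
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            runs.append((int(seq[start]), start, i - start))
            start = i
    return runs


def label_rank_segment(ranks: Sequence[int], min_ttr_bins: int = 3) -> np.ndarray:
    """Label one contiguous unmasked rank sequence bin-by-bin.

    Returns an object array over {IZ, TTR_left, TTR_right, breakage,
    termination_small, late_CTR, unlabelled}. See the module docstring for
    the conventions.
    """
    r = np.asarray(ranks, dtype=int)
    labels = np.full(len(r), "unlabelled", dtype=object)
    runs = _rle(r)
    m = len(runs)
    roles = []
    for i, (v, s, L) in enumerate(runs):
        p = runs[i - 1][0] if i > 0 else None
        q = runs[i + 1][0] if i < m - 1 else None
        if p is None or q is None:
            roles.append("terminal")
        elif p > v and q > v:
            roles.append("IZ")
        elif p < v and q < v:
            roles.append("TERM")
        else:
            roles.append("slope")
    for role, (v, s, L) in zip(roles, runs):
        if role == "IZ":
            labels[s : s + L] = "IZ"
        elif role == "TERM":
            labels[s : s + L] = "termination_small" if L <= 2 else "late_CTR"
    i = 0
    while i < m:
        if roles[i] != "slope":
            i += 1
            continue
        j = i
        while j + 1 < m and roles[j + 1] == "slope":
            j += 1
        chain = list(range(i, j + 1))
        # single-bin terminal runs adjoining the chain at the segment
        # boundary continue the slope (their value set the slope's flank)
        if chain[0] - 1 == 0 and roles[0] == "terminal" and runs[0][2] == 1:
            chain.insert(0, 0)
        if chain[-1] + 1 == m - 1 and roles[m - 1] == "terminal" and runs[m - 1][2] == 1:
            chain.append(m - 1)
        span = sum(runs[c][2] for c in chain)
        if span >= min_ttr_bins:
            upward = runs[chain[0]][0] < runs[chain[-1]][0]
            ttr = "TTR_right" if upward else "TTR_left"
            for c in chain:
                v, s, L = runs[c]
                labels[s : s + L] = ttr if L == 1 else "breakage"
        i = j + 1
    return labels


def label_profile(profile: RankProfile, min_ttr_bins: int = 3) -> np.ndarray:
    """Per-bin labels over the whole genome; masked bins labelled 'masked'
    and splitting chromosomes into independent segments."""
    labels = np.full(profile.index.n_bins, "masked", dtype=object)
    for sl in profile.index.chrom_slices().values():
        ranks = profile.rank[sl]
        ok = ranks != MASKED_RANK
        start = None
        for i in range(len(ranks) + 1):
            if i < len(ranks) and ok[i]:
                if start is None:
                    start = i
            elif start is not None:
                seg = label_rank_segment(ranks[start:i], min_ttr_bins)
                labels[sl.start + start : sl.start + i] = seg
                start = None
    return labels


def call_features(
    profile: RankProfile, min_ttr_bins: int = 3
) -> list:
    """Interpret a rank profile into FeatureCalls.

    Every unmasked bin receives at most one feature; bins in runs whose
    classification would require a flank beyond a segment end, and slope
    chains shorter than ``min_ttr_bins``, stay uncalled.
    """
    labels = label_profile(profile, min_ttr_bins)
    index = profile.index
    calls = []
    for chrom, sl in index.chrom_slices().items():
        seg = labels[sl]
        start = 0
        for i in range(1, len(seg) + 1):
            if i == len(seg) or seg[i] != seg[start]:
                name = seg[start]
                if name not in ("unlabelled", "masked"):
                    calls.append(
                        FeatureCall(
                            chrom,
                            int(index.starts[sl.start + start]),
                            int(index.ends[sl.start + i - 1]),
                            name,
                        )
                    )
                start = i
    return calls


# ---------------------------------------------------------------------------
# Feature annotation and summaries

_TIMING_WINDOWS = (("early", 1, 3), ("early_mid", 4, 6), ("late_mid", 7, 9))


def classify_iz_timing(
    features: Sequence[FeatureCall], heatmap: Heatmap
) -> list:
    """Assign each IZ its peak fraction and timing class.

    peak = argmax of the IZ's mean column profile; classes: early (S1-3),
    early-mid (S4-6), late-mid (S7-9), late (S10 and beyond — the S13-16
    tail folds into 'late'). Non-IZ features pass through untouched.
    """
    out = []
    for f in features:
        if f.feature_class != "IZ":
            out.append(f)
            continue
        i0 = heatmap.index.bin_of(f.chrom, f.start)
        i1 = heatmap.index.bin_of(f.chrom, f.end - 1)
        prof = heatmap.matrix[:, i0 : i1 + 1].mean(axis=1)
        peak = int(prof.argmax()) + 1
        timing = "late"
        for name, lo, hi in _TIMING_WINDOWS:
            if lo <= peak <= hi:
                timing = name
                break
        out.append(replace(f, timing_class=timing, peak_fraction=peak))
    return out


def genome_fraction_summary(
    features: Sequence[FeatureCall], index: BinIndex, mask: np.ndarray | None = None
) -> dict:
    """Fraction of the unmasked genome covered by each feature class.

    Features must be disjoint; classes with no calls report 0. The sum over
    classes equals labelled bins / unmasked bins (<= 1).
    """
    from .core import FEATURE_CLASSES, features_to_label_array

    labels = features_to_label_array(features, index)  # raises on overlap
    if mask is None:
        mask = np.zeros(index.n_bins, dtype=bool)
    ok = ~np.asarray(mask, dtype=bool)
    denom = int(ok.sum())
    if denom == 0:
        raise RepliSeqError("no unmasked bins")
    return {
        cls: float((labels[ok] == cls).sum()) / denom for cls in FEATURE_CLASSES
    }


def compare_feature_sets(sets: Mapping[str, Sequence[tuple]]) -> dict:
    """UpSet-style comparison of IZ interval sets from several samples.

    Two intervals match when they share at least one bin (any bp overlap on
    the same chromosome); matches are grouped by transitive closure, and
    each group contributes one count to exactly one combination (the set of
    sample names represented in the group). Returns
    ``{frozenset(names): count}``.
    """
    if len(sets) < 2:
        raise RepliSeqError("need at least two sets to compare")
    items = []  # (chrom, start, end, set_name, node_id)
    for name, ivs in sets.items():
        for chrom, start, end, *_ in ivs:
            items.append((chrom, int(start), int(end), name))
    parent = list(range(len(items)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    order = sorted(range(len(items)), key=lambda i: (items[i][0], items[i][1]))
    active = []  # indices with running max end per chrom
    for i in order:
        chrom, start, end, _ = items[i]
        active = [j for j in active if items[j][0] == chrom and items[j][2] > start]
        for j in active:
            union(i, j)
        active.append(i)
    groups: dict = {}
    for i, (_, _, _, name) in enumerate(items):
        groups.setdefault(find(i), set()).add(name)
    counts: dict = {}
    for members in groups.values():
        key = frozenset(members)
        counts[key] = counts.get(key, 0) + 1
    return counts


def pileup_signal(
    track: BinnedTrack, features: Sequence[FeatureCall], flank: int
) -> tuple:
    """Signal matrix around feature centres.

    Row i holds the track values at offsets -flank..+flank (in bins of the
    track's index) from the centre bin of feature i; positions that fall
    off the chromosome are NaN and excluded from the column means. Returns
    ``(matrix, column_means, offsets_bp)``.
    """
    if not features:
        raise RepliSeqError("empty feature list")
    index = track.index
    if flank % index.bin_size != 0:
        raise RepliSeqError("flank must be a multiple of the bin size")
    r = flank // index.bin_size
    slices = index.chrom_slices()
    mat = np.full((len(features), 2 * r + 1), np.nan)
    for i, f in enumerate(features):
        centre = index.bin_of(f.chrom, (f.start + f.end) // 2)
        sl = slices[f.chrom]
        lo, hi = centre - r, centre + r + 1
        src_lo, src_hi = max(lo, sl.start), min(hi, sl.stop)
        mat[i, src_lo - lo : src_hi - lo] = track.values[src_lo:src_hi]
    with np.errstate(invalid="ignore"):
        means = np.nanmean(mat, axis=0)
    offsets = np.arange(-r, r + 1) * index.bin_size
    return mat, means, offsets
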