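"""Clustering, centroid ranking, and the replication-feature rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from replitempo.core import BinIndex, BinnedTrack, FeatureCall, Heatmap, RepliSeqError
from replitempo.segment import (
    MASKED_RANK,
    CentroidModel,
    RankProfile,
    call_features,
    classify_iz_timing,
    cluster_profiles,
    compare_feature_sets,
    genome_fraction_summary,
    label_profile,
    label_rank_segment,
    pileup_signal,
    rank_centroids,
)

from _feature_oracle import oracle_labels

B = 50_000


def normalized_heatmap(columns, mask=None):
    columns = np.asarray(columns, float).T
    n = columns.shape[1]
    idx = BinIndex.from_chrom_sizes({"chr1": n * B}, B)
    mask = np.zeros(n, bool) if mask is None else np.asarray(mask, bool)
    return Heatmap(idx, columns, mask, "normalized")


def template(peak, width=1.0):
    prof = np.exp(-0.5 * ((np.arange(1, 17) - peak) / width) ** 2)
    return prof / prof.sum() * 100


class TestClusterProfiles:
    def test_two_templates_agree_with_kmeans_oracle(self, rng):
        from sklearn.cluster import KMeans

        cols = []
        truth = []
        for i in range(200):
            t = i % 2
            truth.append(t)
            prof = template(2 if t == 0 else 14) + rng.normal(0, 0.5, 16)
            prof = np.clip(prof, 0, None)
            cols.append(prof / prof.sum() * 100)
        hm = normalized_heatmap(cols)
        model = cluster_profiles(hm, n_clusters=2)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(
            hm.matrix.T
        )
        # identical partition up to label swap, >= 99 % agreement
        agree = max(
            np.mean((model.labels == km)),
            np.mean((model.labels == 1 - km)),
        )
        assert agree >= 0.99

    def test_identical_columns_share_one_cluster(self):
        hm = normalized_heatmap([template(8)] * 20)
        model = cluster_profiles(hm, n_clusters=5)
        assert model.n_clusters == 1
        assert len(set(model.labels)) == 1

    def test_column_permutation_stability(self, rng):
        cols = [template(p, 1.5) + 0 for p in rng.uniform(2, 15, 40)]
        cols = [c / c.sum() * 100 for c in cols]
        hm = normalized_heatmap(cols)
        model = rank_centroids(cluster_profiles(hm, n_clusters=6))
        perm = rng.permutation(40)
        hm_p = normalized_heatmap([cols[i] for i in perm])
        model_p = rank_centroids(cluster_profiles(hm_p, n_clusters=6))
        # the bin -> ranked-centroid-profile mapping is order independent
        prof_a = model.centroids[model.labels]
        prof_b = model_p.centroids[model_p.labels]
        assert np.allclose(prof_a[perm], prof_b, atol=1e-6)

    def test_too_many_clusters_rejected(self):
        hm = normalized_heatmap([template(5)] * 4)
        with pytest.raises(RepliSeqError):
            cluster_profiles(hm, n_clusters=10)
        with pytest.raises(RepliSeqError):
            cluster_profiles(hm, n_clusters=1)


class TestRankCentroids:
    def _model(self, centroids):
        c = np.asarray(centroids, float)
        return CentroidModel(
            n_clusters=len(c),
            centroids=c,
            labels=np.arange(len(c)),
            cf_params=(0.5, 50),
            seed=0,
        )

    def test_argmax_ordering(self):
        model = self._model([template(9), template(2), template(14)])
        ranked = rank_centroids(model)
        assert list(ranked.rank_of_cluster) == [2, 1, 3]

    def test_tiebreak_sharper_peak_is_earlier(self):
        a = np.zeros(16)
        a[4] = 40.0
        b = np.zeros(16)
        b[4] = 25.0
        ranked = rank_centroids(self._model([b, a]))
        assert list(ranked.rank_of_cluster) == [2, 1]

    def test_single_centroid_gets_rank_one(self):
        ranked = rank_centroids(self._model([template(5)]))
        assert list(ranked.rank_of_cluster) == [1]

    def test_idempotent_and_label_invariant(self):
        model = self._model([template(9), template(2), template(14)])
        once = rank_centroids(model)
        twice = rank_centroids(once)
        assert np.array_equal(once.rank_of_cluster, twice.rank_of_cluster)
        # relabelling clusters leaves bin ranks unchanged
        perm = np.array([2, 0, 1])
        relabeled = CentroidModel(
            3, model.centroids[perm], np.argsort(perm)[model.labels],
            (0.5, 50), 0,
        )
        assert np.array_equal(
            rank_centroids(relabeled).bin_rank, once.bin_rank
        )


class TestFeatureRules:
    @pytest.mark.parametrize(
        "ranks, expected",
        [
            # IZ flanked by later clusters on both sides
            ([5, 3, 3, 5], ["unlabelled", "IZ", "IZ", "unlabelled"]),
            # a full monotone segment is one rightward TTR
            ([1, 2, 3, 4, 5, 6], ["TTR_right"] * 6),
            # plateau inside a slope: breakage flanked by TTR pieces
            (
                [1, 2, 3, 3, 4, 5],
                ["TTR_right", "TTR_right", "breakage", "breakage",
                 "TTR_right", "TTR_right"],
            ),
            # flanked-earlier valleys: small termination vs late CTR
            ([3, 4, 4, 3], ["unlabelled", "termination_small",
                            "termination_small", "unlabelled"]),
            ([3, 4, 4, 4, 3], ["unlabelled", "late_CTR", "late_CTR",
                               "late_CTR", "unlabelled"]),
            # leftward TTR
            ([6, 5, 4, 3, 2, 1], ["TTR_left"] * 6),
            # single-bin IZ regardless of length
            ([5, 1, 5], ["unlabelled", "IZ", "unlabelled"]),
            # short slope chains stay unlabelled
            ([5, 1, 2, 9], ["unlabelled", "IZ", "unlabelled", "unlabelled"]),
        ],
    )
    def test_hand_traced_rules(self, ranks, expected):
        assert list(label_rank_segment(ranks)) == expected

    @given(
        st.lists(st.integers(1, 10), min_size=1, max_size=50),
        st.integers(2, 4),
    )
    def test_agrees_with_brute_force_oracle(self, ranks, min_ttr):
        assert list(label_rank_segment(ranks, min_ttr)) == oracle_labels(
            ranks, min_ttr
        )

    def test_masked_bins_split_segments(self):
        idx = BinIndex.from_chrom_sizes({"chr1": 9 * B}, B)
        rank = np.array([5, 3, 3, 5, MASKED_RANK, 1, 2, 3, 4])
        labels = label_profile(RankProfile(idx, rank))
        assert list(labels[:4]) == ["unlabelled", "IZ", "IZ", "unlabelled"]
        assert labels[4] == "masked"
        assert list(labels[5:]) == ["TTR_right"] * 4

    def test_call_features_emits_bin_aligned_intervals(self):
        idx = BinIndex.from_chrom_sizes({"chr1": 6 * B}, B)
        calls = call_features(RankProfile(idx, np.array([1, 2, 3, 3, 4, 5])))
        assert [
            (c.feature_class, c.start // B, c.end // B) for c in calls
        ] == [
            ("TTR_right", 0, 2),
            ("breakage", 2, 4),
            ("TTR_right", 4, 6),
        ]

    def test_partition_every_unmasked_bin_exactly_once(self, rng):
        idx = BinIndex.from_chrom_sizes({"chr1": 50 * B}, B)
        rank = rng.integers(1, 8, 50)
        rank[rng.random(50) < 0.1] = MASKED_RANK
        profile = RankProfile(idx, rank)
        labels = label_profile(profile)
        calls = call_features(profile)
        from replitempo.core import features_to_label_array

        arr = features_to_label_array(calls, idx)  # raises on double cover
        covered = arr != "unlabelled"
        assert np.array_equal(
            covered, np.isin(labels, ["unlabelled", "masked"], invert=True)
        )


class TestIzTiming:
    @pytest.mark.parametrize("peak, timing", [(2, "early"), (7, "late_mid"),
                                              (5, "early_mid"), (13, "late")])
    def test_peak_windows(self, peak, timing):
        hm = normalized_heatmap([template(peak)] * 3)
        calls = [FeatureCall("chr1", B, 2 * B, "IZ")]
        out = classify_iz_timing(calls, hm)
        assert out[0].timing_class == timing
        assert out[0].peak_fraction == peak

    def test_non_iz_untouched(self):
        hm = normalized_heatmap([template(3)] * 3)
        calls = [FeatureCall("chr1", 0, B, "TTR_left")]
        assert classify_iz_timing(calls, hm) == calls


class TestGenomeFractions:
    def test_simple_fraction(self, small_index):
        calls = [FeatureCall("chr1", 0, 2 * B, "IZ")]
        fracs = genome_fraction_summary(calls, small_index)
        assert fracs["IZ"] == pytest.approx(0.2)
        assert fracs["late_CTR"] == 0.0

    def test_empty_is_all_zero(self, small_index):
        assert set(genome_fraction_summary([], small_index).values()) == {0.0}

    def test_conservation(self, rng, small_index):
        calls = [
            FeatureCall("chr1", 0, 2 * B, "IZ"),
            FeatureCall("chr1", 3 * B, 4 * B, "termination_small"),
            FeatureCall("chr1", 5 * B, 8 * B, "late_CTR"),
        ]
        mask = np.zeros(10, bool)
        mask[9] = True
        fracs = genome_fraction_summary(calls, small_index, mask)
        assert sum(fracs.values()) == pytest.approx(6 / 9)


class TestCompareSets:
    def test_shared_and_unique(self):
        counts = compare_feature_sets(
            {"A": [("chr1", 0, 100_000)], "B": [("chr1", 50_000, 150_000)]}
        )
        assert counts == {frozenset({"A", "B"}): 1}

    def test_disjoint_singletons(self):
        counts = compare_feature_sets(
            {"A": [("chr1", 0, B)], "B": [("chr1", 2 * B, 3 * B)]}
        )
        assert counts == {frozenset({"A"}): 1, frozenset({"B"}): 1}

    def test_three_sets_match_interval_graph_oracle(self, rng):
        import networkx as nx

        sets = {}
        items = []
        for name in "ABC":
            ivs = []
            for _ in range(15):
                s = int(rng.integers(0, 50)) * B
                w = int(rng.integers(1, 4)) * B
                ivs.append(("chr1", s, s + w))
                items.append((name, len(ivs) - 1, s, s + w))
            sets[name] = ivs
        counts = compare_feature_sets(sets)

        g = nx.Graph()
        g.add_nodes_from(range(len(items)))
        for i, (_, _, s1, e1) in enumerate(items):
            for j, (_, _, s2, e2) in enumerate(items):
                if i < j and s1 < e2 and s2 < e1:
                    g.add_edge(i, j)
        expected: dict = {}
        for comp in nx.connected_components(g):
            key = frozenset(items[i][0] for i in comp)
            expected[key] = expected.get(key, 0) + 1
        assert counts == expected


class TestPileup:
    def _track(self, values):
        idx = BinIndex.from_chrom_sizes({"chr1": len(values) * B}, B)
        return BinnedTrack(idx, np.asarray(values, float))

    def test_constant_track_flat_mean(self):
        track = self._track([3.0] * 12)
        feats = [FeatureCall("chr1", 4 * B, 6 * B, "IZ")]
        mat, means, offsets = pileup_signal(track, feats, 2 * B)
        assert np.allclose(means, 3.0)
        assert offsets[0] == -2 * B and offsets[-1] == 2 * B

    def test_spike_at_centre(self):
        vals = np.zeros(11)
        vals[5] = 9.0
        track = self._track(vals)
        feats = [FeatureCall("chr1", 5 * B, 6 * B, "IZ")]
        _, means, offsets = pileup_signal(track, feats, 3 * B)
        assert means[list(offsets).index(0)] == 9.0

    def test_matches_brute_force_per_offset_means(self, rng):
        vals = rng.uniform(0, 10, 30)
        track = self._track(vals)
        feats = [
            FeatureCall("chr1", int(s) * B, int(s + 1) * B, "termination_small")
            for s in rng.integers(0, 30, 8)
        ]
        r = 4
        mat, means, _ = pileup_signal(track, feats, r * B)
        for col, off in enumerate(range(-r, r + 1)):
            acc = []
            for f in feats:
                centre = (f.start + f.end) // 2 // B
                j = centre + off
                if 0 <= j < 30:
                    acc.append(vals[j])
            assert means[col] == pytest.approx(np.mean(acc))

    def test_empty_features_rejected(self):
        with pytest.raises(RepliSeqError):
            pileup_signal(self._track([1.0] * 5), [], B)
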