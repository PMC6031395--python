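"""Sliding windows, OTU clustering, rarefaction, and log-rank comparisons."""

import numpy as np
import pytest

from markerdiv import diversity as dv
from markerdiv._model import AMINO_ACIDS
from markerdiv.profile_hmm import AlignedFragment

AAS = list(AMINO_ACIDS)


def spanning_fragment(fid, n_gaps, width=100):
    """A fragment covering a whole window with exactly n_gaps internal gaps."""
    cols = [0] + list(range(1 + n_gaps, width))
    return AlignedFragment(fid, "g", "A" * len(cols), tuple(cols), (0, width - 1))


def window_of(seqs: dict[str, str], width=100):
    return dv.WindowSlice("g", 0, width, seqs)


def random_window(rng, n, width=100, alphabet=4):
    # low-cardinality alphabet so clusters actually form
    return window_of(
        {f"s{i:03d}": "".join(rng.choice(AAS[:alphabet], width)) for i in range(n)},
        width,
    )


class TestSliceWindow:
    def test_ten_percent_gaps_retained_eleven_discarded(self):
        win = dv.slice_window(
            [spanning_fragment("g10", 10), spanning_fragment("g11", 11)], 0, 100
        )
        assert set(win.members) == {"g10"}

    def test_fragment_outside_window_excluded(self):
        frag = AlignedFragment("f", "g", "A" * 50, tuple(range(150, 200)), (150, 199))
        win = dv.slice_window([frag], 0, 100)
        assert win.members == {}

    def test_partial_span_excluded(self):
        frag = AlignedFragment("f", "g", "A" * 60, tuple(range(30, 90)), (30, 89))
        win = dv.slice_window([frag], 0, 100)
        assert win.members == {}

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            dv.slice_window([], 0, width=0)


class TestClusterOtus:
    def test_identical_sequences_form_one_otu(self):
        win = window_of({f"s{i}": "AC" * 50 for i in range(5)})
        for cutoff in (0.7, 0.8, 0.9):
            assert dv.cluster_otus(win, cutoff).n_otus == 1

    def test_all_distant_sequences_stay_singletons(self):
        rng = np.random.default_rng(0)
        win = window_of({f"s{i}": "".join(rng.choice(AAS, 100)) for i in range(8)})
        clust = dv.cluster_otus(win, 0.70)
        assert clust.n_otus == 8

    def test_members_partition_input(self):
        rng = np.random.default_rng(1)
        win = random_window(rng, 40)
        clust = dv.cluster_otus(win, 0.5)
        members = [m for v in clust.clusters.values() for m in v]
        assert sorted(members) == sorted(win.members)

    def test_every_member_within_cutoff_of_centroid(self):
        rng = np.random.default_rng(2)
        win = random_window(rng, 40)
        clust = dv.cluster_otus(win, 0.5)
        enc = {k: np.frombuffer(v.encode(), np.uint8) for k, v in win.members.items()}
        for cid, members in clust.clusters.items():
            for m in members:
                assert dv._identity(enc[m], enc[cid]) >= 0.5

    def test_count_within_order_perturbation_envelope(self):
        # greedy clustering is order-sensitive; the default (length-sorted)
        # count must fall inside the min-max envelope over random orders
        rng = np.random.default_rng(3)
        win = random_window(rng, 30)
        observed = dv.cluster_otus(win, 0.45).n_otus
        counts = []
        ids = list(win.members)
        for _ in range(100):
            order = [ids[i] for i in rng.permutation(len(ids))]
            counts.append(dv.cluster_otus(win, 0.45, order=order).n_otus)
        assert min(counts) - 1 <= observed <= max(counts) + 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_otu_count_monotone_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        win = random_window(rng, 50)
        n70 = dv.cluster_otus(win, 0.70).n_otus
        n80 = dv.cluster_otus(win, 0.80).n_otus
        n90 = dv.cluster_otus(win, 0.90).n_otus
        assert n70 <= n80 <= n90

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            dv.cluster_otus(window_of({}), 0.0)


def small_clustering():
    return dv.OTUClustering(
        0.8,
        {"c1": ["x1", "x2", "x3"], "c2": ["y1"], "c3": ["z1", "z2"]},
        [],
    )


class TestRarefy:
    def test_full_depth_equals_total_otus_exactly(self):
        clust = small_clustering()
        curve = dv.rarefy(clust, [6], n_replicates=10, seed=0)
        assert curve.mean_otus == [3.0]

    def test_depth_one_is_one(self):
        curve = dv.rarefy(small_clustering(), [1], n_replicates=10, seed=0)
        assert curve.mean_otus == [1.0]

    def test_means_nondecreasing_in_depth(self):
        rng = np.random.default_rng(4)
        sizes = rng.integers(1, 6, size=12)
        clusters = {f"c{i}": [f"c{i}_{j}" for j in range(s)]
                    for i, s in enumerate(sizes)}
        clust = dv.OTUClustering(0.8, clusters, [])
        curve = dv.rarefy(clust, list(range(1, int(sizes.sum()) + 1)), seed=5)
        assert all(b >= a - 1e-12 for a, b in zip(curve.mean_otus, curve.mean_otus[1:]))

    def test_singleton_clusters_mean_equals_depth(self):
        clust = dv.OTUClustering(0.8, {f"c{i}": [f"c{i}"] for i in range(10)}, [])
        curve = dv.rarefy(clust, [1, 4, 7, 10], seed=6)
        assert curve.mean_otus == [1.0, 4.0, 7.0, 10.0]

    def test_depth_beyond_members_rejected(self):
        with pytest.raises(ValueError):
            dv.rarefy(small_clustering(), [7])


def hand_logrank(sizes_a, sizes_b):
    """Independent O-E/V log-rank oracle over the distinct event times."""
    times = sorted(set(sizes_a) | set(sizes_b))
    na, nb = len(sizes_a), len(sizes_b)
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        da = sizes_a.count(t)
        db = sizes_b.count(t)
        d = da + db
        n = na + nb
        if n <= 1:
            break
        o_minus_e += da - d * na / n
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
        na -= da
        nb -= db
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_clusterings_statistic_zero_p_one(self):
        c = small_clustering()
        res = dv.compare_richness_logrank(c, c)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_risk_tables(self):
        ca = dv.OTUClustering(0.8, {f"a{i}": [f"a{i}"] for i in range(3)}, [])
        cb = dv.OTUClustering(
            0.8, {f"b{i}": [f"b{i}_{j}" for j in range(3)] for i in range(3)}, []
        )
        res = dv.compare_richness_logrank(ca, cb)
        assert res.statistic == pytest.approx(hand_logrank([1, 1, 1], [3, 3, 3]))
        assert res.statistic == pytest.approx(5.0)

    def test_statistic_invariant_under_label_swap(self):
        rng = np.random.default_rng(7)
        sa = rng.integers(1, 5, 20)
        sb = rng.integers(1, 7, 15)
        ca = dv.OTUClustering(0.8, {f"a{i}": [f"a{i}_{j}" for j in range(s)]
                                    for i, s in enumerate(sa)}, [])
        cb = dv.OTUClustering(0.8, {f"b{i}": [f"b{i}_{j}" for j in range(s)]
                                    for i, s in enumerate(sb)}, [])
        r1 = dv.compare_richness_logrank(ca, cb)
        r2 = dv.compare_richness_logrank(cb, ca)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dv.compare_richness_logrank(
                small_clustering(), dv.OTUClustering(0.8, {}, [])
            )


def truthlike_fragments(rng, group, n, n_cols=300, n_templates=4):
    """Fragments over random templates, spanning random column ranges."""
    templates = ["".join(rng.choice(AAS[:5], n_cols)) for _ in range(n_templates)]
    frags = []
    for i in range(n):
        tpl = templates[rng.integers(n_templates)]
        length = int(rng.integers(150, n_cols + 1))
        start = int(rng.integers(0, n_cols - length + 1))
        frags.append(
            AlignedFragment(
                f"{group}{i:04d}", group, tpl[start:start + length],
                tuple(range(start, start + length)), (start, start + length - 1),
            )
        )
    return frags


class TestProfiles:
    def test_window_start_arithmetic(self):
        assert dv._window_starts(300, 100, 10) == list(range(0, 201, 10))
        assert len(dv._window_starts(300, 100, 10)) == 21

    def test_richness_profile_invariant_to_group_order(self):
        rng = np.random.default_rng(8)
        ga = truthlike_fragments(rng, "A", 30)
        gb = truthlike_fragments(rng, "B", 30)
        df1 = dv.richness_profile({"A": ga, "B": gb}, n_cols=300, resample_n=10, seed=1)
        df2 = dv.richness_profile({"B": gb, "A": ga}, n_cols=300, resample_n=10, seed=1)
        assert df1.equals(df2)

    def test_underfilled_windows_flagged(self):
        rng = np.random.default_rng(9)
        ga = truthlike_fragments(rng, "A", 5)
        df = dv.richness_profile({"A": ga}, n_cols=300, resample_n=100, seed=1)
        assert df["flagged"].all()
        assert df["n_otus"].isna().all()

    def test_pd_profile_identical_members_zero(self):
        frags = [
            AlignedFragment(f"f{i}", "A", "A" * 120, tuple(range(120)), (0, 119))
            for i in range(5)
        ]
        df = dv.pd_profile({"A": frags}, n_cols=120, n_subsample=5, seed=1)
        assert (df["pd"] == 0.0).all()

    def test_pd_two_blocks_equals_between_block_distance(self):
        # two clusters of identical sequences: the NJ tree is a single
        # internal edge whose length is the between-cluster distance
        sa = "A" * 120
        sb = ("A" * 110) + ("C" * 10)  # p = 10/120
        frags = [
            AlignedFragment(f"a{i}", "G", sa, tuple(range(120)), (0, 119))
            for i in range(3)
        ] + [
            AlignedFragment(f"b{i}", "G", sb, tuple(range(120)), (0, 119))
            for i in range(3)
        ]
        from markerdiv.phylo import protein_distance

        d = protein_distance(sa, sb)
        df = dv.pd_profile({"G": frags}, n_cols=120, width=120, n_subsample=6, seed=1)
        assert df["pd"].iloc[0] == pytest.approx(d, abs=1e-9)
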