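import numpy as np
import pytest
from scipy.spatial.distance import euclidean

from corecirc import (
    FragmentTrack,
    GenomicInterval,
    Peak,
    SignalMatrix,
    cluster_states,
    consensus_peaks,
    generate_state_profiles,
    region_density,
    state_matrix,
)


def peak(start, end, summit=None, signal=1.0, name="p", chrom="chr1"):
    return Peak(
        GenomicInterval(chrom, start, end),
        summit if summit is not None else (start + end) // 2,
        signal,
        name=name,
    )


class TestConsensusPeaks:
    def test_identical_peaks_in_all_lines(self):
        sets = {f"L{i}": [peak(100, 400)] for i in range(1, 5)}
        (c,) = consensus_peaks(sets, min_support=3)
        assert c.support == 4
        assert c.interval == GenomicInterval("chr1", 100, 400)

    def test_two_of_four_lines_excluded(self):
        sets = {
            "L1": [peak(100, 400)],
            "L2": [peak(150, 380)],
            "L3": [],
            "L4": [],
        }
        assert consensus_peaks(sets, min_support=3) == []

    def test_transitive_chained_overlap(self):
        sets = {
            "A": [peak(0, 100)],
            "B": [peak(80, 180)],
            "C": [peak(160, 260)],
            "D": [],
        }
        (c,) = consensus_peaks(sets, min_support=3)
        assert (c.interval.start, c.interval.end, c.support) == (0, 260, 3)

    def test_summit_from_strongest_member_ties_leftmost(self):
        sets = {
            "L1": [peak(0, 100, summit=20, signal=5.0)],
            "L2": [peak(10, 110, summit=90, signal=9.0)],
            "L3": [peak(20, 120, summit=60, signal=9.0)],
        }
        (c,) = consensus_peaks(sets, min_support=3)
        assert c.summit == 60  # among the two signal-9 members, leftmost summit

    def test_adjacent_peaks_do_not_group(self):
        # >= 1 bp overlap required; half-open adjacency is not overlap
        sets = {
            "L1": [peak(0, 100)],
            "L2": [peak(100, 200)],
            "L3": [peak(100, 200)],
        }
        assert consensus_peaks(sets, min_support=3) == []

    def test_min_support_exceeding_peaksets_rejected(self):
        with pytest.raises(ValueError):
            consensus_peaks({"L1": [peak(0, 10)]}, min_support=3)

    def test_lowering_min_support_is_monotone(self, rng):
        sets = {
            f"L{i}": [
                peak(int(s), int(s) + 200, name=f"L{i}p{j}")
                for j, s in enumerate(rng.integers(0, 5000, 15))
            ]
            for i in range(1, 5)
        }
        strict = consensus_peaks(sets, min_support=3)
        loose = consensus_peaks(sets, min_support=2)
        loose_spans = {(c.interval.start, c.interval.end) for c in loose}
        for c in strict:
            assert (c.interval.start, c.interval.end) in loose_spans
        for c in loose + strict:
            assert c.support == len({m.source or m.name[:2] for m in c.members})
            assert all(m.interval.overlaps(c.interval) for m in c.members)


class TestStateMatrix:
    def make_tracks(self, frags_by_mark):
        return {
            mark: {
                "L1": FragmentTrack(frags, total_mapped=100_000, label=f"{mark}:L1")
            }
            for mark, frags in frags_by_mark.items()
        }

    def consensus_for(self, positions):
        sets = {
            f"L{i}": [peak(p - 150, p + 150, name=f"L{i}p{p}") for p in positions]
            for i in range(1, 4)
        }
        return consensus_peaks(sets, min_support=3)

    def test_missing_clustering_mark_rejected(self):
        cons = self.consensus_for([1000])
        tracks = self.make_tracks({"H3K27ac": [], "H3K4me1": []})
        with pytest.raises(ValueError, match="H3K4me3"):
            state_matrix(cons, tracks, window=1000, bin_width=100)

    def test_zero_tracks_give_zero_matrices_and_aligned_rows(self):
        cons = self.consensus_for([1000, 5000])
        tracks = self.make_tracks({m: [] for m in ("H3K27ac", "H3K4me1", "H3K4me3")})
        mats = state_matrix(cons, tracks, window=1000, bin_width=100)
        rows = None
        for m in mats.values():
            assert np.all(m.values == 0)
            assert rows is None or m.row_ids == rows
            rows = m.row_ids

    def test_line_average_matches_density_oracle(self, rng):
        cons = self.consensus_for([2000])
        frags1 = [
            GenomicInterval("chr1", int(s), int(s) + 50)
            for s in rng.integers(1000, 3000, 100)
        ]
        frags2 = [
            GenomicInterval("chr1", int(s), int(s) + 50)
            for s in rng.integers(1500, 2500, 60)
        ]
        t1 = FragmentTrack(frags1, 100_000)
        t2 = FragmentTrack(frags2, 200_000)
        tracks = {
            "H3K27ac": {"L1": t1, "L2": t2},
            "H3K4me1": {"L1": t1},
            "H3K4me3": {"L1": t1},
        }
        mats = state_matrix(cons, tracks, window=400, bin_width=100)
        summit = cons[0].summit
        for j in range(4):
            b = GenomicInterval("chr1", summit - 200 + 100 * j, summit - 200 + 100 * (j + 1))
            expected = (region_density(t1, b) + region_density(t2, b)) / 2
            assert mats["H3K27ac"].values[0, j] == pytest.approx(expected)


def make_matrices(values_by_mark, bin_width=10):
    n, ncols = next(iter(values_by_mark.values())).shape
    return {
        mark: SignalMatrix(
            row_ids=[f"r{i}" for i in range(n)],
            bin_width=bin_width,
            window=bin_width * ncols,
            values=v,
        )
        for mark, v in values_by_mark.items()
    }


class TestClusterStates:
    def test_k1_labels_everything_one(self, rng):
        mats = make_matrices(
            {m: rng.random((5, 8)) for m in ("H3K27ac", "H3K4me1", "H3K4me3")}
        )
        labels = [s.cluster_label for s in cluster_states(mats, k=1)]
        assert labels == [1] * 5

    def test_fewer_rows_than_clusters_rejected(self, rng):
        mats = make_matrices(
            {m: rng.random((2, 4)) for m in ("H3K27ac", "H3K4me1", "H3K4me3")}
        )
        with pytest.raises(ValueError):
            cluster_states(mats, k=3)

    def test_recovers_planted_archetypes_exactly(self):
        mats, labels = generate_state_profiles(n_per_state=50, n_bins=60, seed=5)
        got = [s.cluster_label for s in cluster_states(mats, k=3)]
        assert got == list(labels)

    def test_labels_ordered_by_decreasing_h3k27ac(self):
        mats, _ = generate_state_profiles(n_per_state=20, n_bins=40, seed=2)
        states = cluster_states(mats, k=3)
        means = {}
        for s in states:
            means.setdefault(s.cluster_label, []).append(s.mark_means["H3K27ac"])
        avg = {k: np.mean(v) for k, v in means.items()}
        assert avg[1] > avg[2] > avg[3]

    def test_ward_merges_closest_pair_of_three_singletons(self):
        # points on a line: 0, 1, 5 -> Ward-D2 first merges {0,1}
        # (singleton merge cost = Euclidean distance: 1 < 4 < 5)
        vals = np.array([[0.0], [1.0], [5.0]])
        mats = make_matrices(
            {"H3K27ac": vals, "H3K4me1": np.zeros((3, 1)), "H3K4me3": np.zeros((3, 1))},
            bin_width=1,
        )
        states = cluster_states(mats, k=2, scale=False)
        labels = [s.cluster_label for s in states]
        assert labels[0] == labels[1] != labels[2]
        assert euclidean([0.0], [1.0]) < euclidean([1.0], [5.0])

    def test_partition_invariant_to_row_permutation(self, rng):
        mats, labels = generate_state_profiles(n_per_state=10, n_bins=30, seed=3)
        perm = rng.permutation(30)
        permuted = {
            m: SignalMatrix(
                row_ids=[mat.row_ids[i] for i in perm],
                bin_width=mat.bin_width,
                window=mat.window,
                values=mat.values[perm],
            )
            for m, mat in mats.items()
        }
        base = {s.peak_id: s.cluster_label for s in cluster_states(mats, k=3)}
        shuf = {s.peak_id: s.cluster_label for s in cluster_states(permuted, k=3)}
        assert base == shuf
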