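"""Average-linkage clustering, DBI/variance metrics and cluster-count choice."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from channelgauge.clustering import (
    DistanceMatrix,
    average_linkage,
    choose_k,
    cluster_trajectory,
    davies_bouldin,
    pairwise_rmsd,
    percent_variance,
    representative_frames,
)
from channelgauge.structure import SelectionSpec, Trajectory
from channelgauge.synth import make_basin_trajectory, make_ideal_helix


def naive_average_linkage(full: np.ndarray, k: int) -> np.ndarray:
    """O(n³) reference: recompute every cluster-pair mean from the original
    matrix at each step (no incremental update), same tie rule."""
    n = full.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([full[a, b] for a in clusters[i] for b in clusters[j]])
                key = (d, min(clusters[i]), min(clusters[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
        clusters.sort(key=min)
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(sorted(clusters, key=min)):
        labels[members] = lab
    return labels


def _dm(full: np.ndarray) -> DistanceMatrix:
    return DistanceMatrix(n_frames=full.shape[0], condensed=squareform(full))


class TestPairwiseRmsd:
    def test_identical_and_rigid_frames_are_zero(self, rng):
        s = make_ideal_helix(8)
        from scipy.spatial.transform import Rotation

        frames = [s.coords]
        for i in range(2):
            R = Rotation.random(random_state=np.random.RandomState(i)).as_matrix()
            frames.append(s.coords @ R.T + rng.uniform(-5, 5, 3))
        D = pairwise_rmsd(Trajectory(s, np.stack(frames)),
                          SelectionSpec.make(backbone_only=True))
        assert np.allclose(D.condensed, 0.0, atol=1e-8)

    def test_entries_match_kabsch_oracle(self, rng):
        from channelgauge.metrics import kabsch_superpose

        s = make_ideal_helix(8)
        frames = s.coords + rng.normal(0, 0.5, (6, s.n_atoms, 3))
        D = pairwise_rmsd(Trajectory(s, frames), SelectionSpec.make(backbone_only=True))
        full = D.full()
        for i in range(6):
            for j in range(i + 1, 6):
                assert full[i, j] == pytest.approx(
                    kabsch_superpose(frames[j], frames[i]).rmsd, abs=1e-10
                )


class TestAverageLinkage:
    def test_two_tight_blobs_split_exactly(self, rng):
        n = 10
        full = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < 5) == (j < 5)
                full[i, j] = full[j, i] = rng.uniform(0.1, 0.5) if same else rng.uniform(20, 25)
        labels = average_linkage(_dm(full), 2)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_k_equals_n_gives_singletons(self, rng):
        full = np.abs(rng.normal(2, 1, (6, 6)))
        full = (full + full.T) / 2
        np.fill_diagonal(full, 0)
        labels = average_linkage(_dm(full), 6)
        assert sorted(labels) == list(range(6))

    def test_k_out_of_range_rejected(self, rng):
        full = np.zeros((4, 4))
        with pytest.raises(ValueError):
            average_linkage(_dm(full), 0)
        with pytest.raises(ValueError):
            average_linkage(_dm(full), 5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 13))
        full = rng.uniform(0.1, 10.0, (n, n))
        full = (full + full.T) / 2
        np.fill_diagonal(full, 0)
        k = int(rng.integers(2, n))
        assert np.array_equal(average_linkage(_dm(full), k),
                              naive_average_linkage(full, k))

    def test_frame_reordering_permutes_labels(self, rng):
        traj, manifest = make_basin_trajectory(3, 4, seed=5)
        D = pairwise_rmsd(traj, SelectionSpec.make(atom_names=["CA"]))
        labels = average_linkage(D, 3)
        perm = rng.permutation(traj.n_frames)
        traj2 = Trajectory(traj.topology, traj.frames[perm])
        D2 = pairwise_rmsd(traj2, SelectionSpec.make(atom_names=["CA"]))
        labels2 = average_linkage(D2, 3)
        # same partition of the underlying frames
        part1 = {frozenset(np.flatnonzero(labels == c)) for c in range(3)}
        part2 = {frozenset(perm[np.flatnonzero(labels2 == c)]) for c in range(3)}
        assert part1 == part2


class TestQualityMetrics:
    def test_dbi_closed_form_two_pair_clusters(self):
        full = np.zeros((4, 4))
        full[0, 1] = full[1, 0] = 2.0
        full[2, 3] = full[3, 2] = 2.0
        for i in (0, 1):
            for j in (2, 3):
                full[i, j] = full[j, i] = 10.0
        # S = mean(0, 2) = 1 per cluster, medoid separation 10 → DBI 0.2
        assert davies_bouldin(_dm(full), np.array([0, 0, 1, 1])) == pytest.approx(0.2)

    def test_dbi_zero_for_point_clusters(self):
        full = np.zeros((4, 4))
        full[:2, 2:] = 5.0
        full[2:, :2] = 5.0
        labels = np.array([0, 0, 1, 1])
        assert davies_bouldin(_dm(full), labels) == pytest.approx(0.0)

    def test_dbi_degenerate_medoids_rejected(self):
        full = np.zeros((4, 4))  # all frames coincide
        with pytest.raises(ValueError, match="degenerate"):
            davies_bouldin(_dm(full), np.array([0, 0, 1, 1]))

    def test_dbi_matches_direct_formula(self, rng):
        n = 20
        full = rng.uniform(0.5, 8.0, (n, n))
        full = (full + full.T) / 2
        np.fill_diagonal(full, 0)
        labels = rng.integers(0, 4, n)
        labels[:4] = [0, 1, 2, 3]  # every cluster non-empty
        got = davies_bouldin(_dm(full), labels)
        # independent direct evaluation
        ks = np.unique(labels)
        med, S = {}, {}
        for c in ks:
            mem = np.flatnonzero(labels == c)
            m = mem[np.argmin([full[i, mem].mean() for i in mem])]
            med[c], S[c] = m, full[m, mem].mean()
        expect = np.mean([
            max((S[i] + S[j]) / full[med[i], med[j]] for j in ks if j != i)
            for i in ks
        ])
        assert got == pytest.approx(expect, abs=1e-10)

    def test_percent_variance_limits(self, rng):
        n = 8
        full = rng.uniform(1, 5, (n, n))
        full = (full + full.T) / 2
        np.fill_diagonal(full, 0)
        D = _dm(full)
        assert percent_variance(D, np.zeros(n, dtype=int)) == pytest.approx(0.0)
        assert percent_variance(D, np.arange(n)) == pytest.approx(1.0)

    def test_percent_variance_hand_computed(self):
        full = np.zeros((4, 4))
        full[0, 1] = full[1, 0] = 2.0
        full[2, 3] = full[3, 2] = 2.0
        for i in (0, 1):
            for j in (2, 3):
                full[i, j] = full[j, i] = 10.0
        # SST = (4+4+4·100)/4 = 102 ; SSE = 4/2 + 4/2 = 4 → SSR/SST = 98/102
        got = percent_variance(_dm(full), np.array([0, 0, 1, 1]))
        assert got == pytest.approx(98 / 102, abs=1e-12)


class TestChooseK:
    def test_featureless_metrics_report_no_plateau(self):
        ks = range(2, 8)
        dbi = {k: 5.0 - 0.5 * k for k in ks}          # monotone decreasing
        ssr = {k: 0.1 * k for k in ks}                # constant large gains
        choice = choose_k(dbi, ssr)
        assert choice.rule == "no_plateau"
        assert choice.chosen_k == 7  # best (lowest) DBI

    @pytest.mark.parametrize("c", [3, 5])
    def test_recovers_basin_count(self, c):
        hits = 0
        for seed in range(20):
            traj, _ = make_basin_trajectory(c, 5, seed=seed)
            result = cluster_trajectory(
                traj, SelectionSpec.make(atom_names=["CA"]),
                k_scan=range(2, 9), stride=1,
            )
            hits += result.chosen_k == c
        assert hits >= 18  # ≥ 90 % of seeded runs


class TestRepresentatives:
    def test_singleton_represents_itself(self):
        full = np.array([[0.0, 5.0], [5.0, 0.0]])
        reps = representative_frames(_dm(full), np.array([0, 1]))
        assert reps == {0: 0, 1: 1}

    def test_symmetric_cluster_tie_goes_to_smallest_index(self):
        full = np.full((3, 3), 2.0)
        np.fill_diagonal(full, 0)
        reps = representative_frames(_dm(full), np.zeros(3, dtype=int))
        assert reps[0] == 0

    def test_known_medoid_found(self):
        # frame 1 is closest on average to its co-members
        full = np.array([
            [0.0, 1.0, 3.0],
            [1.0, 0.0, 1.0],
            [3.0, 1.0, 0.0],
        ])
        reps = representative_frames(_dm(full), np.zeros(3, dtype=int))
        assert reps[0] == 1
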