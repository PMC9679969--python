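"""Tanimoto similarity and binding-mode clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from ligmodes.fingerprints import Fingerprint, fingerprint_trajectory
from ligmodes.modes import (
    cluster_binding_modes,
    cluster_specificity,
    representative_frames,
    similarity_matrix,
    tanimoto,
)
from ligmodes.synthdata import SyntheticComplexSpec, make_synthetic_trajectory


def _fp(rows):
    rows = np.asarray(rows, dtype=bool)
    labels = [("A", i + 1, "hydrophobic") for i in range(rows.shape[1])]
    return Fingerprint(rows, labels)


class TestTanimoto:
    def test_identical(self):
        assert tanimoto([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_disjoint(self):
        assert tanimoto([1, 0], [0, 1]) == 0.0

    def test_one_third(self):
        assert tanimoto([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(1 / 3)

    def test_both_empty_is_identical_pattern(self):
        assert tanimoto([0, 0, 0], [0, 0, 0]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            tanimoto([1, 0], [1, 0, 1])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        a=st.lists(st.booleans(), min_size=6, max_size=6),
        b=st.lists(st.booleans(), min_size=6, max_size=6),
        c=st.lists(st.booleans(), min_size=6, max_size=6),
    )
    def test_symmetry_self_unity_triangle(self, a, b, c):
        """Symmetry, self-similarity 1 and the Jaccard-distance triangle
        inequality."""
        assert tanimoto(a, b) == tanimoto(b, a)
        assert tanimoto(a, a) == 1.0
        dab = 1 - tanimoto(a, b)
        dbc = 1 - tanimoto(b, c)
        dac = 1 - tanimoto(a, c)
        assert dac <= dab + dbc + 1e-12


class TestSimilarityMatrix:
    def test_identical_rows_all_ones(self):
        sim = similarity_matrix(_fp([[1, 0, 1]] * 4))
        np.testing.assert_allclose(sim.values, 1.0)

    def test_two_disjoint_blocks(self):
        sim = similarity_matrix(_fp([[1, 1, 0, 0]] * 3 + [[0, 0, 1, 1]] * 3))
        expected = np.kron(np.eye(2), np.ones((3, 3)))
        np.testing.assert_allclose(sim.values, expected)

    def test_matches_pairwise_recomputation(self, rng):
        rows = rng.random((10, 7)) < 0.4
        sim = similarity_matrix(_fp(rows))
        for i in range(10):
            for j in range(10):
                assert sim.values[i, j] == pytest.approx(
                    tanimoto(rows[i], rows[j]), abs=1e-12
                )

    def test_symmetric_unit_diagonal(self, rng):
        sim = similarity_matrix(_fp(rng.random((8, 5)) < 0.5))
        np.testing.assert_allclose(sim.values, sim.values.T)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)


class TestClustering:
    @pytest.mark.parametrize("planted_k", [2, 3])
    def test_recovers_planted_disjoint_modes(self, planted_k):
        spec = SyntheticComplexSpec(n_modes=planted_k, frames=240, dwell=10, seed=42)
        traj, labels = make_synthetic_trajectory(spec)
        assert len(set(labels)) == planted_k  # every planted mode realized
        fp = fingerprint_trajectory(traj, ["PTE"])
        clustering = cluster_binding_modes(fp, seed=0)
        assert clustering.k == planted_k
        assert adjusted_rand_score(labels, clustering.labels) >= 0.95

    def test_all_identical_rows_degenerate_k1(self):
        clustering = cluster_binding_modes(_fp([[1, 0, 1]] * 10))
        assert clustering.k == 1
        assert clustering.sizes == [10]
        assert clustering.specificity == [1.0]

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="at least 3"):
            cluster_binding_modes(_fp([[1, 0], [0, 1]]))

    def test_seeded_reproducibility(self, rng):
        rows = rng.random((40, 9)) < 0.4
        a = cluster_binding_modes(_fp(rows), seed=123)
        b = cluster_binding_modes(_fp(rows), seed=123)
        assert a.k == b.k
        assert (a.labels == b.labels).all()
        assert a.silhouette_by_k == b.silhouette_by_k

    def test_cluster_relabeling_preserves_structure(self, rng):
        """Permuting cluster ids changes nothing about k, the size multiset
        or the specificity multiset."""
        from ligmodes.modes import ModeClustering

        spec = SyntheticComplexSpec(n_modes=3, frames=150, dwell=10, seed=9)
        traj, _ = make_synthetic_trajectory(spec)
        fp = fingerprint_trajectory(traj, ["PTE"])
        a = cluster_binding_modes(fp, seed=0)
        perm = rng.permutation(a.k)
        relabeled = ModeClustering(
            k=a.k, labels=perm[a.labels], silhouette_by_k=a.silhouette_by_k,
            representatives=[], specificity=[], sizes=[int(np.sum(perm[a.labels] == c)) for c in range(a.k)],
            frame_ids=a.frame_ids,
        )
        sim = similarity_matrix(fp)
        assert sorted(relabeled.sizes) == sorted(a.sizes)
        assert sorted(np.round(cluster_specificity(relabeled, sim), 9)) == sorted(
            np.round(a.specificity, 9)
        )

    def test_sizes_sum_and_label_range(self):
        spec = SyntheticComplexSpec(n_modes=3, frames=90, seed=2)
        traj, _ = make_synthetic_trajectory(spec)
        fp = fingerprint_trajectory(traj, ["PTE"])
        c = cluster_binding_modes(fp, seed=0)
        assert sum(c.sizes) == fp.n_frames
        assert set(c.labels) == set(range(c.k))
        assert all(0 <= s <= 1 for s in c.specificity)

    def test_similarity_feature_space_also_recovers(self):
        spec = SyntheticComplexSpec(n_modes=2, frames=80, seed=4)
        traj, labels = make_synthetic_trajectory(spec)
        fp = fingerprint_trajectory(traj, ["PTE"])
        c = cluster_binding_modes(fp, seed=0, feature_space="similarity")
        assert c.k == 2
        assert adjusted_rand_score(labels, c.labels) >= 0.95


class TestRepresentatives:
    def test_identical_rows_lowest_frame_id(self):
        c = cluster_binding_modes(_fp([[1, 0, 1]] * 5))
        assert representative_frames(c, _fp([[1, 0, 1]] * 5)) == [0]

    def test_hand_computed_centroid_distances(self):
        """Cluster {(1,1,0), (1,0,0), (1,1,0)}: centroid (1, 2/3, 0); the
        nearest member is a (1,1,0) row, ties broken by lowest frame id."""
        fp = _fp([[1, 1, 0], [1, 0, 0], [1, 1, 0]])
        from ligmodes.modes import ModeClustering

        clustering = ModeClustering(
            k=1, labels=np.zeros(3, dtype=int), silhouette_by_k={},
            representatives=[], specificity=[], sizes=[3], frame_ids=[0, 1, 2],
        )
        assert representative_frames(clustering, fp) == [0]

    def test_singleton_cluster(self):
        fp = _fp([[1, 0], [0, 1], [0, 1], [0, 1]])
        c = cluster_binding_modes(fp, k_min=2, k_max=2)
        rep_by_cluster = dict(zip(range(c.k), c.representatives))
        singleton = int(np.argmin(c.sizes))
        assert rep_by_cluster[singleton] == int(np.flatnonzero(c.labels == singleton)[0])


class TestSpecificity:
    def test_identical_patterns_unity(self):
        c = cluster_binding_modes(_fp([[1, 0, 1]] * 6))
        assert c.specificity == [1.0]

    def test_two_disjoint_patterns_zero(self):
        fp = _fp([[1, 0], [0, 1]])
        from ligmodes.modes import ModeClustering

        clustering = ModeClustering(
            k=1, labels=np.zeros(2, dtype=int), silhouette_by_k={},
            representatives=[], specificity=[], sizes=[2],
        )
        values = cluster_specificity(clustering, similarity_matrix(fp))
        assert values[0] == 0.0

    def test_hand_computed_three_frame_cluster(self):
        """Pairwise Tanimotos {1, 1/3, 1/3} average to 5/9 = 0.5556."""
        fp = _fp([[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0]])
        from ligmodes.modes import ModeClustering

        clustering = ModeClustering(
            k=1, labels=np.zeros(3, dtype=int), silhouette_by_k={},
            representatives=[], specificity=[], sizes=[3],
        )
        values = cluster_specificity(clustering, similarity_matrix(fp))
        assert values[0] == pytest.approx(0.5556, abs=1e-4)
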