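import numpy as np
import pytest

from gravisyn import clustering as cl
from gravisyn.errors import InvalidArgumentError

GRAVITY = ["1g", "0.6g", "0.38g", "0.16g", "0.07g"]


def _direction_groups(rng, n_groups, per_group, dim=12, jitter=0.02):
    """Well-separated nonnegative direction groups with known membership."""
    bases = np.zeros((n_groups, dim))
    for g in range(n_groups):
        idx = np.arange(dim)[g::n_groups]
        bases[g, idx] = rng.uniform(0.7, 1.0, idx.size)
    vecs, truth = [], []
    for g in range(n_groups):
        for _ in range(per_group):
            v = np.clip(bases[g] + rng.normal(0, jitter, dim), 0, None)
            vecs.append(v / np.linalg.norm(v))
            truth.append(g)
    return np.array(vecs), np.array(truth)


def _pool(vectors, labels=None):
    return cl.ModulePool.from_vectors(vectors, labels)


class TestModulePool:
    def test_rows_normalized(self, rng):
        pool = _pool(rng.uniform(0.1, 1, (5, 4)))
        np.testing.assert_allclose(np.linalg.norm(pool.vectors, axis=1), 1.0, atol=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(InvalidArgumentError):
            _pool(np.array([[1.0, 0.0], [0.0, 0.0]]))

    def test_non_unit_rows_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cl.ModulePool(vectors=np.ones((2, 3)), item_labels=[{}, {}])


class TestSphericalKmeans:
    def test_two_group_recovery(self, rng):
        vecs, truth = _direction_groups(rng, 2, 10)
        res = cl.spherical_kmeans(_pool(vecs), 2, n_init=10, seed=0)
        # perfect recovery up to label permutation
        a = res.assignments
        assert len({tuple(a[truth == g]) for g in (0, 1)}) == 2
        for g in (0, 1):
            assert len(set(a[truth == g])) == 1
        assert set(a) == {0, 1}

    def test_k_equals_n_items(self, rng):
        vecs, _ = _direction_groups(rng, 3, 2)
        res = cl.spherical_kmeans(_pool(vecs), 6, n_init=5, seed=0)
        assert res.mean_silhouette == 0.0
        assert res.flags.get("silhouette_degenerate")

    def test_deterministic(self, rng):
        vecs, _ = _direction_groups(rng, 3, 5)
        a = cl.spherical_kmeans(_pool(vecs), 3, n_init=10, seed=4)
        b = cl.spherical_kmeans(_pool(vecs), 3, n_init=10, seed=4)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_k_too_large(self, rng):
        vecs, _ = _direction_groups(rng, 2, 2)
        with pytest.raises(InvalidArgumentError):
            cl.spherical_kmeans(_pool(vecs), 5)

    def test_duplicate_vectors_no_crash(self):
        vecs = np.tile(np.array([1.0, 0.0, 0.0]), (6, 1))
        res = cl.spherical_kmeans(_pool(vecs), 2, n_init=3, seed=0)
        assert res.feasible

    def test_centroids_unit_norm(self, rng):
        vecs, _ = _direction_groups(rng, 3, 5)
        res = cl.spherical_kmeans(_pool(vecs), 3, n_init=5, seed=0)
        np.testing.assert_allclose(np.linalg.norm(res.centroids, axis=1), 1.0, atol=1e-9)


class TestDedupe:
    def _setup(self, rng, n_per_participant):
        vecs, truth = _direction_groups(rng, 2, 6)
        labels = [{"participant": i % n_per_participant} for i in range(len(vecs))]
        pool = _pool(vecs, labels)
        res = cl.spherical_kmeans(pool, 2, n_init=5, seed=0)
        return pool, res

    def test_keeps_nearest(self):
        vectors = np.array([[1.0, 0.0], [0.98, 0.2], [0.0, 1.0]])
        labels = [{"participant": "A"}, {"participant": "A"}, {"participant": "B"}]
        pool = _pool(vectors, labels)
        res = cl.ClusterResult(
            assignments=np.array([0, 0, 1]),
            centroids=np.array([[1.0, 0.0], [0.0, 1.0]]),
            mean_silhouette=0.0, k=2,
        )
        deduped = cl.dedupe_within_participant(res, pool)
        assert deduped.assignments[0] == 0
        assert deduped.assignments[1] == cl.EXCLUDED
        assert deduped.assignments[2] == 1

    def test_identity_when_unique(self, rng):
        vecs, truth = _direction_groups(rng, 2, 3)
        labels = [{"participant": i} for i in range(len(vecs))]
        pool = _pool(vecs, labels)
        res = cl.spherical_kmeans(pool, 2, n_init=5, seed=0)
        deduped = cl.dedupe_within_participant(res, pool)
        np.testing.assert_array_equal(deduped.assignments, res.assignments)

    def test_three_coclustered_keep_one(self, rng):
        base = np.array([1.0, 0.1, 0.0])
        vecs = np.stack([base + rng.normal(0, 0.01, 3) for _ in range(3)]
                        + [np.array([0.0, 0.0, 1.0])])
        labels = [{"participant": "A"}] * 3 + [{"participant": "B"}]
        pool = _pool(np.clip(vecs, 0, None), labels)
        res = cl.spherical_kmeans(pool, 2, n_init=5, seed=0)
        deduped = cl.dedupe_within_participant(res, pool)
        cluster_of_a = deduped.assignments[0:3]
        assert np.sum(cluster_of_a != cl.EXCLUDED) == 1
        # the retained one is the nearest to its centroid
        kept = int(np.nonzero(cluster_of_a != cl.EXCLUDED)[0][0])
        c = res.assignments[kept]
        d = np.linalg.norm(pool.vectors[:3] - res.centroids[c], axis=1)
        assert kept == int(np.argmin(d))


class TestRepresentatives:
    def test_single_member(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        pool = _pool(v)
        res = cl.ClusterResult(
            assignments=np.array([0, 1]), centroids=v.copy(),
            mean_silhouette=0.0, k=2,
        )
        reps = cl.representative_modules(res, pool)
        np.testing.assert_allclose(reps, v, atol=1e-12)

    def test_two_members_normalized_midpoint(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        pool = _pool(v)
        res = cl.ClusterResult(
            assignments=np.array([0, 0]), centroids=np.array([[0.7, 0.7]]),
            mean_silhouette=0.0, k=1,
        )
        reps = cl.representative_modules(res, pool)
        np.testing.assert_allclose(reps[0], [np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)

    def test_empty_cluster_error(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        pool = _pool(v)
        res = cl.ClusterResult(
            assignments=np.array([0, 0]), centroids=np.zeros((2, 2)),
            mean_silhouette=0.0, k=2,
        )
        with pytest.raises(InvalidArgumentError, match="cluster 1"):
            cl.representative_modules(res, pool)


class TestConstrainedKmeans:
    def _gravity_pool(self, rng, n_groups=4):
        vecs, truth = _direction_groups(rng, n_groups, len(GRAVITY), jitter=0.02)
        labels = []
        for g in range(n_groups):
            for gi, grav in enumerate(GRAVITY):
                labels.append({"gravity": grav, "module": g})
        return _pool(vecs, labels), truth

    def test_one_item_per_gravity_per_cluster(self, rng):
        pool, truth = self._gravity_pool(rng)
        pairs = cl.same_gravity_pairs(pool.item_labels)
        res = cl.constrained_kmeans(pool, 4, pairs, n_init=20, seed=0)
        assert res.feasible and res.constraint_violations == 0
        for c in range(4):
            gravs = [pool.item_labels[i]["gravity"]
                     for i in np.nonzero(res.assignments == c)[0]]
            assert sorted(gravs) == sorted(GRAVITY)

    def test_pigeonhole_infeasible(self):
        vecs = np.eye(4)
        labels = [{"gravity": "1g"}] * 4
        pool = _pool(vecs, labels)
        pairs = cl.same_gravity_pairs(labels)
        res = cl.constrained_kmeans(pool, 3, pairs, n_init=5, seed=0)
        assert not res.feasible
        assert res.mean_silhouette == 0.0

    def test_reduces_to_spherical_without_constraints(self, rng):
        vecs, _ = _direction_groups(rng, 3, 4)
        pool = _pool(vecs)
        a = cl.constrained_kmeans(pool, 3, [], n_init=10, seed=7)
        b = cl.spherical_kmeans(pool, 3, n_init=10, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)


class TestSelectK:
    def test_four_groups(self, rng):
        vecs, _ = _direction_groups(rng, 4, 5)
        k, table, _ = cl.select_k_by_silhouette(_pool(vecs), range(2, 11), seed=0)
        assert k == 4
        assert table[4] > 0.7

    def test_two_groups(self, rng):
        vecs, _ = _direction_groups(rng, 2, 6)
        k, table, _ = cl.select_k_by_silhouette(_pool(vecs), range(2, 11), seed=0)
        assert k == 2

    def test_table_in_range(self, rng):
        vecs, _ = _direction_groups(rng, 3, 4)
        _, table, _ = cl.select_k_by_silhouette(_pool(vecs), range(2, 8), seed=0)
        assert all(-1.0 <= v <= 1.0 for v in table.values())
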