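"""Cosine k-means clustering of module vectors, with cannot-link constraints.

Classifies unit-norm module vectors into clusters by spherical (cosine)
k-means, removes within-participant duplicates, forms per-cluster
representative vectors, clusters representatives across gravity levels under
cannot-link constraints (items from the same gravity level may not share a
cluster), and selects the cluster count by mean silhouette over a candidate
range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_score

from .errors import InvalidArgumentError

EXCLUDED = -1


@dataclass
class ModulePool:
    """Unit-norm module vectors with per-item provenance labels.

    ``item_labels`` entries are dicts with keys such as ``participant``,
    ``gravity``, ``module``, ``kind``.
    """

    vectors: np.ndarray  # n_items x dim, unit-norm rows
    item_labels: list[dict]

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise InvalidArgumentError("vectors must be 2-D")
        if len(self.item_labels) != self.vectors.shape[0]:
            raise InvalidArgumentError("one label per vector required")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms <= 0):
            raise InvalidArgumentError("zero-norm vector in pool")
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise InvalidArgumentError("pool rows must be unit-norm")

    @property
    def n_items(self) -> int:
        return self.vectors.shape[0]

    @classmethod
    def from_vectors(cls, vectors: np.ndarray, item_labels: list[dict] | None = None):
        """Build a pool, normalizing rows to unit norm."""
        vectors = np.asarray(vectors, dtype=float)
        norms = np.linalg.norm(vectors, axis=1, keepdims=True)
        if np.any(norms <= 0):
            raise InvalidArgumentError("zero-norm vector in pool")
        labels = item_labels or [{"item": i} for i in range(vectors.shape[0])]
        return cls(vectors=vectors / norms, item_labels=labels)


@dataclass
class ClusterResult:
    assignments: np.ndarray  # item -> cluster id, EXCLUDED for removed items
    centroids: np.ndarray  # k x dim, unit-norm rows
    mean_silhouette: float
    k: int
    constraint_violations: int = 0
    feasible: bool = True
    inertia: float = float("nan")
    flags: dict = field(default_factory=dict)


def _cosine_distances(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return 1.0 - X @ Y.T  # rows assumed unit-norm


def _normalize_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    return M / np.where(norms > 0, norms, 1.0)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding on cosine distance."""
    n = X.shape[0]
    centroids = [X[rng.integers(n)]]
    for _ in range(1, k):
        d = np.min(_cosine_distances(X, np.stack(centroids)), axis=1)
        d = np.clip(d, 0.0, None)
        total = d.sum()
        if total <= 0:
            centroids.append(X[rng.integers(n)])
            continue
        centroids.append(X[rng.choice(n, p=d / total)])
    return np.stack(centroids)


def _assign_constrained(
    X: np.ndarray,
    centroids: np.ndarray,
    cannot_link: dict[int, set[int]],
    order: np.ndarray,
) -> np.ndarray | None:
    """Sequentially assign each item to its nearest feasible centroid.

    Returns None when some item has no feasible centroid.
    """
    n, k = X.shape[0], centroids.shape[0]
    labels = np.full(n, -1)
    dist = _cosine_distances(X, centroids)
    for i in order:
        blocked = {labels[j] for j in cannot_link.get(i, ()) if labels[j] >= 0}
        choices = [c for c in range(k) if c not in blocked]
        if not choices:
            return None
        labels[i] = min(choices, key=lambda c: (dist[i, c], c))
    return labels


def _kmeans_once(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    cannot_link: dict[int, set[int]],
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float] | None:
    centroids = _kmeanspp_init(X, k, rng)
    labels = None
    for _ in range(max_iter):
        order = rng.permutation(X.shape[0])
        new_labels = _assign_constrained(X, centroids, cannot_link, order)
        if new_labels is None:
            return None
        # refill empty clusters with the items farthest from their centroid
        for c in range(k):
            if not np.any(new_labels == c):
                d = _cosine_distances(X, centroids)[np.arange(X.shape[0]), new_labels]
                cand = int(np.argmax(d))
                new_labels[cand] = c
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = X[labels == c]
            if members.size:
                centroids[c] = members.mean(axis=0)
        centroids = _normalize_rows(centroids)
    inertia = float(
        np.sum(_cosine_distances(X, centroids)[np.arange(X.shape[0]), labels])
    )
    return labels, centroids, inertia


def _pairs_to_adjacency(pairs, n: int) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for a, b in pairs:
        if not (0 <= a < n and 0 <= b < n) or a == b:
            raise InvalidArgumentError(f"invalid cannot-link pair ({a}, {b})")
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def cosine_silhouette(X: np.ndarray, labels: np.ndarray) -> tuple[float, dict]:
    """Mean silhouette under cosine distance; degenerate labelings
    (single cluster, or every item its own cluster) score 0 with a flag."""
    uniq = np.unique(labels)
    if uniq.size < 2 or uniq.size >= X.shape[0]:
        return 0.0, {"silhouette_degenerate": True}
    return float(silhouette_score(X, labels, metric="cosine")), {}


def spherical_kmeans(
    pool: ModulePool, k: int, n_init: int = 50, seed: int = 0
) -> ClusterResult:
    """Cosine k-means: minimizes total (1 - cosine similarity) to unit-norm
    centroids; best of ``n_init`` k-means++-seeded runs."""
    return constrained_kmeans(pool, k, cannot_link=[], n_init=n_init, seed=seed)


def constrained_kmeans(
    pool: ModulePool,
    k: int,
    cannot_link: list[tuple[int, int]],
    n_init: int = 50,
    seed: int = 0,
) -> ClusterResult:
    """COP-k-means on cosine distance.

    Items are assigned in random order to the nearest centroid that does not
    violate a cannot-link constraint against already-assigned items; a run
    with no feasible assignment is abandoned and re-seeded. When every
    restart fails the result is an infeasibility outcome
    (``feasible=False``, silhouette 0), not an exception.
    """
    if k < 1 or k > pool.n_items:
        raise InvalidArgumentError(f"k must be in [1, {pool.n_items}]")
    X = pool.vectors
    adj = _pairs_to_adjacency(cannot_link, pool.n_items)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_init):
        out = _kmeans_once(X, k, rng, adj)
        if out is None:
            continue
        labels, centroids, inertia = out
        if np.any([labels[i] in {labels[j] for j in adj.get(i, ())} for i in range(pool.n_items)]):
            continue  # safety net; sequential assignment should prevent this
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia)

    if best is None:
        return ClusterResult(
            assignments=np.full(pool.n_items, EXCLUDED),
            centroids=np.zeros((k, X.shape[1])),
            mean_silhouette=0.0,
            k=k,
            feasible=False,
            flags={"infeasible": True},
        )

    labels, centroids, inertia = best
    sil, flags = cosine_silhouette(X, labels)
    return ClusterResult(
        assignments=labels,
        centroids=centroids,
        mean_silhouette=sil,
        k=k,
        constraint_violations=0,
        inertia=inertia,
        flags=flags,
    )


def dedupe_within_participant(
    result: ClusterResult,
    pool: ModulePool,
    keep_per_participant: int = 1,
) -> ClusterResult:
    """Keep at most ``keep_per_participant`` modules per (participant,
    cluster) group — the ones nearest (Euclidean) to the cluster centroid;
    the rest are marked excluded."""
    assignments = result.assignments.copy()
    groups: dict[tuple, list[int]] = {}
    for i, lab in enumerate(pool.item_labels):
        c = assignments[i]
        if c == EXCLUDED:
            continue
        groups.setdefault((lab.get("participant"), c), []).append(i)
    for (_, c), items in groups.items():
        if len(items) <= keep_per_participant:
            continue
        d = np.linalg.norm(pool.vectors[items] - result.centroids[c], axis=1)
        ranked = [items[j] for j in np.argsort(d, kind="stable")]
        for i in ranked[keep_per_participant:]:
            assignments[i] = EXCLUDED
    return ClusterResult(
        assignments=assignments,
        centroids=result.centroids,
        mean_silhouette=result.mean_silhouette,
        k=result.k,
        constraint_violations=result.constraint_violations,
        feasible=result.feasible,
        inertia=result.inertia,
        flags=dict(result.flags, deduped=True),
    )


def representative_modules(result: ClusterResult, pool: ModulePool) -> np.ndarray:
    """Per-cluster unit-norm mean of retained members (the representative
    SPc / TEc vectors)."""
    reps = np.empty((result.k, pool.vectors.shape[1]))
    for c in range(result.k):
        members = pool.vectors[result.assignments == c]
        if members.shape[0] == 0:
            raise InvalidArgumentError(f"cluster {c} has no retained members")
        reps[c] = members.mean(axis=0)
    return _normalize_rows(reps)


def same_gravity_pairs(item_labels: list[dict]) -> list[tuple[int, int]]:
    """Cannot-link pairs between all items sharing a gravity label."""
    by_gravity: dict[str, list[int]] = {}
    for i, lab in enumerate(item_labels):
        by_gravity.setdefault(lab.get("gravity"), []).append(i)
    pairs = []
    for items in by_gravity.values():
        pairs.extend(
            (items[a], items[b])
            for a in range(len(items))
            for b in range(a + 1, len(items))
        )
    return pairs


def select_k_by_silhouette(
    pool: ModulePool,
    k_range=range(2, 11),
    constrained: bool = False,
    cannot_link: list[tuple[int, int]] | None = None,
    n_init: int = 50,
    seed: int = 0,
) -> tuple[int, dict[int, float], dict[int, ClusterResult]]:
    """Cluster at each candidate k and pick the largest mean silhouette
    (cosine distance); ties break toward the smaller k; infeasible k score 0.

    Returns ``(k_star, silhouette_table, results)``.
    """
    cannot_link = cannot_link if constrained else []
    if cannot_link is None:
        raise InvalidArgumentError("constrained selection requires cannot_link pairs")
    table: dict[int, float] = {}
    results: dict[int, ClusterResult] = {}
    for k in k_range:
        if k > pool.n_items:
            table[k] = 0.0
            continue
        res = constrained_kmeans(pool, k, cannot_link, n_init=n_init, seed=seed + k)
        results[k] = res
        table[k] = res.mean_silhouette if res.feasible else 0.0
    k_star = max(sorted(table), key=lambda k: (table[k], -k))
    return k_star, table, results
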