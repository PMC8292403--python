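"""Similarity metrics, optimal module matching, bootstrap chance levels,
and nonnegative least-squares reconstruction of clustered modules from CP
components."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .errors import InvalidArgumentError

METRICS = ("cosine", "correlation")


@dataclass
class MatchResult:
    """One-to-one matching between two module sets."""

    pairs: list[tuple[int, int]]
    similarities: list[float]
    metric: str
    overall_median: float
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)


@dataclass
class ChanceLevel:
    """Bootstrap chance level: lower bound of the central 95% interval of
    similarity between randomly paired vectors."""

    lower_bound: float
    n_boot: int
    alpha: float
    metric: str


@dataclass
class CrossModelFit:
    """Nonnegative coefficients expressing target modules in a CP basis."""

    F: np.ndarray  # targets x basis columns
    vaf: np.ndarray  # per-target, percent


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (|a| |b|)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise InvalidArgumentError("zero-norm vector")
    return float(a @ b / (na * nb))


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Centred Pearson correlation coefficient."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    ac, bc = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise InvalidArgumentError("zero-variance vector")
    return float(ac @ bc / (na * nb))


def _metric_fn(metric: str):
    if metric == "cosine":
        return cosine_similarity
    if metric == "correlation":
        return pearson_correlation
    raise InvalidArgumentError(f"unknown metric {metric!r}")


def similarity_matrix(A: np.ndarray, B: np.ndarray, metric: str = "cosine") -> np.ndarray:
    fn = _metric_fn(metric)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    return np.array([[fn(a, b) for b in B] for a in A])


def match_modules(set_A: np.ndarray, set_B: np.ndarray, metric: str = "cosine") -> MatchResult:
    """Optimal one-to-one matching maximizing total similarity.

    When the sets differ in size, the surplus modules are reported as
    unmatched and excluded from the overall median.
    """
    A = np.atleast_2d(np.asarray(set_A, dtype=float))
    B = np.atleast_2d(np.asarray(set_B, dtype=float))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise InvalidArgumentError("empty module set")
    S = similarity_matrix(A, B, metric)
    rows, cols = linear_sum_assignment(-S)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    sims = [float(S[i, j]) for i, j in pairs]
    return MatchResult(
        pairs=pairs,
        similarities=sims,
        metric=metric,
        overall_median=float(np.median(sims)),
        unmatched_a=sorted(set(range(A.shape[0])) - set(rows.tolist())),
        unmatched_b=sorted(set(range(B.shape[0])) - set(cols.tolist())),
    )


def bootstrap_chance_level(
    pool: np.ndarray,
    metric: str = "cosine",
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ChanceLevel:
    """Chance similarity level by vector-level bootstrap resampling.

    Each round draws two distinct indices with replacement from the pool and
    records their similarity; the chance level is the ``alpha/2`` quantile
    of the resulting distribution (lower bound of the central
    ``1 - alpha`` interval).
    """
    pool = np.atleast_2d(np.asarray(pool, dtype=float))
    n = pool.shape[0]
    if n < 2:
        raise InvalidArgumentError("pool must contain at least 2 vectors")
    fn = _metric_fn(metric)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_boot)
    for r in range(n_boot):
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        while j == i:
            j = int(rng.integers(n))
        sims[r] = fn(pool[i], pool[j])
    return ChanceLevel(
        lower_bound=float(np.quantile(sims, alpha / 2.0)),
        n_boot=n_boot,
        alpha=alpha,
        metric=metric,
    )


def nnls_reconstruct(targets: np.ndarray, basis: np.ndarray) -> CrossModelFit:
    """Express each target module as a nonnegative combination of the basis
    columns, reporting the per-target VAF of the reconstruction.

    ``targets`` is targets x dim; ``basis`` is dim x n_columns.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 2 or basis.shape[1] < 1:
        raise InvalidArgumentError("basis must have at least one column")
    if targets.shape[1] != basis.shape[0]:
        raise InvalidArgumentError(
            f"dimension mismatch: targets dim {targets.shape[1]} vs basis dim {basis.shape[0]}"
        )
    F = np.empty((targets.shape[0], basis.shape[1]))
    vafs = np.empty(targets.shape[0])
    for t in range(targets.shape[0]):
        f, _ = nnls(basis, targets[t])
        F[t] = f
        total = float(targets[t] @ targets[t])
        if total == 0:
            raise InvalidArgumentError("all-zero target vector")
        resid = targets[t] - basis @ f
        vafs[t] = 100.0 * (1.0 - float(resid @ resid) / total)
    return CrossModelFit(F=F, vaf=vafs)
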