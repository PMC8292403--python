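"""Nonnegative matrix factorization of cycle matrices.

Lee-Seung multiplicative updates for the squared Frobenius loss, restarted
from random uniform initializations; variance-accounted-for (VAF) goodness
of fit; cross-validated VAF curves over candidate module numbers; and the
minimum-N-above-threshold selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError
from .preprocessing import CycleMatrix

EPS = 1e-12

#: sentinel returned when no candidate reaches the VAF threshold
NOT_REACHED = -1


@dataclass
class ModuleSet:
    """NMF factors for one cycle matrix: spatial weightings ``W``
    (muscles x N, unit-norm columns) and temporal coefficients ``C``
    (N x n_bins)."""

    W: np.ndarray
    C: np.ndarray
    n_modules: int
    vaf: float
    restart_errors: list[float] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.C


@dataclass
class VAFCurve:
    """Cross-validated test VAF per candidate module number."""

    n_values: np.ndarray
    mean_vaf: np.ndarray
    sd_vaf: np.ndarray
    n_folds: int
    n_reps: int


def vaf(M: np.ndarray, M_hat: np.ndarray, uncentred_r2: bool = False) -> float:
    """Variance accounted for, percent.

    Primary definition: ``100 * (1 - SSE / sum(M^2))``. With
    ``uncentred_r2=True`` returns 100 x the squared uncentred correlation
    between the vectorized matrices instead.
    """
    M = np.asarray(M, dtype=float)
    M_hat = np.asarray(M_hat, dtype=float)
    if M.shape != M_hat.shape:
        raise InvalidArgumentError("shapes must match")
    total = float(np.sum(M * M))
    if total == 0:
        raise DegenerateInputError("all-zero reference matrix")
    if uncentred_r2:
        denom = total * float(np.sum(M_hat * M_hat))
        if denom == 0:
            return 0.0
        r = float(np.sum(M * M_hat)) / np.sqrt(denom)
        return 100.0 * r * r
    sse = float(np.sum((M - M_hat) ** 2))
    return 100.0 * (1.0 - sse / total)


def _mu_iterate(
    M: np.ndarray,
    W: np.ndarray,
    C: np.ndarray,
    update_w: bool,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multiplicative updates until the relative loss change drops below
    ``tol``. Returns (W, C, final squared error)."""
    prev = np.inf
    err = float(np.sum((M - W @ C) ** 2))
    for _ in range(max_iter):
        if update_w:
            W = W * (M @ C.T) / (W @ (C @ C.T) + EPS)
        C = C * (W.T @ M) / ((W.T @ W) @ C + EPS)
        prev, err = err, float(np.sum((M - W @ C) ** 2))
        if prev > 0 and (prev - err) / prev < tol:
            break
    return W, C, err


def _normalize_columns(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm spatial columns; scale absorbed into C."""
    norms = np.linalg.norm(W, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    return W / norms, C * norms[:, None]


def nmf_extract(
    M: CycleMatrix | np.ndarray,
    N: int,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    meta: dict | None = None,
) -> ModuleSet:
    """Extract ``N`` modules; keep the restart with the highest VAF.

    Each restart initializes ``W`` and ``C`` uniformly in (0, 1) and runs
    multiplicative updates to convergence. Spatial columns are normalized to
    unit Euclidean norm, with the scale absorbed into ``C``.
    """
    values = M.values if isinstance(M, CycleMatrix) else np.asarray(M, dtype=float)
    if np.any(values < 0):
        raise InvalidArgumentError("matrix must be nonnegative")
    n_rows = values.shape[0]
    if not 1 <= N <= n_rows:
        raise InvalidArgumentError(f"N must be in [1, {n_rows}]")
    if not np.any(values):
        raise DegenerateInputError("all-zero matrix")

    rng = np.random.default_rng(seed)
    best = None
    errors = []
    for _ in range(n_restarts):
        W0 = rng.uniform(0.0, 1.0, (n_rows, N))
        C0 = rng.uniform(0.0, 1.0, (N, values.shape[1]))
        W, C, err = _mu_iterate(values, W0, C0, True, tol, max_iter)
        errors.append(err)
        v = vaf(values, W @ C)
        if best is None or v > best[0]:
            best = (v, W, C)

    v, W, C = best
    W, C = _normalize_columns(W, C)
    return ModuleSet(
        W=W, C=C, n_modules=N, vaf=v, restart_errors=errors, meta=meta or {}
    )


def fit_coefficients(
    M: np.ndarray,
    W: np.ndarray,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, float]:
    """Fit temporal coefficients to ``M`` with frozen spatial weightings.

    Runs C-only multiplicative updates from a random initialization and
    returns ``(C, test VAF)``.
    """
    M = np.asarray(M, dtype=float)
    rng = np.random.default_rng(seed)
    C0 = rng.uniform(0.0, 1.0, (W.shape[1], M.shape[1]))
    _, C, _ = _mu_iterate(M, W, C0, False, tol, max_iter)
    return C, vaf(M, W @ C)


def cross_validated_vaf_curve(
    M: CycleMatrix | np.ndarray,
    N_range=range(1, 13),
    n_folds: int = 5,
    n_reps: int = 20,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> VAFCurve:
    """Cross-validated test VAF per candidate module number.

    Per repeat: randomly partition the time columns into ``n_folds``
    disjoint equal sets; for each fold fit ``W`` on the pooled remaining
    columns, then refit ``C`` only on the held-out columns and record the
    test VAF. Each repeat's value is the mean over its folds; the curve
    reports mean +/- sd over repeats.
    """
    values = M.values if isinstance(M, CycleMatrix) else np.asarray(M, dtype=float)
    n_cols = values.shape[1]
    if n_cols % n_folds != 0:
        raise InvalidArgumentError(
            f"{n_cols} columns not divisible by {n_folds} folds"
        )
    fold_size = n_cols // n_folds
    rng = np.random.default_rng(seed)
    N_values = list(N_range)

    rep_vafs = np.empty((len(N_values), n_reps))
    for rep in range(n_reps):
        perm = rng.permutation(n_cols)
        folds = [perm[f * fold_size:(f + 1) * fold_size] for f in range(n_folds)]
        for ni, N in enumerate(N_values):
            fold_scores = []
            for f in range(n_folds):
                test_idx = folds[f]
                train_idx = np.concatenate([folds[j] for j in range(n_folds) if j != f])
                fit = nmf_extract(
                    values[:, train_idx], N,
                    n_restarts=n_restarts,
                    seed=int(rng.integers(2**31)),
                    tol=tol, max_iter=max_iter,
                )
                _, test_vaf = fit_coefficients(
                    values[:, test_idx], fit.W,
                    seed=int(rng.integers(2**31)), tol=tol, max_iter=max_iter,
                )
                fold_scores.append(test_vaf)
            rep_vafs[ni, rep] = np.mean(fold_scores)

    return VAFCurve(
        n_values=np.array(N_values),
        mean_vaf=rep_vafs.mean(axis=1),
        sd_vaf=rep_vafs.std(axis=1),
        n_folds=n_folds,
        n_reps=n_reps,
    )


def select_module_number(curve: VAFCurve, threshold: float = 90.0) -> tuple[int, dict]:
    """Smallest N whose mean cross-validated VAF exceeds ``threshold``.

    Returns ``(N, info)``. If no candidate reaches the threshold the first
    element is :data:`NOT_REACHED` and ``info`` carries the best candidate.
    """
    if curve.n_values.size == 0:
        raise InvalidArgumentError("empty VAF curve")
    above = np.nonzero(curve.mean_vaf > threshold)[0]
    if above.size == 0:
        best = int(np.argmax(curve.mean_vaf))
        return NOT_REACHED, {
            "reached": False,
            "max_n": int(curve.n_values[best]),
            "max_vaf": float(curve.mean_vaf[best]),
        }
    idx = int(above[0])
    return int(curve.n_values[idx]), {
        "reached": True,
        "vaf": float(curve.mean_vaf[idx]),
    }


def select_module_number_incremental(
    M: CycleMatrix | np.ndarray,
    N_max: int = 12,
    threshold: float = 90.0,
    **cv_kwargs,
) -> tuple[int, VAFCurve]:
    """Scan N upward, stopping at the first candidate whose mean
    cross-validated VAF exceeds the threshold.

    Equivalent to building the full curve and applying
    :func:`select_module_number`, but avoids fitting larger models once the
    rule has fired.
    """
    means, sds = [], []
    n_folds = cv_kwargs.get("n_folds", 5)
    n_reps = cv_kwargs.get("n_reps", 20)
    selected = NOT_REACHED
    for N in range(1, N_max + 1):
        c = cross_validated_vaf_curve(M, N_range=[N], **cv_kwargs)
        means.append(c.mean_vaf[0])
        sds.append(c.sd_vaf[0])
        if c.mean_vaf[0] > threshold:
            selected = N
            break
    curve = VAFCurve(
        n_values=np.arange(1, len(means) + 1),
        mean_vaf=np.array(means),
        sd_vaf=np.array(sds),
        n_folds=n_folds,
        n_reps=n_reps,
    )
    return selected, curve


def group_module_number(per_participant: list[int]) -> int:
    """Group-level module number: mode across participants, ties broken
    toward the smaller N. Not-reached sentinels are ignored."""
    counts: dict[int, int] = {}
    for n in per_participant:
        if n != NOT_REACHED:
            counts[n] = counts.get(n, 0) + 1
    if not counts:
        return NOT_REACHED
    best = max(counts.values())
    return min(n for n, c in counts.items() if c == best)
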