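"""Nonnegative CANDECOMP/PARAFAC decomposition of the 3-way EMG array.

Stacks cycle matrices into a muscles x bins x condition-instances tensor and
fits a nonnegative CP model by multiplicative updates on the squared-error
loss. Factor columns are normalized to unit Euclidean norm with the scale
absorbed into per-component lambdas; the per-slice gains quantify how
strongly each component is recruited in each condition instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import khatri_rao

from .errors import DegenerateInputError, InvalidArgumentError
from .factorization import vaf
from .preprocessing import CycleMatrix

EPS = 1e-12


@dataclass
class EMGTensor:
    """Nonnegative muscles x bins x slices array with per-slice labels."""

    values: np.ndarray
    slice_labels: list[dict]  # per slice: participant / gravity / speed
    muscle_labels: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidArgumentError("tensor must be 3-way")
        if np.any(self.values < 0):
            raise InvalidArgumentError("tensor must be nonnegative")
        if len(self.slice_labels) != self.values.shape[2]:
            raise InvalidArgumentError("one label per slice required")
        keys = [tuple(sorted(lab.items())) for lab in self.slice_labels]
        if len(set(keys)) != len(keys):
            raise InvalidArgumentError("duplicate slice labels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class CPModel:
    """Nonnegative CP factors with unit-norm columns and explicit scaling."""

    lambdas: np.ndarray  # N
    W_st: np.ndarray  # muscles x N
    C_st: np.ndarray  # bins x N
    T: np.ndarray  # slices x N
    vaf: float
    restart_errors: list[float] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.lambdas.size

    def reconstruct(self) -> np.ndarray:
        return np.einsum("n,in,jn,kn->ijk", self.lambdas, self.W_st, self.C_st, self.T)


def build_tensor(matrices: list[CycleMatrix], slice_labels: list[dict] | None = None) -> EMGTensor:
    """Stack cycle matrices into a 3-way tensor in the supplied order."""
    if not matrices:
        raise InvalidArgumentError("empty slice list")
    ref = matrices[0]
    for m in matrices:
        if m.muscle_labels != ref.muscle_labels:
            raise InvalidArgumentError("inconsistent muscle ordering across slices")
        if m.values.shape != ref.values.shape:
            raise InvalidArgumentError("inconsistent matrix shapes across slices")
    if slice_labels is None:
        slice_labels = [
            {"participant": m.participant, "condition": m.condition} for m in matrices
        ]
    return EMGTensor(
        values=np.stack([m.values for m in matrices], axis=2),
        slice_labels=slice_labels,
        muscle_labels=ref.muscle_labels,
    )


def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _init_factors(
    X: np.ndarray,
    unfolds: list[np.ndarray],
    N: int,
    rng: np.random.Generator,
    kind: str,
) -> list[np.ndarray]:
    if kind == "uniform":
        return [rng.uniform(0.0, 1.0, (d, N)) for d in X.shape]
    # fiber init: random data fibers plus a uniform floor; keeps support on
    # weak, disjoint components that multiplicative updates cannot revive
    # once a mode loses them
    factors = []
    for U in unfolds:
        cols = U[:, rng.integers(U.shape[1], size=N)].astype(float)
        scale = cols.max() if cols.max() > 0 else 1.0
        factors.append(cols + rng.uniform(0.0, 0.1 * scale, cols.shape))
    return factors


def _ncp_once(
    X: np.ndarray,
    N: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    init: str = "uniform",
) -> tuple[list[np.ndarray], float]:
    """One multiplicative-update run; returns factors and final SSE."""
    unfolds = [_unfold(X, m) for m in range(3)]
    factors = _init_factors(X, unfolds, N, rng, init)
    total = float(np.sum(X * X))

    def sse() -> float:
        A, B, C = factors
        kr = khatri_rao(B, C)
        norm_hat = float(np.sum((A.T @ A) * (kr.T @ kr)))
        cross = float(np.sum((unfolds[0] @ kr) * A))
        return max(total - 2.0 * cross + norm_hat, 0.0)

    prev = sse()
    for _ in range(max_iter):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            kr = khatri_rao(*others)
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            num = unfolds[mode] @ kr
            den = factors[mode] @ gram + EPS
            factors[mode] *= num / den
        err = sse()
        if prev > 0 and (prev - err) / prev < tol:
            prev = err
            break
        prev = err
    return factors, prev


def ncp_decompose(
    tensor: EMGTensor | np.ndarray,
    N: int,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    meta: dict | None = None,
) -> CPModel:
    """Fit a nonnegative CP model; keep the restart with the highest VAF.

    After convergence each factor column is normalized to unit Euclidean
    norm, the product of norms becomes the component's lambda, and components
    are sorted by lambda descending.
    """
    X = tensor.values if isinstance(tensor, EMGTensor) else np.asarray(tensor, dtype=float)
    if X.ndim != 3:
        raise InvalidArgumentError("tensor must be 3-way")
    if np.any(X < 0):
        raise InvalidArgumentError("tensor must be nonnegative")
    if not np.any(X):
        raise DegenerateInputError("all-zero tensor")
    if not 1 <= N <= min(X.shape):
        raise InvalidArgumentError(f"N must be in [1, {min(X.shape)}]")

    rng = np.random.default_rng(seed)
    best = None
    errors = []
    for r in range(n_restarts):
        init = "uniform" if r % 2 == 0 else "fiber"
        factors, err = _ncp_once(X, N, rng, tol, max_iter, init=init)
        errors.append(err)
        if best is None or err < best[0]:
            best = (err, factors)

    err, (A, B, C) = best[0], best[1]
    norms = [np.linalg.norm(F, axis=0) for F in (A, B, C)]
    lam = norms[0] * norms[1] * norms[2]
    A, B, C = (
        F / np.where(n > 0, n, 1.0) for F, n in zip((A, B, C), norms)
    )
    order = np.argsort(-lam, kind="stable")
    model = CPModel(
        lambdas=lam[order],
        W_st=A[:, order],
        C_st=B[:, order],
        T=C[:, order],
        vaf=100.0 * (1.0 - err / float(np.sum(X * X))),
        restart_errors=errors,
        meta=meta or {},
    )
    return model


def tensor_vaf(tensor: EMGTensor | np.ndarray, model: CPModel) -> float:
    """VAF of the CP reconstruction over all tensor entries, percent."""
    X = tensor.values if isinstance(tensor, EMGTensor) else np.asarray(tensor, dtype=float)
    return vaf(X, model.reconstruct())


def summarize_gains(
    model: CPModel, slice_labels: list[dict], by: str = "gravity"
) -> dict[str, np.ndarray]:
    """Mean per-component gain over the slices sharing each value of the
    ``by`` label (e.g. per gravity level), preserving first-seen order."""
    out: dict[str, list[int]] = {}
    for i, lab in enumerate(slice_labels):
        out.setdefault(lab.get(by), []).append(i)
    return {key: model.T[idx].mean(axis=0) for key, idx in out.items()}
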