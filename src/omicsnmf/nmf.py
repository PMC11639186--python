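"""Non-negative matrix factorization and the centroid-consistency loss.

A non-negative matrix ``Y (m x q)`` is factorized as ``Y ~ V U`` with
``V (m x c) >= 0`` read as soft cluster memberships and ``U (c x q) >= 0`` as
cluster centroids in feature space.  The centroid-consistency loss compares
the centroids of a generated batch against reference centroids precomputed
from the observed data; because it only involves centroids, samples with no
observed target profile can contribute to it.

Three technical points make the loss usable inside gradient training:

* NMF factors are unordered, so generated centroids are aligned to the
  reference by an optimal assignment before the distance is taken.
* NMF factors are scale-ambiguous, so every decomposition is normalized to
  unit-maximum membership columns (the scale is absorbed into the centroids).
* The decomposition itself has no useful gradient; instead the memberships
  from a detached decomposition are frozen and the centroids are re-fit by
  non-negative least squares, a map whose gradient in the batch is the fixed
  active-set least-squares solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

__all__ = [
    "NMFFactors",
    "nmf_decompose",
    "ReferenceCentroids",
    "reference_centroids",
    "match_components",
    "refit_centroids",
    "nmf_loss",
    "nmf_loss_and_grad",
]

_EPS = 1e-12


@dataclass
class NMFFactors:
    """Result of one NMF run: memberships ``V``, centroids ``U``, fit error."""

    V: np.ndarray  # (m, c), >= 0, unit-max columns
    U: np.ndarray  # (c, q), >= 0
    c: int
    recon_error: float  # ||Y - V U||_F
    objective_history: np.ndarray  # squared Frobenius objective per iteration

    def __post_init__(self) -> None:
        assert (self.V >= 0).all() and (self.U >= 0).all()
        assert self.V.shape[1] == self.c == self.U.shape[0]
        assert self.recon_error >= 0


def _validate_nonneg(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if not np.isfinite(Y).all():
        raise ValueError("matrix contains non-finite entries")
    if (Y < 0).any():
        raise ValueError("matrix contains negative entries; NMF requires Y >= 0")
    return Y


def nmf_decompose(
    Y: np.ndarray,
    c: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> NMFFactors:
    """Frobenius-objective NMF by Lee–Seung multiplicative updates.

    Centroids are initialized uniform random scaled by ``sqrt(mean(Y) / c)``
    and fully determined by ``seed``; memberships are initialized by
    projecting each data row onto the random initial centroids (rescaled to
    match the data magnitude).  Because the membership init is a function of
    the row's content — not its position — the entire update trajectory is
    exactly equivariant under row permutations, so the fitted centroids do
    not depend on sample order.  Iteration stops at ``max_iter`` or when the
    relative decrease of ``||Y - VU||_F^2`` falls below ``tol``.  The returned
    factors are normalized so each membership column of ``V`` has unit maximum,
    with the scale absorbed into the corresponding centroid row of ``U``.
    """
    Y = _validate_nonneg(Y)
    m, q = Y.shape
    if not 1 <= c <= min(m, q):
        raise ValueError(f"cluster count c={c} must satisfy 1 <= c <= min{Y.shape}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(Y.mean(), _EPS) / c)
    U = rng.uniform(0.0, 1.0, size=(c, q)) * scale
    # row-content-based membership init (row-permutation equivariant)
    V = Y @ U.T
    R = V @ U
    denom = float(np.sum(R * R))
    if denom > 0:
        V *= float(np.sum(Y * R)) / denom  # best scalar fit of V0 U to Y
    else:
        V = np.full((m, c), scale)

    history = []
    prev = np.inf
    for _ in range(max_iter):
        # standard Frobenius multiplicative updates; eps guards 0/0
        U *= (V.T @ Y) / (V.T @ V @ U + _EPS)
        V *= (Y @ U.T) / (V @ (U @ U.T) + _EPS)
        obj = float(np.linalg.norm(Y - V @ U) ** 2)
        history.append(obj)
        if prev < np.inf and prev > 0 and (prev - obj) / prev < tol:
            break
        prev = obj

    # unit-max membership columns; scale moved into U rows
    col_max = V.max(axis=0)
    nz = col_max > 0
    V[:, nz] /= col_max[nz]
    U[nz, :] *= col_max[nz, None]

    err = float(np.linalg.norm(Y - V @ U))
    return NMFFactors(V=V, U=U, c=c, recon_error=err, objective_history=np.array(history))


@dataclass
class ReferenceCentroids:
    """Cached reference decomposition of the observed training target rows.

    The centroid matrix ``factors.U`` is the fixed reference compared against
    every generated mini-batch during training.  The cache key is a content
    fingerprint of the decomposed matrix plus the NMF settings, so changing
    the training data forces recomputation.
    """

    factors: NMFFactors
    fingerprint: tuple

    @property
    def U(self) -> np.ndarray:
        return self.factors.U


_REF_CACHE: dict[tuple, ReferenceCentroids] = {}


def _fingerprint(Y: np.ndarray, c: int, seed: int, max_iter: int, tol: float) -> tuple:
    Y = np.ascontiguousarray(Y)
    import hashlib

    h = hashlib.sha1(Y.tobytes()).hexdigest()
    return (h, Y.shape, c, seed, max_iter, tol)


def reference_centroids(
    Y_train: np.ndarray,
    c: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ReferenceCentroids:
    """Decompose the training target rows once and cache the centroids.

    After the multiplicative-update decomposition the centroids are re-fit by
    fixed-membership NNLS — the same estimator applied to every generated
    batch — so reference and batch centroids are directly comparable (in
    particular, a batch identical to the training data under the same seed
    yields exactly the reference centroids).
    """
    Y_train = _validate_nonneg(Y_train)
    key = _fingerprint(Y_train, c, seed, max_iter, tol)
    ref = _REF_CACHE.get(key)
    if ref is None:
        factors = nmf_decompose(Y_train, c, seed=seed, max_iter=max_iter, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            U_refit = refit_centroids(Y_train, factors.V)
        err = float(np.linalg.norm(Y_train - factors.V @ U_refit))
        factors = NMFFactors(
            V=factors.V, U=U_refit, c=c, recon_error=err,
            objective_history=factors.objective_history,
        )
        ref = ReferenceCentroids(factors=factors, fingerprint=key)
        _REF_CACHE[key] = ref
    return ref


def match_components(U_ref: np.ndarray, U_hat: np.ndarray) -> np.ndarray:
    """Optimal row alignment of two centroid matrices.

    Returns the permutation ``pi`` minimizing
    ``sum_i ||U_ref[i] - U_hat[pi[i]]||^2``, solved exactly by the Hungarian
    algorithm on the pairwise squared-distance matrix.
    """
    U_ref = np.asarray(U_ref, float)
    U_hat = np.asarray(U_hat, float)
    if U_ref.shape != U_hat.shape:
        raise ValueError(f"shape mismatch: {U_ref.shape} vs {U_hat.shape}")
    diff = U_ref[:, None, :] - U_hat[None, :, :]
    cost = np.einsum("ijk,ijk->ij", diff, diff)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


def refit_centroids(Y_hat: np.ndarray, V_hat: np.ndarray) -> np.ndarray:
    """Centroids for a batch under fixed memberships, by per-column NNLS.

    Solves ``U_hat = argmin_{U>=0} ||Y_hat - V_hat U||_F^2`` one target
    feature (column) at a time.  Unlike a fresh decomposition this map is
    piecewise linear in ``Y_hat``, which is what makes the centroid loss
    differentiable with respect to generated data.
    """
    Y_hat = np.asarray(Y_hat, float)
    V_hat = np.asarray(V_hat, float)
    b, q = Y_hat.shape
    if V_hat.shape[0] != b:
        raise ValueError("membership rows must match batch rows")
    c = V_hat.shape[1]
    dead = ~(V_hat > 0).any(axis=0)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} all-zero membership column(s); "
            "their centroid rows are returned as zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    U_hat = np.zeros((c, q))
    for j in range(q):
        U_hat[:, j], _ = nnls(V_hat, Y_hat[:, j])
    U_hat[dead, :] = 0.0
    return U_hat


def nmf_loss(
    U_ref: np.ndarray,
    Y_hat_batch: np.ndarray,
    c: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> float:
    """Centroid-consistency loss of a generated batch against the reference."""
    loss, _ = nmf_loss_and_grad(U_ref, Y_hat_batch, c, seed=seed, max_iter=max_iter, tol=tol)
    return loss


def nmf_loss_and_grad(
    U_ref: np.ndarray,
    Y_hat_batch: np.ndarray,
    c: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
    V_hat: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Centroid loss and its gradient with respect to the generated batch.

    Pipeline: decompose the (gradient-detached) batch to get memberships
    ``V_hat``; re-fit centroids ``U_hat`` by NNLS under fixed ``V_hat``; align
    ``U_hat`` rows to ``U_ref`` by optimal assignment; return the squared
    Frobenius distance ``||U_ref - U_hat[pi]||_F^2``.

    The gradient treats memberships, assignment, and the NNLS active set as
    constant at the solution: on the free (strictly positive) entries of each
    centroid column the NNLS solution is the linear map
    ``u_F = (V_F' V_F)^-1 V_F' y``, whose adjoint propagates the centroid-space
    gradient back to the batch.
    """
    U_ref = np.asarray(U_ref, float)
    Y_hat_batch = _validate_nonneg(Y_hat_batch)
    b, q = Y_hat_batch.shape
    if U_ref.shape != (c, q):
        raise ValueError(f"U_ref shape {U_ref.shape} inconsistent with c={c}, q={q}")
    if b < c:
        raise ValueError(
            f"batch of {b} rows is too small to estimate {c} centroids; "
            "use a batch size >= the cluster count"
        )

    if V_hat is None:
        factors = nmf_decompose(Y_hat_batch, c, seed=seed, max_iter=max_iter, tol=tol)
        V_hat = factors.V
    else:
        V_hat = np.asarray(V_hat, float)  # caller-supplied fixed memberships
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        U_hat = refit_centroids(Y_hat_batch, V_hat)
    perm = match_components(U_ref, U_hat)
    diff = U_hat[perm] - U_ref  # row i of U_ref matched to row perm[i] of U_hat
    loss = float(np.sum(diff * diff))

    # dL/dU_hat, undoing the permutation
    G_U = np.zeros_like(U_hat)
    G_U[perm] = 2.0 * diff

    grad = np.zeros_like(Y_hat_batch)
    gram = V_hat.T @ V_hat
    for j in range(q):
        free = U_hat[:, j] > 0
        if not free.any():
            continue
        Vf = V_hat[:, free]
        g = G_U[free, j]
        # adjoint of u_F = (Vf'Vf)^-1 Vf' y  ->  dL/dy = Vf (Vf'Vf)^-1 g
        sol = np.linalg.solve(gram[np.ix_(free, free)], g)
        grad[:, j] = Vf @ sol
    return loss, grad
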