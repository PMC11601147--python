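"""Regularised SVD pseudo-inversion and two-stage image reconstruction.

The system matrix is factorised once, ``P ~= U S V^T`` (economy SVD,
truncated to normalised singular values above ``sv_threshold``).  A
regularised reciprocal ``S+`` of the singular values — hard truncation
(TSVD) or the Tikhonov filter ``s / (s^2 + (alpha s_max)^2)`` — then yields
the pseudo-inverse ``P+ = V S+ U^T``, which is never materialised: images
are reconstructed by the cheap two-stage product

    R = V [ (S+ U^T) B ] .

Only ``stage1 = S+ U^T`` depends on the regulariser and its strength, so
``alpha`` can be changed at runtime without re-factorising.

Factorisation backends
----------------------
``lapack``
    LAPACK ``gesdd`` in double precision — exact; the default for matrices
    whose smaller dimension is at most 2048.
``gram``
    Deterministic normal-equations route for large matrices: the Gram
    matrix ``P^T P`` is accumulated in float64, eigendecomposed, and
    ``U = P V S^-1`` is formed in single precision.  Retained singular
    values are accurate down to ~1e-6 of the largest (the truncation
    default is 1e-4), but U-column orthonormality degrades towards the
    smallest retained values (roughly eps32 * s_max / s), so this backend
    is labelled approximate; reconstruction at practical regularisation
    strengths is unaffected.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .forward import SystemMatrix

logger = logging.getLogger("opusdmi")

#: matrices with min(shape) above this use the gram backend under "auto"
_LAPACK_MAX_MINDIM = 2048
#: gram backend cannot resolve singular values below the float32 noise floor
_GRAM_SV_FLOOR = 1e-7


class InversionError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# factorisation
# --------------------------------------------------------------------------

@dataclass
class SVDFactors:
    """Truncated economy SVD of a system matrix (single-precision storage)."""

    U: np.ndarray               # [m, n_svd] float32
    S: np.ndarray               # [n_svd] float32, descending
    V: np.ndarray               # [n, n_svd] float32
    sv_threshold: float
    provenance: str = ""
    backend: str = "lapack"
    matrix: SystemMatrix | None = None

    def __post_init__(self):
        if not (np.all(np.diff(self.S) <= 0) and np.all(self.S >= 0)):
            raise InversionError("singular values must be non-negative and "
                                 "non-increasing")
        if self.S.size and self.S[0] > 0 and \
                self.S[-1] < self.sv_threshold * self.S[0] * (1 - 1e-6):
            raise InversionError("truncation threshold not honoured")

    @property
    def rank(self) -> int:
        return self.S.size

    def orthonormality_defect(self, n_probe: int = 64) -> float:
        """Max deviation of probed U/V column Gram blocks from identity."""
        defect = 0.0
        for M in (self.U, self.V):
            step = max(1, M.shape[1] // n_probe)
            cols = np.asarray(M[:, ::step], np.float64)
            g = cols.T @ cols
            defect = max(defect, float(np.max(np.abs(
                g - np.eye(g.shape[0])))))
        return defect

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.provenance.encode())
        h.update(repr((self.sv_threshold, self.U.shape, self.backend))
                 .encode())
        return h.hexdigest()[:16]


def _as_entries(matrix):
    if isinstance(matrix, SystemMatrix):
        return matrix.entries, matrix
    return np.asarray(matrix), None


def _truncate(U, S, Vt, sv_threshold, floor=0.0):
    smax = S[0] if S.size else 0.0
    thr = max(sv_threshold, floor) * smax
    keep = S >= thr if thr > 0 else slice(None)
    return U[:, keep], S[keep], Vt[keep].T


def _decompose_lapack(entries, sv_threshold):
    U, S, Vt = scipy.linalg.svd(np.asarray(entries, np.float64),
                                full_matrices=False, lapack_driver="gesdd")
    U, S, V = _truncate(U, S, Vt, sv_threshold)
    return (np.asarray(U, np.float32), np.asarray(S, np.float32),
            np.asarray(V, np.float32))


def _decompose_gram(entries, sv_threshold):
    m, n = entries.shape
    transpose = m < n
    A = entries.T if transpose else entries
    A64 = np.asarray(A, np.float64)
    # K = A^T A via the BLAS rank-k update on the Fortran view (no copy);
    # only the lower triangle is filled, which eigh reads by default
    K = scipy.linalg.blas.dsyrk(1.0, A64.T, trans=0, lower=1)
    del A64
    w, vecs = scipy.linalg.eigh(K, lower=True, driver="evd",
                                overwrite_a=True, check_finite=False)
    del K
    w = w[::-1]
    vecs = vecs[:, ::-1]
    S = np.sqrt(np.maximum(w, 0.0))
    smax = S[0] if S.size else 0.0
    keep = S >= max(sv_threshold, _GRAM_SV_FLOOR) * smax
    S = S[keep]
    V = np.ascontiguousarray(vecs[:, keep])
    del vecs
    W = np.asarray(V / S[None, :], np.float32)
    U = np.asarray(A, np.float32) @ W
    del W
    V32 = np.asarray(V, np.float32)
    S32 = np.asarray(S, np.float32)
    if transpose:
        return V32, S32, np.asarray(U, np.float32)
    return np.asarray(U, np.float32), S32, V32


def decompose(matrix, sv_threshold: float = 1e-4,
              backend: str = "auto") -> SVDFactors:
    """Truncated economy SVD of the system matrix.

    The threshold applies to singular values normalised by the largest
    (``S/max(S)``); ties at the threshold are retained.  Deterministic for a
    fixed input under every backend.
    """
    entries, sm = _as_entries(matrix)
    if not (0 <= sv_threshold < 1):
        raise InversionError("sv_threshold must satisfy 0 <= t < 1")
    if not np.all(np.isfinite(entries)):
        raise InversionError("matrix contains non-finite entries")
    if backend == "auto":
        backend = "lapack" if min(entries.shape) <= _LAPACK_MAX_MINDIM \
            else "gram"
    t0 = time.time()
    if backend == "lapack":
        U, S, V = _decompose_lapack(entries, sv_threshold)
    elif backend == "gram":
        U, S, V = _decompose_gram(entries, sv_threshold)
    else:
        raise InversionError(f"unknown decomposition backend {backend!r}")
    logger.info("decompose[%s]: %s -> rank %d in %.1f s", backend,
                entries.shape, S.size, time.time() - t0)
    return SVDFactors(U=U, S=S, V=V, sv_threshold=sv_threshold,
                      provenance=sm.provenance_hash() if sm else "",
                      backend=backend, matrix=sm)


# --------------------------------------------------------------------------
# closed-form regularisation of the reciprocal singular values
# --------------------------------------------------------------------------

def regularize_tsvd(S, alpha: float) -> np.ndarray:
    """Truncated-SVD reciprocal: 1/s where s >= alpha * max(S), else 0.

    Ties at the threshold are kept (the comparison is >=).
    """
    if not (0 <= alpha <= 1):
        raise InversionError("TSVD alpha must satisfy 0 <= alpha <= 1")
    S = np.asarray(S, np.float64)
    if S.size == 0:
        return S.copy()
    thr = alpha * S.max()
    out = np.zeros_like(S)
    keep = (S >= thr) & (S > 0)
    out[keep] = 1.0 / S[keep]
    return out


def regularize_tikhonov(S, alpha: float) -> np.ndarray:
    """Tikhonov-filtered reciprocal: s / (s^2 + (alpha * max(S))^2)."""
    if alpha < 0:
        raise InversionError("Tikhonov alpha must be non-negative")
    S = np.asarray(S, np.float64)
    if S.size == 0:
        return S.copy()
    lam = alpha * S.max()
    denom = S ** 2 + lam ** 2
    out = np.zeros_like(S)
    nz = denom > 0
    out[nz] = S[nz] / denom[nz]
    return out


_REGULARIZERS = {"tsvd": regularize_tsvd, "tikhonov": regularize_tikhonov}


# --------------------------------------------------------------------------
# two-stage reconstruction operator
# --------------------------------------------------------------------------

@dataclass
class ReconstructionOperator:
    """Materialised two-stage pseudo-inverse: ``P+ b = stage2 (stage1 b)``.

    ``stage1 = S+ U^T`` (shape [n_svd, m]) carries the regularisation;
    ``stage2 = V`` (shape [n, n_svd]).  The full ``P+`` is never formed.
    """

    stage1: np.ndarray
    stage2: np.ndarray
    regularizer: str
    alpha: float
    provenance: str = ""
    matrix: SystemMatrix | None = None

    def __post_init__(self):
        if self.stage1.shape[0] != self.stage2.shape[1]:
            raise InversionError("stage1 rows must equal stage2 columns "
                                 "(the retained rank)")

    @property
    def rank(self) -> int:
        return self.stage1.shape[0]

    def apply(self, b_flat: np.ndarray) -> np.ndarray:
        """Two-stage product with float64 accumulation."""
        b = np.asarray(b_flat, np.float64).ravel()
        if b.size != self.stage1.shape[1]:
            raise InversionError(
                f"data length {b.size} != matrix rows {self.stage1.shape[1]}")
        y = _chunked_dot(self.stage1, b)
        return _chunked_dot(self.stage2, y)


def _chunked_dot(A, x, chunk: int = 2048) -> np.ndarray:
    """A @ x with the float32 operand promoted blockwise to float64."""
    out = np.empty(A.shape[0])
    for i in range(0, A.shape[0], chunk):
        out[i:i + chunk] = np.asarray(A[i:i + chunk], np.float64) @ x
    return out


def build_operator(factors: SVDFactors, regularizer: str = "tikhonov",
                   alpha: float = 0.01) -> ReconstructionOperator:
    """Materialise ``stage1 = S+ U^T`` for the chosen closed-form filter."""
    try:
        sdag = _REGULARIZERS[regularizer](factors.S, alpha)
    except KeyError:
        raise InversionError(f"unknown regulariser {regularizer!r}") from None
    stage1 = (np.asarray(sdag, np.float32)[:, None]
              * factors.U.T).astype(np.float32, copy=False)
    return ReconstructionOperator(stage1=stage1, stage2=factors.V,
                                  regularizer=regularizer, alpha=float(alpha),
                                  provenance=factors.provenance,
                                  matrix=factors.matrix)


def reconstruct(bscan, operator: ReconstructionOperator) -> np.ndarray:
    """Reconstruct a reflectivity image [n_z, n_x] from a B-scan.

    Refuses B-scans whose geometry/acquisition provenance disagrees with the
    operator's source matrix.
    """
    sm = operator.matrix
    if sm is None:
        raise InversionError("operator lacks matrix provenance; use "
                             "operator.apply for raw vectors")
    if bscan.acquisition.content_hash() != sm.acquisition.content_hash():
        raise InversionError("B-scan acquisition settings do not match the "
                             "operator's system matrix")
    if bscan.geometry is not None and \
            bscan.geometry.content_hash() != sm.geometry.content_hash():
        raise InversionError("B-scan geometry does not match the operator's "
                             "system matrix")
    vec = operator.apply(bscan.flatten())
    return sm.grid.image_from_vector(vec)
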