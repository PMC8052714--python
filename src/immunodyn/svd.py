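"""Singular value decomposition engine with early-stopping policies.

The inverse problem ``dx/dt = K a`` is massively underdetermined (50
equations, 28,605 unknowns); its minimum-norm least-squares solution is
``a = V S+ U^T dx/dt``.  The factorization here is the classic
Golub-Kahan-Reinsch procedure, written for very wide matrices:

1. the matrix is oriented tall (wide inputs are factored via their
   transpose) and reduced to an upper-bidiagonal ``B`` by alternating left
   and right Householder reflections;
2. implicit-shift QR sweeps drive the superdiagonal of ``B`` to zero while
   Givens rotations are accumulated into small square factors;
3. the accumulated orthogonal factors are assembled into economy-size
   ``U`` (one column per left singular vector) and ``Vt`` (one row per
   right singular vector).

Step 2 supports three stopping modes.  ``full_convergence`` is a standard
SVD.  ``max_sweeps`` stops after a fixed number of sweeps, zeroes
sub-tolerance off-diagonals and takes the diagonal as the singular values;
because only orthogonal transformations have been applied, the accumulated
factors with the *current* middle matrix still reproduce the input to
roundoff, but the diagonal-only reconstruction may not.  The default
``ill_conditioned_guard`` freezes any active block whose adjacent diagonal
entries are nearly equal — the regime of nearly equal singular values in
which further iteration is ill-conditioned — and converges the rest.
Early-stopped factorizations leave the left singular vectors partially
mixed (no longer a signed permutation in the structured case), which is the
mechanism that lets several biomarkers share activity in one mode.

Sign convention: every ``U`` column is flipped so that its
largest-magnitude component is positive (ties broken by lowest row index),
making factorizations reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StopPolicy",
    "SVDFactors",
    "SolutionVector",
    "QualityReport",
    "bidiagonalize",
    "svd_factorize",
    "pseudo_solve",
    "quality_check",
]


@dataclass(frozen=True)
class StopPolicy:
    """When to stop the implicit-shift QR iteration.

    mode
        ``full_convergence`` | ``max_sweeps`` | ``ill_conditioned_guard``.
    off_diagonal_tol
        relative tolerance below which a superdiagonal entry is declared
        zero (relative to the two adjacent diagonal entries).
    max_sweeps
        sweep budget for ``max_sweeps`` mode; also a safety cap for the
        other modes.
    near_equal_ratio
        ``ill_conditioned_guard``: a block is frozen when two adjacent
        diagonal entries differ by less than this relative ratio.
    """

    mode: str = "ill_conditioned_guard"
    off_diagonal_tol: float = 1e-12
    max_sweeps: int = 500
    near_equal_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if self.mode not in ("full_convergence", "max_sweeps",
                             "ill_conditioned_guard"):
            raise ValueError(f"unknown stop mode {self.mode!r}")
        if self.off_diagonal_tol <= 0 or self.near_equal_ratio <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_sweeps < 0:
            raise ValueError("max_sweeps must be >= 0")


@dataclass
class SVDFactors:
    """Economy-size factors ``K ~= U diag(sigma) Vt`` plus convergence data."""

    U: np.ndarray          # (m, r)
    sigma: np.ndarray      # (r,), non-negative, non-increasing
    Vt: np.ndarray         # (r, n)
    sweeps_used: int
    stopped_early: bool
    recon_error: float     # ||U S Vt - K||_F / ||K||_F
    policy: StopPolicy
    frozen_blocks: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SolutionVector:
    """Minimum-norm least-squares solution of ``K a = dxdt``."""

    a: np.ndarray
    rank_used: int
    residual: float        # ||K a - dxdt|| / ||dxdt||


def _householder(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Reflector (v, beta) with ``(I - beta v v^T) x = alpha e_0``."""
    alpha = -math.copysign(np.linalg.norm(x), x[0] if x[0] != 0 else 1.0)
    v = x.astype(float, copy=True)
    if alpha == 0.0:
        return v, 0.0, 0.0
    v[0] -= alpha
    vnorm2 = v @ v
    beta = 2.0 / vnorm2 if vnorm2 > 0 else 0.0
    return v, beta, alpha


def _bidiag_tall(A: np.ndarray):
    """Golub-Kahan reduction of tall ``A`` (m >= n) to upper bidiagonal.

    Returns the left reflectors (for deferred accumulation), the bidiagonal
    ``(d, e)`` and the accumulated right orthogonal factor ``V0`` (n x n).
    """
    A = A.astype(float, copy=True)
    m, n = A.shape
    d = np.zeros(n)
    e = np.zeros(max(n - 1, 0))
    left: list[tuple[np.ndarray, float]] = []
    V0 = np.eye(n)
    for k in range(n):
        v, beta, alpha = _householder(A[k:, k])
        left.append((v, beta))
        d[k] = alpha
        if beta != 0.0 and k + 1 < n:
            # support-aware application: reflector vectors are extremely
            # sparse for single-nonzero-column inputs (the pipeline's K)
            nz = np.flatnonzero(v)
            if nz.size < v.size // 4:
                rows = nz + k
                w = beta * (v[nz] @ A[rows, k + 1:])
                if np.any(w):
                    A[rows, k + 1:] -= np.outer(v[nz], w)
            else:
                w = beta * (v @ A[k:, k + 1:])
                A[k:, k + 1:] -= np.outer(v, w)
        if k < n - 1:
            if k < n - 2:
                vr, br, ar = _householder(A[k, k + 1:])
                e[k] = ar
                if br != 0.0:
                    w = br * (A[k + 1:, k + 1:] @ vr)
                    A[k + 1:, k + 1:] -= np.outer(w, vr)
                    V0[:, k + 1:] -= np.outer(V0[:, k + 1:] @ vr, br * vr)
            else:
                e[k] = A[k, k + 1]
    return left, d, e, V0


def _accumulate_left(left, m: int, top: np.ndarray) -> np.ndarray:
    """Form ``H_0 H_1 ... H_{n-1} [[top], [0]]`` without building U0."""
    n = len(left)
    Q = np.zeros((m, top.shape[1]))
    Q[:top.shape[0]] = top
    for k in range(n - 1, -1, -1):
        v, beta = left[k]
        if beta != 0.0:
            nz = np.flatnonzero(v)
            if nz.size < v.size // 4:
                rows = nz + k
                w = beta * (v[nz] @ Q[rows])
                Q[rows] -= np.outer(v[nz], w)
            else:
                w = beta * (v @ Q[k:])
                Q[k:] -= np.outer(v, w)
    return Q


def _givens(a: float, b: float) -> tuple[float, float]:
    """(c, s) such that ``c*a - s*b = r`` and ``s*a + c*b = 0``."""
    if b == 0.0:
        return 1.0, 0.0
    r = math.hypot(a, b)
    return a / r, -b / r


class _BidiagQR:
    """Implicit-shift QR on an upper-bidiagonal matrix with accumulation."""

    def __init__(self, d: np.ndarray, e: np.ndarray, policy: StopPolicy):
        self.n = d.size
        self.d = d.astype(float, copy=True)
        self.e = e.astype(float, copy=True)
        self.policy = policy
        self.Ub = np.eye(self.n)
        self.Vb = np.eye(self.n)
        self.sweeps = 0
        self.frozen: list[tuple[int, int]] = []
        self.converged = False

    def _apply(self, M: np.ndarray, i: int, j: int, c: float, s: float):
        """Columns (i, j) of M <- (col_i, col_j) @ [[c, s], [-s, c]]."""
        ci = M[:, i].copy()
        cj = M[:, j].copy()
        M[:, i] = c * ci - s * cj
        M[:, j] = s * ci + c * cj

    def _neglect(self) -> None:
        d, e = self.d, self.e
        tol = self.policy.off_diagonal_tol
        for i in range(self.n - 1):
            if abs(e[i]) <= tol * (abs(d[i]) + abs(d[i + 1])):
                e[i] = 0.0

    def _blocks(self) -> list[tuple[int, int]]:
        """Maximal ranges [lo, hi] with every interior superdiagonal != 0."""
        out = []
        lo = 0
        for i in range(self.n - 1):
            if self.e[i] == 0.0:
                if i > lo:
                    out.append((lo, i))
                lo = i + 1
        if self.n - 1 > lo:
            out.append((lo, self.n - 1))
        return out

    def _zero_diagonal_fix(self, lo: int, hi: int) -> bool:
        """If a diagonal entry vanishes, rotate its superdiagonal away."""
        d, e = self.d, self.e
        scale = float(np.max(np.abs(d[lo:hi + 1])) + np.max(np.abs(e[lo:hi])))
        for k in range(lo, hi):
            if abs(d[k]) <= 1e-15 * scale:
                d[k] = 0.0
                f = e[k]
                e[k] = 0.0
                for j in range(k + 1, hi + 1):
                    r = math.hypot(d[j], f)
                    if r == 0.0:
                        break
                    cj, sj = d[j] / r, f / r
                    d[j] = r
                    if j < hi:
                        f = -sj * e[j]
                        e[j] = cj * e[j]
                    # rows (j, k) of B mixed -> Ub columns (j, k)
                    Uj = self.Ub[:, j].copy()
                    Uk = self.Ub[:, k].copy()
                    self.Ub[:, j] = cj * Uj + sj * Uk
                    self.Ub[:, k] = -sj * Uj + cj * Uk
                return True
        return False

    def _sweep(self, lo: int, hi: int) -> None:
        d, e = self.d, self.e
        # Wilkinson shift from the trailing 2x2 of B^T B
        dm, dn = d[hi - 1], d[hi]
        em = e[hi - 1]
        emm = e[hi - 2] if hi - 1 > lo else 0.0
        t11 = dm * dm + emm * emm
        t22 = dn * dn + em * em
        t12 = dm * em
        if t12 == 0.0:
            mu = t22
        else:
            delta = (t11 - t22) / 2.0
            denom = delta + math.copysign(math.hypot(delta, t12),
                                          delta if delta != 0 else 1.0)
            mu = t22 - t12 * t12 / denom
        f = d[lo] * d[lo] - mu
        g = d[lo] * e[lo]
        for k in range(lo, hi):
            c, s = _givens(f, g)
            if k > lo:
                e[k - 1] = c * f - s * g
            f = c * d[k] - s * e[k]
            e[k] = s * d[k] + c * e[k]
            g = -s * d[k + 1]
            d[k + 1] = c * d[k + 1]
            self._apply(self.Vb, k, k + 1, c, s)
            c, s = _givens(f, g)
            d[k] = c * f - s * g
            f = c * e[k] - s * d[k + 1]
            d[k + 1] = s * e[k] + c * d[k + 1]
            if k < hi - 1:
                g = -s * e[k + 1]
                e[k + 1] = c * e[k + 1]
            self._apply(self.Ub, k, k + 1, c, s)
        e[hi - 1] = f

    def run(self) -> None:
        policy = self.policy
        cap = (policy.max_sweeps if policy.mode == "max_sweeps"
               else max(policy.max_sweeps, 30 * self.n))
        while True:
            self._neglect()
            blocks = self._blocks()
            active = []
            self.frozen = []
            for lo, hi in blocks:
                if policy.mode == "ill_conditioned_guard":
                    dd = np.abs(self.d[lo:hi + 1])
                    near = np.abs(np.diff(dd)) < (
                        policy.near_equal_ratio * np.maximum(dd[:-1], dd[1:]))
                    if np.any(near):
                        self.frozen.append((lo, hi))
                        continue
                active.append((lo, hi))
            if not active:
                self.converged = not self.frozen
                return
            if self.sweeps >= cap:
                self.converged = False
                return
            for lo, hi in active:
                if not self._zero_diagonal_fix(lo, hi):
                    self._sweep(lo, hi)
            self.sweeps += 1


def bidiagonalize(K: np.ndarray):
    """Factor ``K = U0 B V0^T`` with square bidiagonal ``B`` (side = rows).

    ``K`` must have no more rows than columns (the wide orientation used by
    the pipeline); the transpose is reduced by Householder reflections, so
    the returned ``B`` is lower bidiagonal.  Returns ``(U0, B, V0)`` with
    ``U0`` (m x m) orthogonal, ``B`` (m x m), ``V0`` (n x m) with
    orthonormal columns.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2:
        raise ValueError("K must be a matrix")
    if not np.all(np.isfinite(K)):
        raise ValueError("K has non-finite entries")
    m, n = K.shape
    if m > n:
        raise ValueError("bidiagonalize expects rows <= columns")
    left, d, e, V0_small = _bidiag_tall(K.T)
    B_upper = np.diag(d)
    if m > 1:
        B_upper[np.arange(m - 1), np.arange(1, m)] = e
    U0_tall = _accumulate_left(left, n, np.eye(m))
    # K^T = U0_tall B_upper V0_small^T  =>  K = V0_small B_upper^T U0_tall^T
    B = B_upper.T
    # sign-normalize the diagonal (fold flips into the right factor)
    signs = np.where(np.diag(B) < 0, -1.0, 1.0)
    B = B * signs                  # flip columns of lower-bidiagonal B
    U0_tall = U0_tall * signs      # and matching columns of the right factor
    return V0_small, B, U0_tall


def svd_factorize(K: np.ndarray, policy: StopPolicy | None = None,
                  compute_recon: bool = True) -> SVDFactors:
    """Factor ``K`` into economy-size singular factors under a stop policy."""
    if policy is None:
        policy = StopPolicy()
    K = np.asarray(K, dtype=float)
    if not np.all(np.isfinite(K)):
        raise ValueError("K has non-finite entries")
    m, n = K.shape
    transposed = m <= n        # pipeline orientation: wide input
    A = K.T if transposed else K
    left, d, e, V0 = _bidiag_tall(A)
    qr = _BidiagQR(d, e, policy)
    qr.run()
    r = min(m, n)
    sig = qr.d.copy()
    signs = np.where(sig < 0, -1.0, 1.0)
    sig = np.abs(sig)
    Ub = qr.Ub * signs                 # fold diagonal signs into tall-side U
    order = np.argsort(-sig, kind="stable")
    sig = sig[order]
    Ub = Ub[:, order]
    Vb = qr.Vb[:, order]
    U_tall = _accumulate_left(left, A.shape[0], Ub)
    V_small = V0 @ Vb
    if transposed:
        U, Vt = V_small, U_tall.T
    else:
        U, Vt = U_tall, V_small.T
    # deterministic sign convention on U columns
    lead = np.argmax(np.abs(U), axis=0)
    flip = np.where(U[lead, np.arange(r)] < 0, -1.0, 1.0)
    U = U * flip
    Vt = Vt * flip[:, None]
    stopped_early = not qr.converged
    normK = np.linalg.norm(K)
    if compute_recon:
        recon = (np.linalg.norm((U * sig) @ Vt - K) / normK
                 if normK > 0 else 0.0)
    else:
        # exact-arithmetic estimate: mass left outside the diagonal of B
        recon = float(np.linalg.norm(qr.e)) / normK if normK > 0 else 0.0
    return SVDFactors(U=U, sigma=sig, Vt=Vt, sweeps_used=qr.sweeps,
                      stopped_early=stopped_early, recon_error=float(recon),
                      policy=policy, frozen_blocks=list(qr.frozen))


def pseudo_solve(factors: SVDFactors, dxdt: np.ndarray,
                 rank_tol: float = 1e-12) -> SolutionVector:
    """Minimum-norm least-squares solution ``a = V S+ U^T dxdt``.

    Singular values below ``rank_tol * max(sigma)`` are treated as zero.
    With positive concentrations K generically has full row rank, so rank
    deficiency signals degenerate input.
    """
    dxdt = np.asarray(dxdt, dtype=float)
    if dxdt.shape != (factors.U.shape[0],):
        raise ValueError("dxdt length does not match factor row count")
    smax = float(factors.sigma[0]) if factors.sigma.size else 0.0
    if smax == 0.0:
        if np.linalg.norm(dxdt) > 0:
            raise np.linalg.LinAlgError(
                "all singular values are zero but dxdt is nonzero: "
                "unsolvable direction")
        keep = np.zeros(factors.sigma.shape, dtype=bool)
    else:
        keep = factors.sigma > rank_tol * smax
    coeff = np.zeros(factors.sigma.size)
    proj = factors.U.T @ dxdt
    coeff[keep] = proj[keep] / factors.sigma[keep]
    a = factors.Vt.T @ coeff
    pred = factors.U @ (factors.sigma * (factors.Vt @ a))
    nd = np.linalg.norm(dxdt)
    residual = float(np.linalg.norm(pred - dxdt) / nd) if nd > 0 else 0.0
    return SolutionVector(a=a, rank_used=int(keep.sum()), residual=residual)


@dataclass
class QualityReport:
    """Machine-precision back-computation check of a factorization+solve."""

    recon_error: float
    rate_residual: float
    stopped_early: bool
    recon_bound: float
    rate_bound: float
    passed: bool


def quality_check(factors: SVDFactors, solution: SolutionVector,
                  K: np.ndarray, dxdt: np.ndarray,
                  recon_bound: float = 1e-8,
                  rate_bound: float = 1e-6) -> QualityReport:
    """Back-compute the inputs from the results and compare.

    The factorization must reproduce ``K`` and, for fully converged runs,
    ``K a`` must reproduce ``dx/dt`` (relative to its norm).  Early-stopped
    runs report the achieved residuals without asserting the rate bound.
    """
    K = np.asarray(K, dtype=float)
    dxdt = np.asarray(dxdt, dtype=float)
    normK = np.linalg.norm(K)
    recon = (float(np.linalg.norm((factors.U * factors.sigma) @ factors.Vt
                                  - K) / normK) if normK > 0 else 0.0)
    nd = np.linalg.norm(dxdt)
    rate = (float(np.linalg.norm(K @ solution.a - dxdt) / nd)
            if nd > 0 else 0.0)
    ok = recon <= recon_bound
    if not factors.stopped_early:
        ok = ok and rate <= rate_bound
    return QualityReport(recon, rate, factors.stopped_early,
                         recon_bound, rate_bound, ok)
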