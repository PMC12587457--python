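"""FSAI-preconditioned Krylov solvers for the FEM systems.

The preconditioner is a factorized sparse approximate inverse (FSAI): a
sparse lower-triangular ``G`` with ``M^-1 = G^T G ~ A^-1``, so applying the
preconditioner costs two sparse matrix-vector products instead of two
triangular solves.  Per row ``i`` with pattern index set ``P_i`` (always
containing ``i``), the row is the solution of the dense local system
``A[P_i, P_i] y = e_last`` scaled by ``1/sqrt(y_last)`` -- the rows of the
exact inverse Cholesky factor restricted to the pattern.

Three patterns are provided (named after the solver they were tuned for):

``bicgstab3``
    Per row, the three largest-magnitude entries of the lower triangle
    including the diagonal (the diagonal is always forced in).
``pcg_diag4``
    The diagonal plus the four largest-magnitude strictly-lower entries.
``full_lower``
    The whole lower triangle of A: FSAI then reproduces the exact inverse
    Cholesky factor (useful for verification, dense-ish).

Real symmetric positive definite systems (CW, moments, time stepping, DCS)
are solved with preconditioned CG; complex symmetric frequency-domain
systems ``A + i w B`` with BiCGStab, preconditioned by the FSAI of the real
part.  Ties in the "largest values" selection are broken by the smaller
column index, so the construction is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

PATTERN_KINDS = ("bicgstab3", "pcg_diag4", "full_lower")


class SolverError(RuntimeError):
    """Krylov solver breakdown or non-convergence."""


@dataclass
class SolveInfo:
    """Per-column iteration counts and final true relative residuals."""

    iterations: np.ndarray
    residuals: np.ndarray
    converged: np.ndarray


@dataclass
class FsaiPreconditioner:
    """Sparse approximate inverse factor G with M^-1 v = G^T (G v)."""

    G: sparse.csr_matrix
    pattern_kind: str
    GT: sparse.csr_matrix = field(init=False, repr=False)

    def __post_init__(self):
        self.GT = self.G.T.tocsr()

    def apply(self, v: np.ndarray) -> np.ndarray:
        return self.GT @ (self.G @ v)


def _lookup_entries(A: sparse.csr_matrix, rows: np.ndarray,
                    cols: np.ndarray) -> np.ndarray:
    """Vectorized A[rows, cols] lookup on a CSR with sorted indices."""
    n = A.shape[0]
    row_of_entry = np.repeat(np.arange(n), np.diff(A.indptr))
    global_key = row_of_entry * n + A.indices
    want = rows.astype(np.int64) * n + cols.astype(np.int64)
    pos = np.searchsorted(global_key, want)
    pos = np.minimum(pos, len(global_key) - 1)
    vals = A.data[pos]
    return np.where(global_key[pos] == want, vals, 0.0)


def _pattern(A: sparse.csr_matrix, pattern_kind: str):
    """Row-wise FSAI pattern as (indptr, indices), diagonal always last."""
    n = A.shape[0]
    L = sparse.tril(A, 0).tocsr()
    L.sort_indices()
    rows = np.repeat(np.arange(n), np.diff(L.indptr))
    cols = L.indices
    vals = L.data

    if pattern_kind == "full_lower":
        # every lower-triangular position, not only structural nonzeros:
        # FSAI on the complete pattern reproduces the exact inverse Cholesky
        rows = np.repeat(np.arange(n), np.arange(1, n + 1))
        cols = np.concatenate([np.arange(i + 1) for i in range(n)])
        indptr = np.searchsorted(rows, np.arange(n + 1))
        return indptr, cols
    if pattern_kind in ("bicgstab3", "pcg_diag4"):
        if pattern_kind == "bicgstab3":
            cand = np.ones(len(cols), dtype=bool)
            m = 3
        else:
            cand = cols < rows
            m = 4
        order = np.lexsort((cols[cand], -np.abs(vals[cand]), rows[cand]))
        rsel = rows[cand][order]
        first = np.searchsorted(rsel, np.arange(n))
        rank = np.arange(len(rsel)) - first[rsel]
        keep = np.zeros(len(cols), dtype=bool)
        keep[np.flatnonzero(cand)[order[rank < m]]] = True
    else:
        raise ValueError(
            f"unknown pattern {pattern_kind!r}; use one of {PATTERN_KINDS}")
    keep[cols == rows] = True  # FSAI requires the diagonal
    rows, cols = rows[keep], cols[keep]
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    indptr = np.searchsorted(rows, np.arange(n + 1))
    return indptr, cols


def build_fsai(A: sparse.csr_matrix,
               pattern_kind: str = "pcg_diag4") -> FsaiPreconditioner:
    """Build the FSAI preconditioner of a symmetric positive definite A.

    Rows whose local pattern submatrix is singular (or not positive) fall
    back to the diagonal-only row ``1/sqrt(A[i,i])`` with a warning.
    """
    A = sparse.csr_matrix(A)
    A.sort_indices()
    n = A.shape[0]
    diag = A.diagonal()
    if np.any(diag <= 0):
        raise ValueError("FSAI requires a positive diagonal")
    indptr, cols = _pattern(A, pattern_kind)
    counts = np.diff(indptr)
    gvals = np.zeros(len(cols))
    fallback_rows: list[int] = []
    for k in np.unique(counts):
        sel = np.flatnonzero(counts == k)
        if k == 1:
            gvals[indptr[sel]] = 1.0 / np.sqrt(diag[sel])
            continue
        # (m, k) pattern columns per selected row; diagonal is the last one
        pat = cols[(indptr[sel][:, None] + np.arange(k)[None]).ravel()]
        pat = pat.reshape(len(sel), k)
        rr = np.repeat(pat, k, axis=1).ravel()
        cc = np.tile(pat, (1, k)).ravel()
        sub = _lookup_entries(A, rr, cc).reshape(len(sel), k, k)
        rhs = np.zeros((len(sel), k))
        rhs[:, -1] = 1.0
        try:
            y = np.linalg.solve(sub, rhs[..., None])[..., 0]
            bad = ~np.isfinite(y).all(axis=1) | (y[:, -1] <= 0)
        except np.linalg.LinAlgError:
            y = np.zeros((len(sel), k))
            bad = np.ones(len(sel), dtype=bool)
            for j in range(len(sel)):
                try:
                    y[j] = np.linalg.solve(sub[j], rhs[j])
                    bad[j] = not np.isfinite(y[j]).all() or y[j, -1] <= 0
                except np.linalg.LinAlgError:
                    pass
        good = ~bad
        scale = np.sqrt(np.where(good, y[:, -1], 1.0))
        yv = (y / scale[:, None])
        pos = (indptr[sel][:, None] + np.arange(k)[None])
        gvals[pos[good].ravel()] = yv[good].ravel()
        for j in np.flatnonzero(bad):
            i = sel[j]
            gvals[indptr[i]:indptr[i + 1]] = 0.0
            gvals[indptr[i + 1] - 1] = 1.0 / np.sqrt(diag[i])
            fallback_rows.append(int(i))
    if fallback_rows:
        warnings.warn(f"FSAI: {len(fallback_rows)} row(s) fell back to "
                      "diagonal-only (singular local system)", stacklevel=2)
    G = sparse.csr_matrix((gvals, cols, indptr), shape=(n, n))
    G.sort_indices()
    return FsaiPreconditioner(G=G, pattern_kind=pattern_kind)


def _as_columns(Q) -> np.ndarray:
    Q = Q.toarray() if sparse.issparse(Q) else np.asarray(Q)
    return Q.reshape(len(Q), -1)


def pcg_solve(A: sparse.csr_matrix, M: FsaiPreconditioner | None, Q,
              tol: float = 1e-12, maxit: int = 1000,
              x0: np.ndarray | None = None) -> tuple[np.ndarray, SolveInfo]:
    """Preconditioned conjugate gradients, one RHS column at a time.

    Converges when the (recurrence) relative residual drops below ``tol``;
    the reported residuals are recomputed as ``||A x - q|| / ||q||``.
    """
    Q = _as_columns(Q)
    n, ncol = Q.shape
    X = np.zeros((n, ncol))
    iters = np.zeros(ncol, dtype=int)
    resid = np.zeros(ncol)
    conv = np.ones(ncol, dtype=bool)
    for j in range(ncol):
        b = Q[:, j]
        bnorm = np.linalg.norm(b)
        if bnorm == 0.0:
            continue
        if x0 is None:
            x = np.zeros(n)
        else:
            x0a = np.asarray(x0, dtype=float)
            x = (x0a if x0a.ndim == 1 else x0a[:, j]).copy()
        r = b - A @ x if np.any(x) else b.copy()
        z = M.apply(r) if M is not None else r
        p = z.copy()
        rz = r @ z
        it = 0
        while np.linalg.norm(r) / bnorm > tol and it < maxit:
            Ap = A @ p
            curv = p @ Ap
            if curv <= 0:
                raise SolverError(f"PCG breakdown (non-positive curvature) "
                                  f"in column {j}")
            alpha = rz / curv
            x += alpha * p
            r -= alpha * Ap
            z = M.apply(r) if M is not None else r
            rz_new = r @ z
            p = z + (rz_new / rz) * p
            rz = rz_new
            it += 1
        X[:, j] = x
        iters[j] = it
        resid[j] = np.linalg.norm(b - A @ x) / bnorm
        conv[j] = resid[j] <= tol * 10
    return X, SolveInfo(iters, resid, conv)


def bicgstab_solve(Ac: sparse.spmatrix, M: FsaiPreconditioner | None, Q,
                   tol: float = 1e-12, maxit: int = 1000
                   ) -> tuple[np.ndarray, SolveInfo]:
    """Preconditioned BiCGStab for the complex symmetric FD system.

    The (real) FSAI preconditioner is applied to complex vectors
    component-wise.  A rho-breakdown triggers one restart from the current
    iterate before raising.
    """
    Q = _as_columns(Q)
    n, ncol = Q.shape
    X = np.zeros((n, ncol), dtype=complex)
    iters = np.zeros(ncol, dtype=int)
    resid = np.zeros(ncol)
    conv = np.ones(ncol, dtype=bool)

    def precond(v):
        if M is None:
            return v
        return M.apply(v.real) + 1j * M.apply(v.imag)

    for j in range(ncol):
        b = Q[:, j].astype(complex)
        bnorm = np.linalg.norm(b)
        if bnorm == 0.0:
            continue
        x = np.zeros(n, dtype=complex)
        it = 0
        restarted = False
        while True:
            r = b - Ac @ x
            r_hat = r.copy()
            rho = alpha = omega = 1.0 + 0j
            v = p = np.zeros(n, dtype=complex)
            broke = False
            while np.linalg.norm(r) / bnorm > tol and it < maxit:
                rho_new = np.vdot(r_hat, r)
                if rho_new == 0 or omega == 0:
                    broke = True
                    break
                beta = (rho_new / rho) * (alpha / omega)
                rho = rho_new
                p = r + beta * (p - omega * v)
                phat = precond(p)
                v = Ac @ phat
                denom = np.vdot(r_hat, v)
                if denom == 0:
                    broke = True
                    break
                alpha = rho / denom
                s = r - alpha * v
                if np.linalg.norm(s) / bnorm <= tol:
                    x = x + alpha * phat
                    r = s
                    it += 1
                    break
                shat = precond(s)
                t = Ac @ shat
                tt = np.vdot(t, t)
                omega = np.vdot(t, s) / tt if tt != 0 else 0.0
                x = x + alpha * phat + omega * shat
                r = s - omega * t
                it += 1
            if broke and not restarted:
                restarted = True
                continue
            if broke:
                raise SolverError(f"BiCGStab breakdown in column {j}")
            break
        X[:, j] = x
        iters[j] = it
        resid[j] = np.linalg.norm(b - Ac @ x) / bnorm
        conv[j] = resid[j] <= tol * 10
    return X, SolveInfo(iters, resid, conv)


def choose_solver(problem_kind: str) -> tuple[str, str]:
    """Automatic solver/pattern selection by problem kind.

    Frequency-domain problems (complex systems) use BiCGStab with the
    ``bicgstab3`` pattern; every real problem (CW, time stepping, moments,
    DCS) uses PCG with ``pcg_diag4``.
    """
    kinds = {"cw": ("pcg", "pcg_diag4"),
             "fd": ("bicgstab", "bicgstab3"),
             "tpsf": ("pcg", "pcg_diag4"),
             "moments": ("pcg", "pcg_diag4"),
             "dcs": ("pcg", "pcg_diag4")}
    try:
        return kinds[problem_kind]
    except KeyError:
        raise ValueError(f"unknown problem kind {problem_kind!r}; "
                         f"expected one of {sorted(kinds)}") from None


def solve_system(A, Q, problem_kind: str = "cw", tol: float = 1e-12,
                 maxit: int = 1000, precond: FsaiPreconditioner | None = None,
                 x0=None):
    """Convenience wrapper: pick solver, build FSAI, solve all columns."""
    solver, pattern = choose_solver(problem_kind)
    if precond is None:
        Areal = A.real.tocsr() if np.iscomplexobj(A.data) else A
        precond = build_fsai(Areal, pattern)
    if solver == "pcg":
        X, info = pcg_solve(A, precond, Q, tol=tol, maxit=maxit, x0=x0)
    else:
        X, info = bicgstab_solve(A, precond, Q, tol=tol, maxit=maxit)
    if not info.converged.all():
        bad = np.flatnonzero(~info.converged)
        warnings.warn(f"solver did not reach tol={tol:g} for column(s) "
                      f"{bad.tolist()} (residuals "
                      f"{info.residuals[bad]})", stacklevel=2)
    return X, info, precond
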