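"""Voxel-space adjoint Jacobians and Tikhonov reconstruction.

Sensitivities of boundary data to per-voxel optical parameters are
computed by the adjoint method: solve the direct fields Phi (sources) and
the adjoint fields Psi (detectors injected as sources, without the
one-scattering-length displacement), interpolate both into voxel space,
and form element-wise products:

* absorption block       ``dI/dmua_j    = -Phi_j Psi_j V``
* scattering block       ``dI/dmusp_j   = +3 kappa_j^2 grad(Phi)_j . grad(Psi)_j V``
  (the kappa chain rule ``dkappa/dmusp = -3 kappa^2`` applied to the
  stiffness sensitivity; gradients are the P1 per-element constants of
  the containing element)
* fluorescence yield     ``dI_m/dgamma_j = Phi^x_j Psi^m_j V / (1 + i w tau_j)``
* fluorescence lifetime  ``dI_m/dtau_j   = -i w gamma_j Phi^x_j Psi^m_j V / (1 + i w tau_j)^2``
  (identically zero at w=0, so the CW fluorescence Jacobian has only the
  real gamma block)
* DCS flow index         ``dG1(tau)/d(alphaDb)_j = -2 musp_j k0^2 tau Phi_j Psi_j V``

``V`` is the voxel volume, restricted to voxels inside the mesh.  With
``log_data=True`` (default for standard and DCS) rows are divided by the
channel's boundary value, giving d log(I) sensitivities; the fluorescence
default divides by the excitation boundary value (Born-ratio data).
Frequency-domain Jacobians interleave real and imaginary rows
(R, I, R, I, ...) with parameter blocks side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import (DcsOperator, assemble_fluorescence, assemble_standard,
                       build_source_vectors)
from .forward import boundary_data
from .grids import VoxelGrid
from .mesh import Mesh, MeshValidationError
from .solvers import build_fsai, choose_solver, pcg_solve, solve_system


@dataclass
class Jacobian:
    """Sensitivity matrix over inside voxels.

    ``matrix`` has one row per channel (two interleaved rows, real then
    imaginary, per channel in the frequency domain) and one block of
    ``grid.n_inside`` columns per entry of ``params``.
    """

    matrix: np.ndarray
    params: tuple[str, ...]
    grid: VoxelGrid
    link: np.ndarray
    log_data: bool = False
    omega: float = 0.0
    tau: float | None = None

    def block(self, param: str) -> np.ndarray:
        i = self.params.index(param)
        p = self.grid.n_inside
        return self.matrix[:, i * p:(i + 1) * p]

    def image(self, param: str, row: int) -> np.ndarray:
        """One channel's sensitivity map reshaped onto the grid."""
        return self.grid.as_image(self.block(param)[row])


def _adjoint_sources(mesh: Mesh):
    """Load vectors for the detectors (projected, not moved inside)."""
    det = mesh.optodes.detectors
    if len(det) == 0:
        raise MeshValidationError("mesh has no detectors")
    elem, w = mesh.locate(det, tol=1e-6)
    if np.any(elem == 0):
        raise MeshValidationError("detector outside the mesh")
    from scipy import sparse
    rows = mesh.elements0[elem - 1].ravel()
    cols = np.repeat(np.arange(len(det)), mesh.dim + 1)
    return sparse.coo_matrix((w.ravel(), (rows, cols)),
                             shape=(mesh.n_nodes, len(det))).tocsr()


def _element_gradients(mesh: Mesh, fields: np.ndarray) -> np.ndarray:
    """P1 gradients per element: (n_elements, dim, n_fields)."""
    from .assembly import _element_geometry
    _, grads = _element_geometry(mesh)  # (E, dim+1, dim)
    vals = fields[mesh.elements0]       # (E, dim+1, F)
    return np.einsum("evd,evf->edf", grads, vals)


def _voxel_fields(grid: VoxelGrid, nodal: np.ndarray) -> np.ndarray:
    return grid.project(nodal)[grid.inside_mask]


def _voxel_gradients(mesh: Mesh, grid: VoxelGrid, nodal: np.ndarray):
    egrad = _element_gradients(mesh, nodal)
    return egrad[grid.elem[grid.inside_mask] - 1]  # (n_inside, dim, F)


def _interleave_fd(rows_complex: np.ndarray) -> np.ndarray:
    out = np.empty((2 * rows_complex.shape[0], rows_complex.shape[1]))
    out[0::2] = rows_complex.real
    out[1::2] = rows_complex.imag
    return out


def jacobian_standard(mesh: Mesh, grid: VoxelGrid, omega: float = 0.0,
                      log_data: bool = True, tol: float = 1e-12,
                      maxit: int = 1000) -> Jacobian:
    """Standard-problem Jacobian with (mua, musp) blocks."""
    smat = assemble_standard(mesh)
    Q = build_source_vectors(mesh)
    Qd = _adjoint_sources(mesh)
    if omega == 0.0:
        pc = build_fsai(smat.A, choose_solver("cw")[1])
        phi, _ = pcg_solve(smat.A, pc, Q, tol=tol, maxit=maxit)
        psi, _ = pcg_solve(smat.A, pc, Qd, tol=tol, maxit=maxit)
    else:
        Ac = (smat.A + 1j * omega * smat.B).tocsr()
        pc = build_fsai(smat.A, choose_solver("fd")[1])
        phi, _, _ = solve_system(Ac, Q, "fd", tol=tol, maxit=maxit, precond=pc)
        psi, _, _ = solve_system(Ac, Qd, "fd", tol=tol, maxit=maxit, precond=pc)

    link = mesh.optodes.link
    vol = grid.voxel_volume
    phi_v = _voxel_fields(grid, phi)
    psi_v = _voxel_fields(grid, psi)
    gphi = _voxel_gradients(mesh, grid, phi)
    gpsi = _voxel_gradients(mesh, grid, psi)
    kappa_v = _voxel_fields(grid, mesh.props.kappa)

    si, di = link[:, 0] - 1, link[:, 1] - 1
    mua_rows = -(phi_v[:, si] * psi_v[:, di]).T * vol
    grad_dot = np.einsum("vds,vds->vs", gphi[:, :, si], gpsi[:, :, di])
    musp_rows = (3.0 * kappa_v**2)[:, None].T * grad_dot.T * vol
    rows = np.concatenate([mua_rows, musp_rows], axis=1)
    if log_data:
        bval = boundary_data(mesh, phi)
        if np.any(bval == 0):
            raise ZeroDivisionError("zero boundary value on a channel under "
                                    "the log-data option")
        rows = rows / bval[:, None]
    matrix = _interleave_fd(rows) if omega > 0 else np.real(rows)
    return Jacobian(matrix=matrix, params=("mua", "musp"), grid=grid,
                    link=link.copy(), log_data=log_data, omega=omega)


def jacobian_fluorescence(mesh: Mesh, grid: VoxelGrid, omega: float = 0.0,
                          born_ratio: bool = True, tol: float = 1e-12,
                          maxit: int = 1000) -> Jacobian:
    """Fluorescence Jacobian: gamma block (CW) or gamma+tau blocks (FD)."""
    sx, sm = assemble_fluorescence(mesh)
    Q = build_source_vectors(mesh)
    Qd = _adjoint_sources(mesh)
    gamma, tau = mesh.props.gamma, mesh.props.tau
    if omega == 0.0:
        pcx = build_fsai(sx.A, "pcg_diag4")
        pcm = build_fsai(sm.A, "pcg_diag4")
        phix, _ = pcg_solve(sx.A, pcx, Q, tol=tol, maxit=maxit)
        psim, _ = pcg_solve(sm.A, pcm, Qd, tol=tol, maxit=maxit)
    else:
        Axc = (sx.A + 1j * omega * sx.B).tocsr()
        Amc = (sm.A + 1j * omega * sm.B).tocsr()
        phix, _, _ = solve_system(Axc, Q, "fd", tol=tol, maxit=maxit,
                                  precond=build_fsai(sx.A, "bicgstab3"))
        psim, _, _ = solve_system(Amc, Qd, "fd", tol=tol, maxit=maxit,
                                  precond=build_fsai(sm.A, "bicgstab3"))
    link = mesh.optodes.link
    si, di = link[:, 0] - 1, link[:, 1] - 1
    vol = grid.voxel_volume
    phix_v = _voxel_fields(grid, phix)
    psim_v = _voxel_fields(grid, psim)
    prod = (phix_v[:, si] * psim_v[:, di]).T * vol  # (channels, voxels)
    if omega == 0.0:
        rows = prod
        params = ("gamma",)
    else:
        tau_v = _voxel_fields(grid, tau)
        gamma_v = _voxel_fields(grid, gamma)
        denom = 1.0 + 1j * omega * tau_v
        rows = np.concatenate(
            [prod / denom[None], prod * (-1j * omega * gamma_v / denom**2)[None]],
            axis=1)
        params = ("gamma", "tau")
    if born_ratio:
        bx = boundary_data(mesh, phix)
        if np.any(bx == 0):
            raise ZeroDivisionError("zero excitation boundary value")
        rows = rows / bx[:, None]
    matrix = _interleave_fd(rows) if omega > 0 else np.real(rows)
    return Jacobian(matrix=matrix, params=params, grid=grid,
                    link=link.copy(), log_data=born_ratio, omega=omega)


def jacobian_dcs(mesh: Mesh, grid: VoxelGrid, tau_vector,
                 log_data: bool = True, tol: float = 1e-12,
                 maxit: int = 1000) -> list[Jacobian]:
    """Per-delay alphaDb Jacobians of the DCS problem (log form default).

    The tau=0 entry yields the zero matrix (the chain-rule factor
    ``2 musp k0^2 tau`` vanishes).
    """
    tau_vector = np.asarray(tau_vector, dtype=float)
    if np.any(tau_vector < 0):
        raise ValueError("delays must be >= 0")
    op = DcsOperator(mesh)
    Q = build_source_vectors(mesh)
    Qd = _adjoint_sources(mesh)
    link = mesh.optodes.link
    si, di = link[:, 0] - 1, link[:, 1] - 1
    vol = grid.voxel_volume
    props = mesh.props
    musp_v = _voxel_fields(grid, props.musp)
    k0 = props.k0
    out = []
    phi_prev = psi_prev = None
    for tau in tau_vector:
        A_tau = op.at(float(tau))
        pc = build_fsai(A_tau, choose_solver("dcs")[1])
        phi, _ = pcg_solve(A_tau, pc, Q, tol=tol, maxit=maxit, x0=phi_prev)
        psi, _ = pcg_solve(A_tau, pc, Qd, tol=tol, maxit=maxit, x0=psi_prev)
        phi_prev, psi_prev = phi, psi
        phi_v = _voxel_fields(grid, phi)
        psi_v = _voxel_fields(grid, psi)
        scale = 2.0 * musp_v * k0**2 * float(tau)
        rows = -(phi_v[:, si] * psi_v[:, di]).T * scale[None] * vol
        if log_data:
            bval = boundary_data(mesh, phi)
            rows = rows / bval[:, None]
        out.append(Jacobian(matrix=rows, params=("alphaDb",), grid=grid,
                            link=link.copy(), log_data=log_data,
                            tau=float(tau)))
    return out


def tikhonov_reconstruct(J: Jacobian | np.ndarray, y: np.ndarray,
                         lam: float) -> np.ndarray:
    """Underdetermined Tikhonov update image.

    ``x = J^T (J J^T + lam * max(diag(J J^T)) I)^-1 y``; the regularizer is
    scaled by the largest diagonal of J J^T so that ``lam`` is unit-free.
    Returns the per-inside-voxel update vector (use ``grid.as_image`` for
    the masked picture).
    """
    if lam <= 0:
        raise ValueError("regularizer must be positive")
    mat = J.matrix if isinstance(J, Jacobian) else np.asarray(J)
    y = np.asarray(y, dtype=float)
    if mat.shape[0] != len(y):
        raise ValueError(f"J has {mat.shape[0]} rows but y has {len(y)}")
    JJt = mat @ mat.T
    scale = float(np.max(np.diag(JJt)))
    if scale == 0:
        return np.zeros(mat.shape[1])
    rhs = np.linalg.solve(JJt + lam * scale * np.eye(len(y)), y)
    return mat.T @ rhs
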