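"""Forward data engines: CW/FD fields, TPSFs, direct moments, and DCS.

All engines share the same pattern: assemble the FEM operators, build the
point-source load matrix Q, solve with the automatically selected
FSAI-preconditioned Krylov solver, and read out boundary data by
barycentric interpolation of the nodal field at the projected detector
points, in the order of the channel link table.

Time-resolved data come in two flavors:

* ``femdata_tpsf_*`` -- theta-scheme time stepping (Crank-Nicolson by
  default, with two backward-Euler half-step startup steps to damp the
  impulsive initial condition) of ``B dPhi/dt + A Phi = 0`` launched from
  the mass-consistent impulse ``B Phi0 = Q``.
* ``moments_*`` -- direct Mellin-transform moments: each order is one
  extra linear solve, ``m0 = A^-1 Q`` (the CW field) and
  ``m_n = n A^-1 (B m_{n-1})``.  For fluorescence the re-emission chain
  carries the extra source recursion ``s_n = gamma .* m_n^x + n tau .* s_{n-1}``
  and ``m_n^m = (A^m)^-1 (n B^m m_{n-1}^m + U s_n)``.

The DCS engine sweeps the delay time of the correlation-diffusion operator
``A(tau) = A(0) + tau * M_dyn`` and normalizes boundary G1 curves by their
tau=0 (CW) value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .assembly import (DcsOperator, SystemMatrices, assemble_fluorescence,
                       assemble_standard, build_source_vectors)
from .mesh import Mesh, MeshValidationError
from .solvers import build_fsai, choose_solver, pcg_solve, solve_system

#: mesh size below which time stepping uses a direct sparse LU of the
#: constant step operator instead of iterating per step
_DIRECT_STEP_LIMIT = 20000


# ---------------------------------------------------------------------------
# result containers

@dataclass
class FieldData:
    """Nodal fluence and boundary channel data of a CW/FD solve."""

    phi: np.ndarray              # (n_nodes, n_sources)
    boundary: np.ndarray         # (n_channels,), complex for FD
    omega: float
    link: np.ndarray
    phi_grid: np.ndarray | None = None


@dataclass
class TpsfData:
    """Temporal point spread functions per channel on a uniform time grid."""

    time: np.ndarray             # (n_t,), s
    curves: np.ndarray           # (n_channels, n_t)
    link: np.ndarray
    curves_grid: np.ndarray | None = None

    def moments(self, max_order: int = 2) -> np.ndarray:
        """Trapezoid moments of the curves: row n holds <t^n> (n=0 raw)."""
        out = np.empty((max_order + 1, len(self.curves)))
        out[0] = np.trapezoid(self.curves, self.time, axis=1)
        for n in range(1, max_order + 1):
            out[n] = np.trapezoid(self.curves * self.time**n, self.time,
                                  axis=1) / out[0]
        return out


@dataclass
class MomentsData:
    """Mellin-transform moments: nodal fields and boundary values."""

    mellin_fields: list[np.ndarray]      # per order: (n_nodes, n_sources)
    mellin_boundary: np.ndarray          # (K+1, n_channels), unnormalized
    normalized: np.ndarray               # row 0: <t0>; row n: <t^n>
    link: np.ndarray
    fields_grid: list[np.ndarray] | None = None

    @property
    def mean_time(self) -> np.ndarray:
        return self.normalized[1]

    @property
    def variance(self) -> np.ndarray:
        return self.normalized[2] - self.normalized[1] ** 2


@dataclass
class G1Data:
    """Electric-field autocorrelation curves per channel."""

    tau_vector: np.ndarray
    G1: np.ndarray               # (n_channels, n_tau)
    g1: np.ndarray               # normalized by the tau=0 value per channel
    link: np.ndarray
    G1_grid: np.ndarray | None = None


# ---------------------------------------------------------------------------
# helpers

def _detector_readout(mesh: Mesh):
    """(elem0, weights) of each detector for barycentric interpolation."""
    det = mesh.optodes.detectors
    if len(det) == 0:
        raise MeshValidationError("mesh has no detectors")
    elem, w = mesh.locate(det, tol=1e-6)
    if np.any(elem == 0):
        bad = np.flatnonzero(elem == 0) + 1
        raise MeshValidationError(f"detector(s) {bad.tolist()} outside the mesh")
    return mesh.elements0[elem - 1], w


def boundary_data(mesh: Mesh, phi: np.ndarray) -> np.ndarray:
    """Per-channel boundary values: field of the linked source at the
    linked detector, in link-table order."""
    link = mesh.optodes.link
    if len(link) == 0:
        raise MeshValidationError("mesh has no channel link table")
    enodes, w = _detector_readout(mesh)
    det_vals = np.einsum("dv,dvs->ds", w, phi[enodes])  # (n_det, n_src)
    return det_vals[link[:, 1] - 1, link[:, 0] - 1]


def _maybe_grid(grid, phi):
    return None if grid is None else grid.project(phi)


# ---------------------------------------------------------------------------
# CW / FD

def femdata_standard(mesh: Mesh, omega: float = 0.0, grid=None,
                     tol: float = 1e-12, maxit: int = 1000,
                     smat: SystemMatrices | None = None) -> FieldData:
    """CW (omega=0) or frequency-domain fluence and boundary data."""
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if smat is None:
        smat = assemble_standard(mesh)
    Q = build_source_vectors(mesh)
    if omega == 0.0:
        phi, _, _ = solve_system(smat.A, Q, "cw", tol=tol, maxit=maxit)
    else:
        Ac = (smat.A + 1j * omega * smat.B).tocsr()
        precond = build_fsai(smat.A, choose_solver("fd")[1])
        phi, _, _ = solve_system(Ac, Q, "fd", tol=tol, maxit=maxit,
                                 precond=precond)
    return FieldData(phi=phi, boundary=boundary_data(mesh, phi), omega=omega,
                     link=mesh.optodes.link.copy(),
                     phi_grid=_maybe_grid(grid, phi))


def femdata_fluorescence(mesh: Mesh, omega: float = 0.0, grid=None,
                         tol: float = 1e-12, maxit: int = 1000):
    """Coupled excitation/re-emission solve.

    Returns ``(data_x, data_m, born_ratio)`` where the Born ratio is the
    re-emission boundary value divided by the excitation boundary value,
    per channel (the default reported fluorescence quantity).
    """
    sx, sm = assemble_fluorescence(mesh)
    Q = build_source_vectors(mesh)
    gamma, tau = mesh.props.gamma, mesh.props.tau
    kind = "cw" if omega == 0.0 else "fd"
    if omega == 0.0:
        phix, _, _ = solve_system(sx.A, Q, "cw", tol=tol, maxit=maxit)
        qm = sx.U @ (gamma[:, None] * phix)
        phim, _, _ = solve_system(sm.A, qm, "cw", tol=tol, maxit=maxit)
    else:
        Axc = (sx.A + 1j * omega * sx.B).tocsr()
        phix, _, _ = solve_system(Axc, Q, kind, tol=tol, maxit=maxit,
                                  precond=build_fsai(sx.A, "bicgstab3"))
        phitilde = gamma[:, None] * phix / (1.0 + 1j * omega * tau)[:, None]
        qm = sx.U @ phitilde
        Amc = (sm.A + 1j * omega * sm.B).tocsr()
        phim, _, _ = solve_system(Amc, qm, kind, tol=tol, maxit=maxit,
                                  precond=build_fsai(sm.A, "bicgstab3"))
    bx = boundary_data(mesh, phix)
    bm = boundary_data(mesh, phim)
    link = mesh.optodes.link.copy()
    data_x = FieldData(phix, bx, omega, link, _maybe_grid(grid, phix))
    data_m = FieldData(phim, bm, omega, link, _maybe_grid(grid, phim))
    with np.errstate(divide="ignore", invalid="ignore"):
        born = bm / bx
    return data_x, data_m, born


# ---------------------------------------------------------------------------
# time stepping

class _ThetaStepper:
    """Constant-step theta scheme for B dPhi/dt + A Phi = S(t).

    One operator factorization (small meshes: sparse LU; large meshes: one
    FSAI preconditioner) is reused across all steps.
    """

    def __init__(self, A, B, dt: float, theta: float, tol: float, maxit: int):
        self.A, self.B, self.dt, self.theta = A, B, dt, theta
        self.tol, self.maxit = tol, maxit
        self.lhs = (B / dt + theta * A).tocsr()
        self.rhs_op = (B / dt - (1.0 - theta) * A).tocsr()
        if A.shape[0] <= _DIRECT_STEP_LIMIT:
            self._lu = splu(self.lhs.tocsc())
            self._pc = None
        else:
            self._lu = None
            self._pc = build_fsai(self.lhs, choose_solver("tpsf")[1])

    def solve(self, rhs: np.ndarray, x0=None) -> np.ndarray:
        if self._lu is not None:
            return self._lu.solve(rhs)
        x, _ = pcg_solve(self.lhs, self._pc, rhs, tol=self.tol,
                         maxit=self.maxit, x0=x0)
        return x

    def step(self, phi: np.ndarray, s_mid: np.ndarray | None = None):
        rhs = self.rhs_op @ phi
        if s_mid is not None:
            rhs = rhs + s_mid
        return self.solve(rhs, x0=phi)


def _time_grid(t_end: float, dt: float) -> np.ndarray:
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    n_steps = int(round(t_end / dt))
    if abs(n_steps * dt - t_end) > 1e-9 * t_end:
        raise ValueError("t_end must be an integer multiple of dt")
    return np.arange(n_steps + 1) * dt


def _mass_consistent_impulse(smat: SystemMatrices, Q, tol, maxit) -> np.ndarray:
    """Phi(0+) solving B Phi0 = Q (impulse launched into the mass matrix)."""
    pc = build_fsai(smat.B.tocsr(), "pcg_diag4")
    phi0, _ = pcg_solve(smat.B.tocsr(), pc, Q, tol=tol, maxit=maxit)
    return phi0


def femdata_tpsf_standard(mesh: Mesh, t_end: float, dt: float, grid=None,
                          theta: float = 0.5, tol: float = 1e-12,
                          maxit: int = 1000,
                          smat: SystemMatrices | None = None) -> TpsfData:
    """Boundary TPSFs by theta-scheme stepping of the standard problem.

    The first step is replaced by two backward-Euler half steps
    (Rannacher startup) so the impulsive start does not ring through the
    Crank-Nicolson scheme.
    """
    if smat is None:
        smat = assemble_standard(mesh)
    Q = build_source_vectors(mesh)
    time = _time_grid(t_end, dt)
    phi = _mass_consistent_impulse(smat, Q, tol, maxit)
    enodes, w = _detector_readout(mesh)
    link = mesh.optodes.link
    curves = np.empty((len(link), len(time)))
    grids = [] if grid is not None else None

    def record(k, phi_k):
        det_vals = np.einsum("dv,dvs->ds", w, phi_k[enodes])
        curves[:, k] = det_vals[link[:, 1] - 1, link[:, 0] - 1]
        if grids is not None:
            grids.append(grid.project(phi_k))

    record(0, phi)
    startup = _ThetaStepper(smat.A, smat.B, dt / 2.0, 1.0, tol, maxit)
    phi = startup.step(startup.step(phi))
    record(1, phi)
    stepper = _ThetaStepper(smat.A, smat.B, dt, theta, tol, maxit)
    # theta >= 1/2 is unconditionally stable for the SPD pencil (A, B);
    # explicit-leaning schemes are monitored for energy growth
    energy = float(phi[:, 0] @ (smat.B @ phi[:, 0])) if theta < 0.5 else None
    for k in range(2, len(time)):
        phi = stepper.step(phi)
        record(k, phi)
        if energy is not None and k % 10 == 0:
            e_now = float(phi[:, 0] @ (smat.B @ phi[:, 0]))
            if e_now > energy * (1 + 1e-9):
                raise RuntimeError(
                    "time stepping is unstable (energy growth); reduce dt "
                    "or use theta >= 0.5")
            energy = e_now
    return TpsfData(time=time, curves=curves, link=link.copy(),
                    curves_grid=np.stack(grids, axis=-1) if grids else None)


def femdata_tpsf_fluorescence(mesh: Mesh, t_end: float, dt: float, grid=None,
                              theta: float = 0.5, tol: float = 1e-12,
                              maxit: int = 1000):
    """Excitation and re-emission TPSFs of a fluorescence mesh.

    The excitation field is stepped as in the standard problem; the
    re-emission source is the running exponential convolution
    ``w_{k+1} = w_k e^(-dt/tau) + (gamma .* Phi^x_{k+1})(1 - e^(-dt/tau))``
    (instantaneous re-emission where tau=0) applied through the overlap
    matrix U, and the emission field is stepped with that source.
    """
    sx, sm = assemble_fluorescence(mesh)
    Q = build_source_vectors(mesh)
    gamma, tau = mesh.props.gamma, mesh.props.tau
    time = _time_grid(t_end, dt)
    enodes, wdet = _detector_readout(mesh)
    link = mesh.optodes.link

    def record(curves, k, phi_k):
        det_vals = np.einsum("dv,dvs->ds", wdet, phi_k[enodes])
        curves[:, k] = det_vals[link[:, 1] - 1, link[:, 0] - 1]

    curves_x = np.empty((len(link), len(time)))
    curves_m = np.empty((len(link), len(time)))
    grids_x = [] if grid is not None else None
    grids_m = [] if grid is not None else None

    phix = _mass_consistent_impulse(sx, Q, tol, maxit)
    inst = tau <= 0

    def decay_factor(step: float) -> np.ndarray:
        return np.where(inst, 0.0, np.exp(-step / np.where(inst, 1.0, tau)))

    def convolve(wconv, phix_new, decay):
        new = wconv * decay[:, None] + (gamma[:, None] * phix_new
                                        ) * (1.0 - decay)[:, None]
        if np.any(inst):
            new[inst] = gamma[inst, None] * phix_new[inst]
        return new

    decay_full = decay_factor(dt)
    decay_half = decay_factor(dt / 2.0)
    wconv = convolve(np.zeros_like(phix), phix, decay_full)
    phim = np.zeros_like(phix)

    def record_all(k):
        record(curves_x, k, phix)
        record(curves_m, k, phim)
        if grids_x is not None:
            grids_x.append(grid.project(phix))
            grids_m.append(grid.project(phim))

    record_all(0)
    # startup: two backward-Euler half steps for the excitation field
    sx_start = _ThetaStepper(sx.A, sx.B, dt / 2.0, 1.0, tol, maxit)
    sm_start = _ThetaStepper(sm.A, sm.B, dt / 2.0, 1.0, tol, maxit)
    for _ in range(2):
        phix = sx_start.step(phix)
        w_new = convolve(wconv, phix, decay_half)
        phim = sm_start.step(phim, sm.U @ w_new)
        wconv = w_new
    record_all(1)
    sx_step = _ThetaStepper(sx.A, sx.B, dt, theta, tol, maxit)
    sm_step = _ThetaStepper(sm.A, sm.B, dt, theta, tol, maxit)
    for k in range(2, len(time)):
        phix = sx_step.step(phix)
        w_new = convolve(wconv, phix, decay_full)
        phim = sm_step.step(phim, sm.U @ (theta * w_new + (1 - theta) * wconv))
        wconv = w_new
        record_all(k)
    return (TpsfData(time, curves_x, link.copy(),
                     np.stack(grids_x, axis=-1) if grids_x else None),
            TpsfData(time, curves_m, link.copy(),
                     np.stack(grids_m, axis=-1) if grids_m else None))


# ---------------------------------------------------------------------------
# direct moments

def _normalize_moments(mellin_boundary: np.ndarray) -> np.ndarray:
    normalized = mellin_boundary.copy()
    normalized[1:] /= mellin_boundary[0]
    return normalized


def moments_standard(mesh: Mesh, max_order: int = 2, grid=None,
                     tol: float = 1e-12, maxit: int = 1000,
                     smat: SystemMatrices | None = None) -> MomentsData:
    """Mellin moments of the standard problem, one solve per order."""
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    if smat is None:
        smat = assemble_standard(mesh)
    Q = build_source_vectors(mesh)
    pc = build_fsai(smat.A, choose_solver("moments")[1])
    fields = []
    m_prev = None
    for n in range(max_order + 1):
        rhs = Q if n == 0 else n * (smat.B @ m_prev)
        m_n, _ = pcg_solve(smat.A, pc, rhs, tol=tol, maxit=maxit, x0=m_prev)
        fields.append(m_n)
        m_prev = m_n
    mellin_b = np.stack([boundary_data(mesh, f) for f in fields])
    return MomentsData(
        mellin_fields=fields, mellin_boundary=mellin_b,
        normalized=_normalize_moments(mellin_b), link=mesh.optodes.link.copy(),
        fields_grid=[_maybe_grid(grid, f) for f in fields] if grid else None)


def moments_fluorescence(mesh: Mesh, max_order: int = 2, grid=None,
                         tol: float = 1e-12, maxit: int = 1000):
    """Mellin moments of excitation and re-emission fields.

    Implements the coupled recursion: ``m0x = (Ax)^-1 Q``,
    ``s0 = gamma .* m0x``, ``m0m = (Am)^-1 U s0`` and for n >= 1
    ``mnx = n (Ax)^-1 Bx m_{n-1}^x``,
    ``sn = gamma .* mnx + n (tau .* s_{n-1})``,
    ``mnm = (Am)^-1 (n Bm m_{n-1}^m + U sn)``.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    sx, sm = assemble_fluorescence(mesh)
    Q = build_source_vectors(mesh)
    gamma, tau = mesh.props.gamma, mesh.props.tau
    pcx = build_fsai(sx.A, "pcg_diag4")
    pcm = build_fsai(sm.A, "pcg_diag4")
    fx, fm = [], []
    m_x, _ = pcg_solve(sx.A, pcx, Q, tol=tol, maxit=maxit)
    s_n = gamma[:, None] * m_x
    m_m, _ = pcg_solve(sm.A, pcm, sm.U @ s_n, tol=tol, maxit=maxit)
    fx.append(m_x)
    fm.append(m_m)
    for n in range(1, max_order + 1):
        m_x, _ = pcg_solve(sx.A, pcx, n * (sx.B @ fx[-1]), tol=tol,
                           maxit=maxit, x0=fx[-1])
        s_n = gamma[:, None] * m_x + n * tau[:, None] * s_n
        m_m, _ = pcg_solve(sm.A, pcm, n * (sm.B @ fm[-1]) + sm.U @ s_n,
                           tol=tol, maxit=maxit, x0=fm[-1])
        fx.append(m_x)
        fm.append(m_m)
    link = mesh.optodes.link.copy()
    bx = np.stack([boundary_data(mesh, f) for f in fx])
    bm = np.stack([boundary_data(mesh, f) for f in fm])
    if np.any(bm[0] == 0):
        raise MeshValidationError("zero re-emission intensity on a channel "
                                  "(degenerate moment normalization)")
    mk = dict(link=link)
    data_x = MomentsData(fx, bx, _normalize_moments(bx), **mk,
                         fields_grid=[_maybe_grid(grid, f) for f in fx]
                         if grid else None)
    data_m = MomentsData(fm, bm, _normalize_moments(bm), **mk,
                         fields_grid=[_maybe_grid(grid, f) for f in fm]
                         if grid else None)
    return data_x, data_m


# ---------------------------------------------------------------------------
# DCS

def femdata_dcs(mesh: Mesh, tau_vector, grid=None, tol: float = 1e-12,
                maxit: int = 1000) -> G1Data:
    """G1(tau)/g1(tau) curves by sweeping the correlation-diffusion operator.

    ``tau_vector`` must be sorted ascending and start at 0 (the CW solve
    used for normalization).  Each delay reuses the previous solution as
    the warm start; the FSAI preconditioner is rebuilt per delay (cheap,
    vectorized) because the operator's diagonal grows with tau.
    """
    tau_vector = np.asarray(tau_vector, dtype=float)
    if tau_vector.ndim != 1 or len(tau_vector) == 0:
        raise ValueError("tau_vector must be a non-empty 1D array")
    if tau_vector[0] != 0.0 or np.any(np.diff(tau_vector) <= 0):
        raise ValueError("tau_vector must start at 0 and increase strictly")
    op = DcsOperator(mesh)
    Q = build_source_vectors(mesh)
    _, pattern = choose_solver("dcs")
    link = mesh.optodes.link
    G1 = np.empty((len(link), len(tau_vector)))
    grids = [] if grid is not None else None
    phi_prev = None
    for i, tau in enumerate(tau_vector):
        A_tau = op.at(tau)
        pc = build_fsai(A_tau, pattern)
        phi, _ = pcg_solve(A_tau, pc, Q, tol=tol, maxit=maxit, x0=phi_prev)
        G1[:, i] = boundary_data(mesh, phi)
        if grids is not None:
            grids.append(grid.project(phi))
        phi_prev = phi
    g1 = G1 / G1[:, :1]
    return G1Data(tau_vector=tau_vector, G1=G1, g1=g1, link=link.copy(),
                  G1_grid=np.stack(grids, axis=-1) if grids else None)
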