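"""Sparse FEM operators for the diffusion and correlation-diffusion models.

For linear (P1) elements on simplices, the frequency-domain diffusion
equation discretizes into the complex-symmetric system ``(A + i w B) Phi = Q``
with

* ``A = K(kappa) + M(mua) + (1/(2 beta)) * M_boundary`` -- the
  kappa-weighted stiffness matrix, the mua-weighted mass matrix, and the
  surface mass matrix from the Robin boundary condition
  ``Phi + 2 beta kappa dPhi/dnu = 0``;
* ``B = M(1/c)`` -- the mass matrix weighted by the inverse speed of light;
* ``U`` -- the unweighted basis-overlap (mass) matrix, used to project
  nodal source densities (fluorescence re-emission) into FEM load vectors.

Per-element weighted integrals use the element mean of the nodal property
values, the standard lowest-order choice consistent with P1 accuracy.

The DCS (correlation-diffusion) operator is ``A(tau) = A(0) + tau * M_dyn``
with ``M_dyn = M(2 * alphaDb * musp * k0^2)``; :class:`DcsOperator` caches
``A(0)`` and ``M_dyn`` so sweeping the delay time is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .analytical import boundary_beta
from .mesh import DcsProps, Mesh, MeshValidationError, StandardProps


@dataclass
class SystemMatrices:
    """Assembled FEM operators of one wavelength block."""

    A: sparse.csr_matrix
    B: sparse.csr_matrix
    U: sparse.csr_matrix
    beta_boundary: float

    @property
    def n(self) -> int:
        return self.A.shape[0]


def _element_geometry(mesh: Mesh):
    """Element volumes and constant P1 basis gradients.

    Returns ``(vol, grads)`` with ``grads`` of shape (E, dim+1, dim): the
    gradient of each vertex basis function, constant per element.
    """
    v = mesh.nodes[mesh.elements0]  # (E, dim+1, dim)
    d = mesh.dim
    t = v[:, 1:] - v[:, :1]  # (E, dim, dim) rows = edge vectors
    vol = np.abs(np.linalg.det(t)) / (2.0 if d == 2 else 6.0)
    tinv = np.linalg.inv(t)  # columns map to barycentric gradients
    grads_rest = np.swapaxes(tinv, 1, 2)  # (E, dim, dim): grad of w_1..w_d
    grads0 = -grads_rest.sum(axis=1, keepdims=True)
    return vol, np.concatenate([grads0, grads_rest], axis=1)


def _accumulate(mesh: Mesh, local: np.ndarray) -> sparse.csr_matrix:
    """Assemble per-element (E, k, k) local matrices into global CSR."""
    e0 = mesh.elements0
    k = e0.shape[1]
    rows = np.repeat(e0, k, axis=1).ravel()
    cols = np.tile(e0, (1, k)).ravel()
    mat = sparse.coo_matrix((local.ravel(), (rows, cols)),
                            shape=(mesh.n_nodes, mesh.n_nodes))
    out = mat.tocsr()
    out.sum_duplicates()
    out.sort_indices()
    return out


def stiffness_matrix(mesh: Mesh, coeff) -> sparse.csr_matrix:
    """Stiffness matrix with element-mean coefficient weighting."""
    vol, grads = _element_geometry(mesh)
    cbar = np.asarray(coeff)[mesh.elements0].mean(axis=1)
    local = np.einsum("e,eid,ejd->eij", cbar * vol, grads, grads)
    return _accumulate(mesh, local)


def mass_matrix(mesh: Mesh, coeff=None) -> sparse.csr_matrix:
    """Mass matrix, optionally weighted by the element-mean of ``coeff``."""
    vol, _ = _element_geometry(mesh)
    d = mesh.dim
    k = d + 1
    base = (np.ones((k, k)) + np.eye(k)) / ((d + 1) * (d + 2))
    w = vol if coeff is None else vol * np.asarray(coeff)[mesh.elements0].mean(axis=1)
    local = w[:, None, None] * base[None]
    return _accumulate(mesh, local)


def boundary_mass_matrix(mesh: Mesh) -> sparse.csr_matrix:
    """Surface mass matrix over the boundary facets.

    Uses the exact closed-form facet mass matrices: for a triangle,
    area/12 * (2 on the diagonal, 1 off); for an edge, length/6 * (2, 1).
    """
    bf, _ = mesh.boundary_faces()
    verts = mesh.nodes[bf - 1]
    if mesh.dim == 2:
        meas = np.linalg.norm(verts[:, 1] - verts[:, 0], axis=1)
        base = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
    else:
        meas = 0.5 * np.linalg.norm(
            np.cross(verts[:, 1] - verts[:, 0], verts[:, 2] - verts[:, 0]), axis=1)
        base = (np.ones((3, 3)) + np.eye(3)) / 12.0
    local = meas[:, None, None] * base[None]
    k = bf.shape[1]
    rows = np.repeat(bf - 1, k, axis=1).ravel()
    cols = np.tile(bf - 1, (1, k)).ravel()
    mat = sparse.coo_matrix((local.ravel(), (rows, cols)),
                            shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    mat.sum_duplicates()
    mat.sort_indices()
    return mat


def robin_beta(mesh: Mesh, method: str = "groenhuis") -> float:
    """Boundary-reflection beta from the modal boundary refractive index.

    One global beta is used; the refractive index is taken as the modal
    value over boundary nodes (boundaries are assumed homogeneous).
    """
    ri = mesh.props.ri[mesh.boundary_flag]
    vals, counts = np.unique(ri, return_counts=True)
    return boundary_beta(float(vals[np.argmax(counts)]), 1.0, method)


def _assemble_block(mesh: Mesh, props: StandardProps,
                    beta_method: str = "groenhuis") -> SystemMatrices:
    if np.any(props.mua <= 0) or np.any(props.musp <= 0):
        raise MeshValidationError("optical properties must be positive")
    K = stiffness_matrix(mesh, props.kappa)
    Ma = mass_matrix(mesh, props.mua)
    beta = robin_beta(mesh, beta_method)
    Mb = boundary_mass_matrix(mesh)
    A = (K + Ma + Mb / (2.0 * beta)).tocsr()
    A.sort_indices()
    B = mass_matrix(mesh, 1.0 / props.c)
    U = mass_matrix(mesh)
    return SystemMatrices(A=A, B=B, U=U, beta_boundary=beta)


def assemble_standard(mesh: Mesh, beta_method: str = "groenhuis") -> SystemMatrices:
    """Assemble A, B, U for a standard (or DCS, at tau=0) mesh."""
    if mesh.kind not in ("standard", "dcs"):
        raise MeshValidationError(f"expected standard/dcs mesh, got {mesh.kind}")
    return _assemble_block(mesh, mesh.props, beta_method)


def assemble_fluorescence(mesh: Mesh, beta_method: str = "groenhuis"):
    """Assemble the excitation and re-emission blocks of a fluorescence mesh.

    Returns ``(smat_x, smat_m)``; the overlap matrix U is shared.
    """
    if mesh.kind != "fluorescence":
        raise MeshValidationError(f"expected fluorescence mesh, got {mesh.kind}")
    sx = _assemble_block(mesh, mesh.props.block("x"), beta_method)
    sm = _assemble_block(mesh, mesh.props.block("m"), beta_method)
    sm.U = sx.U
    return sx, sm


class DcsOperator:
    """Cached correlation-diffusion operator A(tau) = A(0) + tau * M_dyn."""

    def __init__(self, mesh: Mesh, beta_method: str = "groenhuis"):
        if mesh.kind != "dcs":
            raise MeshValidationError(f"expected dcs mesh, got {mesh.kind}")
        props: DcsProps = mesh.props
        self.smat = assemble_standard(mesh, beta_method)
        self.M_dyn = mass_matrix(
            mesh, 2.0 * props.alphaDb * props.musp * props.k0**2)

    def at(self, tau_delay: float) -> sparse.csr_matrix:
        if tau_delay < 0:
            raise ValueError("tau_delay must be >= 0")
        if tau_delay == 0.0:
            return self.smat.A
        A = (self.smat.A + tau_delay * self.M_dyn).tocsr()
        A.sort_indices()
        return A


def assemble_dcs(mesh: Mesh, tau_delay: float,
                 beta_method: str = "groenhuis") -> SystemMatrices:
    """One-shot A(tau) assembly (see :class:`DcsOperator` for sweeps)."""
    op = DcsOperator(mesh, beta_method)
    s = op.smat
    return SystemMatrices(A=op.at(tau_delay), B=s.B, U=s.U,
                          beta_boundary=s.beta_boundary)


def build_source_vectors(mesh: Mesh, dense: bool = False) -> sparse.csr_matrix:
    """FEM load matrix Q (n_nodes x n_sources) for unit point sources.

    Each source's unit strength is distributed over the vertices of its
    containing element by barycentric weights, so every column sums to 1.
    """
    src = mesh.optodes.sources
    if len(src) == 0:
        raise MeshValidationError("mesh has no sources; call place_optodes first")
    elem, w = mesh.locate(src, tol=1e-9)
    if np.any(elem == 0):
        bad = np.flatnonzero(elem == 0) + 1
        raise MeshValidationError(f"source(s) {bad.tolist()} outside the mesh")
    rows = mesh.elements0[elem - 1].ravel()
    cols = np.repeat(np.arange(len(src)), mesh.dim + 1)
    Q = sparse.coo_matrix((w.ravel(), (rows, cols)),
                          shape=(mesh.n_nodes, len(src))).tocsr()
    return Q.toarray() if dense else Q
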