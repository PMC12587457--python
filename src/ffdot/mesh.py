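"""Mesh data model, classic ASCII I/O, synthetic generators, and optodes.

A :class:`Mesh` is a 2D triangular or 3D tetrahedral finite-element mesh
with per-node optical properties and attached source/detector geometry.
Element connectivity is one-based throughout, for compatibility with the
classic ASCII mesh format understood by the long-lived MATLAB toolboxes in
this field.  Three mesh kinds are supported:

``standard``
    Single-wavelength absorption/scattering (``mua``, ``musp``, ``ri``).
``fluorescence``
    Excitation and re-emission property blocks plus the lumped fluorophore
    yield ``gamma = eta * muaf`` and lifetime ``tau``.
``dcs``
    Standard properties plus the lumped flow index ``alphaDb`` and the
    laser wavelength.

Lengths are mm, times seconds, optical coefficients mm^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .analytical import C_VACUUM


class MeshFormatError(ValueError):
    """A mesh file is malformed or missing."""


class MeshValidationError(ValueError):
    """Mesh data violate a structural invariant."""


def _infer_n(*fields) -> int:
    """Number of nodes implied by the longest per-node field."""
    return max(np.atleast_1d(np.asarray(f)).shape[0] for f in fields)


def _pernode(values, n: int, name: str, minimum=None, strict=False) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0 or arr.shape == (1,):
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise MeshValidationError(f"{name}: expected scalar or length-{n} array")
    if minimum is not None:
        bad = arr <= minimum if strict else arr < minimum
        if np.any(bad):
            op = ">" if strict else ">="
            raise MeshValidationError(f"{name} must be {op} {minimum}")
    return arr


@dataclass
class StandardProps:
    """Per-node absorption, reduced scattering and refractive index."""

    mua: np.ndarray
    musp: np.ndarray
    ri: np.ndarray

    kind = "standard"

    def __init__(self, mua, musp, ri, *, n_nodes: int | None = None):
        n = n_nodes if n_nodes is not None else _infer_n(mua, musp, ri)
        self.mua = _pernode(mua, n, "mua", 0.0, strict=True)
        self.musp = _pernode(musp, n, "musp", 0.0, strict=True)
        self.ri = _pernode(ri, n, "ri", 1.0)

    @property
    def kappa(self) -> np.ndarray:
        """Diffusion coefficient 1/(3(mua+musp)), mm."""
        return 1.0 / (3.0 * (self.mua + self.musp))

    @property
    def c(self) -> np.ndarray:
        """Speed of light in the medium, mm/s."""
        return C_VACUUM / self.ri


@dataclass
class FluorProps:
    """Fluorescence properties: excitation (x) and re-emission (m) blocks.

    ``gamma`` is the lumped fluorophore yield eta*muaf (mm^-1) and ``tau``
    the lifetime in seconds.
    """

    muax: np.ndarray
    muspx: np.ndarray
    muam: np.ndarray
    muspm: np.ndarray
    gamma: np.ndarray
    tau: np.ndarray
    ri: np.ndarray

    kind = "fluorescence"

    def __init__(self, muax, muspx, muam, muspm, gamma, tau, ri, *,
                 n_nodes: int | None = None):
        n = (n_nodes if n_nodes is not None
             else _infer_n(muax, muspx, muam, muspm, gamma, tau, ri))
        self.muax = _pernode(muax, n, "muax", 0.0, strict=True)
        self.muspx = _pernode(muspx, n, "muspx", 0.0, strict=True)
        self.muam = _pernode(muam, n, "muam", 0.0, strict=True)
        self.muspm = _pernode(muspm, n, "muspm", 0.0, strict=True)
        self.gamma = _pernode(gamma, n, "gamma", 0.0)
        self.tau = _pernode(tau, n, "tau", 0.0)
        self.ri = _pernode(ri, n, "ri", 1.0)

    def block(self, which: str) -> StandardProps:
        """Standard-property view of the ``"x"`` or ``"m"`` wavelength."""
        if which == "x":
            return StandardProps(self.muax, self.muspx, self.ri)
        if which == "m":
            return StandardProps(self.muam, self.muspm, self.ri)
        raise ValueError("which must be 'x' or 'm'")

    @property
    def c(self) -> np.ndarray:
        return C_VACUUM / self.ri


@dataclass
class DcsProps(StandardProps):
    """Standard properties plus the lumped flow index alphaDb (mm^2/s)."""

    alphaDb: np.ndarray
    wavelength: float

    kind = "dcs"

    def __init__(self, mua, musp, ri, alphaDb, wavelength: float = 785.0, *,
                 n_nodes: int | None = None):
        if n_nodes is None:
            n_nodes = _infer_n(mua, musp, ri, alphaDb)
        super().__init__(mua, musp, ri, n_nodes=n_nodes)
        self.alphaDb = _pernode(alphaDb, self.mua.shape[0], "alphaDb", 0.0)
        if wavelength <= 0:
            raise MeshValidationError("wavelength must be positive (nm)")
        self.wavelength = float(wavelength)

    @property
    def k0(self) -> float:
        """Wavenumber 2*pi/lambda with lambda converted from nm to mm."""
        return 2.0 * np.pi / (self.wavelength * 1e-6)


@dataclass
class Optodes:
    """Source/detector positions and the channel link table (one-based)."""

    sources: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    detectors: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    link: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    moved: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self):
        self.sources = np.atleast_2d(np.asarray(self.sources, dtype=float))
        self.detectors = np.atleast_2d(np.asarray(self.detectors, dtype=float))
        self.link = np.atleast_2d(np.asarray(self.link, dtype=int)).reshape(-1, 2)
        self.moved = np.asarray(self.moved, dtype=bool)
        if self.sources.size == 0:
            self.sources = self.sources.reshape(0, self.sources.shape[-1] or 3)
        if self.detectors.size == 0:
            self.detectors = self.detectors.reshape(0, self.detectors.shape[-1] or 3)
        if self.moved.size == 0:
            self.moved = np.zeros(len(self.sources), dtype=bool)
        ns, nd = len(self.sources), len(self.detectors)
        if self.link.size:
            if self.link[:, 0].min() < 1 or self.link[:, 0].max() > ns:
                raise MeshValidationError("link source index out of range")
            if self.link[:, 1].min() < 1 or self.link[:, 1].max() > nd:
                raise MeshValidationError("link detector index out of range")

    @property
    def n_channels(self) -> int:
        return len(self.link)

    def __len__(self) -> int:
        return len(self.sources) + len(self.detectors)


class Mesh:
    """Simplex mesh with optical properties and optodes.

    Parameters
    ----------
    nodes:
        (N, dim) coordinates in mm, dim in {2, 3}.
    elements:
        (E, dim+1) **one-based** node indices.
    props:
        One of :class:`StandardProps`, :class:`FluorProps`, :class:`DcsProps`.
    region:
        Optional per-element integer labels (default all 1).
    """

    def __init__(self, nodes, elements, props=None, region=None, optodes=None):
        self.nodes = np.asarray(nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] not in (2, 3):
            raise MeshValidationError("nodes must be (N, 2) or (N, 3)")
        self.elements = np.asarray(elements, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] != self.dim + 1:
            raise MeshValidationError(
                f"elements must be (E, {self.dim + 1}) for a {self.dim}D mesh")
        if self.elements.size and (self.elements.min() < 1
                                   or self.elements.max() > self.n_nodes):
            raise MeshValidationError(
                "element node index out of range [1, n_nodes]")
        self.region = (np.ones(self.n_elements, dtype=int) if region is None
                       else np.asarray(region, dtype=int))
        if self.region.shape != (self.n_elements,):
            raise MeshValidationError("region must have one label per element")
        if props is not None and len(np.atleast_1d(
                getattr(props, "ri", np.zeros(self.n_nodes)))) != self.n_nodes:
            props = _broadcast_props(props, self.n_nodes)
        self.props = props
        self.optodes = optodes if optodes is not None else Optodes(
            np.zeros((0, self.dim)), np.zeros((0, self.dim)))
        self._fix_orientation()
        self.boundary_flag = self._compute_boundary_flags()
        self._tree: cKDTree | None = None

    # -- basic queries -----------------------------------------------------
    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def kind(self) -> str:
        return self.props.kind if self.props is not None else "none"

    @property
    def elements0(self) -> np.ndarray:
        """Zero-based connectivity view (for numpy indexing)."""
        return self.elements - 1

    def __repr__(self) -> str:
        return (f"<Mesh {self.dim}D kind={self.kind} nodes={self.n_nodes} "
                f"elements={self.n_elements} channels={self.optodes.n_channels}>")

    # -- geometry ----------------------------------------------------------
    def element_volumes(self) -> np.ndarray:
        """Signed simplex volumes (areas in 2D), mm^dim."""
        v = self.nodes[self.elements0]
        edges = v[:, 1:] - v[:, :1]
        if self.dim == 2:
            det = edges[:, 0, 0] * edges[:, 1, 1] - edges[:, 0, 1] * edges[:, 1, 0]
            return det / 2.0
        return np.linalg.det(edges) / 6.0

    def _fix_orientation(self) -> None:
        vol = self.element_volumes()
        flip = vol < 0
        if np.any(flip):
            self.elements[flip, -2:] = self.elements[flip, -2:][:, ::-1]
            vol = self.element_volumes()
        if np.any(vol <= 0):
            raise MeshValidationError("degenerate element (zero volume)")

    def faces(self) -> tuple[np.ndarray, np.ndarray]:
        """All element facets and their owning element index (0-based).

        Facets are (dim) node indices (one-based), one row per element facet.
        """
        e = self.elements
        d = self.dim
        idx = [np.delete(np.arange(d + 1), i) for i in range(d + 1)]
        facets = np.concatenate([e[:, i] for i in idx], axis=0)
        owners = np.tile(np.arange(self.n_elements), d + 1)
        return facets, owners

    def boundary_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Facets on the outer surface and their owner elements (0-based)."""
        facets, owners = self.faces()
        key = np.sort(facets, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
        on_boundary = counts[inv] == 1
        return facets[on_boundary], owners[on_boundary]

    def _compute_boundary_flags(self) -> np.ndarray:
        flags = np.zeros(self.n_nodes, dtype=bool)
        if self.n_elements:
            bf, _ = self.boundary_faces()
            flags[bf.ravel() - 1] = True
        return flags

    # -- point location ----------------------------------------------------
    def _centroid_tree(self) -> cKDTree:
        if self._tree is None:
            centroids = self.nodes[self.elements0].mean(axis=1)
            self._tree = cKDTree(centroids)
        return self._tree

    def barycentric(self, elem_idx0, points) -> np.ndarray:
        """Barycentric coordinates of ``points`` in elements ``elem_idx0``."""
        points = np.atleast_2d(points)
        v = self.nodes[self.elements0[elem_idx0]]
        t = np.swapaxes(v[:, 1:] - v[:, :1], 1, 2)  # (n, dim, dim)
        rhs = points - v[:, 0]
        w_rest = np.linalg.solve(t, rhs[..., None])[..., 0]
        return np.concatenate([1.0 - w_rest.sum(axis=1, keepdims=True), w_rest],
                              axis=1)

    def locate(self, points, tol: float = 1e-9, k_max: int = 64):
        """Find containing elements for points.

        Returns ``(elem, weights)`` where ``elem`` holds **one-based**
        element indices (0 where the point is outside the mesh) and
        ``weights`` the (n, dim+1) barycentric coordinates.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        elem = np.zeros(n, dtype=np.int64)
        weights = np.zeros((n, self.dim + 1))
        tree = self._centroid_tree()
        pending = np.arange(n)
        k = min(8, self.n_elements)
        while pending.size and k <= min(k_max, self.n_elements):
            _, cand = tree.query(points[pending], k=k)
            cand = np.atleast_2d(cand.reshape(len(pending), -1))
            found = np.zeros(pending.size, dtype=bool)
            for j in range(cand.shape[1]):
                todo = ~found
                if not np.any(todo):
                    break
                w = self.barycentric(cand[todo, j], points[pending[todo]])
                ok = np.all(w >= -tol, axis=1)
                rows = pending[todo][ok]
                elem[rows] = cand[todo, j][ok] + 1
                weights[rows] = w[ok]
                found[np.flatnonzero(todo)[ok]] = True
            pending = pending[~found]
            if k == min(k_max, self.n_elements):
                break
            k = min(k * 4, k_max, self.n_elements)
        return elem, weights

    def contains(self, points, tol: float = 1e-9) -> np.ndarray:
        elem, _ = self.locate(points, tol=tol)
        return elem > 0

    def interpolate(self, nodal, points) -> np.ndarray:
        """Linearly interpolate a nodal field at points inside the mesh."""
        elem, w = self.locate(points)
        if np.any(elem == 0):
            raise MeshValidationError("interpolation point outside the mesh")
        nodal = np.asarray(nodal)
        vals = nodal[self.elements0[elem - 1]]  # (n, dim+1, ...)
        return np.einsum("nv,nv...->n...", w, vals)

    # -- optodes -----------------------------------------------------------
    def place_optodes(self, raw_sources=None, raw_detectors=None, link=None,
                      move_sources: bool = True) -> Optodes:
        """Project optodes onto the surface; move sources inside.

        Sources are projected onto the nearest surface point and then moved
        one scattering length 1/musp (1/muspx for fluorescence meshes) along
        the inward surface normal; detectors are projected only.  If the
        displaced source would leave the mesh (thin geometry), it falls back
        to the deepest interior point along the normal, with a warning.
        """
        if raw_sources is None:
            raw_sources = self.optodes.sources
        if raw_detectors is None:
            raw_detectors = self.optodes.detectors
        raw_sources = np.atleast_2d(np.asarray(raw_sources, dtype=float))
        raw_detectors = np.atleast_2d(np.asarray(raw_detectors, dtype=float))
        if link is None:
            link = self.optodes.link
            if len(link) == 0 and len(raw_sources) and len(raw_detectors):
                # default: all source-detector pairs
                s, d = np.meshgrid(np.arange(1, len(raw_sources) + 1),
                                   np.arange(1, len(raw_detectors) + 1),
                                   indexing="ij")
                link = np.column_stack([s.ravel(), d.ravel()])

        musp = (self.props.muspx if self.kind == "fluorescence"
                else self.props.musp)
        placed_sources = np.empty_like(raw_sources)
        moved = np.zeros(len(raw_sources), dtype=bool)
        for i, p in enumerate(raw_sources):
            proj, normal_in = self._project_to_surface(p)
            if not move_sources:
                placed_sources[i] = proj
                continue
            # scattering length at the projection point
            elem, w = self.locate(proj[None], tol=1e-6)
            ell = 1.0 / float(w[0] @ musp[self.elements0[elem[0] - 1]])
            candidate = proj + normal_in * ell
            if self.contains(candidate[None], tol=1e-9)[0]:
                placed_sources[i] = candidate
            else:
                depths = np.linspace(ell, 0.0, 64, endpoint=False)
                pts = proj[None] + depths[:, None] * normal_in[None]
                inside = self.contains(pts, tol=1e-9)
                if not np.any(inside):
                    raise MeshValidationError(
                        f"source {i + 1}: no interior point along the normal")
                placed_sources[i] = pts[np.argmax(inside)]
                warnings.warn(
                    f"source {i + 1} displaced less than one scattering "
                    "length (thin geometry)", stacklevel=2)
            moved[i] = True
        placed_detectors = np.array(
            [self._project_to_surface(p)[0] for p in raw_detectors]
        ).reshape(-1, self.dim)
        self.optodes = Optodes(placed_sources, placed_detectors, link, moved)
        return self.optodes

    def _project_to_surface(self, point) -> tuple[np.ndarray, np.ndarray]:
        """Nearest surface point and unit inward normal there.

        The normal is the area-weighted average of the normals of all
        boundary faces touching the projected point (robust at edges and
        vertices); ties in the distance are broken by lowest face index.
        """
        point = np.asarray(point, dtype=float)
        bf, owners = self.boundary_faces()
        verts = self.nodes[bf - 1]  # (F, dim, dim)
        if self.dim == 2:
            proj, dist = _project_point_segments(point, verts)
        else:
            proj, dist = _project_point_triangles(point, verts)
        best = int(np.argmin(dist))  # argmin takes the first (lowest) index
        best_point = proj[best]
        normals, areas = self._outward_face_normals(bf, owners)
        touch = np.linalg.norm(proj - best_point, axis=1) <= 1e-9 + 1e-12 * dist[best]
        touch &= dist <= dist[best] * (1 + 1e-9) + 1e-9
        avg = -(normals[touch] * areas[touch, None]).sum(axis=0)
        norm = np.linalg.norm(avg)
        if norm == 0:
            avg, norm = -normals[best], 1.0
        return best_point, avg / norm

    def _outward_face_normals(self, bf, owners) -> tuple[np.ndarray, np.ndarray]:
        verts = self.nodes[bf - 1]
        if self.dim == 2:
            edge = verts[:, 1] - verts[:, 0]
            normals = np.column_stack([edge[:, 1], -edge[:, 0]])
            areas = np.linalg.norm(edge, axis=1)
        else:
            normals = np.cross(verts[:, 1] - verts[:, 0], verts[:, 2] - verts[:, 0])
            areas = 0.5 * np.linalg.norm(normals, axis=1)
        normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
        # orient away from the owning element's centroid
        centroids = self.nodes[self.elements0[owners]].mean(axis=1)
        to_face = verts.mean(axis=1) - centroids
        sign = np.sign(np.einsum("ij,ij->i", normals, to_face))
        sign[sign == 0] = 1.0
        return normals * sign[:, None], areas

    # -- I/O ---------------------------------------------------------------
    def save_nirfast(self, basename) -> None:
        save_nirfast_ascii(self, basename)


# ---------------------------------------------------------------------------
# point-to-facet projections

def _project_point_segments(p, verts):
    a, b = verts[:, 0], verts[:, 1]
    ab = b - a
    t = np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return proj, np.linalg.norm(proj - p, axis=1)


def _project_point_triangles(p, verts):
    """Exact point-to-triangle projection (Ericson's algorithm), vectorized."""
    a, b, c = verts[:, 0], verts[:, 1], verts[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    proj = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    proj[m] = a[m]
    done |= m
    m = (d3 >= 0) & (d4 <= d3) & ~done  # vertex b
    proj[m] = b[m]
    done |= m
    m = (d6 >= 0) & (d5 <= d6) & ~done  # vertex c
    proj[m] = c[m]
    done |= m
    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~done  # edge ab
    v = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0.0)
    proj[m] = a[m] + v[m, None] * ab[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~done  # edge ac
    w = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0.0)
    proj[m] = a[m] + w[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0) & ~done  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0.0)
    proj[m] = b[m] + w[m, None] * (c - b)[m]
    done |= m
    m = ~done  # interior
    denom = va + vb + vc
    v = vb / np.where(denom == 0, 1, denom)
    w = vc / np.where(denom == 0, 1, denom)
    proj[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return proj, np.linalg.norm(proj - p, axis=1)


# ---------------------------------------------------------------------------
# classic ASCII format
#
# basename.node  : boundary_flag(0/1) x y [z]       -- one line per node
# basename.elem  : one-based node indices           -- one line per element
# basename.param : line 1 kind keyword (stnd | fluor | dcs; dcs carries the
#                  wavelength in nm as a second token), then per-node columns:
#                    stnd : mua kappa ri
#                    fluor: muax kappax muam kappam gamma tau ri
#                    dcs  : mua kappa ri alphaDb
# basename.source: line 1 "fixed", then x y [z] [moved-flag]
# basename.meas  : line 1 "fixed", then x y [z]
# basename.link  : source det active(0/1)           -- one line per channel
#
# kappa is stored (not musp) to match the legacy toolboxes; musp is
# recovered as 1/(3 kappa) - mua on load.

_KIND_KEYWORDS = {"stnd": "standard", "fluor": "fluorescence", "dcs": "dcs"}
_KEYWORDS_KIND = {v: k for k, v in _KIND_KEYWORDS.items()}


def _read_table(path: Path, what: str) -> np.ndarray:
    try:
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    rows.append([float(tok) for tok in line.split()])
                except ValueError as exc:
                    raise MeshFormatError(
                        f"{path}: line {ln}: {exc}") from None
        if not rows:
            raise MeshFormatError(f"{path}: empty {what} file")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise MeshFormatError(f"{path}: ragged rows in {what} file")
        return np.asarray(rows, dtype=float)
    except FileNotFoundError:
        raise MeshFormatError(f"{path}: mandatory {what} file missing") from None


def load_nirfast_ascii(basename) -> Mesh:
    """Load a mesh from the classic ASCII multi-file format.

    ``basename.node``, ``basename.elem`` and ``basename.param`` are
    mandatory; ``.source``, ``.meas`` and ``.link`` are optional and yield
    empty optodes when absent.
    """
    base = Path(basename)
    nodetab = _read_table(base.with_suffix(base.suffix + ".node"), "node")
    nodes = nodetab[:, 1:]
    elements = _read_table(base.with_suffix(base.suffix + ".elem"), "elem")
    if not np.allclose(elements, np.round(elements)):
        raise MeshFormatError(f"{base}.elem: non-integer node index")
    elements = elements.astype(np.int64)

    ppath = base.with_suffix(base.suffix + ".param")
    try:
        with open(ppath) as fh:
            header = fh.readline().split()
    except FileNotFoundError:
        raise MeshFormatError(f"{ppath}: mandatory param file missing") from None
    if not header or header[0] not in _KIND_KEYWORDS:
        raise MeshFormatError(
            f"{ppath}: line 1: expected kind keyword stnd|fluor|dcs")
    kind = _KIND_KEYWORDS[header[0]]
    table = np.loadtxt(ppath, skiprows=1, ndmin=2)
    if len(table) != len(nodes):
        raise MeshFormatError(
            f"{ppath}: {len(table)} property rows for {len(nodes)} nodes")

    def musp_from(kcol, mua):
        return 1.0 / (3.0 * kcol) - mua

    if kind == "standard":
        if table.shape[1] < 3:
            raise MeshFormatError(f"{ppath}: stnd needs 3 columns")
        mua, kap, ri = table[:, 0], table[:, 1], table[:, 2]
        props = StandardProps(mua, musp_from(kap, mua), ri)
    elif kind == "fluorescence":
        if table.shape[1] < 7:
            raise MeshFormatError(f"{ppath}: fluor needs 7 columns")
        muax, kapx, muam, kapm, gamma, tau, ri = table[:, :7].T
        props = FluorProps(muax, musp_from(kapx, muax), muam,
                           musp_from(kapm, muam), gamma, tau, ri)
    else:
        if table.shape[1] < 4:
            raise MeshFormatError(f"{ppath}: dcs needs 4 columns")
        wavelength = float(header[1]) if len(header) > 1 else 785.0
        mua, kap, ri, adb = table[:, :4].T
        props = DcsProps(mua, musp_from(kap, mua), ri, adb, wavelength)

    dim = nodes.shape[1]
    optodes = None
    spath = base.with_suffix(base.suffix + ".source")
    mpath = base.with_suffix(base.suffix + ".meas")
    lpath = base.with_suffix(base.suffix + ".link")
    sources = np.zeros((0, dim))
    detectors = np.zeros((0, dim))
    link = np.zeros((0, 2), dtype=int)
    moved = np.zeros(0, dtype=bool)
    if spath.exists():
        stab = _read_optode_table(spath)
        if stab.shape[1] == dim + 1:
            sources, moved = stab[:, :dim], stab[:, dim].astype(bool)
        else:
            if stab.shape[1] != dim:
                warnings.warn(f"{spath}: unexpected column count, "
                              "reading first coordinates best-effort")
            sources, moved = stab[:, :dim], np.zeros(len(stab), dtype=bool)
    if mpath.exists():
        detectors = _read_optode_table(mpath)[:, :dim]
    if lpath.exists():
        ltab = _read_table(lpath, "link").astype(int)
        active = ltab[:, 2].astype(bool) if ltab.shape[1] > 2 else np.ones(
            len(ltab), dtype=bool)
        link = ltab[active, :2]
    optodes = Optodes(sources, detectors, link, moved)

    mesh = Mesh(nodes, elements, props, optodes=optodes)
    loaded_flags = nodetab[:, 0].astype(bool)
    if not np.array_equal(loaded_flags, mesh.boundary_flag):
        warnings.warn(f"{base}.node: stored boundary flags disagree with "
                      "mesh topology; recomputed flags kept")
    return mesh


def _read_optode_table(path: Path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.split() and first.split()[0] != "fixed":
        warnings.warn(f"{path}: missing 'fixed' header, reading best-effort")
        return _read_table(path, "optode")
    return np.loadtxt(path, skiprows=1, ndmin=2)


def save_nirfast_ascii(mesh: Mesh, basename) -> None:
    """Write the mesh in the classic ASCII multi-file format.

    ``load_nirfast_ascii(save(...))`` is the identity up to the 17
    significant digits of the float format.  Optode files are emitted only
    when the mesh has optodes.
    """
    base = Path(basename)
    if base.parent and not base.parent.exists():
        raise OSError(f"directory {base.parent} does not exist")
    fmt = "%.17g"
    nodetab = np.column_stack([mesh.boundary_flag.astype(float), mesh.nodes])
    np.savetxt(base.with_suffix(base.suffix + ".node"), nodetab,
               fmt=["%d"] + [fmt] * mesh.dim)
    np.savetxt(base.with_suffix(base.suffix + ".elem"), mesh.elements, fmt="%d")

    p = mesh.props
    if mesh.kind == "standard":
        header = "stnd"
        table = np.column_stack([p.mua, p.kappa, p.ri])
    elif mesh.kind == "fluorescence":
        header = "fluor"
        kx = 1.0 / (3.0 * (p.muax + p.muspx))
        km = 1.0 / (3.0 * (p.muam + p.muspm))
        table = np.column_stack([p.muax, kx, p.muam, km, p.gamma, p.tau, p.ri])
    elif mesh.kind == "dcs":
        header = f"dcs {p.wavelength:.17g}"
        table = np.column_stack([p.mua, p.kappa, p.ri, p.alphaDb])
    else:
        raise MeshValidationError("mesh has no properties to save")
    with open(base.with_suffix(base.suffix + ".param"), "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, table, fmt=fmt)

    opt = mesh.optodes
    if len(opt.sources):
        with open(base.with_suffix(base.suffix + ".source"), "w") as fh:
            fh.write("fixed\n")
            np.savetxt(fh, np.column_stack([opt.sources,
                                            opt.moved.astype(float)]),
                       fmt=[fmt] * mesh.dim + ["%d"])
    if len(opt.detectors):
        with open(base.with_suffix(base.suffix + ".meas"), "w") as fh:
            fh.write("fixed\n")
            np.savetxt(fh, opt.detectors, fmt=fmt)
    if len(opt.link):
        np.savetxt(base.with_suffix(base.suffix + ".link"),
                   np.column_stack([opt.link, np.ones(len(opt.link), dtype=int)]),
                   fmt="%d")


# ---------------------------------------------------------------------------
# synthetic mesh generators

def make_disk_mesh(radius: float, target_nodes: int, props=None,
                   with_optodes: bool = False, n_detectors: int = 15) -> Mesh:
    """2D triangular disk mesh from concentric rings + Delaunay.

    Node count lands within about +-20% of ``target_nodes``.  With
    ``with_optodes=True``, one source and ``n_detectors`` detectors are
    placed equally spaced on the circumference (source at angle 0) and all
    source-detector channels linked.
    """
    if radius <= 0:
        raise MeshValidationError("radius must be positive")
    if target_nodes < 10:
        raise MeshValidationError("target_nodes must be >= 10")
    h = radius * np.sqrt(np.pi / target_nodes / np.sqrt(3.0) * 2.0)
    n_rings = max(2, int(round(radius / h)))
    pts = [np.zeros((1, 2))]
    for i in range(1, n_rings + 1):
        r = radius * i / n_rings
        n_i = max(6, int(round(2.0 * np.pi * r / (radius / n_rings))))
        theta = 2.0 * np.pi * np.arange(n_i) / n_i
        # stagger alternate rings for better-shaped triangles
        theta += (np.pi / n_i) * (i % 2)
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    nodes = np.concatenate(pts, axis=0)
    tri = Delaunay(nodes)
    elements = tri.simplices.astype(np.int64) + 1
    mesh = Mesh(nodes, elements)
    areas = mesh.element_volumes()
    if np.any(areas < 1e-12 * (radius / n_rings) ** 2):
        raise MeshValidationError("disk generation produced a degenerate triangle")
    if props is not None:
        mesh.props = _broadcast_props(props, mesh.n_nodes)
    if with_optodes:
        n_opt = n_detectors + 1
        theta = 2.0 * np.pi * np.arange(n_opt) / n_opt
        ring = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        link = np.column_stack([np.ones(n_detectors, dtype=int),
                                np.arange(1, n_detectors + 1)])
        mesh.place_optodes(ring[:1], ring[1:], link)
    return mesh


def graded_coords(length: float, fine_lo: float, fine_hi: float,
                  fine_h: float, coarse_h: float) -> np.ndarray:
    """1D coordinate vector over [0, length], fine inside [fine_lo, fine_hi].

    Useful for slabs where accuracy matters only in the photon corridor
    between source and detector; the transition between spacings is abrupt
    (acceptable for the diffusion operator, which stays SPD on stretched
    tetrahedra).
    """
    segs = []
    if fine_lo > 0:
        segs.append(np.linspace(0.0, fine_lo,
                                max(1, int(round(fine_lo / coarse_h))) + 1))
    segs.append(np.linspace(fine_lo, fine_hi,
                            max(1, int(round((fine_hi - fine_lo) / fine_h))) + 1))
    if fine_hi < length:
        segs.append(np.linspace(
            fine_hi, length,
            max(1, int(round((length - fine_hi) / coarse_h))) + 1))
    return np.unique(np.concatenate(segs))


def make_slab_mesh(lx: float, ly: float, lz: float, spacing: float | None,
                   props=None, coords=None) -> Mesh:
    """Structured tetrahedral slab on [0,lx]x[0,ly]x[0,lz].

    Each hexahedral cell is split into six tetrahedra along its main
    diagonal (Kuhn subdivision), which is conforming across cells; the
    total element volume equals lx*ly*lz exactly.  ``coords=(xs, ys, zs)``
    replaces the uniform spacing by explicit (possibly graded) coordinate
    vectors spanning the same box.
    """
    if min(lx, ly, lz) <= 0:
        raise MeshValidationError("slab dimensions must be positive")
    if coords is not None:
        xs, ys, zs = (np.asarray(c, dtype=float) for c in coords)
        for c, l in ((xs, lx), (ys, ly), (zs, lz)):
            if c[0] != 0.0 or abs(c[-1] - l) > 1e-9 or np.any(np.diff(c) <= 0):
                raise MeshValidationError(
                    "coords must ascend from 0 to the slab dimensions")
        nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    else:
        if spacing is None or spacing >= min(lx, ly, lz):
            raise MeshValidationError(
                "spacing must be smaller than every dimension")
        nx, ny, nz = (max(1, int(round(l / spacing))) for l in (lx, ly, lz))
        xs = np.linspace(0.0, lx, nx + 1)
        ys = np.linspace(0.0, ly, ny + 1)
        zs = np.linspace(0.0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    c = np.stack([nid(i + di, j + dj, k + dk)
                  for di in (0, 1) for dj in (0, 1) for dk in (0, 1)], axis=1)
    # corner order: c[:, b] with bit pattern b = (di<<2)|(dj<<1)|dk
    # Kuhn: six tets along the path 000 -> 111, one per axis permutation
    paths = [(4, 2, 1), (4, 1, 2), (2, 4, 1), (2, 1, 4), (1, 4, 2), (1, 2, 4)]
    tets = []
    for p in paths:
        v0 = c[:, 0]
        v1 = c[:, p[0]]
        v2 = c[:, p[0] | p[1]]
        v3 = c[:, 7]
        tets.append(np.stack([v0, v1, v2, v3], axis=1))
    elements = np.concatenate(tets, axis=0).astype(np.int64) + 1
    mesh = Mesh(nodes, elements)
    if props is not None:
        mesh.props = _broadcast_props(props, mesh.n_nodes)
    return mesh


def _broadcast_props(props, n: int):
    """Re-instantiate props with scalar fields expanded to n nodes."""
    if isinstance(props, FluorProps):
        return FluorProps(*(np.resize(getattr(props, f), n) for f in
                            ("muax", "muspx", "muam", "muspm", "gamma",
                             "tau", "ri")))
    if isinstance(props, DcsProps):
        return DcsProps(*(np.resize(getattr(props, f), n) for f in
                          ("mua", "musp", "ri", "alphaDb")),
                        props.wavelength)
    if isinstance(props, StandardProps):
        return StandardProps(*(np.resize(getattr(props, f), n) for f in
                               ("mua", "musp", "ri")))
    raise TypeError("props must be StandardProps, FluorProps or DcsProps")
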