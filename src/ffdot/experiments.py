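"""Reference validation experiments.

Self-contained, parameter-free experiment drivers used by the test suite
and the acceptance script.  Each function builds its synthetic geometry,
runs the forward engines, and compares against the independent oracle
(TPSF time stepping vs. Mellin recursion, or the semi-infinite analytical
solutions), returning plain floats.

Geometries and conditions:

* **Moment-validation disks** -- homogeneous 2D disks of 43 mm radius with
  about 2000 nodes, one source and 15 equally spaced circumferential
  detectors.  Standard disk: mua=0.01, musp'=1, n=1.33.  Fluorescence
  disk: muax=0.0089, muspx'=1.3141, muam=0.0062, muspm'=1.2739,
  gamma=1.8e-4 mm^-1, tau=1 ns, n=1.33.
* **Reference slab** -- 120 x 120 x 60 mm structured tetrahedral slab,
  mua=0.01, musp'=1, n=1.37; source at the bottom-face center (moved one
  scattering length inside), detector 20 mm away.  The grid is graded:
  0.9 mm spacing in the source-detector corridor, 5 mm elsewhere
  (~141k nodes), which keeps numerical dispersion at the sub-percent
  level at a tractable size.
* **DCS slab** -- same geometry at 750 nm with alphaDb in
  {1e-7, 1e-6, 1e-5} mm^2/s.
"""

from __future__ import annotations

import numpy as np

from .analytical import SemiInfiniteSetup, semi_infinite_tr
from .forward import (femdata_dcs, femdata_standard, femdata_tpsf_fluorescence,
                      femdata_tpsf_standard, moments_fluorescence,
                      moments_standard)
from .grids import build_grid_mapping
from .jacobians import Jacobian, jacobian_standard, tikhonov_reconstruct
from .mesh import (DcsProps, FluorProps, Mesh, StandardProps, graded_coords,
                   make_disk_mesh, make_slab_mesh)

TABLE_STANDARD = dict(mua=0.01, musp=1.0, ri=1.33)
TABLE_FLUOR = dict(muax=0.0089, muspx=1.3141, muam=0.0062, muspm=1.2739,
                   gamma=0.00018, tau=1e-9, ri=1.33)
SLAB_PROPS = dict(mua=0.01, musp=1.0, ri=1.37)
SLAB_SDS = 20.0          # source-detector separation, mm
DCS_WAVELENGTH = 750.0   # nm
DCS_ALPHA_DB = (1e-7, 1e-6, 1e-5)   # mm^2/s


def validation_disk(kind: str = "standard") -> Mesh:
    """43 mm moment-validation disk (~2000 nodes, 1 source, 15 detectors)."""
    if kind == "standard":
        props = StandardProps(n_nodes=1, **TABLE_STANDARD)
    else:
        props = FluorProps(n_nodes=1, **TABLE_FLUOR)
    return make_disk_mesh(43.0, 2000, props, with_optodes=True)


def disk_moment_difference(kind: str = "standard") -> float:
    """Max relative difference (%) of <t1>, <t2> between TPSF and Mellin.

    TPSF spans: 10 ns (standard) or 15 ns (fluorescence), 10 ps steps.
    The fluorescence case takes the worst difference over both the
    excitation and the re-emission data.
    """
    mesh = validation_disk(kind)
    if kind == "standard":
        mom = moments_standard(mesh, 2)
        tp = femdata_tpsf_standard(mesh, 10e-9, 10e-12)
        pairs = [(tp, mom)]
    else:
        momx, momm = moments_fluorescence(mesh, 2)
        tx, tm = femdata_tpsf_fluorescence(mesh, 15e-9, 10e-12)
        pairs = [(tx, momx), (tm, momm)]
    worst = 0.0
    for tp, mom in pairs:
        got = tp.moments(2)
        for order in (1, 2):
            rel = np.abs(got[order] - mom.normalized[order]
                         ) / mom.normalized[order]
            worst = max(worst, rel.max())
    return 100.0 * worst


def reference_slab(props=None, fine: float = 0.9, coarse: float = 5.0) -> Mesh:
    """Graded 120x120x60 mm slab with the 20 mm reference channel placed."""
    if props is None:
        props = StandardProps(n_nodes=1, **SLAB_PROPS)
    xs = graded_coords(120.0, 40.0, 100.0, fine, coarse)
    ys = graded_coords(120.0, 45.0, 75.0, fine, coarse)
    zs = graded_coords(60.0, 0.0, 22.5, fine, coarse)
    mesh = make_slab_mesh(120.0, 120.0, 60.0, None, props,
                          coords=(xs, ys, zs))
    mesh.place_optodes([[60.0, 60.0, 0.0]],
                       [[60.0 + SLAB_SDS, 60.0, 0.0]], [[1, 1]])
    return mesh


def slab_moment_errors(mesh: Mesh | None = None) -> list[float]:
    """Relative errors (%) of normalized moments 1..3 vs the EBC oracle.

    The oracle integrates the semi-infinite extrapolated-boundary
    time-resolved reflectance on a 0.25 ps grid out to 20 ns.
    """
    if mesh is None:
        mesh = reference_slab()
    mom = moments_standard(mesh, 3)
    setup = SemiInfiniteSetup(bc_kind="ebc", beta_method="groenhuis",
                              ri_in=SLAB_PROPS["ri"], mua=SLAB_PROPS["mua"],
                              musp=SLAB_PROPS["musp"])
    t = np.arange(1, 80001) * 0.25e-12
    _, refl = semi_infinite_tr(setup, SLAB_SDS, t)
    a0 = np.trapezoid(refl, t)
    errors = []
    for order in (1, 2, 3):
        oracle = np.trapezoid(refl * t**order, t) / a0
        errors.append(100.0 * abs(mom.normalized[order][0] - oracle) / oracle)
    return errors


def dcs_tau_vector(n: int = 50) -> np.ndarray:
    """Delay grid: 0 plus n log-spaced points over [1e-8, 1e-3] s."""
    return np.concatenate([[0.0], np.logspace(-8, -3, n)])


def dcs_slab_mse(alpha_db_values=DCS_ALPHA_DB, fine: float = 0.9,
                 n_tau: int = 50) -> list[float]:
    """MSE between FEM and analytical EBC g1 curves per alphaDb value."""
    taus = dcs_tau_vector(n_tau)
    setup = SemiInfiniteSetup(bc_kind="ebc", beta_method="groenhuis",
                              ri_in=SLAB_PROPS["ri"], mua=SLAB_PROPS["mua"],
                              musp=SLAB_PROPS["musp"])
    out = []
    for adb in alpha_db_values:
        props = DcsProps(SLAB_PROPS["mua"], SLAB_PROPS["musp"],
                         SLAB_PROPS["ri"], adb, DCS_WAVELENGTH, n_nodes=1)
        mesh = reference_slab(props, fine=fine)
        fem = femdata_dcs(mesh, taus).g1[0]
        from .analytical import semi_infinite_dcs
        ana = semi_infinite_dcs(setup, SLAB_SDS, adb, DCS_WAVELENGTH, taus)
        out.append(float(np.mean((fem - ana) ** 2)))
    return out


def anomaly_localization(seed: int, grid_spacings=(2.0, 3.0, 5.0),
                         noise_level: float = 0.05) -> list[float]:
    """Tikhonov reconstruction of a 5% absorption anomaly on the disk.

    A 10 mm-radius region centered 20 mm off-center gets a 5% mua
    increase; the log-intensity differences of a 16-optode all-pairs array
    are corrupted with Gaussian noise (sigma = 5% of each datum) and
    reconstructed with the regularizer lam=10 at each grid spacing.
    Returns the distance (mm) between the reconstructed-anomaly centroid
    (half-maximum support) and the true center, per spacing.
    """
    rng = np.random.default_rng(seed)
    props = StandardProps(n_nodes=1, **TABLE_STANDARD)
    mesh = make_disk_mesh(43.0, 2000, props)
    n_opt = 16
    theta = 2 * np.pi * np.arange(n_opt) / n_opt
    ring = np.column_stack([43 * np.cos(theta), 43 * np.sin(theta)])
    s, d = np.meshgrid(np.arange(1, n_opt + 1), np.arange(1, n_opt + 1),
                       indexing="ij")
    link = np.column_stack([s[s != d], d[s != d]])
    mesh.place_optodes(ring, ring, link)

    center = np.array([20.0, 0.0])
    inside_anom = np.linalg.norm(mesh.nodes - center, axis=1) <= 10.0
    perturbed = Mesh(mesh.nodes, mesh.elements,
                     StandardProps(mesh.props.mua * (1 + 0.05 * inside_anom),
                                   mesh.props.musp, mesh.props.ri),
                     optodes=mesh.optodes)
    y = (np.log(femdata_standard(perturbed, 0.0).boundary)
         - np.log(femdata_standard(mesh, 0.0).boundary))
    y = y + noise_level * np.abs(y) * rng.standard_normal(len(y))

    distances = []
    for spacing in grid_spacings:
        g = np.arange(-44.0, 44.01, spacing)
        vg = build_grid_mapping(mesh, g, g)
        J = jacobian_standard(mesh, vg, log_data=True)
        J_mua = Jacobian(J.block("mua"), ("mua",), vg, J.link, log_data=True)
        x = tikhonov_reconstruct(J_mua, y, 10.0)
        x = np.clip(x, 0.0, None)
        support = x >= 0.5 * x.max()
        pts = vg.centers[vg.inside_mask][support]
        centroid = (pts * x[support, None]).sum(axis=0) / x[support].sum()
        distances.append(float(np.linalg.norm(centroid - center)))
    return distances
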