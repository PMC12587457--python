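"""Adjoint voxel-space Jacobians against perturbation oracles; Tikhonov."""

import numpy as np
import pytest

import ffdot as ff


def disk_grid(mesh, spacing=2.0, extent=45.0):
    g = np.arange(-extent, extent + spacing / 2, spacing)
    return ff.build_grid_mapping(mesh, g, g)


def gaussian_blob(points, center, sigma=5.0):
    d2 = ((points - np.asarray(center)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2 * sigma**2))


def perturbed_disk(mesh, dmua=None, dmusp=None):
    p = mesh.props
    mua = p.mua + (dmua if dmua is not None else 0.0)
    musp = p.musp + (dmusp if dmusp is not None else 0.0)
    return ff.Mesh(mesh.nodes, mesh.elements,
                   ff.StandardProps(mua, musp, p.ri), optodes=mesh.optodes)


class TestStandardJacobian:
    def test_log_mua_sensitivity_is_negative(self, small_disk):
        vg = disk_grid(small_disk)
        J = ff.jacobian_standard(small_disk, vg, log_data=True)
        assert np.all(J.block("mua") <= 1e-15)

    def test_mua_block_matches_central_difference(self, jac_disk):
        vg = disk_grid(jac_disk)
        J = ff.jacobian_standard(jac_disk, vg, log_data=True)
        blob_nodal = 1e-3 * gaussian_blob(jac_disk.nodes, [10.0, 0.0])
        blob_vox = 1e-3 * gaussian_blob(vg.centers[vg.inside_mask],
                                        [10.0, 0.0])
        up = ff.femdata_standard(perturbed_disk(jac_disk, dmua=blob_nodal),
                                 0.0).boundary
        dn = ff.femdata_standard(perturbed_disk(jac_disk, dmua=-blob_nodal),
                                 0.0).boundary
        fd = (np.log(up) - np.log(dn)) / 2.0
        predicted = J.block("mua") @ blob_vox
        np.testing.assert_allclose(predicted, fd, rtol=0.05)

    def test_musp_block_matches_central_difference(self, jac_disk):
        vg = disk_grid(jac_disk)
        J = ff.jacobian_standard(jac_disk, vg, log_data=True)
        blob_nodal = 0.02 * gaussian_blob(jac_disk.nodes, [-8.0, 6.0])
        blob_vox = 0.02 * gaussian_blob(vg.centers[vg.inside_mask],
                                        [-8.0, 6.0])
        up = ff.femdata_standard(perturbed_disk(jac_disk, dmusp=blob_nodal),
                                 0.0).boundary
        dn = ff.femdata_standard(perturbed_disk(jac_disk,
                                                dmusp=-blob_nodal),
                                 0.0).boundary
        fd = (np.log(up) - np.log(dn)) / 2.0
        predicted = J.block("musp") @ blob_vox
        # scattering sensitivity changes sign across channels; guard the
        # relative check with a small floor where fd crosses zero
        np.testing.assert_allclose(predicted, fd, rtol=0.05,
                                   atol=0.005 * np.abs(fd).max())

    def test_banana_maximum_lies_near_surface_between_optodes(self,
                                                              small_disk):
        vg = disk_grid(small_disk)
        J = ff.jacobian_standard(small_disk, vg, log_data=True)
        row = np.abs(J.block("mua")[7])  # mid-separation channel
        centers = vg.centers[vg.inside_mask]
        peak = centers[np.argmax(row)]
        src = small_disk.optodes.sources[0]
        det = small_disk.optodes.detectors[7]
        # the sensitivity crescent peaks near the optodes / chord, not at
        # the disk center
        assert np.linalg.norm(peak) > 0.5 * 43.0
        chord_mid = (src + det) / 2
        assert np.linalg.norm(peak - chord_mid) < 43.0

    def test_source_detector_swap_symmetry(self):
        # sources are moved one scattering length inside while detectors
        # are not, so agreement holds away from the optodes themselves
        props = ff.StandardProps(0.01, 1.0, 1.33, n_nodes=1)
        m = ff.make_disk_mesh(43.0, 2000, props)
        theta = 2 * np.pi * np.arange(8) / 8
        ring = np.column_stack([43 * np.cos(theta), 43 * np.sin(theta)])
        m.place_optodes(ring[[0]], ring[[3]], [[1, 1]])
        vg = disk_grid(m, 3.0)
        J1 = ff.jacobian_standard(m, vg, log_data=True).block("mua")[0]
        m.place_optodes(ring[[3]], ring[[0]], [[1, 1]])
        J2 = ff.jacobian_standard(m, vg, log_data=True).block("mua")[0]
        c = vg.centers[vg.inside_mask]
        far = ((np.linalg.norm(c - ring[0], axis=1) > 8)
               & (np.linalg.norm(c - ring[3], axis=1) > 8))
        assert np.abs(J1 - J2)[far].max() <= 0.05 * np.abs(J1[far]).max()

    def test_fd_jacobian_interleaves_real_imag(self, tiny_disk):
        vg = disk_grid(tiny_disk, 4.0, 22.0)
        omega = 2 * np.pi * 1e8
        J = ff.jacobian_standard(tiny_disk, vg, omega=omega, log_data=False)
        n_ch = len(tiny_disk.optodes.link)
        assert J.matrix.shape == (2 * n_ch, 2 * vg.n_inside)

    def test_voxel_volume_scaling(self, small_disk):
        # coarser voxels cover more tissue, so per-voxel sensitivities grow
        J2 = ff.jacobian_standard(small_disk, disk_grid(small_disk, 2.0),
                                  log_data=True)
        J4 = ff.jacobian_standard(small_disk, disk_grid(small_disk, 4.0),
                                  log_data=True)
        m2 = np.abs(J2.block("mua")).max()
        m4 = np.abs(J4.block("mua")).max()
        assert m4 == pytest.approx(4 * m2, rel=0.35)


class TestFluorescenceJacobian:
    def test_cw_returns_single_real_gamma_block(self, fluor_disk):
        vg = disk_grid(fluor_disk, 3.0, 32.0)
        J = ff.jacobian_fluorescence(fluor_disk, vg)
        assert J.params == ("gamma",)
        assert J.matrix.shape == (len(fluor_disk.optodes.link), vg.n_inside)
        assert np.isrealobj(J.matrix)
        assert np.all(J.matrix >= -1e-18)

    def test_gamma_block_matches_central_difference(self, fluor_disk):
        vg = disk_grid(fluor_disk, 2.0, 32.0)
        J = ff.jacobian_fluorescence(fluor_disk, vg, born_ratio=True)
        p = fluor_disk.props
        blob_nodal = 2e-5 * gaussian_blob(fluor_disk.nodes, [8.0, 0.0])
        blob_vox = 2e-5 * gaussian_blob(vg.centers[vg.inside_mask],
                                        [8.0, 0.0])
        outs = []
        for sgn in (+1, -1):
            pert = ff.Mesh(fluor_disk.nodes, fluor_disk.elements,
                           ff.FluorProps(p.muax, p.muspx, p.muam, p.muspm,
                                         p.gamma + sgn * blob_nodal, p.tau,
                                         p.ri),
                           optodes=fluor_disk.optodes)
            outs.append(ff.femdata_fluorescence(pert, 0.0)[2])
        fd = (outs[0] - outs[1]) / 2.0
        predicted = J.matrix @ blob_vox
        np.testing.assert_allclose(predicted, fd, rtol=0.05)

    def test_uniform_perturbation_row_sum(self):
        props = ff.FluorProps(0.0089, 1.3141, 0.0062, 1.2739, 0.00018, 1e-9,
                              1.33, n_nodes=1)
        m = ff.make_disk_mesh(30.0, 1000, props, with_optodes=True)
        g = np.arange(-30.0, 30.01, 2.0)
        vg = ff.build_grid_mapping(m, g, g)
        J = ff.jacobian_fluorescence(m, vg, born_ratio=True)
        delta = 2e-5
        p = m.props
        pert = ff.Mesh(m.nodes, m.elements,
                       ff.FluorProps(p.muax, p.muspx, p.muam, p.muspm,
                                     p.gamma + delta, p.tau, p.ri),
                       optodes=m.optodes)
        born0 = ff.femdata_fluorescence(m, 0.0)[2]
        born1 = ff.femdata_fluorescence(pert, 0.0)[2]
        predicted = J.matrix.sum(axis=1) * delta
        np.testing.assert_allclose(predicted, born1 - born0, rtol=0.05)


class TestDcsJacobian:
    def test_zero_delay_gives_zero_matrix(self, dcs_slab):
        xg = np.arange(10.0, 51.0, 5.0)
        zg = np.arange(1.0, 25.0, 5.0)
        vg = ff.build_grid_mapping(dcs_slab, xg, xg, zg)
        J = ff.jacobian_dcs(dcs_slab, vg, [0.0, 1e-5])
        assert np.all(J[0].matrix == 0.0)
        assert np.abs(J[1].matrix).max() > 0

    def test_alphadb_column_matches_central_difference(self):
        props = ff.DcsProps(0.01, 1.0, 1.37, 1e-6, 750.0, n_nodes=1)
        m = ff.make_slab_mesh(60, 60, 30, 1.5, props)
        m.place_optodes([[20, 30, 0]], [[40, 30, 0]], [[1, 1]])
        xg = np.arange(5.0, 56.0, 2.0)
        zg = np.arange(1.0, 20.0, 2.0)
        vg = ff.build_grid_mapping(m, xg, xg, zg)
        tau = 1e-4
        J = ff.jacobian_dcs(m, vg, [tau], log_data=True)[0]
        center = [30.0, 30.0, 5.0]
        blob_nodal = 2e-7 * gaussian_blob(m.nodes, center)
        blob_vox = 2e-7 * gaussian_blob(vg.centers[vg.inside_mask], center)
        vals = []
        for sgn in (+1, -1):
            pert = ff.Mesh(m.nodes, m.elements,
                           ff.DcsProps(0.01, 1.0, 1.37,
                                       1e-6 + sgn * blob_nodal, 750.0),
                           optodes=m.optodes)
            g = ff.femdata_dcs(pert, np.array([0.0, tau]))
            vals.append(np.log(g.G1[:, 1]))
        fd = (vals[0] - vals[1]) / 2.0
        predicted = J.matrix @ blob_vox
        np.testing.assert_allclose(predicted, fd, rtol=0.05)

    def test_proportional_to_delay_times_cw_pattern(self, dcs_slab):
        xg = np.arange(10.0, 51.0, 5.0)
        zg = np.arange(1.0, 25.0, 5.0)
        vg = ff.build_grid_mapping(dcs_slab, xg, xg, zg)
        taus = [0.0, 1e-6, 2e-6]
        J = ff.jacobian_dcs(dcs_slab, vg, taus, log_data=False)
        # at small delays the fields barely change, so J(2 tau) ~ 2 J(tau)
        dev = np.abs(J[2].matrix - 2 * J[1].matrix).max()
        assert dev <= 0.05 * np.abs(J[1].matrix).max()


class TestTikhonov:
    def test_zero_data_zero_image(self, small_disk):
        vg = disk_grid(small_disk, 3.0)
        J = ff.jacobian_standard(small_disk, vg, log_data=True)
        x = ff.tikhonov_reconstruct(J, np.zeros(J.matrix.shape[0]), 10.0)
        assert np.all(x == 0)

    def test_stronger_regularization_shrinks_solution(self, small_disk):
        vg = disk_grid(small_disk, 3.0)
        J = ff.jacobian_standard(small_disk, vg, log_data=True)
        rng = np.random.default_rng(11)
        y = rng.normal(size=J.matrix.shape[0])
        norms = [np.linalg.norm(ff.tikhonov_reconstruct(J, y, lam))
                 for lam in (1.0, 10.0, 100.0, 1e4)]
        assert np.all(np.diff(norms) < 0)

    def test_invalid_regularizer_rejected(self, small_disk):
        vg = disk_grid(small_disk, 3.0)
        J = ff.jacobian_standard(small_disk, vg, log_data=True)
        with pytest.raises(ValueError):
            ff.tikhonov_reconstruct(J, np.zeros(J.matrix.shape[0]), 0.0)
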