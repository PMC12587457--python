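import numpy as np
import pytest

import ffdot as ff


@pytest.fixture(scope="session")
def unit_tet():
    """Single right tetrahedron with unit legs, standard properties."""
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    elements = np.array([[1, 2, 3, 4]])
    props = ff.StandardProps(0.01, 1.0, 1.33, n_nodes=4)
    return ff.Mesh(nodes, elements, props)


@pytest.fixture(scope="session")
def small_disk():
    """~400-node standard disk with 1 source and 15 detectors."""
    props = ff.StandardProps(0.01, 1.0, 1.33, n_nodes=1)
    return ff.make_disk_mesh(43.0, 400, props, with_optodes=True)


@pytest.fixture(scope="session")
def tiny_disk():
    """Coarse disk for dense-oracle comparisons."""
    props = ff.StandardProps(0.01, 1.0, 1.33, n_nodes=1)
    return ff.make_disk_mesh(20.0, 60, props, with_optodes=True)


@pytest.fixture(scope="session")
def fluor_disk():
    """Coarse fluorescence disk (re-emission properties of a dye phantom)."""
    props = ff.FluorProps(0.0089, 1.3141, 0.0062, 1.2739, 0.00018, 1e-9,
                          1.33, n_nodes=1)
    return ff.make_disk_mesh(30.0, 300, props, with_optodes=True)


@pytest.fixture(scope="session")
def jac_disk():
    """~2000-node disk: fine enough for 5%-level perturbation oracles."""
    props = ff.StandardProps(0.01, 1.0, 1.33, n_nodes=1)
    return ff.make_disk_mesh(43.0, 2000, props, with_optodes=True)


@pytest.fixture(scope="session")
def small_slab():
    """Coarse tetrahedral slab with one 15 mm channel on the top face."""
    props = ff.StandardProps(0.01, 1.0, 1.37, n_nodes=1)
    mesh = ff.make_slab_mesh(60.0, 60.0, 30.0, 5.0, props)
    mesh.place_optodes([[22.5, 30.0, 0.0]], [[37.5, 30.0, 0.0]], [[1, 1]])
    return mesh


@pytest.fixture(scope="session")
def dcs_slab():
    """Coarse DCS slab at 750 nm."""
    props = ff.DcsProps(0.01, 1.0, 1.37, 1e-6, 750.0, n_nodes=1)
    mesh = ff.make_slab_mesh(60.0, 60.0, 30.0, 5.0, props)
    mesh.place_optodes([[22.5, 30.0, 0.0]], [[37.5, 30.0, 0.0]], [[1, 1]])
    return mesh
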