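import numpy as np
import pytest

from kneedeg import materials as M
from kneedeg import simplified_joint as SJ
from kneedeg.atlas import load_atlas, load_gait_waveform


@pytest.fixture(scope="session")
def library():
    return M.load_default_materials()


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def gait():
    return load_gait_waveform()


@pytest.fixture(scope="session")
def coarse_fixture_geometry():
    """Reduced-density calibration fixture for fast transient runs."""
    return SJ.SimplifiedGeometry(n_r_tibial=10, n_z_tibial=4,
                                 n_phi_femoral=8, n_rho_femoral=3)


@pytest.fixture(scope="session")
def htipe_ramp(library):
    """One default-resolution HTIPE ramp on the calibration fixture."""
    return SJ.run_ramp_experiment("htipe", n_steps=40, library=library)


@pytest.fixture(scope="session")
def frpve_ramp(library):
    return SJ.run_ramp_experiment("frpve", n_steps=40, library=library)


def make_column_model(material, nz=24, radius=1.0, thickness=2.0,
                      drained_top=True, stab_alpha=0.005):
    """Confined-compression column: u_r = 0 everywhere, base fixed."""
    from kneedeg import fe_solver as FE

    mesh = FE.rect_block_mesh(radius=radius, thickness=thickness, nr=1, nz=nz)
    drained = [(0, "top")] if drained_top else []
    model = FE.BiphasicModel(
        [(mesh, material)],
        fixed_u=[(0, "base", "z"), (0, "all", "r")],
        drained=drained,
        stab_alpha=stab_alpha,
    )
    areas = FE._surface_node_areas(model.nodes, mesh.node_sets["top"])
    pattern = np.zeros(model.ndof_u + model.nn)
    pattern[2 * mesh.node_sets["top"] + 1] = -areas
    return model, mesh, pattern, float(areas.sum())


def terzaghi_pressure(z_frac_from_drained, T, n_terms=200):
    """Series solution of 1-D consolidation: drained top, sealed base."""
    s = 0.0
    for m in range(n_terms):
        Mm = 0.5 * np.pi * (2 * m + 1)
        s += 2.0 / Mm * np.sin(Mm * z_frac_from_drained) * np.exp(-Mm * Mm * T)
    return s
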