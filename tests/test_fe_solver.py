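import numpy as np
import pandas as pd
import pytest

from kneedeg import fe_solver as FE
from kneedeg import materials as M
from conftest import make_column_model, terzaghi_pressure


class TestMeshes:
    def test_block_volume_exact(self):
        mesh = FE.rect_block_mesh(radius=4.0 / np.sqrt(np.pi), thickness=2.0,
                                  nr=16, nz=6)
        assert mesh.element_volumes().sum() == pytest.approx(32.0, rel=1e-12)

    def test_axis_nodes_on_axis(self):
        mesh = FE.rect_block_mesh(1.0, 1.0, 4, 4)
        assert np.allclose(mesh.nodes[mesh.node_sets["axis"], 0], 0.0)

    def test_positive_jacobians_enforced(self, library):
        mesh = FE.spherical_cap_mesh(2.0, 2.0, 0.5 * np.pi, 10, 4)
        model = FE.BiphasicModel([(mesh, library["htipe"]["femur"])],
                                 fixed_u=[(0, "bone", "rz")])
        assert np.all(model.w > 0)

    def test_cap_depth_field(self):
        mesh = FE.spherical_cap_mesh(35.0, 2.5, 0.4, 12, 4)
        assert np.all((mesh.hz >= 0) & (mesh.hz <= 1))
        assert mesh.hz.max() > 0.8 and mesh.hz.min() < 0.2

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            FE.rect_block_mesh(0.0, 1.0, 4, 4)
        with pytest.raises(ValueError):
            FE.spherical_cap_mesh(2.0, 3.0, 0.5, 4, 2)


class TestConsolidation:
    def test_matches_terzaghi_series(self, library):
        """Sealed-sides column, drained top, step load: pore pressure
        follows the 1-d consolidation series within 2%."""
        tib = library["htipe"]["tibia"]
        C = M.ti_stiffness_matrix(tib)
        cv = C[2, 2] * tib.k * M.SI_PERM_TO_MM
        h = 2.0
        model, mesh, pattern, area = make_column_model(tib)
        sigma0 = 0.1
        times = np.concatenate([[0, 1e-3], np.linspace(0.1, 8.0, 80)])
        forces = np.where(times >= 1e-3, sigma0, times / 1e-3 * sigma0)
        fh = model.march(FE.LoadProtocol(times, forces), nodal_force=pattern)
        z = model.nodes[:, 1]
        for k in (12, 40, 70):
            t = fh.times[k]
            T = cv * t / h**2
            for frac in (0.3, 0.6, 1.0):     # depth fraction from drained top
                nid = int(np.argmin(np.abs(z - h * (1 - frac))
                                    + model.nodes[:, 0]))
                p_ref = sigma0 * terzaghi_pressure(frac, T)
                assert fh.pore_pressure[k, nid] == pytest.approx(
                    p_ref, abs=0.02 * sigma0)

    def test_undrained_instant_response(self, library):
        """Sealed column under a fast step: p approaches the applied stress."""
        tib = library["htipe"]["tibia"]
        model, mesh, pattern, area = make_column_model(tib, drained_top=False)
        sigma0 = 0.1
        fh = model.march(FE.LoadProtocol(np.array([0.0, 1e-4]),
                                         np.array([0.0, sigma0])),
                         nodal_force=pattern)
        assert fh.pore_pressure[-1].mean() == pytest.approx(sigma0, rel=0.02)

    def test_drained_limit_high_permeability(self, library):
        """With permeability scaled up 10^6, pore pressure vanishes."""
        from dataclasses import replace
        tib = replace(library["htipe"]["tibia"], k=1e-9)
        model, mesh, pattern, area = make_column_model(tib)
        fh = model.march(FE.LoadProtocol(np.array([0.0, 0.1, 1.0]),
                                         np.array([0.0, 0.1, 0.1])),
                         nodal_force=pattern)
        assert np.abs(fh.pore_pressure[-1]).max() < 1e-3 * 0.1

    def test_slow_loading_small_pressure(self, library):
        """Load rate -> 0: the response approaches the drained solution."""
        tib = library["htipe"]["tibia"]
        model, mesh, pattern, area = make_column_model(tib)
        t_slow = 2000.0                      # >> consolidation time (~19 s)
        fh = model.march(FE.LoadProtocol(np.linspace(0, t_slow, 41),
                                         np.linspace(0, 0.1, 41)),
                         nodal_force=pattern)
        assert np.abs(fh.pore_pressure[-1]).max() < 0.02 * 0.1

    def test_zero_force_zero_fields(self, library):
        model, mesh, pattern, area = make_column_model(library["htipe"]["tibia"])
        fh = model.march(FE.LoadProtocol(np.array([0.0, 0.1]),
                                         np.array([0.0, 0.0])),
                         nodal_force=pattern)
        assert np.allclose(fh.displacement, 0.0)
        assert np.allclose(fh.pore_pressure, 0.0)
        assert np.allclose(fh.elem_stress, 0.0)


class TestReaction:
    def test_base_reaction_balances_applied_force(self, htipe_ramp):
        """Axial reaction at the fixed base equals the applied force at
        every recorded step (within 0.5%)."""
        fh = htipe_ramp
        for k in range(1, len(fh.times)):
            applied = fh.applied_force[k]
            if applied < 1.0:
                continue
            assert abs(abs(fh.reaction_force[k]) - applied) < 0.005 * applied


class TestRefinement:
    def test_peak_contact_pressure_mesh_converged(self, library):
        """Halving the element size changes peak contact pressure < 5%."""
        from kneedeg import simplified_joint as SJ

        a = SJ.run_ramp_experiment("htipe", n_steps=20, library=library)
        fine = SJ.SimplifiedGeometry(n_r_tibial=32, n_z_tibial=12,
                                     n_phi_femoral=28, n_rho_femoral=10)
        b = SJ.run_ramp_experiment("htipe", geometry=fine, n_steps=20,
                                   library=library)
        pa = FE.extract_summary(a)["per_time"]["contact_pressure_peak"].iloc[-1]
        pb = FE.extract_summary(b)["per_time"]["contact_pressure_peak"].iloc[-1]
        assert abs(pa - pb) / pb < 0.05


class TestSummaries:
    def _toy_history(self, pressures, areas, times=None):
        nt = 1 if np.ndim(pressures) == 1 else len(pressures)
        pressures = np.atleast_2d(np.asarray(pressures, dtype=float))
        ns = pressures.shape[1]
        ne = 2
        times = np.asarray(times if times is not None else np.arange(nt), dtype=float)
        return FE.FieldHistory(
            times=times,
            displacement=np.zeros((nt, 4, 2)),
            pore_pressure=np.zeros((nt, 4)),
            elem_stress=np.zeros((nt, ne, 4)),
            elem_strain=np.zeros((nt, ne, 4)),
            elem_pressure=np.zeros((nt, ne)),
            tensile_stress=np.zeros((nt, ne)),
            tensile_strain=np.zeros((nt, ne)),
            compressive_strain=np.zeros((nt, ne)),
            contact_pressure=pressures,
            contact_area=np.array([areas[p > 0].sum() for p in pressures]),
            contact_node_r=np.linspace(0, 1, ns),
            contact_node_area=np.asarray(areas, dtype=float),
            reaction_force=np.zeros(nt),
            master_disp=np.zeros(nt),
            elem_volumes=np.ones(ne),
            elem_centers=np.array([[0.1, 0.5], [0.9, 0.5]]),
            elem_body=np.zeros(ne, dtype=int),
            applied_force=np.zeros(nt),
        )

    def test_uniform_pressure_mean_equals_peak(self):
        fh = self._toy_history(np.array([[2.0, 2.0]]), np.array([1.0, 1.0]))
        tab = FE.extract_summary(fh)["per_time"]
        assert tab["contact_pressure_mean"][0] == pytest.approx(2.0)
        assert tab["contact_pressure_peak"][0] == pytest.approx(2.0)

    def test_two_node_mean_and_peak(self):
        fh = self._toy_history(np.array([[1.0, 3.0]]), np.array([1.0, 1.0]))
        tab = FE.extract_summary(fh)["per_time"]
        assert tab["contact_pressure_mean"][0] == pytest.approx(2.0)
        assert tab["contact_pressure_peak"][0] == pytest.approx(3.0)
        assert tab["contact_area"][0] == pytest.approx(2.0)

    def test_no_contact_reported_missing_not_zero(self):
        fh = self._toy_history(np.array([[0.0, 0.0]]), np.array([1.0, 1.0]))
        tab = FE.extract_summary(fh)["per_time"]
        assert np.isnan(tab["contact_pressure_mean"][0])
        assert np.isnan(tab["tensile_stress_mean"][0])

    def test_window_average_of_linear_ramp(self):
        t = np.linspace(0.0, 1.0, 11)
        tab = pd.DataFrame({"time": t, "contact_pressure_peak": 4.0 * t})
        out = FE.window_average(tab, (0.0, 1.0))
        assert out["contact_pressure_peak"] == pytest.approx(2.0)

    def test_window_outside_span_rejected(self):
        tab = pd.DataFrame({"time": [0.0, 1.0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            FE.window_average(tab, (0.5, 2.0))


class TestProtocol:
    def test_must_start_at_zero(self):
        with pytest.raises(ValueError):
            FE.LoadProtocol(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            FE.LoadProtocol(np.array([0.5, 1.0]), np.array([0.0, 2.0]))

    def test_piecewise_linear_interpolation(self):
        p = FE.LoadProtocol.ramp(50.0, 0.2, 4)
        assert p.force_at(0.1) == pytest.approx(25.0)

    def test_singular_without_constraints(self, library):
        mesh = FE.rect_block_mesh(1.0, 1.0, 2, 2)
        model = FE.BiphasicModel([(mesh, library["htipe"]["tibia"])])
        pattern = np.zeros(model.ndof_u + model.nn)
        pattern[1] = -1.0
        with pytest.raises(RuntimeError):
            model.march(FE.LoadProtocol(np.array([0.0, 1.0]),
                                        np.array([0.0, 1.0])),
                        nodal_force=pattern)
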