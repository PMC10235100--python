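import numpy as np
import pytest
from dataclasses import replace

from kneedeg import simplified_joint as SJ
from kneedeg.fe_solver import LoadProtocol, extract_summary


class TestFixtureGeometry:
    def test_block_volume_and_radius(self):
        g = SJ.SimplifiedGeometry()
        assert g.block_volume == pytest.approx(32.0)
        assert g.hemisphere_radius == 2.0
        assert g.equivalent_radius == pytest.approx(4.0 / np.sqrt(np.pi))
        assert g.equivalent_radius == pytest.approx(2.2568, abs=1e-4)

    def test_meshes_carry_geometry_metadata(self):
        tibial, femoral = SJ.build_fixture()
        meta = femoral.meta["geometry"]
        assert meta["hemisphere_radius_mm"] == 2.0
        assert meta["block_volume_mm3"] == pytest.approx(32.0)
        assert tibial.element_volumes().sum() == pytest.approx(32.0, rel=1e-12)

    def test_fixture_fibrils_surface_parallel(self):
        _, femoral = SJ.build_fixture()
        assert np.allclose(femoral.normal_angle, 0.0)

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            SJ.SimplifiedGeometry(block_thickness=-1.0)


class TestRampExperiment:
    def test_reaction_reaches_applied_force(self, htipe_ramp):
        fh = htipe_ramp
        assert fh.times[-1] == pytest.approx(0.2)
        assert abs(abs(fh.reaction_force[-1]) - 50.0) < 0.005 * 50.0

    def test_zero_force_protocol_zero_fields(self, library,
                                             coarse_fixture_geometry):
        tibial, femoral = SJ.build_fixture(coarse_fixture_geometry)
        from kneedeg.fe_solver import BiphasicModel
        model = BiphasicModel(
            [(tibial, library["htipe"]["tibia"]),
             (femoral, library["htipe"]["femur"])],
            fixed_u=[(0, "base", "rz")], drive=(1, "bone"), contact=(1, 0))
        fh = model.march(LoadProtocol(np.array([0.0, 0.2]),
                                      np.array([0.0, 0.0])))
        assert np.allclose(fh.tensile_stress, 0.0)
        assert np.allclose(fh.pore_pressure, 0.0, atol=1e-12)

    def test_frpve_surface_tension_under_contact(self, frpve_ramp):
        """The fibril-reinforced run concentrates surface-parallel tension
        in the loaded region (positive max principal stress near the
        contact, exceeding the far field)."""
        fh = frpve_ramp
        near = fh.elem_centers[:, 0] < 1.0
        far = fh.elem_centers[:, 0] > 2.0
        assert fh.tensile_stress[-1][near].max() > 1.0
        assert (fh.tensile_stress[-1][near].max()
                > 2.0 * fh.tensile_stress[-1][far].max())


class TestCompareMaterials:
    def test_identical_histories_zero_difference(self, htipe_ramp):
        d = SJ.compare_materials(htipe_ramp, htipe_ramp, window=(0.1, 0.2))
        assert np.allclose(d["abs_diff"].astype(float), 0.0, atol=1e-12)

    def test_scaled_stresses_ten_percent(self, htipe_ramp):
        import copy
        b = copy.deepcopy(htipe_ramp)
        for attr in ("tensile_stress", "elem_pressure", "contact_pressure",
                     "elem_stress"):
            setattr(b, attr, 1.1 * getattr(b, attr))
        d = SJ.compare_materials(b, htipe_ramp, window=(0.1, 0.2))
        stress_rows = d[d["response"].isin(
            ["contact_pressure", "pore_pressure", "tensile_stress"])]
        assert np.allclose(stress_rows["rel_diff"].astype(float), 0.1, atol=1e-9)

    def test_mismatched_grids_rejected(self, htipe_ramp, library,
                                       coarse_fixture_geometry):
        other = SJ.run_ramp_experiment("htipe", geometry=coarse_fixture_geometry,
                                       n_steps=10, library=library)
        with pytest.raises(ValueError):
            SJ.compare_materials(htipe_ramp, other)

    def test_model_differences_nonzero(self, htipe_ramp, frpve_ramp):
        """The simpler model does not replicate the fibril-reinforced
        reference exactly; differences are finite and well-defined."""
        d = SJ.compare_materials(htipe_ramp, frpve_ramp, window=(0.1, 0.2))
        ts = d[(d.response == "tensile_stress")]
        assert np.all(np.isfinite(ts["rel_diff"].astype(float)))
        assert np.any(np.abs(ts["rel_diff"].astype(float)) > 0.01)


class TestCalibration:
    def test_degenerate_start_at_truth_returns_truth(self, library,
                                                     coarse_fixture_geometry):
        g = coarse_fixture_geometry
        ref = SJ.run_ramp_experiment("htipe", geometry=g, n_steps=6,
                                     library=library)
        res = SJ.calibrate_simple_material(
            ref, (library["htipe"]["tibia"], library["htipe"]["femur"]),
            free=("E_11",), geometry=g, n_steps=6, max_nfev=8)
        assert res.params_femur.E_11 == pytest.approx(60.0, rel=0.01)
        assert res.objective < 1e-10

    def test_self_recovery_from_perturbed_start(self, library,
                                                coarse_fixture_geometry):
        """Reference generated with the published homogeneous set; the
        optimiser recovers it within 10% from a 40%/30% perturbed start."""
        g = coarse_fixture_geometry
        ref = SJ.run_ramp_experiment("htipe", geometry=g, n_steps=8,
                                     library=library)
        fem0 = replace(library["htipe"]["femur"], E_11=60.0 * 1.4,
                       G_13=7.9 * 0.7)
        tib0 = replace(library["htipe"]["tibia"], E_11=50.0 * 1.4,
                       G_13=6.4 * 0.7)
        res = SJ.calibrate_simple_material(
            ref, (tib0, fem0), free=("E_11", "G_13"), geometry=g,
            n_steps=8, max_nfev=60)
        assert res.params_femur.E_11 == pytest.approx(60.0, rel=0.10)
        assert res.params_femur.G_13 == pytest.approx(7.9, rel=0.10)

    def test_invalid_factor_bounds_rejected(self, htipe_ramp, library):
        with pytest.raises(ValueError):
            SJ.calibrate_simple_material(
                htipe_ramp,
                (library["htipe"]["tibia"], library["htipe"]["femur"]),
                bounds=(2.0, 5.0))
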