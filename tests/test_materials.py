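import numpy as np
import pytest

from kneedeg import materials as M


class TestStiffness:
    @pytest.mark.parametrize("which", [
        ("htipe", "femur"), ("htipe", "tibia"),
        ("tipe", "superficial"), ("tipe", "middle"), ("tipe", "deep"),
    ])
    def test_default_sets_positive_definite(self, library, which):
        """Every shipped transversely isotropic set is admissible under the
        S_ij = -nu_ij/E_ii compliance convention."""
        model, part = which
        p = library[model][part] if model == "htipe" else getattr(library[model], part)
        C = M.ti_stiffness_matrix(p)
        assert np.linalg.eigvalsh(C).min() > 0
        assert np.allclose(C, C.T)

    def test_isotropy_limit_matches_closed_form(self):
        E, nu = 10.0, 0.3
        p = M.TransverseIsotropicParams(
            E_11=E, E_33=E, nu_12=nu, nu_13=nu,
            G_12=E / (2 * (1 + nu)), G_13=E / (2 * (1 + nu)), k=1e-15)
        assert np.allclose(M.ti_stiffness_matrix(p),
                           M.isotropic_stiffness_matrix(E, nu), atol=1e-9)

    def test_inadmissible_set_reports_eigenvalues(self):
        with pytest.raises(ValueError, match="eigenvalue"):
            M.TransverseIsotropicParams(E_11=1.0, E_33=100.0, nu_12=0.45,
                                        nu_13=0.9, G_12=1.0, G_13=1.0, k=1e-15)

    def test_frpve_instantaneous_stiffness_positive(self, library):
        """Matrix plus tensioned-fibril tangent is positive definite."""
        p = library["frpve"]["femur"]
        C = M.isotropic_stiffness_matrix(p.E_m, p.nu_m)
        assert np.linalg.eigvalsh(C).min() > 0


class TestFluidFraction:
    def test_frpve_depth_profile(self):
        assert M.fluid_fraction(0.0, "frpve") == pytest.approx(0.8)
        assert M.fluid_fraction(1.0, "frpve") == pytest.approx(0.65)

    def test_simple_models_constant(self):
        hz = np.linspace(0, 1, 11)
        assert np.allclose(M.fluid_fraction(hz, "htipe"), 0.8)
        assert np.allclose(M.fluid_fraction(hz, "tipe"), 0.8)

    def test_affine_in_depth_and_bounded(self):
        hz = np.linspace(0, 1, 101)
        nf = M.fluid_fraction(hz, "frpve")
        assert np.allclose(np.diff(nf, 2), 0.0, atol=1e-12)
        assert np.all((nf > 0) & (nf < 1))

    def test_out_of_range_depth_rejected(self):
        with pytest.raises(ValueError):
            M.fluid_fraction(1.5, "frpve")


class TestFibrilKernel:
    def test_elastic_limit_without_damping(self, library):
        """eta = 0 reduces the update to sigma = (E0 + Eeps*eps)*eps."""
        from dataclasses import replace
        p = replace(library["frpve"]["femur"], eta=0.0)
        eps = 0.05
        sig, sig_m, _ = M.fibril_stress_update(
            np.array([eps]), np.array([0.0]), np.array([0.0]), p, dt=1e-3)
        assert sig[0] == pytest.approx((p.E_0 + p.E_eps * eps) * eps, rel=1e-12)
        assert sig_m[0] == 0.0

    def test_relaxation_decays_to_elastic_limit(self, library):
        """Constant strain after a ramp: stress decreases monotonically
        towards the equilibrium spring value."""
        p = library["frpve"]["femur"]
        dt, eps_hold = 0.01, 0.08
        e_prev, s_m = np.array([0.0]), np.array([0.0])
        # ramp over 10 steps
        for k in range(1, 11):
            e = np.array([eps_hold * k / 10])
            sig, s_m, _ = M.fibril_stress_update(e, e_prev, s_m, p, dt)
            e_prev = e
        hold = []
        for _ in range(2000):
            sig, s_m, _ = M.fibril_stress_update(e_prev, e_prev, s_m, p, dt=1.0)
            hold.append(sig[0])
        hold = np.array(hold)
        assert np.all(np.diff(hold) <= 1e-12)
        elastic = (p.E_0 + p.E_eps * eps_hold) * eps_hold
        assert hold[-1] == pytest.approx(elastic, rel=1e-3)
        assert hold[0] >= elastic

    def test_tension_only(self, library):
        p = library["frpve"]["tibia"]
        sig, _, kt = M.fibril_stress_update(
            np.array([-0.1]), np.array([0.0]), np.array([0.0]), p, dt=1e-2)
        assert sig[0] == 0.0 and kt[0] == 0.0

    def test_zero_strain_zero_stress(self, library):
        p = library["frpve"]["femur"]
        stress, state = M.frpve_stress_update(
            np.zeros((3, 3)), np.zeros((3, 3)), M.MaterialState.zero(), p, dt=1e-3)
        assert np.allclose(stress, 0.0)

    def test_point_update_matches_kernel_along_fibril(self, library):
        """Uniaxial stretch along a surface-parallel fibril: the fibril part
        of the stress equals the 1-d kernel times the family multiplicity."""
        from dataclasses import replace
        arch = M.FibrilArchitecture.surface_parallel()
        arch = replace(arch, n_secondary=0)
        p = replace(library["frpve"]["femur"], eta=0.0, architecture=arch)
        eps = np.zeros((3, 3))
        eps[0, 0] = 0.05
        stress, _ = M.frpve_stress_update(
            eps, np.zeros((3, 3)), M.MaterialState.zero(), p, dt=1e-3, hz=1.0)
        lam = p.E_m * p.nu_m / ((1 + p.nu_m) * (1 - 2 * p.nu_m))
        G = p.E_m / (2 * (1 + p.nu_m))
        matrix_11 = lam * 0.05 + 2 * G * 0.05
        fib = (p.E_0 + p.E_eps * 0.05) * 0.05 * arch.family_weight
        assert stress[0, 0] == pytest.approx(matrix_11 + fib, rel=1e-10)

    def test_invalid_dt_rejected(self, library):
        with pytest.raises(ValueError):
            M.fibril_stress_update(np.array([0.1]), np.array([0.0]),
                                   np.array([0.0]), library["frpve"]["femur"], dt=0.0)


class TestArchitecture:
    def test_directions_unit_norm_and_continuous(self):
        arch = M.FibrilArchitecture()
        hz = np.linspace(0, 1, 201)
        dirs, w = arch.families_local(hz)
        assert np.allclose(np.linalg.norm(dirs, axis=-1), 1.0)
        # orientation varies continuously with depth
        assert np.max(np.abs(np.diff(dirs, axis=0))) < 0.02
        assert len(w) == dirs.shape[1]

    def test_surface_parallel_override(self):
        arch = M.FibrilArchitecture.surface_parallel()
        assert np.allclose(arch.tilt_angle(np.linspace(0, 1, 11)), 0.0)

    def test_arcade_limits(self):
        arch = M.FibrilArchitecture()
        assert arch.tilt_angle(1.0) == pytest.approx(0.0)
        assert arch.tilt_angle(0.0) == pytest.approx(np.pi / 2)
        assert arch.tilt_angle(arch.transition_depth) == pytest.approx(0.0)


class TestZoneLookup:
    def test_surface_and_deep(self, library):
        z = library["tipe"]
        assert M.tipe_zone_lookup(1.0, z).E_11 == pytest.approx(24.0)
        assert M.tipe_zone_lookup(0.0, z).E_11 == pytest.approx(8.485)

    def test_boundary_belongs_to_deeper_zone(self, library):
        z = library["tipe"]
        assert M.tipe_zone_lookup(0.85, z).E_11 == pytest.approx(16.97)
        assert M.tipe_zone_lookup(0.5, z).E_11 == pytest.approx(8.485)

    def test_range_check(self, library):
        with pytest.raises(ValueError):
            M.tipe_zone_lookup(-0.1, library["tipe"])


def test_material_yaml_roundtrip_values(library):
    """Shipped defaults carry the published parameter values."""
    fem = library["frpve"]["femur"]
    assert (fem.E_eps, fem.E_0, fem.E_m) == (150.0, 0.92, 0.215)
    assert fem.eta == 1062.0 and fem.k_0 == pytest.approx(6.0e-15)
    ht = library["htipe"]["tibia"]
    assert (ht.E_11, ht.E_33, ht.G_12, ht.G_13) == (50.0, 3.0, 4.4, 6.4)
    assert library["tipe"].zone_fractions == (0.15, 0.35, 0.50)
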