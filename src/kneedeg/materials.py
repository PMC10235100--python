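"""Constitutive models for articular cartilage.

Three material descriptions are provided:

* **FRPVE** -- fibril-reinforced poroviscoelastic: a fluid-saturated
  mixture of an isotropic non-fibrillar matrix (``E_m``, ``nu_m``) and a
  tension-only collagen fibril network whose modulus stiffens with
  strain (``E_f = E_0 + E_eps * eps_f``) and which dissipates through a
  dashpot ``eta``.  Fibril orientation follows a depth-wise arcade:
  parallel to the articular surface superficially, bending towards the
  surface normal in the deep tissue.
* **TIPE** -- transversely isotropic poroelastic with three depth zones
  (superficial/middle/deep), identical for femoral and tibial cartilage.
* **HTIPE** -- depth-homogeneous transversely isotropic poroelastic whose
  parameters were calibrated to mimic the FRPVE response.

All moduli are in MPa, the damping coefficient in MPa*s and
permeabilities in m^4 N^-1 s^-1 (SI); the finite-element layer works in
a mm-N-MPa-s system and converts permeability at the boundary.

Poisson's ratio convention: ``nu_ij`` characterises the transverse
strain in the *j*-direction when the tissue is stressed in the
*i*-direction, giving compliance entries ``S_ij = -nu_ij / E_ii``.
Under this convention every shipped parameter set yields a symmetric
positive-definite stiffness (the alternative convention would make the
HTIPE ``nu_13 = 1.9`` thermodynamically inadmissible).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "FRPVEParams",
    "TransverseIsotropicParams",
    "ZonalTIPE",
    "FibrilArchitecture",
    "MaterialState",
    "ti_stiffness_matrix",
    "isotropic_stiffness_matrix",
    "fluid_fraction",
    "fibril_stress_update",
    "frpve_stress_update",
    "tipe_zone_lookup",
    "load_default_materials",
    "SI_PERM_TO_MM",
]

#: 1 m^4 N^-1 s^-1 = 1e12 mm^4 N^-1 s^-1
SI_PERM_TO_MM = 1.0e12


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FibrilArchitecture:
    """Discretised arcade-like collagen architecture.

    ``n_primary`` fibrils are represented by ``n_primary // 2``
    orthogonal in-plane line families; the network stress sums over
    fibril directions, so each line family carries multiplicity
    ``family_weight`` (the two antiparallel fibrils of a line see the
    same strain).  Each primary family is tilted from the surface plane
    towards the surface normal below ``transition_depth``: parallel to
    the surface for ``hz >= transition_depth`` and rotating linearly to
    surface-normal at the bone interface (``hz = 0``).
    ``transition_depth = 0`` reproduces the surface-parallel
    architecture used in the simplified calibration fixture.

    ``n_secondary`` fibrils form a diagonally oriented secondary
    network (+-45 degrees between surface plane and normal) that
    provides the shear stiffness of the collagen mesh; without it the
    fibril-reinforced composite would have only the (nearly fluid)
    matrix shear modulus and collapse under contact shear.
    """

    n_primary: int = 4
    transition_depth: float = 2.0 / 3.0
    n_secondary: int = 4
    primary_density_factor: float = 3.009

    def __post_init__(self) -> None:
        if self.n_primary < 2 or self.n_primary % 2:
            raise ValueError("n_primary must be a positive even count")
        if not 0.0 <= self.transition_depth <= 1.0:
            raise ValueError("transition_depth must lie in [0, 1]")

    @classmethod
    def surface_parallel(cls, n_primary: int = 4) -> "FibrilArchitecture":
        """Architecture with fibrils parallel to the surface at all depths."""
        return cls(n_primary=n_primary, transition_depth=0.0)

    def tilt_angle(self, hz: float | np.ndarray) -> np.ndarray:
        """Angle (rad) between fibril direction and the surface plane at depth ``hz``."""
        hz = np.asarray(hz, dtype=float)
        if np.any(hz < -1e-12) or np.any(hz > 1 + 1e-12):
            raise ValueError("hz must lie in [0, 1]")
        td = self.transition_depth
        if td == 0.0:
            return np.zeros_like(hz)
        return 0.5 * np.pi * np.clip((td - hz) / td, 0.0, 1.0)

    @property
    def n_families(self) -> int:
        return max(1, self.n_primary // 2)

    @property
    def family_weight(self) -> float:
        """Fibril multiplicity per represented primary family.

        The network stress is a sum over fibril *directions*; the two
        antiparallel fibrils of one line carry the same strain, so each
        represented line family contributes with multiplicity
        ``n_primary / n_families`` (= 2 for the default 4-fibril
        arcade), further weighted by the relative density of primary
        over secondary fibrils (``primary_density_factor``).
        """
        return self.n_primary / self.n_families * self.primary_density_factor

    def directions(self, hz: float) -> list[np.ndarray]:
        """Unit primary-fibril directions in the local surface frame.

        The frame is (e1 = in-plane meridian, e2 = in-plane hoop,
        e3 = surface normal).  One direction per fibril line family;
        each carries ``family_weight`` fibrils.
        """
        theta = float(self.tilt_angle(hz))
        c, s = np.cos(theta), np.sin(theta)
        dirs = [np.array([c, 0.0, s]), np.array([0.0, c, s])]
        return dirs[: self.n_families]

    def families_local(self, hz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All fibril families (primary + secondary) at depths ``hz``.

        Returns ``(dirs, weights)`` with ``dirs`` of shape
        ``(len(hz), n_families_total, 3)`` in the local surface frame
        and per-family fibril multiplicities ``weights``.  Secondary
        fibrils form a fixed +-45 degree diagonal set (two in the
        meridian-normal plane, two in the hoop-normal plane) that gives
        the network its shear stiffness; they use the same stress law
        as the primaries.
        """
        hz = np.asarray(hz, dtype=float)
        theta = self.tilt_angle(hz)
        c, s = np.cos(theta), np.sin(theta)
        z = np.zeros_like(theta)
        dirs = [np.stack([c, z, s], axis=-1)]
        weights = [self.family_weight]
        if self.n_families > 1:
            dirs.append(np.stack([z, c, s], axis=-1))
            weights.append(self.family_weight)
        if self.n_secondary:
            w = self.n_secondary / 4.0
            h = np.full_like(theta, np.sqrt(0.5))
            for v in ((h, z, h), (h, z, -h), (z, h, h), (z, h, -h)):
                dirs.append(np.stack(v, axis=-1))
                weights.append(w)
        return np.stack(dirs, axis=-2), np.asarray(weights)


@dataclass(frozen=True)
class FRPVEParams:
    """Fibril-reinforced poroviscoelastic parameter set (one tissue)."""

    E_eps: float
    E_0: float
    E_m: float
    nu_m: float
    eta: float
    k_0: float                       # m^4 N^-1 s^-1
    n_f_surface_coeffs: tuple[float, float] = (0.8, 0.15)
    architecture: FibrilArchitecture = field(default_factory=FibrilArchitecture)

    def __post_init__(self) -> None:
        if min(self.E_eps, self.E_0, self.E_m) <= 0:
            raise ValueError("all moduli must be positive")
        if not 0.0 <= self.nu_m < 0.5:
            raise ValueError("nu_m must lie in [0, 0.5)")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.k_0 <= 0:
            raise ValueError("k_0 must be positive")
        a, b = self.n_f_surface_coeffs
        for hz in (0.0, 1.0):
            if not 0.0 < a - b * hz < 1.0:
                raise ValueError("fluid fraction must stay inside (0, 1)")


@dataclass(frozen=True)
class TransverseIsotropicParams:
    """Engineering constants of a transversely isotropic poroelastic tissue.

    The plane of isotropy (axes 1-2) is parallel to the articular
    surface and represents the primary collagen fibril orientation; axis
    3 is the surface normal.  ``E_22 = E_11``, ``nu_23 = nu_13`` and
    ``G_23 = G_13`` by symmetry.
    """

    E_11: float
    E_33: float
    nu_12: float
    nu_13: float
    G_12: float
    G_13: float
    k: float                         # m^4 N^-1 s^-1
    n_f: float = 0.8
    plane_of_isotropy: str = "parallel to surface"

    @property
    def E_22(self) -> float:
        return self.E_11

    @property
    def nu_23(self) -> float:
        return self.nu_13

    @property
    def G_23(self) -> float:
        return self.G_13

    def __post_init__(self) -> None:
        if min(self.E_11, self.E_33, self.G_12, self.G_13) <= 0:
            raise ValueError("all moduli must be positive")
        if self.k <= 0:
            raise ValueError("permeability must be positive")
        if not 0.0 < self.n_f < 1.0:
            raise ValueError("fluid fraction must lie in (0, 1)")
        # fail early on inadmissible elasticity
        ti_stiffness_matrix(self)


@dataclass(frozen=True)
class ZonalTIPE:
    """Three-zone transversely isotropic poroelastic cartilage."""

    superficial: TransverseIsotropicParams
    middle: TransverseIsotropicParams
    deep: TransverseIsotropicParams
    zone_fractions: tuple[float, float, float] = (0.15, 0.35, 0.50)

    def __post_init__(self) -> None:
        f = np.asarray(self.zone_fractions, dtype=float)
        if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("zone fractions must be positive and sum to 1")


@dataclass
class MaterialState:
    """Viscoelastic history carried by the FRPVE fibril network.

    ``fibril_strain`` and ``maxwell_stress`` hold one value per fibril
    family; ``time`` is the elapsed simulation time.
    """

    fibril_strain: np.ndarray
    maxwell_stress: np.ndarray
    time: float = 0.0

    @classmethod
    def zero(cls, n_families: int = 6) -> "MaterialState":
        return cls(np.zeros(n_families), np.zeros(n_families), 0.0)

    @classmethod
    def for_architecture(cls, arch: FibrilArchitecture) -> "MaterialState":
        n = arch.n_families + (4 if arch.n_secondary else 0)
        return cls.zero(n)


# ---------------------------------------------------------------------------
# elasticity
# ---------------------------------------------------------------------------

def ti_stiffness_matrix(p: TransverseIsotropicParams) -> np.ndarray:
    """6x6 stiffness (MPa) from engineering constants, Voigt order
    (11, 22, 33, 23, 13, 12) with engineering shear strains.

    Raises ``ValueError`` with the eigenvalue spectrum if the resulting
    stiffness is not positive definite (invalid parameter set or wrong
    Poisson convention).
    """
    E1, E3 = p.E_11, p.E_33
    S = np.zeros((6, 6))
    S[0, 0] = S[1, 1] = 1.0 / E1
    S[2, 2] = 1.0 / E3
    S[0, 1] = S[1, 0] = -p.nu_12 / E1
    S[0, 2] = S[2, 0] = -p.nu_13 / E1
    S[1, 2] = S[2, 1] = -p.nu_23 / E1
    S[3, 3] = 1.0 / p.G_23
    S[4, 4] = 1.0 / p.G_13
    S[5, 5] = 1.0 / p.G_12
    eigvals = np.linalg.eigvalsh(S)
    if np.any(eigvals <= 0.0):
        raise ValueError(
            "non-positive-definite compliance; eigenvalues of the assembled "
            f"compliance matrix: {np.sort(eigvals)}"
        )
    C = np.linalg.inv(S)
    return 0.5 * (C + C.T)


def isotropic_stiffness_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness (Voigt, engineering shears)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    G = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2 * G
    C[3, 3] = C[4, 4] = C[5, 5] = G
    return C


# ---------------------------------------------------------------------------
# fluid fraction
# ---------------------------------------------------------------------------

def fluid_fraction(
    hz: float | np.ndarray,
    model: Literal["frpve", "tipe", "htipe"],
    params: FRPVEParams | TransverseIsotropicParams | None = None,
) -> np.ndarray:
    """Fluid (water) fraction at normalized depth ``hz``.

    For FRPVE the tabulated law is ``n_f(hz) = a - b*hz`` with
    ``hz = 1`` at the articular surface and ``hz = 0`` at the bone
    interface; note this places the *lower* fluid fraction at the
    surface, which is opposite to the physiological gradient -- the
    coefficients are configurable through ``FRPVEParams`` and are
    evaluated exactly as printed.  TIPE/HTIPE use a constant fraction.
    """
    hz = np.asarray(hz, dtype=float)
    if np.any(hz < 0.0) or np.any(hz > 1.0):
        raise ValueError("hz must lie in [0, 1]")
    if model == "frpve":
        a, b = params.n_f_surface_coeffs if params is not None else (0.8, 0.15)
        return a - b * hz
    if model in ("tipe", "htipe"):
        nf = params.n_f if params is not None else 0.8
        return np.full_like(hz, nf)
    raise ValueError(f"unknown material kind: {model!r}")


# ---------------------------------------------------------------------------
# FRPVE fibril kernel
# ---------------------------------------------------------------------------

#: width of the C1-smoothed tension gate [strain]; stresses inside the
#: band are O(E_0 * EPS_GATE), negligible against working stresses.
EPS_GATE = 5e-3


def fibril_stress_update(
    eps_f: np.ndarray,
    eps_prev: np.ndarray,
    sigma_m_prev: np.ndarray,
    p: FRPVEParams,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One implicit update of the fibril stress law (vectorised).

    The fibril is a tension-only, strain-stiffening spring
    ``sigma_eq = (E_0 + E_eps * eps) * eps`` in parallel with a Maxwell
    branch (the same secant spring in series with dashpot ``eta``).
    With ``eta = 0`` the Maxwell branch vanishes and the update is the
    algebraic elastic limit; under constant strain the Maxwell stress
    relaxes monotonically to zero so the total tends to the elastic
    limit.  The tension-only switch is smoothed over a strain band of
    width ``EPS_GATE`` (cubic smoothstep) so the global Newton loop
    sees a continuous tangent.  Returns
    ``(sigma_total, sigma_maxwell, tangent)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    eps_f = np.asarray(eps_f, dtype=float)
    eps_t = np.maximum(eps_f, 0.0)
    E_sec = p.E_0 + p.E_eps * eps_t
    sigma_eq = E_sec * eps_t
    if p.eta > 0.0:
        denom = 1.0 + E_sec * dt / p.eta
        sigma_m = (sigma_m_prev + E_sec * (eps_t - np.maximum(eps_prev, 0.0))) / denom
        k_maxwell = E_sec / denom
    else:
        sigma_m = np.zeros_like(eps_t)
        k_maxwell = np.zeros_like(eps_t)
    raw = sigma_eq + sigma_m
    raw_k = p.E_0 + 2.0 * p.E_eps * eps_t + k_maxwell
    t = np.clip(eps_f / EPS_GATE, 0.0, 1.0)
    gate = t * t * (3.0 - 2.0 * t)
    sigma = gate * raw
    # gated secant tangent: omitting the gate-derivative term keeps the
    # operator positive and monotone, which the fixed-point loop needs
    tangent = gate * raw_k
    sigma_m = gate * sigma_m
    return sigma, sigma_m, tangent


def frpve_stress_update(
    strain: np.ndarray,
    strain_rate: np.ndarray,
    state: MaterialState,
    p: FRPVEParams,
    arch: FibrilArchitecture | None = None,
    dt: float = 1e-3,
    hz: float = 1.0,
) -> tuple[np.ndarray, MaterialState]:
    """Effective-stress update for a material point (local surface frame).

    ``strain`` is the small-strain tensor (3x3) expressed in the local
    frame (e1, e2 in the surface plane, e3 the surface normal).  Total
    effective stress is the isotropic non-fibrillar matrix stress plus
    the sum of fibril-family stresses projected onto their directions.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    arch = arch or p.architecture
    strain = np.asarray(strain, dtype=float)
    dirs, weights = arch.families_local(np.array([hz]))
    dirs = dirs[0]                                    # (nfam, 3)
    eps_f = np.einsum("fi,ij,fj->f", dirs, strain, dirs)
    n = len(dirs)
    prev_eps = state.fibril_strain[:n]
    prev_sm = state.maxwell_stress[:n]
    sigma_f, sigma_m, _ = fibril_stress_update(eps_f, prev_eps, prev_sm, p, dt)
    if not np.all(np.isfinite(sigma_f)):
        raise RuntimeError(f"non-convergent fibril update, residual {sigma_f}")
    lam = p.E_m * p.nu_m / ((1 + p.nu_m) * (1 - 2 * p.nu_m))
    G = p.E_m / (2 * (1 + p.nu_m))
    stress = lam * np.trace(strain) * np.eye(3) + 2 * G * strain
    for d, s, w in zip(dirs, sigma_f, weights):
        stress += w * s * np.outer(d, d)
    new_state = MaterialState(eps_f.copy(), sigma_m.copy(), state.time + dt)
    return stress, new_state


# ---------------------------------------------------------------------------
# TIPE zone lookup
# ---------------------------------------------------------------------------

def tipe_zone_lookup(hz: float, z: ZonalTIPE) -> TransverseIsotropicParams:
    """Zone parameters at normalized depth ``hz``.

    Zones are half-open from the surface: a depth exactly on a zone
    boundary belongs to the deeper zone.
    """
    if not 0.0 <= hz <= 1.0:
        raise ValueError("hz must lie in [0, 1]")
    fs, fm, _ = z.zone_fractions
    b_sup = 1.0 - fs
    b_mid = 1.0 - fs - fm
    if hz > b_sup:
        return z.superficial
    if hz > b_mid:
        return z.middle
    return z.deep


# ---------------------------------------------------------------------------
# shipped defaults
# ---------------------------------------------------------------------------

def _ti_from_dict(d: dict) -> TransverseIsotropicParams:
    return TransverseIsotropicParams(
        E_11=float(d["E_11"]), E_33=float(d["E_33"]),
        nu_12=float(d["nu_12"]), nu_13=float(d["nu_13"]),
        G_12=float(d["G_12"]), G_13=float(d["G_13"]),
        k=float(d["k"]), n_f=float(d["n_f"]),
    )


def _frpve_from_dict(d: dict, arch: FibrilArchitecture | None = None) -> FRPVEParams:
    nf = d.get("n_f", {"a": 0.8, "b": 0.15})
    kwargs = {}
    if arch is not None:
        kwargs["architecture"] = arch
    return FRPVEParams(
        E_eps=float(d["E_eps"]), E_0=float(d["E_0"]), E_m=float(d["E_m"]),
        nu_m=float(d["nu_m"]), eta=float(d["eta"]), k_0=float(d["k_0"]),
        n_f_surface_coeffs=(float(nf["a"]), float(nf["b"])), **kwargs,
    )


def load_default_materials(path: str | None = None) -> dict:
    """Load the shipped (or a user) material parameter file.

    Returns ``{"frpve": {"femur": FRPVEParams, "tibia": FRPVEParams},
    "htipe": {...}, "tipe": ZonalTIPE}``.
    """
    if path is None:
        text = resources.files("kneedeg.data").joinpath("materials.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    tipe_raw = raw["tipe"]
    tipe = ZonalTIPE(
        superficial=_ti_from_dict(tipe_raw["superficial"]),
        middle=_ti_from_dict(tipe_raw["middle"]),
        deep=_ti_from_dict(tipe_raw["deep"]),
        zone_fractions=tuple(float(f) for f in tipe_raw["zone_fractions"]),
    )
    return {
        "frpve": {side: _frpve_from_dict(raw["frpve"][side]) for side in ("femur", "tibia")},
        "htipe": {side: _ti_from_dict(raw["htipe"][side]) for side in ("femur", "tibia")},
        "tipe": tipe,
    }


def frpve_with_architecture(p: FRPVEParams, arch: FibrilArchitecture) -> FRPVEParams:
    """Copy of ``p`` with a different fibril architecture."""
    return replace(p, architecture=arch)
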