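"""Simplified tibiofemoral calibration fixture.

The calibration experiment replaces the knee with a desk-scale fixture:
a tibial cartilage block (2 mm thick, 4 mm x 4 mm square footprint,
32 mm^3) pressed by a femoral cartilage hemisphere of radius 2 mm under
an axial ramp of 50 N applied within 0.2 s (the approximate duration of
the loading response of gait).  The tibial base is fixed, the femoral
body translates axially only, fluid cannot leave any boundary and the
contact interface is impermeable.

The fixture is axisymmetric here: the square block becomes a cylinder
of equal cross-sectional area (radius 4/sqrt(pi) mm), which preserves
the block volume and the contact mechanics while keeping
deformable-deformable contact tractable.  Collagen fibrils (and the
plane of isotropy of the simpler models) lie parallel to the articular
surfaces through the whole depth in this fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from . import materials as mat
from .fe_solver import (
    AxiMesh,
    BiphasicModel,
    FieldHistory,
    LoadProtocol,
    extract_summary,
    rect_block_mesh,
    spherical_cap_mesh,
    window_average,
)

__all__ = [
    "SimplifiedGeometry",
    "build_fixture",
    "run_ramp_experiment",
    "compare_materials",
    "calibrate_simple_material",
]

MaterialKind = Literal["frpve", "htipe", "tipe"]


@dataclass(frozen=True)
class SimplifiedGeometry:
    """Dimensions and mesh densities of the calibration fixture."""

    block_thickness: float = 2.0     # mm
    block_side: float = 4.0          # mm
    hemisphere_radius: float = 2.0   # mm
    n_r_tibial: int = 16
    n_z_tibial: int = 6
    n_phi_femoral: int = 14
    n_rho_femoral: int = 5

    def __post_init__(self) -> None:
        if min(self.block_thickness, self.block_side, self.hemisphere_radius) <= 0:
            raise ValueError("degenerate fixture dimensions")

    @property
    def block_volume(self) -> float:
        return self.block_thickness * self.block_side**2

    @property
    def equivalent_radius(self) -> float:
        """Radius of the cylinder with the block's cross-sectional area."""
        return self.block_side / np.sqrt(np.pi)


def build_fixture(g: SimplifiedGeometry | None = None) -> tuple[AxiMesh, AxiMesh]:
    """Tibial and femoral meshes of the axisymmetric fixture.

    Both meshes carry normalized-depth fields; fibril orientation for
    this fixture is surface-parallel through the whole depth, encoded
    by a zero ``normal_angle`` everywhere (the material surface frame
    is horizontal even inside the hemisphere, matching a press whose
    fibrils run parallel to both articular surfaces).
    """
    g = g or SimplifiedGeometry()
    tibial = rect_block_mesh(g.equivalent_radius, g.block_thickness,
                             g.n_r_tibial, g.n_z_tibial, surface="top")
    femoral = spherical_cap_mesh(
        outer_radius=g.hemisphere_radius,
        thickness=g.hemisphere_radius,
        phi_max=0.5 * np.pi,
        n_phi=g.n_phi_femoral,
        n_rho=g.n_rho_femoral,
        apex_z=g.block_thickness,
    )
    # surface-parallel architecture for the whole fixture
    femoral.normal_angle[:] = 0.0
    femoral.meta["geometry"] = tibial.meta["geometry"] = {
        "block_volume_mm3": g.block_volume,
        "hemisphere_radius_mm": g.hemisphere_radius,
        "equivalent_cylinder_radius_mm": g.equivalent_radius,
    }
    return tibial, femoral


def _fixture_materials(kind: MaterialKind, library: dict | None):
    lib = library or mat.load_default_materials()
    if kind == "frpve":
        arch = mat.FibrilArchitecture.surface_parallel()
        fem = replace(lib["frpve"]["femur"], architecture=arch)
        tib = replace(lib["frpve"]["tibia"], architecture=arch)
        return tib, fem
    if kind == "htipe":
        return lib["htipe"]["tibia"], lib["htipe"]["femur"]
    if kind == "tipe":
        return lib["tipe"], lib["tipe"]
    raise ValueError(f"unknown material kind {kind!r}")


def run_ramp_experiment(
    material: MaterialKind | tuple,
    geometry: SimplifiedGeometry | None = None,
    force: float = 50.0,
    duration: float = 0.2,
    n_steps: int = 40,
    library: dict | None = None,
    penalty_factor: float = 100.0,
) -> FieldHistory:
    """Run the axial ramp (default 50 N in 0.2 s) on the fixture.

    ``material`` is a model name ('frpve' | 'htipe' | 'tipe') or an
    explicit ``(tibial_material, femoral_material)`` pair.
    """
    g = geometry or SimplifiedGeometry()
    tibial, femoral = build_fixture(g)
    if isinstance(material, str):
        mat_tib, mat_fem = _fixture_materials(material, library)
    else:
        mat_tib, mat_fem = material
    model = BiphasicModel(
        regions=[(tibial, mat_tib), (femoral, mat_fem)],
        fixed_u=[(0, "base", "rz")],
        drive=(1, "bone"),
        contact=(1, 0),
        penalty_factor=penalty_factor,
    )
    protocol = LoadProtocol.ramp(force, duration, n_steps)
    return model.march(protocol)


_DIFF_RESPONSES = ("contact_pressure", "pore_pressure", "tensile_stress",
                   "tensile_strain", "compressive_strain")


def compare_materials(
    a: FieldHistory,
    b: FieldHistory,
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-response differences (a - b), absolute and relative to ``b``.

    ``a`` is the candidate (simpler) model, ``b`` the reference; mean
    and peak summaries are window-averaged before differencing.
    """
    if len(a.times) != len(b.times) or not np.allclose(a.times, b.times):
        raise ValueError("histories must share a time grid")
    window = window or (a.times[0], a.times[-1])
    wa = window_average(extract_summary(a)["per_time"], window)
    wb = window_average(extract_summary(b)["per_time"], window)
    rows = []
    for rname in _DIFF_RESPONSES + ("contact_area",):
        stats = ("mean", "peak") if rname != "contact_area" else ("",)
        for stat in stats:
            key = f"{rname}_{stat}" if stat else rname
            va, vb = wa[key], wb[key]
            rows.append({
                "response": rname, "stat": stat or "area",
                "value_a": va, "value_b": vb,
                "abs_diff": va - vb,
                "rel_diff": (va - vb) / vb if vb not in (0.0,) and np.isfinite(vb) else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    params_femur: mat.TransverseIsotropicParams
    params_tibia: mat.TransverseIsotropicParams
    factors: dict[str, float]
    objective: float
    n_evaluations: int
    history: list = field(default_factory=list)


def calibrate_simple_material(
    reference: FieldHistory,
    x0: tuple[mat.TransverseIsotropicParams, mat.TransverseIsotropicParams],
    free: tuple[str, ...] = ("E_11", "E_33", "G_12", "G_13", "nu_12", "nu_13"),
    bounds: tuple[float, float] = (0.2, 5.0),
    weights: tuple[float, float] = (0.7, 0.3),
    geometry: SimplifiedGeometry | None = None,
    force: float = 50.0,
    duration: float = 0.2,
    n_steps: int = 40,
    max_nfev: int = 60,
) -> CalibrationResult:
    """Fit homogeneous transversely isotropic materials to a reference run.

    Optimises multiplicative factors on the ``free`` engineering
    constants of the starting ``(tibial, femoral)`` pair ``x0`` (the
    same factor applies to both bodies, preserving their stiffness
    ratio), minimising a weighted least-squares mismatch of the
    tensile-stress summary curves (weight ``weights[0]``) and of the
    femoral axial indentation-depth history (weight ``weights[1]``) on
    the calibration fixture.  Fluid fraction and permeability stay
    pinned to the starting values.  Parameter sets that lose positive
    definiteness or defeat the solver are penalised rather than raised.
    """
    from scipy.optimize import least_squares

    g = geometry or SimplifiedGeometry()
    tib0, fem0 = x0
    lo, hi = bounds
    if not lo < 1.0 < hi:
        raise ValueError("factor bounds must bracket 1.0")
    v0 = np.ones(len(free))

    ref_tab = extract_summary(reference)["per_time"]
    ref_ts = np.nan_to_num(np.c_[ref_tab["tensile_stress_mean"],
                                 ref_tab["tensile_stress_peak"]])
    ref_def = reference.master_disp.copy()
    scale_ts = max(np.abs(ref_ts).max(), 1e-9)
    scale_def = max(np.abs(ref_def).max(), 1e-9)
    w_ts, w_def = weights
    n_eval = 0

    def build(v):
        kw_f = {f: getattr(fem0, f) * float(c) for f, c in zip(free, v)}
        kw_t = {f: getattr(tib0, f) * float(c) for f, c in zip(free, v)}
        return replace(tib0, **kw_t), replace(fem0, **kw_f)

    def residual(v: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        try:
            tib, fem = build(v)
            fh = run_ramp_experiment((tib, fem), geometry=g, force=force,
                                     duration=duration, n_steps=n_steps)
        except (ValueError, RuntimeError):
            return np.full(ref_ts.size + ref_def.size, 1e3)
        tab = extract_summary(fh)["per_time"]
        ts = np.nan_to_num(np.c_[tab["tensile_stress_mean"],
                                 tab["tensile_stress_peak"]])
        r1 = np.sqrt(w_ts) * (ts - ref_ts).ravel() / scale_ts
        r2 = np.sqrt(w_def) * (fh.master_disp - ref_def) / scale_def
        return np.concatenate([r1, r2])

    res = least_squares(residual, v0, bounds=(np.full_like(v0, lo),
                                              np.full_like(v0, hi)),
                        max_nfev=max_nfev, diff_step=0.08,
                        xtol=1e-6, ftol=1e-10)
    tib_fit, fem_fit = build(res.x)
    return CalibrationResult(
        params_femur=fem_fit, params_tibia=tib_fit,
        factors={f: float(c) for f, c in zip(free, res.x)},
        objective=float(res.cost), n_evaluations=n_eval)
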