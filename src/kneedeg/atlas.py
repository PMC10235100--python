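"""Atlas-to-subject geometry scaling and gait-load scaling.

Instead of segmenting images, subject models are generated by scaling a
template ("atlas") geometry by the ratios of measured anatomical
dimensions (distal femur and tibiofemoral joint space) between subject
and atlas.  Cartilage thickness is scaled *radially* -- along the local
surface normal -- which avoids the geometric distortion a cartesian
stretch produces when subject and atlas thicknesses differ strongly.
A generic stance-phase axial knee-force waveform (expressed in body
weights) is scaled by the subject's body weight and by the medial
compartment's load share.

The full-mesh template is out of scope here: scaling acts on a
parametric :class:`SurrogateGeometry` (effective femoral condyle
radius, medial cartilage thickness, plateau extent) consumed by the
axisymmetric contact surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AnatomicalDims",
    "SurrogateGeometry",
    "GaitLoad",
    "scale_factors",
    "radial_thickness_scale",
    "scale_gait",
    "load_atlas",
    "load_gait_waveform",
]

GRAVITY = 9.81  # m s^-2


@dataclass(frozen=True)
class AnatomicalDims:
    """Morphological knee dimensions used for atlas scaling [mm, kg]."""

    femoral_width: float
    medial_compartment_width: float
    medial_thickness: float
    lateral_thickness: float
    joint_space: float
    body_weight: float

    def __post_init__(self) -> None:
        vals = (self.femoral_width, self.medial_compartment_width,
                self.medial_thickness, self.lateral_thickness,
                self.joint_space, self.body_weight)
        if any(v <= 0 for v in vals):
            raise ValueError("anatomical dimensions must be positive")
        for t in (self.medial_thickness, self.lateral_thickness):
            if not 1.0 <= t <= 10.0:
                raise ValueError(f"cartilage thickness {t} mm outside 1-10 mm")


@dataclass(frozen=True)
class SurrogateGeometry:
    """Parametric stand-in for the scaled FE mesh (one medial compartment)."""

    contact_radius: float            # effective femoral condyle radius [mm]
    medial_thickness: float          # total cartilage thickness [mm]
    plateau_radius: float            # tibial plateau extent [mm]
    femoral_layer_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.contact_radius, self.medial_thickness, self.plateau_radius) <= 0:
            raise ValueError("surrogate geometry must be positive")

    @property
    def femoral_thickness(self) -> float:
        return self.medial_thickness * self.femoral_layer_fraction

    @property
    def tibial_thickness(self) -> float:
        return self.medial_thickness * (1.0 - self.femoral_layer_fraction)


@dataclass(frozen=True)
class GaitLoad:
    """Generic stance-phase axial knee load in body-weight multiples."""

    stance_percent: np.ndarray
    bw_multiple: np.ndarray
    medial_share: float = 0.65
    stance_duration: float = 0.6     # s

    def __post_init__(self) -> None:
        sp = np.asarray(self.stance_percent, dtype=float)
        bw = np.asarray(self.bw_multiple, dtype=float)
        object.__setattr__(self, "stance_percent", sp)
        object.__setattr__(self, "bw_multiple", bw)
        if np.any(bw < 0):
            raise ValueError("gait load must be non-negative")
        if not 0.0 < self.medial_share <= 1.0:
            raise ValueError("medial load share must lie in (0, 1]")

    def resample(self, n_points: int) -> "GaitLoad":
        sp = np.linspace(0.0, 100.0, n_points)
        bw = np.interp(sp, self.stance_percent, self.bw_multiple)
        return replace(self, stance_percent=sp, bw_multiple=bw)

    def times(self) -> np.ndarray:
        return self.stance_percent / 100.0 * self.stance_duration


def scale_factors(subject: AnatomicalDims, atlas: AnatomicalDims) -> dict[str, float]:
    """Subject/atlas ratios per dimension (multiplicative, 1.0 at identity).

    ``thickness`` is the medial-cartilage scaling factor that downstream
    statistics relate to model-difference magnitudes.
    """
    return {
        "femoral_width": subject.femoral_width / atlas.femoral_width,
        "medial_compartment_width":
            subject.medial_compartment_width / atlas.medial_compartment_width,
        "thickness": subject.medial_thickness / atlas.medial_thickness,
        "lateral_thickness": subject.lateral_thickness / atlas.lateral_thickness,
        "joint_space": subject.joint_space / atlas.joint_space,
    }


def radial_thickness_scale(geom: SurrogateGeometry, factor: float) -> SurrogateGeometry:
    """Scale cartilage thickness along the surface normal only.

    In-plane dimensions (contact radius, plateau extent) are untouched,
    so repeated application composes multiplicatively and no surface
    self-intersection can occur for positive factors.
    """
    if factor <= 0:
        raise ValueError("thickness scale factor must be positive")
    new_t = geom.medial_thickness * factor
    if new_t <= 0:
        raise ValueError("scaled thickness is non-positive")
    return replace(geom, medial_thickness=new_t)


def scale_width(geom: SurrogateGeometry, factor: float) -> SurrogateGeometry:
    """Scale the in-plane dimensions (condyle radius, plateau extent)."""
    if factor <= 0:
        raise ValueError("width scale factor must be positive")
    return replace(geom, contact_radius=geom.contact_radius * factor,
                   plateau_radius=geom.plateau_radius * factor)


def scale_gait(generic: GaitLoad, body_weight: float) -> np.ndarray:
    """Axial medial-compartment force samples [N] for a subject.

    ``force(t) = bw_multiple(t) * body_weight * g * medial_share``.
    """
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    return generic.bw_multiple * body_weight * GRAVITY * generic.medial_share


# ---------------------------------------------------------------------------
# shipped defaults
# ---------------------------------------------------------------------------

def load_atlas(path: str | None = None) -> dict:
    """Load the atlas configuration (shipped surrogate defaults or user file).

    Returns ``{"dims": AnatomicalDims, "geometry": SurrogateGeometry,
    "gait": {...}}``.
    """
    if path is None:
        text = resources.files("kneedeg.data").joinpath("atlas.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    d = raw["dimensions"]
    dims = AnatomicalDims(
        femoral_width=float(d["femoral_width_mm"]),
        medial_compartment_width=float(d["medial_compartment_width_mm"]),
        medial_thickness=float(d["medial_thickness_mm"]),
        lateral_thickness=float(d["lateral_thickness_mm"]),
        joint_space=float(d["joint_space_mm"]),
        body_weight=float(d["body_weight_kg"]),
    )
    s = raw["surrogate"]
    geometry = SurrogateGeometry(
        contact_radius=float(s["contact_radius_mm"]),
        medial_thickness=dims.medial_thickness,
        plateau_radius=float(s["tibial_plateau_radius_mm"]),
        femoral_layer_fraction=float(s["femoral_layer_fraction"]),
    )
    return {"dims": dims, "geometry": geometry, "gait": raw.get("gait", {})}


def load_gait_waveform(path: str | None = None, medial_share: float = 0.65,
                       stance_duration: float = 0.6) -> GaitLoad:
    """Load a gait waveform CSV (columns stance_percent, bw_multiple)."""
    if path is None:
        with resources.files("kneedeg.data").joinpath("gait_waveform.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    if not {"stance_percent", "bw_multiple"} <= set(df.columns):
        raise ValueError("gait CSV needs columns stance_percent, bw_multiple")
    return GaitLoad(df["stance_percent"].to_numpy(),
                    df["bw_multiple"].to_numpy(),
                    medial_share=medial_share,
                    stance_duration=stance_duration)
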