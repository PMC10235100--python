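"""Synthetic cohort generation.

Generates per-knee subject records that reproduce the published
per-KL-group sample statistics (age, BMI, medial and lateral cartilage
thickness; group sizes; counts of subjects with constant knee pain) of
the observational cohort the method was verified on, standing in for
registry data that cannot be redistributed.

Sampling is Gaussian, truncated by the inclusion rules (no subject
older than 70 years at baseline; cartilage thickness above 1 mm).  The
tabulated moments describe the *post-inclusion* sample, so the parent
Gaussian parameters are moment-matched such that the truncated
distribution reproduces the target mean and SD rather than the parent.

Body weight is not tabulated (only BMI); it is derived through a
subject height sampled from N(1.70, 0.09) m -- an explicit modelling
assumption flagged in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .atlas import AnatomicalDims, SurrogateGeometry, scale_factors
from .joint_surrogate import KneeCase

__all__ = [
    "SubjectRecord",
    "GroupStats",
    "CohortConfig",
    "generate_cohort",
    "assign_geometry",
    "cohort_to_cases",
    "load_default_cohort_config",
    "cohort_dataframe",
]

KL_GROUPS = ("KL01", "KL2", "KL34")
SIDES = ("left", "right")


@dataclass(frozen=True)
class SubjectRecord:
    """One knee of one synthetic subject."""

    subject_id: str
    side: str                        # 'left' | 'right'
    age: float                       # years, baseline
    bmi: float                       # kg/m^2
    height: float                    # m
    body_weight: float               # kg
    medial_thickness: float          # mm
    lateral_thickness: float         # mm
    kl_group: str                    # KL grade group at 8-year follow-up
    pain: bool
    dims: AnatomicalDims | None = None
    thickness_factor: float = 1.0


@dataclass(frozen=True)
class GroupStats:
    n: int
    pain: int
    age: tuple[float, float]         # mean, SD
    bmi: tuple[float, float]
    medial: tuple[float, float]
    lateral: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= self.pain <= self.n:
            raise ValueError("pain count outside group size")
        for m, s in (self.age, self.bmi, self.medial, self.lateral):
            if s < 0:
                raise ValueError("SD must be non-negative")


@dataclass
class CohortConfig:
    groups: dict[str, dict[str, GroupStats]]     # side -> group -> stats
    age_max: float = 70.0
    age_min: float = 40.0
    thickness_min: float = 1.0
    height_mean: float = 1.70
    height_sd: float = 0.09
    seed: int = 0

    def subset(self, sides=SIDES, kl_groups=KL_GROUPS) -> "CohortConfig":
        groups = {s: {g: self.groups[s][g] for g in kl_groups if g in self.groups[s]}
                  for s in sides}
        return CohortConfig(groups, self.age_max, self.age_min,
                            self.thickness_min, self.height_mean,
                            self.height_sd, self.seed)


def load_default_cohort_config(path: str | None = None, seed: int = 0) -> CohortConfig:
    """Shipped per-group subject statistics (or a user YAML)."""
    if path is None:
        text = resources.files("kneedeg.data").joinpath("cohort_table1.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    groups = {}
    for side, entries in raw["groups"].items():
        groups[side] = {}
        for gname, g in entries.items():
            groups[side][gname] = GroupStats(
                n=int(g["n"]), pain=int(g["pain"]),
                age=tuple(g["age"]), bmi=tuple(g["bmi"]),
                medial=tuple(g["medial"]), lateral=tuple(g["lateral"]))
    return CohortConfig(
        groups=groups,
        age_max=float(raw.get("age_max", 70.0)),
        age_min=float(raw.get("age_min", 40.0)),
        thickness_min=float(raw.get("thickness_min", 1.0)),
        height_mean=float(raw.get("height_mean_m", 1.70)),
        height_sd=float(raw.get("height_sd_m", 0.09)),
        seed=seed,
    )


def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Truncated normal whose *truncated* moments equal (mean, sd).

    The tabulated statistics describe the post-inclusion sample, so the
    parent Gaussian is adjusted by moment matching; the shift is small
    (the truncation bounds sit 2 or more SDs from the means) but matters
    when sample means are checked to a tenth of a year.
    """
    if not lo < mean < hi:
        raise ValueError(
            f"target mean {mean} incompatible with truncation [{lo}, {hi}]")

    def trunc_moments(v):
        mu, s = v
        s = abs(s)
        a, b = (lo - mu) / s, (hi - mu) / s
        m, var = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [m - mean, np.sqrt(var) - sd]

    sol = optimize.root(trunc_moments, x0=[mean, sd], method="hybr")
    if not sol.success:
        raise ValueError(f"truncation moment matching failed for "
                         f"mean={mean}, sd={sd}, bounds=({lo}, {hi})")
    mu, s = sol.x[0], abs(sol.x[1])
    a, b = (lo - mu) / s, (hi - mu) / s
    return stats.truncnorm(a, b, loc=mu, scale=s)


def _sample(rng, mean, sd, lo, hi, n):
    if sd == 0.0:
        return np.full(n, mean)
    dist = _matched_truncnorm(mean, sd, lo, hi)
    return dist.rvs(size=n, random_state=rng)


def generate_cohort(cfg: CohortConfig) -> list[SubjectRecord]:
    """Sample one knee record per configured cohort slot.

    Deterministic given ``cfg.seed``; group sizes and pain counts are
    exact, continuous covariates are truncated-Gaussian.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[SubjectRecord] = []
    for side in sorted(cfg.groups):
        for gname in sorted(cfg.groups[side]):
            g = cfg.groups[side][gname]
            age = _sample(rng, *g.age, cfg.age_min, cfg.age_max, g.n)
            bmi = _sample(rng, *g.bmi, 15.0, 60.0, g.n)
            med = _sample(rng, *g.medial, cfg.thickness_min, 10.0, g.n)
            lat = _sample(rng, *g.lateral, cfg.thickness_min, 10.0, g.n)
            height = np.clip(rng.normal(cfg.height_mean, cfg.height_sd, g.n),
                             1.40, 2.10)
            pain = np.zeros(g.n, dtype=bool)
            pain[rng.choice(g.n, size=g.pain, replace=False)] = True
            for i in range(g.n):
                records.append(SubjectRecord(
                    subject_id=f"{side[0].upper()}-{gname}-{i:04d}",
                    side=side,
                    age=float(age[i]),
                    bmi=float(bmi[i]),
                    height=float(height[i]),
                    body_weight=float(bmi[i] * height[i] ** 2),
                    medial_thickness=float(med[i]),
                    lateral_thickness=float(lat[i]),
                    kl_group=gname,
                    pain=bool(pain[i]),
                ))
    return records


def assign_geometry(
    rec: SubjectRecord,
    atlas_dims: AnatomicalDims,
    atlas_geometry: SurrogateGeometry,
    rng: np.random.Generator,
    radius_spread: float = 0.05,
) -> SubjectRecord:
    """Attach anatomical dimensions and a scaled surrogate geometry.

    The subject's medial thickness is copied into the dimensions; the
    femoral width (hence contact radius) is sampled around the atlas
    value with relative SD ``radius_spread``.  Returns a new record
    whose ``dims`` carry the subject dimensions and whose
    ``thickness_factor`` is the subject/atlas medial thickness ratio.
    """
    width_ratio = float(rng.normal(1.0, radius_spread)) if radius_spread > 0 else 1.0
    width_ratio = max(width_ratio, 0.5)
    dims = AnatomicalDims(
        femoral_width=atlas_dims.femoral_width * width_ratio,
        medial_compartment_width=atlas_dims.medial_compartment_width * width_ratio,
        medial_thickness=rec.medial_thickness,
        lateral_thickness=rec.lateral_thickness,
        joint_space=atlas_dims.joint_space,
        body_weight=rec.body_weight,
    )
    factors = scale_factors(dims, atlas_dims)
    from dataclasses import replace
    return replace(rec, dims=dims, thickness_factor=factors["thickness"])


def cohort_to_cases(
    records: list[SubjectRecord],
    atlas_dims: AnatomicalDims,
    atlas_geometry: SurrogateGeometry,
    seed: int = 0,
    radius_spread: float = 0.05,
) -> list[KneeCase]:
    """Scale the atlas surrogate for every record and emit knee cases."""
    from dataclasses import replace

    rng = np.random.default_rng(seed + 1)
    cases = []
    for rec in records:
        rec = assign_geometry(rec, atlas_dims, atlas_geometry, rng, radius_spread)
        factors = scale_factors(rec.dims, atlas_dims)
        geom = replace(
            atlas_geometry,
            contact_radius=atlas_geometry.contact_radius * factors["femoral_width"],
            plateau_radius=atlas_geometry.plateau_radius
            * factors["medial_compartment_width"],
            medial_thickness=atlas_geometry.medial_thickness * factors["thickness"],
        )
        cases.append(KneeCase(
            knee_id=rec.subject_id,
            geometry=geom,
            body_weight=rec.body_weight,
            baseline_age=rec.age,
            kl_group=rec.kl_group,
            pain=rec.pain,
            thickness_factor=rec.thickness_factor,
        ))
    return cases


def cohort_dataframe(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flat per-knee table (one row per knee) for CSV round-trips."""
    return pd.DataFrame([{
        "subject_id": r.subject_id, "side": r.side, "age": r.age,
        "bmi": r.bmi, "height": r.height, "body_weight": r.body_weight,
        "medial_thickness": r.medial_thickness,
        "lateral_thickness": r.lateral_thickness,
        "kl_group": r.kl_group, "pain": r.pain,
        "thickness_factor": r.thickness_factor,
    } for r in records])
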