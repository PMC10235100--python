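"""Age-dependent cartilage degeneration algorithm.

Degeneration is driven by collagen-network overload: an element is
considered degenerated at a given age when the maximum principal
tensile stress it experiences at any point of the gait cycle exceeds an
age-dependent failure threshold.  The threshold is a continuous,
piecewise-linear, non-increasing function of age: 30 MPa below 30
years, falling to 10 MPa at 45, 7 MPa at 65, 6.8 MPa at 75 and constant
beyond.  The degenerated volume DEG(age) is the summed volume of the
exceeding elements; the predicted 8-year progression is
``D = DEG(baseline + 8) - DEG(baseline)``, a post-processing step on a
single gait simulation (no stiffness-degradation feedback loop).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "tensile_threshold",
    "degenerated_volume",
    "progression_8y",
    "DegenerationResult",
    "THRESHOLD_BREAK_AGES",
]

#: Ages at which the piecewise-linear threshold changes slope [years].
THRESHOLD_BREAK_AGES = (30.0, 45.0, 65.0, 75.0)


def tensile_threshold(age: float | np.ndarray) -> float | np.ndarray:
    """Tensile-stress failure threshold [MPa] at a given age [years].

    Piecewise law (boundary ages follow the printed inequality chain,
    e.g. age 30 belongs to the second segment):

    * age < 30:            30
    * 30 <= age <= 45:     30 - (age - 30) * (20/15)
    * 45 <  age <= 65:     10 - (age - 45) * (3/20)
    * 65 <  age <= 75:      7 - (age - 65) * (2/100)
    * age > 75:             6.8
    """
    scalar = np.isscalar(age)
    a = np.asarray(age, dtype=float)
    if np.any(a <= 0):
        raise ValueError("age must be positive")
    t = np.empty_like(a)
    t[a < 30] = 30.0
    m = (a >= 30) & (a <= 45)
    t[m] = 30.0 - (a[m] - 30.0) * (20.0 / 15.0)
    m = (a > 45) & (a <= 65)
    t[m] = 10.0 - (a[m] - 45.0) * (3.0 / 20.0)
    m = (a > 65) & (a <= 75)
    t[m] = 7.0 - (a[m] - 65.0) * (2.0 / 100.0)
    t[a > 75] = 6.8
    return float(t) if scalar else t


def degenerated_volume(
    max_tensile_stress: np.ndarray,
    volumes: np.ndarray,
    age: float,
) -> float:
    """DEG(age) [mm^3]: summed volume of elements whose maximum-over-gait
    tensile stress strictly exceeds the age threshold."""
    s = np.asarray(max_tensile_stress, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if s.shape != v.shape:
        raise ValueError("stress and volume arrays must align")
    return float(v[s > tensile_threshold(age)].sum())


@dataclass(frozen=True)
class DegenerationResult:
    """Predicted degeneration of one knee over an 8-year follow-up."""

    baseline_age: float
    deg_baseline: float          # DEG(b) [mm^3]
    deg_followup: float          # DEG(b + 8) [mm^3]
    exceed_baseline: np.ndarray  # per-element flags at age b
    exceed_followup: np.ndarray  # per-element flags at age b + 8

    @property
    def D(self) -> float:
        """Progression D = DEG(b+8) - DEG(b) [mm^3]; non-negative because
        the threshold never increases with age."""
        return self.deg_followup - self.deg_baseline


def progression_8y(
    max_tensile_stress: np.ndarray,
    volumes: np.ndarray,
    baseline_age: float,
    horizon: float = 8.0,
) -> DegenerationResult:
    """Evaluate DEG at baseline and follow-up age and their difference."""
    s = np.asarray(max_tensile_stress, dtype=float)
    v = np.asarray(volumes, dtype=float)
    tb = tensile_threshold(baseline_age)
    tf = tensile_threshold(baseline_age + horizon)
    flag_b = s > tb
    flag_f = s > tf
    return DegenerationResult(
        baseline_age=float(baseline_age),
        deg_baseline=float(v[flag_b].sum()),
        deg_followup=float(v[flag_f].sum()),
        exceed_baseline=flag_b,
        exceed_followup=flag_f,
    )
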