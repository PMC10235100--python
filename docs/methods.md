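# Methods

`kneedeg` re-implements, at desk scale, an atlas-based finite-element
workflow for predicting personalized progression of knee osteoarthritis
from simulated cartilage overloading. This note documents the models,
the numerical choices, what the synthetic data emulate, and the known
limits of the surrogate.

## The modelling chain

1. **Cohort.** Synthetic per-knee subject records (age, BMI, cartilage
   thicknesses, 8-year Kellgren–Lawrence outcome group, pain flag) are
   sampled from published per-group statistics.
2. **Atlas scaling.** A template ("atlas") parametric geometry of the
   medial tibiofemoral compartment is scaled per subject: in-plane
   dimensions by anatomical width ratios, cartilage thickness by a
   *radial* (surface-normal) factor. A generic stance-phase axial knee
   force waveform, expressed in body weights, is scaled by subject
   weight and by a medial load-share factor (0.65).
3. **Contact simulation.** The scaled geometry is run through an
   axisymmetric biphasic finite-element contact model once per
   constitutive law (FRPVE, TIPE, HTIPE), producing per-element maximum
   principal effective ("tensile") stress over the stance phase.
4. **Degeneration.** An element degenerates at age `A` when its
   max-over-stance tensile stress exceeds a piecewise-linear,
   non-increasing threshold `T(A)` (30 MPa below age 30, 10 MPa at 45,
   7 MPa at 65, 6.8 MPa beyond 75; continuous at all breakpoints).
   `DEG(A)` is the summed volume of exceeding elements; predicted
   8-year progression is `D = DEG(b + 8) − DEG(b)`. This is pure
   post-processing of one simulation — no stiffness-degradation
   feedback loop.
5. **Statistics.** Bland–Altman agreement and thickness-scaling
   regressions between constitutive models, Mann–Whitney/Wilcoxon group
   tests, and ROC/AUC for classifying knees that progress to
   radiographic OA (KL34) versus those that stay healthy (KL01).

## Constitutive models

All three materials are biphasic (incompressible solid + fluid, Darcy
flow); moduli in MPa, permeability converted from m⁴ N⁻¹ s⁻¹ to the
internal mm–N–MPa–s system.

**HTIPE / TIPE.** Transversely isotropic poroelastic, engineering
constants with the compliance convention `S_ij = −nu_ij / E_ii`
(transverse strain in *j* per stress in *i*). Under this convention
every shipped parameter set is positive definite; the alternative
convention would make the HTIPE `nu_13 = 1.9` inadmissible, which fixes
the interpretation. TIPE has three depth zones
(superficial/middle/deep); the zone fractions are not published, so the
conventional 15/35/50 % split of thickness is the configurable default.
A depth exactly on a zone boundary belongs to the deeper zone.

**FRPVE.** Isotropic non-fibrillar matrix (`E_m`, `nu_m`) plus a
tension-only collagen network. Each fibril follows a strain-stiffening
law `sigma_eq = (E_0 + E_eps·eps) eps` in parallel with a Maxwell
branch (the same secant spring in series with dashpot `eta`), so
`eta = 0` reduces exactly to the algebraic elastic limit and constant
strain relaxes monotonically toward it. The exact equations of the
source constitutive family are not fully published; this
standard-linear-solid form is the package's reconstruction and is
isolated behind one kernel function so it can be swapped.

The network architecture required three reconstruction decisions:

* the network stress sums over fibril *directions*, so each of the two
  orthogonal in-plane primary line families carries multiplicity 2
  ("4 primary fibrils" read literally);
* primary fibrils carry the literature density factor `C = 3.009`
  relative to secondary fibrils;
* a secondary fibril set (four ±45° diagonals between surface plane and
  normal, configurable count) provides the network's shear stiffness.
  Without it the composite has only the near-fluid matrix shear modulus
  (≈0.09 MPa) and collapses unphysically under contact shear — the
  arcade-primary-only reduction is mechanically degenerate.

These choices were validated against the benchmark the published
parameter sets themselves provide: the HTIPE set was originally
calibrated to reproduce the FRPVE response on the calibration fixture,
and on that fixture it agrees with this package's FRPVE to ~12–15 % in
peak tensile stress. The depth-wise arcade (primaries parallel to the surface above
`hz = 2/3`, rotating linearly to surface-normal at the bone interface)
is used at joint scale; the calibration fixture overrides it with
surface-parallel fibrils at all depths, as in the original experiment.

The FRPVE fluid fraction is evaluated exactly as printed,
`n_f(hz) = 0.8 − 0.15·hz` with `hz = 1` at the articular surface — note
this places the *lower* fluid fraction at the surface, opposite to
physiology; the coefficients are configurable and deliberately not
"fixed". The fluid fraction does not enter the linear poroelastic
equations (only permeability and stiffness do) and is carried as a
material property.

## Finite-element solver

Axisymmetric 4-node quadrilaterals, equal-order bilinear u–p, 2×2
Gauss, backward Euler (unconditionally stable). Sealed (zero-flux)
boundaries everywhere unless a drained node set is declared; the
contact interface is impermeable. Contact is frictionless
node-to-segment penalty along the axial direction (the master surface
is nominally flat), with penalty stiffness `100 × E_char × area /
thickness` per node; `E_char` includes the fibril secant stiffness at a
representative 15 % stretch, because scaling by the drained matrix
modulus of a fibril-reinforced body would permit millimetre-scale
interpenetration. The axis node's vanishing tributary area is floored
at 20 % of the mean so first contact can bootstrap.

The nonlinear loop is a semismooth Newton iteration on the true
residual with backtracking line search, a trust-region-style cap on
displacement updates (30 % of the thinnest layer), and tangent springs
on nearly-touching contact nodes for stabilisation. Load increments
that fail to converge are bisected recursively (up to 32 sub-steps); at
maximum depth a stalled iterate is accepted only if equilibrium holds
to 2–5 % of the load scale (`loose_tol`), and such steps are counted.
In practice they occur only at the near-zero-force stance boundaries.
The tension-only fibril gate is smoothed over a 5·10⁻³ strain band
(cubic smoothstep) so the Newton operator stays continuous; the stress
error inside the band is O(`E_0`·10⁻³) MPa.

Near-undrained steps use an artificial-storage stabilization of 0.5 %
of the model's characteristic axial compliance; this biases the
undrained pore pressure by the same 0.5 % and the consolidation
benchmark by less than that. The solver reproduces the 1-D
consolidation series solution to <2 % of the applied stress, the
undrained instantaneous limit to ~0.5 %, and the drained limit when
permeability is scaled up; the axial base reaction balances the applied
force to <0.1 % at every converged step. Halving the element size
changes the fixture's peak contact pressure by ~4 %.

Kinematics are small-strain and the mesh is not updated. Under the
50 N fixture load, local strains reach tens of percent, where a
finite-strain model would stiffen geometrically; see "Limitations".

## Fixture and joint surrogates

The calibration fixture is the published simplified joint: a 2 mm ×
4 mm × 4 mm tibial block (32 mm³) and a femoral hemisphere of radius
2 mm, loaded by a 50 N axial ramp in 0.2 s with the tibial base fixed
and the femoral body restricted to axial translation. Axisymmetry
replaces the square block by a cylinder of equal cross-section (radius
4/√π ≈ 2.257 mm), which preserves volume and contact mechanics. The
solid hemisphere's degenerate centre is truncated at 15 % of the radius
and merged into the driven (bone) node set.

The knee-level surrogate replaces the full 3-D knee mesh — the central
fidelity trade-off of this package. The medial compartment is a
spherical femoral cartilage cap (effective condyle radius 35 mm in the
synthetic atlas) on a flat tibial disk (plateau radius 15 mm), each
carrying half the subject's medial thickness, bonded to rigid bone.
Gait is resolved at 26 stance points over 0.6 s; stance windows are
loading response 0–20 % and terminal extension 80–100 % (the sub-phases
are named but not delimited in the source; both are configurable).
Model-to-model comparisons use the average over the two windows of the
in-window *peak* of each summary trace (the "green box" convention),
with the time-averaged variant also available. Summary "mean" values
are volume-weighted over the elements inside the current contact patch;
"peak" values are maxima over that patch; time points without contact
report missing values, never zero.

The generic gait waveform (double peak, 2.5 BW at ~15 % and 2.8 BW at
~85 % stance, 0.65 medial share) is a synthetic surrogate: the original
template's waveform is not published. Its final sample retains 0.25 BW
rather than unloading to exactly zero — physiologically the swing
transition keeps residual compartment load, and a fully unloaded
contact state is numerically indeterminate for the penalty press.

## Synthetic cohort

Group sizes, pain counts and the mean ± SD of age, BMI and cartilage
thickness per KL group and side are taken verbatim from the published
subject table (214 knees total; KL01/KL2/KL34 at 8-year follow-up).
Sampling is truncated-Gaussian: age ≤ 70 years (the inclusion rule),
thickness > 1 mm. Because the tabulated moments describe the
*post-inclusion* sample, the parent Gaussian is moment-matched so that
the truncated distribution reproduces the targets (the naive parent
would undershoot the mean age by ~0.2 years). Body weight is derived
from BMI via a height drawn from N(1.70, 0.09) m — an explicit
assumption, flagged in the configuration, since weight is not
tabulated. Pain flags are assigned uniformly at random within each
group to the configured count. No left/right correlation is modelled
(knees are treated as units). Geometry assignment scales the atlas by
the thickness ratio (reported as the ratio, which is also what the
thickness-scaling regressions use) and samples the anatomical width
around the atlas value with 5 % relative SD.

What passing cohort-level tests shows: the *mechanistic* separation —
heavier (higher-BMI) KL34 groups load cartilage harder, produce more
threshold exceedance, and are distinguishable by AUC > 0.5. What it
does not show: the published AUC values (0.683/0.682/0.635) or
correlation tables, which depend on the real registry data and the
full 3-D models and are out of scope by design.

## Known limitations

* **Small strains.** The fixture and joint loads drive local strains
  beyond the small-strain regime; the missing geometric stiffening
  affects the soft FRPVE most.
* **FRPVE reconstruction.** With the source equations not fully
  published, the fibril law here is a standard-linear-solid
  reconstruction. On the
  calibration fixture it tracks the published HTIPE benchmark to
  ~12–15 % in peak tensile stress, but at joint scale its tensile
  stresses sit *below* both simple models: cohort-average window-peak
  differences are ≈35 % against HTIPE and ≈10 % against TIPE — the
  *reverse* of the original 3-D result (HTIPE <10 %, TIPE >30 %).
  The inversion is an honest fidelity limit of the reduced constitutive
  law plus linear kinematics, and is reported as such rather than
  tuned away. Conclusions that depend on which simple model is closer
  to FRPVE do not transfer from this surrogate.
* **Axisymmetry.** No condyle shape, meniscus (reduced to the medial
  load-share scalar), lateral compartment, or subject-specific gait.
* **Degeneration model.** Single-simulation post-processing with an
  age threshold on tensile stress; no collagen-damage feedback or
  inflammatory mechanisms.
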