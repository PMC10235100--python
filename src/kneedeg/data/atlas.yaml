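# Surrogate atlas configuration.
#
# The original atlas geometry is an external full-knee FE template; its
# absolute dimensions are not part of this package's sources, so the
# values below are SYNTHETIC surrogate defaults chosen at the
# population centre of the cohort statistics and at textbook anatomical
# magnitudes.  All entries are configurable.
dimensions:
  femoral_width_mm: 85.0          # mediolateral width of distal femur
  medial_compartment_width_mm: 30.0
  medial_thickness_mm: 5.0        # combined medial cartilage thickness
  lateral_thickness_mm: 5.5
  joint_space_mm: 10.0
  body_weight_kg: 80.0
surrogate:
  contact_radius_mm: 35.0         # effective medial femoral condyle radius
  femoral_layer_fraction: 0.5     # share of medial thickness on the femur
  tibial_plateau_radius_mm: 15.0
gait:
  medial_load_share: 0.65
  stance_duration_s: 0.6
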