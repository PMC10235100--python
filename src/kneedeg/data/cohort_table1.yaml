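# Default synthetic-cohort configuration: per-KL-group, per-side subject
# statistics (mean +- SD) of baseline age, BMI and MRI-derived cartilage
# thicknesses, with group sizes and counts of subjects reporting constant
# knee pain.  KL groups reflect the Kellgren-Lawrence grade at the 8-year
# follow-up: KL01 (grades 0-1), KL2 (grade 2), KL34 (grades 3-4).
# Subjects older than 70 years at baseline are excluded; the stated
# moments describe the post-inclusion (age-truncated) sample.
age_max: 70.0
age_min: 40.0
thickness_min: 1.0
height_mean_m: 1.70
height_sd_m: 0.09
groups:
  left:
    KL01: {n: 70, pain: 15, age: [56.1, 6.2], bmi: [28.3, 5.2], medial: [5.0, 1.0], lateral: [5.6, 0.8]}
    KL2:  {n: 20, pain: 1,  age: [58.1, 5.1], bmi: [27.4, 4.7], medial: [4.9, 0.6], lateral: [5.4, 0.8]}
    KL34: {n: 16, pain: 2,  age: [57.1, 6.2], bmi: [31.8, 5.1], medial: [5.1, 1.0], lateral: [5.3, 1.3]}
  right:
    KL01: {n: 69, pain: 12, age: [56.0, 5.8], bmi: [28.5, 5.6], medial: [5.1, 0.9], lateral: [5.6, 1.0]}
    KL2:  {n: 29, pain: 4,  age: [57.9, 6.1], bmi: [29.0, 5.1], medial: [5.0, 1.0], lateral: [5.6, 0.9]}
    KL34: {n: 10, pain: 0,  age: [56.0, 7.2], bmi: [30.5, 5.9], medial: [5.3, 0.7], lateral: [5.3, 0.6]}
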