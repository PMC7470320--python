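# Default attribute schema for the TAVI case-base.
# Quantitative ranges are clinically coherent adult intervals and double as
# the range_a normalisation bounds; engines remain schema-driven, so a
# site-specific schema config can replace this file wholesale.
attributes:
  - {name: age, kind: quantitative, range: [60, 95]}
  - {name: weight, kind: quantitative, range: [40, 120]}
  - {name: height, kind: quantitative, range: [140, 195]}
  - {name: body_mass_index, kind: quantitative, range: [16, 40]}
  - {name: body_surface_area, kind: quantitative, range: [1.3, 2.4]}
  - {name: aortic_annulus_diameter, kind: quantitative, range: [18, 29]}
  - {name: aortic_annulus_area, kind: quantitative, range: [300, 700]}
  - {name: aortic_valve_area, kind: quantitative, range: [0.4, 1.2]}
  - {name: lvot_calcification, kind: binary}
  - {name: iliofemoral_min_diameter_right, kind: quantitative, range: [4, 12]}
  - {name: iliofemoral_min_diameter_left, kind: quantitative, range: [4, 12]}
  - {name: tortuosity_right, kind: ordinal, categories: ["No", Mild, Moderate, Severe]}
  - {name: tortuosity_left, kind: ordinal, categories: ["No", Mild, Moderate, Severe]}
  - {name: calcification_right, kind: ordinal, categories: ["No", Mild, Moderate, Heavy, Massive]}
  - {name: calcification_left, kind: ordinal, categories: ["No", Mild, Moderate, Heavy, Massive]}
  - {name: previous_aneurysm_or_thrombus, kind: binary}
decisions:
  vascular_access:
    - right trans-femoral
    - left trans-femoral
    - left trans-subclavian
    - trans-aortic
    - trans-apical
  prosthesis:
    - Edwards Sapien XT 23
    - Edwards Sapien XT 26
    - Medtronic CoreValve 26
    - Medtronic CoreValve 29
results:
  - procedure_success
  - post_aortic_valve_area
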