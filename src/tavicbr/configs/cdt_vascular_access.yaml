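# Default clinical decision tree for the vascular access decision.
# Level 1 holds the ilio-femoral minimal diameters (the first anatomical
# gate for a trans-femoral route); level 2 the vessel quality grades;
# level 3 prior femoral disease and general patient factors.  Rules vary
# between hospitals and physicians, so this file is an overridable default.
decision: vascular_access
levels:
  - [iliofemoral_min_diameter_right, iliofemoral_min_diameter_left]
  - [tortuosity_right, tortuosity_left, calcification_right, calcification_left]
  - [previous_aneurysm_or_thrombus, age, body_mass_index]
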