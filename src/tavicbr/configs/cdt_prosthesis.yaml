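# Default clinical decision tree for the joint prosthesis type+size decision.
# Annulus dimensions dominate sizing (level 1); valve area and LVOT
# calcification refine the choice; access-dependent and morphometric factors
# sit deepest.  Overridable per site.
decision: prosthesis
levels:
  - [aortic_annulus_diameter, aortic_annulus_area]
  - [aortic_valve_area, lvot_calcification]
  - [iliofemoral_min_diameter_right, iliofemoral_min_diameter_left, body_surface_area]
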