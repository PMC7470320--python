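# Synthetic stand-in for the manufacturers' Instruction-For-Use anatomical
# windows per prosthesis label: solution-consistent intervals used by the
# data-augmentation procedure for measurement attributes tied to the
# prosthesis decision.  Values are plausible sizing windows, editable.
decision: prosthesis
ranges:
  Edwards Sapien XT 23:
    aortic_annulus_diameter: [18, 22]
    aortic_annulus_area: [300, 430]
  Edwards Sapien XT 26:
    aortic_annulus_diameter: [21, 25]
    aortic_annulus_area: [400, 550]
  Medtronic CoreValve 26:
    aortic_annulus_diameter: [20, 23]
    aortic_annulus_area: [360, 480]
  Medtronic CoreValve 29:
    aortic_annulus_diameter: [23, 27]
    aortic_annulus_area: [480, 650]
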