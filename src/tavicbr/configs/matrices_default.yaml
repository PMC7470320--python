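# Expert ordinal distance matrices.  Calcification uses the five-grade
# expert table; ordinal attributes without an entry here fall back to the
# same profile interpolated onto their own category count.
matrices:
  - attribute: calcification_right
    categories: ["No", Mild, Moderate, Heavy, Massive]
    matrix:
      - [0.00, 0.15, 0.50, 0.90, 1.00]
      - [0.15, 0.00, 0.20, 0.50, 0.70]
      - [0.50, 0.20, 0.00, 0.20, 0.50]
      - [0.90, 0.50, 0.20, 0.00, 0.15]
      - [1.00, 0.70, 0.50, 0.15, 0.00]
  - attribute: calcification_left
    categories: ["No", Mild, Moderate, Heavy, Massive]
    matrix:
      - [0.00, 0.15, 0.50, 0.90, 1.00]
      - [0.15, 0.00, 0.20, 0.50, 0.70]
      - [0.50, 0.20, 0.00, 0.20, 0.50]
      - [0.90, 0.50, 0.20, 0.00, 0.15]
      - [1.00, 0.70, 0.50, 0.15, 0.00]
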