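# Default marker co-expression phenotype rules for the five mIF panels.
# "positive" markers must all be positive, "negative" markers all negative.
# Rules are nested: a CD3+CD8+ cell also matches CD3+.
rules:
  # ----- panel 1: CK, CD3, CD8, PD-1, PD-L1, CD68 -----
  - {name: "CK+",              panel: 1, positive: [CK]}
  - {name: "CK+PD-L1+",        panel: 1, positive: [CK, PD-L1]}
  - {name: "CK+PD-L1neg",      panel: 1, positive: [CK], negative: [PD-L1]}
  - {name: "CD3+",             panel: 1, positive: [CD3]}
  - {name: "CD3+CD8+",         panel: 1, positive: [CD3, CD8]}
  - {name: "CD3+PD-1+",        panel: 1, positive: [CD3, PD-1]}
  - {name: "CD3+PD-L1+",       panel: 1, positive: [CD3, PD-L1]}
  - {name: "CD3+PD-1+PD-L1+",  panel: 1, positive: [CD3, PD-1, PD-L1]}
  - {name: "CD3+CD8+PD-1+",    panel: 1, positive: [CD3, CD8, PD-1]}
  - {name: "CD3+CD8+PD-L1+",   panel: 1, positive: [CD3, CD8, PD-L1]}
  - {name: "CD68+",            panel: 1, positive: [CD68]}
  - {name: "CD68+PD-L1+",      panel: 1, positive: [CD68, PD-L1]}

  # ----- panel 2: CK, CD3, CD8, CD45RO, GZB, FOXP3 -----
  - {name: "CK+",                 panel: 2, positive: [CK]}
  - {name: "CD3+",                panel: 2, positive: [CD3]}
  - {name: "CD3+CD8+",            panel: 2, positive: [CD3, CD8]}
  - {name: "CD3+CD8+GZB+",        panel: 2, positive: [CD3, CD8, GZB]}
  - {name: "CD3+CD45RO+",         panel: 2, positive: [CD3, CD45RO]}
  - {name: "CD3+CD8+CD45RO+",     panel: 2, positive: [CD3, CD8, CD45RO]}
  - {name: "CD3+CD8negFOXP3+",    panel: 2, positive: [CD3, FOXP3], negative: [CD8]}
  - {name: "CD3+CD45RO+FOXP3+",   panel: 2, positive: [CD3, CD45RO, FOXP3]}

  # ----- panel 3: CK, CD3, PD-L1, B7-H3, B7-H4, IDO-1, VISTA -----
  - {name: "CK+",          panel: 3, positive: [CK]}
  - {name: "CK+PD-L1+",    panel: 3, positive: [CK, PD-L1]}
  - {name: "CK+PD-L1neg",  panel: 3, positive: [CK], negative: [PD-L1]}
  - {name: "CK+B7-H3+",    panel: 3, positive: [CK, B7-H3]}
  - {name: "CK+B7-H4+",    panel: 3, positive: [CK, B7-H4]}
  - {name: "CK+IDO-1+",    panel: 3, positive: [CK, IDO-1]}
  - {name: "CD3+",         panel: 3, positive: [CD3]}
  - {name: "CD3+B7-H3+",   panel: 3, positive: [CD3, B7-H3]}
  - {name: "CD3+PD-L1+",   panel: 3, positive: [CD3, PD-L1]}

  # ----- panel 4: CK, CD3, ICOS, LAG3, OX40, TIM3, CD20 -----
  - {name: "CK+",        panel: 4, positive: [CK]}
  - {name: "CD3+",       panel: 4, positive: [CD3]}
  - {name: "CD3+ICOS+",  panel: 4, positive: [CD3, ICOS]}
  - {name: "CD3+LAG3+",  panel: 4, positive: [CD3, LAG3]}
  - {name: "CD3+OX40+",  panel: 4, positive: [CD3, OX40]}
  - {name: "CD3+TIM3+",  panel: 4, positive: [CD3, TIM3]}
  - {name: "CD20+",      panel: 4, positive: [CD20]}
  - {name: "CD20+ICOS+", panel: 4, positive: [CD20, ICOS]}
  - {name: "CD20+OX40+", panel: 4, positive: [CD20, OX40]}
  - {name: "CD20+LAG3+", panel: 4, positive: [CD20, LAG3]}
  - {name: "CD20+TIM3+", panel: 4, positive: [CD20, TIM3]}

  # ----- panel 5: CK, Arg-1, CD11b, CD14, CD33, CD66b, CD68 -----
  - {name: "CK+",                panel: 5, positive: [CK]}
  - {name: "CD68+",              panel: 5, positive: [CD68]}
  - {name: "CD68+CD11b+",        panel: 5, positive: [CD68, CD11b]}
  - {name: "CD66b+",             panel: 5, positive: [CD66b]}
  - {name: "CD11b+CD66b+",       panel: 5, positive: [CD11b, CD66b]}
  - {name: "CD11b+CD66b+CD33+",  panel: 5, positive: [CD11b, CD66b, CD33]}
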