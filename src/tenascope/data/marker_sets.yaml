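# Paralog-diagnostic gene neighborhoods for synteny-based assignment.
# Weights default to 1; markers found immediately adjacent to the focal
# locus receive a 1.5x bonus at scoring time.  Symbols match
# case-insensitively after synonym normalization (see symbol_synonyms).
marker_sets:
  TNC:
    TNFSF8: 1.0
    PAPPA1: 1.0
    ASTN2: 1.0
    TESK: 1.0
    TRAF2A: 1.0
    NOTCH1: 1.0
    B3GALT8: 1.0
  TNR:
    COP1: 1.0
    PAPPA2: 1.0
    ASTN1: 1.0
    ATF6A: 1.0
    CC2D1B: 1.0
  TNW:
    MRPS14: 1.0
    KIAA0040: 1.0
  TNX:
    CYP21: 1.0
    C4: 1.0
    ATF6B: 1.0
    NOTCH4: 1.0
    PSMB: 1.0

# Gene-naming drift across genome projects.  Keys are canonical symbols,
# values are the synonyms collapsed onto them.
symbol_synonyms:
  TNW: [TNN, tnn]
  TNX: [TNXB, TNXBa]
  CYP21: [Cyp21a2, CYP21A2, Cyp21b]
  TNFSF8: [TNSF8]
  C4: [C4b, C4B]
  TESK: [TESK1, TESK2]
  COP1: [RFWD2]
  PSMB: [psmb10, PSMB7, psmb7]
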