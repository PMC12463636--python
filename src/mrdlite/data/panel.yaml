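# Panel definition: required channels per tube and the alias map used to
# normalize site-specific channel labels (antibody-fluorochrome conjugate
# names vary between instruments and reagent lots).
panel:
  required:
    TUBE1_SURFACE: [FSC, SSC, CD45, CD19, CD10, CD34]
    TUBE2_SYTO: [FSC, SSC, CD45, SYTO13, CD235A]
  aliases:
    FSC-A: FSC
    FSC-H: FSC
    SSC-A: SSC
    SSC-H: SSC
    CD19 FITC: CD19
    CD19-FITC: CD19
    CD10 APC: CD10
    CD10-APC: CD10
    CD34 PE: CD34
    CD34-PE: CD34
    CD45 PERCP: CD45
    CD45-PERCP: CD45
    SYTO 13: SYTO13
    SYTO-13: SYTO13
    CD235A FITC: CD235A
    GLYCOPHORIN A: CD235A
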