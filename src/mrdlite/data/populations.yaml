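# Default synthetic bone-marrow geometry for day-15 post-induction samples.
#
# Scatter channels (FSC, SSC) are normal on a linear 0..1000 scale.
# Fluorescence channels are log10-normal: [mean, sd] are on the log10 scale
# of a 5-decade detector (linear range 1..100000).
#
# The geometry is fixed once so that the default gates separate populations:
# RBC_DEBRIS sits below the FSC debris boundary (100), NEUT sits above the
# SSC pseudo-Ficoll boundary (300), and the CD19/CD10/CD34 positive and
# negative populations are >3 sd apart around the 2.5-decade threshold.
detector_range: 100000.0
scatter_range: 1000.0
scatter_channels: [FSC, SSC]

populations:
  LYMPH:                      # mature non-B lymphocytes (B cells are modelled only as BLAST)
    scatter: {FSC: [280.0, 40.0], SSC: [90.0, 25.0]}
    fluor:
      CD45: [3.8, 0.15]
      CD19: [1.0, 0.30]
      CD10: [1.0, 0.30]
      CD34: [1.0, 0.30]
      SYTO13: [3.5, 0.20]
      CD235A: [1.0, 0.30]
  MONO:
    scatter: {FSC: [420.0, 50.0], SSC: [180.0, 40.0]}
    fluor:
      CD45: [3.5, 0.15]
      CD19: [1.2, 0.30]       # monocyte autofluorescence, still far below threshold
      CD10: [1.0, 0.30]
      CD34: [1.2, 0.30]
      SYTO13: [3.5, 0.20]
      CD235A: [1.0, 0.30]
  NEUT:
    scatter: {FSC: [450.0, 60.0], SSC: [500.0, 70.0]}
    fluor:
      CD45: [3.2, 0.15]
      CD19: [1.0, 0.30]
      CD10: [3.0, 0.30]       # neutrophils are genuinely CD10+, but CD19-
      CD34: [1.0, 0.30]
      SYTO13: [3.5, 0.20]
      CD235A: [1.0, 0.30]
  ERYTHROID_NUCLEATED:
    scatter: {FSC: [180.0, 30.0], SSC: [60.0, 20.0]}
    fluor:
      CD45: [1.5, 0.25]
      CD19: [1.0, 0.30]
      CD10: [1.0, 0.30]
      CD34: [1.0, 0.30]
      SYTO13: [3.5, 0.20]
      CD235A: [3.6, 0.15]
  RBC_DEBRIS:                 # non-nucleated: residual red cells, platelets, debris
    scatter: {FSC: [40.0, 30.0], SSC: [30.0, 25.0]}
    fluor:
      CD45: [0.8, 0.30]
      CD19: [0.8, 0.30]
      CD10: [0.8, 0.30]
      CD34: [0.8, 0.30]
      SYTO13: [0.8, 0.30]
      CD235A: [3.3, 0.30]
  BLAST:
    scatter: {FSC: [300.0, 45.0], SSC: [100.0, 30.0]}
    fluor:
      CD45: [2.8, 0.20]       # characteristic dim CD45
      CD19: [3.5, 0.15]
      SYTO13: [3.5, 0.20]
      CD235A: [1.0, 0.30]
    # CD10/CD34 depend on the blast phenotype:
    blast_marker_positive: [3.5, 0.15]
    blast_marker_negative: [1.0, 0.30]

# Base composition of a raw (pre-preparation) day-15 aspirate.
# Nucleated shares are relative to the nucleated compartment; the blast
# fraction is carved out of the nucleated compartment at spec-build time.
composition:
  rbc_debris_fraction: 0.5
  nucleated:
    LYMPH: 0.55
    MONO: 0.10
    NEUT: 0.25
    ERYTHROID_NUCLEATED: 0.10

# Preparation-method effects (retention multipliers applied to fractions,
# followed by renormalization).
preparation:
  ficoll_neut_retention: 0.02
  ficoll_debris_retention: 0.05
  bulk_lysis_debris_residual: 0.10
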