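# Default gating configuration, tuned once against the default synthetic
# geometry in populations.yaml. Real-data use requires site recalibration.
gates:
  - name: nondebris              # debris exclusion on FSC vs SSC
    channel_x: FSC
    channel_y: SSC
    transform: [linear, linear]
    rect: [100.0, 1000.0, 0.0, 1000.0]   # xmin, xmax, ymin, ymax
  - name: pseudo_ficoll          # limited scatter gate eliminating neutrophils
    parent: nondebris
    channel_x: FSC
    channel_y: SSC
    transform: [linear, linear]
    rect: [100.0, 600.0, 0.0, 300.0]

# The debris *region* used for back-gating (candidate blast clusters must
# fall outside this field on FSC/SSC).
debris_region:
  channel_x: FSC
  channel_y: SSC
  transform: [linear, linear]
  rect: [0.0, 100.0, 0.0, 1000.0]

# Marker positivity thresholds on the log10 scale (strict >; an event at
# exactly the threshold is negative).
thresholds:
  CD19: 2.5
  CD10: 2.5
  CD34: 2.5
  CD45: 2.0
  SYTO13: 2.0
  CD235A: 2.5

cluster:
  radius: 0.15                 # log10 units, fixed-radius connectivity
  min_cluster: 10              # limit of detection in events
  backgate_min_fraction: 0.9   # share of cluster events required outside debris
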