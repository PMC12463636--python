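# mrdlite

Simplified flow-cytometry analysis of **measurable residual disease (MRD)**
in pediatric B-lineage acute lymphoblastic leukemia (B-ALL), built for
resource-constrained laboratories and exercised entirely on synthetic
bone-marrow cytometry data with known ground truth.

The package is aimed at clinical-cytometry and biostatistics developers who
want a tested, end-to-end reference implementation of a day-15
post-induction MRD workflow: event-data I/O, gating, hemodilution-corrected
quantification, risk stratification, and an in-silico validation of the
bulk-lysis vs Ficoll preparation comparison.

## The assay in brief

A four-antibody panel (CD19, CD10, CD34, CD45) plus a second tube with a
nuclear dye (Syto13) and the erythroid marker CD235a is enough to quantify
residual B-lymphoblasts at day 15 of induction — before normal regenerating
B-cell precursors (hematogones) appear and confound the phenotype. The
analysis chain is:

1. **Debris exclusion** on FSC vs SSC.
2. **Pseudo-Ficoll gate** — a limited scatter gate that removes
   neutrophils from bulk-lysed samples, mimicking the mononuclear fraction
   a Ficoll density gradient would recover.
3. **Blast detection** — a cluster of events that is CD19⁺CD10⁺ or
   CD19⁺CD34⁺, formalized as a fixed-radius connected component in the
   log₁₀ two-marker plane. The limit of detection is a **cluster of ten
   events** that back-gates outside the debris field.
4. **Quantification** — raw MRD is the blast-cluster count as a percentage
   of the Tube 1 pseudo-Ficoll gate. Tube 2 supplies a **correction
   factor**

   CF = N<sub>gate</sub> / (N<sub>gate</sub> − N<sub>Syto13⁻CD45⁻</sub>),

   which restricts the denominator to nucleated cells; corrected MRD =
   raw MRD × CF (capped at 100%). CF > 5 (i.e. > 80% non-nucleated events
   in the gate — severe hemodilution) triggers a limited-sensitivity
   disclaimer and a re-draw recommendation.
5. **Categorization** into the clinical bins < 0.01%, 0.01–0.1%, 0.1–10%
   and > 10% of mononuclear cells.
6. **Risk stratification** — configurable decision trees (CNS1/2/3 status,
   marrow M1/M2/M3, prednisone response at ≥ 1000 blasts/mm³, day-33
   marrow > 5%) in two workflows: ORIGINAL (clinical features only) and
   UPDATED (re-classified by the day-15 MRD category), yielding
   VLR/LR/IR/HR with a full decision trace.

Because no patient-level event data are public, the package ships a
first-class synthetic-marrow generator (Gaussian scatter, log-normal
fluorescence, multinomial population sampling) with per-event truth
labels, preparation-method effects and hemodilution, so every stage is
testable against known ground truth. See `docs/methods.md` for the model
and its limits.

## Worked example

```python
from mrdlite import (make_sample_spec, apply_preparation, generate_tube_pair,
                     quantify_sample)

# 5% (of nucleated cells) blast burden, bulk-lysis preparation, 100k events
spec = apply_preparation(make_sample_spec(0.05, n_events=100_000, seed=11))
tube1, tube2, truth = generate_tube_pair(spec)
result = quantify_sample(tube1, tube2)
print(f"true  : {100 * truth.true_blast_fraction_of_mononuclear:.3f}%")
print(f"raw   : {result.mrd_raw_pct:.3f}%   corrected: "
      f"{result.mrd_corrected_pct:.3f}%  (CF {result.correction_factor:.3f})")
print(f"events: {result.blast_events}  category: {result.category}")
```

prints

```
true  : 6.577%
raw   : 6.552%   corrected: 6.573%  (CF 1.003)
events: 4577  category: POS_0.1_10
```

— the corrected MRD recovers the labelled truth to ~0.1% relative error:
4577 clustered CD19⁺CD10⁺ events over a 69 852-event pseudo-Ficoll
denominator, inflated by a correction factor of 1.003 because a small
number of non-nucleated events leak into the scatter gate.

The same pipeline is scriptable from the shell:

```bash
mrdlite simulate --n-patients 3 --n-events 100000 --out cohort/ --seed 7
mrdlite quantify --tube1 cohort/P0000_tube1.fcs --tube2 cohort/P0000_tube2.fcs \
                 --out P0000_mrd.json
mrdlite run --config run.yaml          # full simulate->report pipeline
mrdlite compare --n 10 --range 0.5 30 --events 500000 --seeds 20
```

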