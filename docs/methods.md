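# Methods

This note documents the models, parameter choices and numerical
conventions behind `mrdlite`, and what the synthetic validation does and
does not demonstrate about real marrow samples.

## Synthetic marrow model

A day-15 post-induction aspirate is modelled as a finite mixture of six
event classes: lymphocytes (non-B), monocytes, neutrophils, nucleated
erythroid precursors, non-nucleated residue (unlysed red cells, platelets,
debris — the `RBC_DEBRIS` class) and leukemic blasts. Event counts per
class are multinomial in the class fractions; within a class each channel
is independent: scatter (FSC, SSC) is normal on a linear 0–1000 scale,
fluorescence is log₁₀-normal on a five-decade detector (linear range
1–10⁵), truncated at the detector limits. This is the standard first-order
cytometry model; the default geometry (`src/mrdlite/data/populations.yaml`)
was fixed once so that the populations the gates must separate are
separated by > 3 sd:

* `RBC_DEBRIS` FSC 40 ± 30 sits below the debris boundary (FSC = 100);
  ≈ 2% of it leaks above, which is what the correction factor later sees.
* `NEUT` SSC 500 ± 70 sits above the pseudo-Ficoll SSC boundary (300);
  lymphocytes (90 ± 25), monocytes (180 ± 40) and blasts (100 ± 30) sit
  below it.
* Positive fluorescence populations are at 3.5 ± 0.15 decades, negatives
  at ≈ 1.0 ± 0.3, around positivity thresholds of 2.5 decades (2.0 for
  CD45 and Syto13 negativity). Blasts carry the characteristic dim CD45
  (2.8 ± 0.2). Neutrophils are CD10⁺ but CD19⁻, so they never enter the
  blast candidate set.

The base composition is 50% non-nucleated events and a nucleated
compartment of 55% lymphocytes, 10% monocytes, 25% neutrophils, 10%
nucleated erythroids; the blast burden is carved out of the nucleated
compartment. These are plausible round figures for a regenerating marrow
with peripheral-blood admixture, chosen once; downstream results are
insensitive to moderate changes because all quantities are ratios within
the gated compartments.

**Two tubes, independent draws.** The surface tube (FSC, SSC, CD45, CD19,
CD10, CD34) and the nuclear-dye tube (FSC, SSC, CD45, SYTO13, CD235A) are
independent seeded draws from the same composition. This mirrors the
physical assay — the tubes are different aliquots — and forces the
denominator correction to be a genuine between-tube estimate rather than
a shared-array shortcut.

**Preparation effects** are retention multipliers on class fractions,
renormalized: Ficoll retains 2% of neutrophils and 5% of non-nucleated
events; bulk lysis retains everything nucleated and 10% of non-nucleated
events, scaled further by the hemodilution factor. The relative
composition of the nucleated non-neutrophil compartment is preserved in
both arms by construction. Acquired event counts scale with the surviving
event mass, which reproduces the direction (and roughly the size) of the
higher event recovery of bulk lysis (~410k vs ~300k CD45⁺ events at a
500k acquisition cap in the default study).

**Hemodilution** is modelled purely as inflation of the non-nucleated
fraction in the bulk-lysis arm — exactly the signal the Syto13⁻CD45⁻
subtraction keys on. Because the default scatter geometry already excludes
~98% of non-nucleated events before the marker stage, the correction
factor stays near 1 for hemodilution factors of 1–3 and only reaches the
disclaimer threshold (CF > 5, i.e. > 80% non-nucleated events inside the
pseudo-Ficoll gate) for extreme factors (~10³). The factor is therefore a
relative stress knob for the correction pathway, not a calibrated
clinical dilution ratio; tests that need the disclaimer use an extreme
value deliberately.

## Gating and clustering conventions

* Gates are closed regions (boundary points are inside); rectangle gates
  are the default geometry, convex polygons are supported.
* Marker positivity is strict (`log10(x) > t`); an event exactly at the
  threshold is negative. Thresholds are fixed in config; a quantile mode
  (q = 0.995 of a designated negative reference population) is available.
* A blast "cluster" is a fixed-radius connected component in the log₁₀
  (CD19, CD10) or (CD19, CD34) plane, radius 0.15 decades — the simplest
  reproducible formalization of a visually contiguous population, and
  roughly one population standard deviation. The component algorithm bins
  points into a grid of cell size r/√2 (same-cell points are provably
  within r), then links neighbouring cells via a subset screen backed by
  an exact KD-tree query; it is exact and permutation-invariant, and is
  tested against an O(n²) brute-force oracle.
* The limit of detection is a qualifying component of ≥ 10 events.
  Back-gating is formalized as ≥ 90% of the component's events falling
  outside the FSC/SSC debris region. In the default chain the parent gate
  already excludes debris, so back-gating bites only when gating order is
  customized; it is retained as an explicit, configurable safety check.
* With `min_cluster=1` and infinite radius the detector provably reduces
  to plain double-positive counting (tested).

## Quantification conventions

* CF = N/(N − N<sub>Syto⁻CD45⁻</sub>) computed on the Tube 2 pseudo-Ficoll
  gate; corrected MRD = raw MRD × CF, capped at 100%. Equivalently the
  denominator is restricted to nucleated events. A sample whose gated
  events are all Syto13⁻CD45⁻ has no denominator and raises an
  unquantifiable-sample error.
* Nucleated erythroid (CD235a⁺Syto13⁺) events are *not* subtracted from
  the denominator; only the quoted Syto13⁻CD45⁻ subtraction is applied.
* Category bins partition [0, 100]: [0, 0.01) negative, [0.01, 0.1),
  [0.1, 10], (10, 100] — lower-closed at 0.01 and 0.1, "greater than 10%"
  strict. The 10-event rule applies to the cluster size, not the
  percentage; when no qualifying cluster exists the category is forced
  negative regardless of stray double-positive events.
* Unsuitable diagnostic phenotypes (not CD19⁺CD10⁺ or CD19⁺CD34⁺) still
  produce a structured result, flagged unreportable. Results with CF > 5
  are likewise unreportable for risk re-classification: they carry the
  limited-sensitivity disclaimer and route the risk tree to its clinical
  fallback branch.

## Risk trees

The shipped trees encode only the rules the protocol summary states:
prednisone poor response (≥ 1000 blasts/mm³ at day 8), CNS3, day-33 marrow
blasts > 5%, marrow M bands (M2 = [5, 25)% for continuity with M3 ≥ 25%),
CNS3-before-CNS2 precedence, and MRD re-classification in the UPDATED
workflow (negative → VLR for otherwise low-risk patients, 0.1–10% → IR,
\> 10% → HR). Numeric age/WBC branch points are not published; the shipped
cutoffs (age < 1 or ≥ 10 years, WBC ≥ 50 000/µL → intermediate) are
placeholders marked `ASSUMED` in `risk_tree.yaml` and are meant to be
overridden per site. The whole tree is config-driven YAML with a generic
comparator engine, validated for duplicate rule ids, unknown leaves and
cycles; every traversal returns the full (rule, value, outcome) trace.
The engine is tested for exhaustive-grid equivalence against an
independently derived truth table committed to the repository, and for
monotonicity: raising only the MRD category never lowers the risk group.

## Split-sample study and problem sizes

The in-silico bulk-lysis vs Ficoll validation draws 10 samples per seed
with true burdens log-uniform on 0.5–30% of mononuclear cells, generates
both arms from one base composition (counting noise only — the arms are
aliquots), acquires up to 500 000 events (fewer in the Ficoll arm, in
proportion to recovery), runs the full pipeline on each arm and reports
the Pearson r of corrected MRD with a t-distribution p-value. Averaged
over 20 seeds the mean r is ≈ 0.9999; the near-cutoff subset (0.09–0.2%)
is reported qualitatively only, since with a few hundred blast events the
attainable r is dominated by counting noise. End-to-end recovery is
measured on a 4 × 3 grid of burdens (0.1–10%) × hemodilution (1–3) at
500 000 events; the median relative error of corrected MRD against truth
labels is ≈ 0.02%, far inside the 10% requirement. These sizes keep the
full validation at a few minutes on one CPU while using the assay's
actual acquisition cap.

## What the synthetic validation does not show

The generator omits doublets, dead-cell discrimination, spectral
spillover/compensation, instrument drift, inter-sample staining
variability and hematogone regeneration. Passing tests therefore
demonstrate correctness of the *analysis chain* under the stated
first-order model, not clinical performance on real marrow: default gate
geometry and thresholds require site recalibration, and the assay is by
construction invalid at later treatment time points where hematogones
mimic the blast phenotype. FCS support covers the common core of versions
3.0/3.1 (list mode, F/D/I data, uniform integer widths, no escaped TEXT
delimiters); the writer emits deterministic single-dataset FCS 3.1
(float32) so identical samples round-trip byte-identically.
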