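# Methods

## Tree induction

Trees are induced with the C4.5/J4.8 gain-ratio criterion. At each
node, for every available attribute the best admissible split is
found; the split with the maximum gain ratio becomes the node test,
and induction recurses until a node is pure, falls below twice the
minimum leaf weight, or no admissible split with positive gain
remains.

**Numeric attributes.** Candidate thresholds are the midpoints of
consecutive distinct sorted known values; the winning threshold is
reported as the largest observed value not exceeding the best
midpoint, so printed thresholds are always data values (e.g.
`max_axis <= 25.84`). A split is admissible when both branches carry
at least `min_leaf_weight` (default 2, the J4.8 `minNumObj`) of
instance weight.

**Nominal attributes.** One multiway split with a branch per declared
category; a nominal attribute is used at most once per path. Empty
branches become zero-weight leaves predicting the parent majority.

**Missing values.** The information gain is computed on the subset
with known attribute values and multiplied by the known weight
fraction *F*; the split information is the entropy of the branch
weight proportions *including* the missing-weight group as an extra
term. During induction and classification a record missing the test
attribute descends every branch with its weight multiplied by the
branch proportions observed among known-valued records. Weight is
conserved exactly at every node.

**Threshold-count penalty.** Numeric split gains are reduced by
`log2(number of admissible candidate thresholds) / node weight` (the
C4.5 release-8 MDL correction, on by default as in WEKA J4.8). This
term is what keeps spurious razor-thin thresholds on uninformative
attributes out of the trees; without it, a continuous noise attribute
with ~200 distinct values will occasionally carve two or three
misclassified records out of an otherwise pure node. Within an
attribute we select the threshold by the corrected gain ratio
(WEKA selects by raw gain and corrects afterwards; on the data sizes
used here the two readings coincide except in contrived ties).
`SplitEvaluation` objects report the uncorrected textbook quantities
so that hand-derived examples remain checkable.

**Pruning.** Pessimistic subtree replacement: a subtree is collapsed
to a leaf when the leaf's estimated error count (observed errors plus
the upper binomial confidence limit correction at confidence 0.25)
does not exceed the sum over the subtree's leaves by more than 0.1
errors. Subtree raising is deliberately not implemented.

**Tie-breaking.** Equal gain ratios are resolved by schema attribute
order, then by the lower threshold; class-probability ties in
prediction resolve to the earlier class label. Together with seeded
fold assignment this makes every pipeline output a pure function of
its seed.

## Cross-validation

Stratified k-fold assignment shuffles each class with the seeded
generator and deals records round-robin, so per-class fold counts
differ by at most one — for the 225-grain, 3-taxon design every fold
is exactly 45 grains (15 per taxon) and every training set 180 (60
per taxon). A pass builds k trees and records each fold's percent
correct, confusion matrix and split-attribute set. Repeated CV draws
independent fold seeds from a spawned seed sequence; the overall mean
is the unweighted mean of repetition means (folds are equal-sized, so
this equals pooled accuracy). Subset comparisons reuse one fold
assignment per repetition across all subsets — a paired design that
removes fold-assignment noise from subset differences.

## Feature selection

The ranking counts, per attribute, the number of trees (full-data
tree plus the k fold trees of one CV pass) whose internal nodes use
it. The core subset is by default the union (every attribute used by
at least one tree); a minimum-frequency variant (`min_count`) is
available. Low-cost augmentation closes the subset under derivation
inputs and measurement groups: counting pores to obtain the total
already yields the top/lateral/oblique counts, and measuring all onci
for the maximum width yields the minimum, so these attributes come
"for free". The closure is a fixed point, hence idempotent. The
"easiest to identify automatically" subset is a human judgment and is
supplied by name (default: lateral pore count, both axes, axes
difference), not computed.

## Synthetic data

The generator emulates the 13-attribute, 3-taxon, 75-grains-per-taxon
study design whose original data are not deposited. What is known
about that material fixes the calibration targets: most alder grains
show more than 3 pores, most hazel grains exceed 24.39 µm maximum and
22.24 µm minimum axis, most birch grains have a maximum oncus width
of at most 10.19 µm and an axes difference below 2.92 µm, and some
grains have no measurable onci. The distribution parameters
themselves are this package's choices, built so that the class signal
lives in exactly the six attributes the selection procedure is meant
to find and nowhere else:

- **Pores.** A grain has an intrinsic visible total (alder 4–6 with a
  tail at 3; birch and hazel 2–3 with *identical* distributions).
  Orientation moves some pores out of the lateral position; the
  non-lateral pores split evenly between top and oblique. Top and
  oblique counts are therefore conditionally class-independent given
  the total and lateral counts. Birch and hazel never show 3 lateral
  pores, so a lateral count of 3 on a 3-pored grain is an
  alder-specific signature.
- **Axes.** Maximum axis and axes difference are drawn with a common
  regression of elongation on size (conditional mean of the
  difference grows by 0.34 µm per µm of maximum axis; larger grains
  are more elongated). The minimum axis is the exact difference
  `max − diff`. Alder matches hazel in the maximum axis but is
  strongly elongated, so its minimum axis resembles birch — each of
  the three axes attributes separates a different pair of taxa.
- **Oncus widths.** Maximum width separates birch (≈8.2 µm) from the
  other taxa (≈12–13 µm). The width gap (max − min) is chosen per
  taxon so that the minimum width has equal mean *and* similar spread
  everywhere, i.e. carries no class signal.
- **Noise attributes.** Wall thickness, both oncus heights and the
  slide position are identically distributed in all taxa.
- **Missingness.** With probability 0.1 all four oncus fields of a
  grain are missing jointly, emulating grains whose onci could not be
  measured.

Derived attributes are exact by construction (difference and sum
identities hold to machine precision), all µm values are positive,
and the same config (including seed) regenerates a bit-identical
table.

What the generator does **not** model: the correlation structure
between axes and oncus sizes within a taxon (drawn independently),
image-level artefacts, measurement rounding, between-slide effects,
and any real-data deviation from truncated-normal shapes. Passing
tests therefore demonstrate that the pipeline implements the method
correctly under the stated design, not that the method would reach
the same accuracy on new real material.

## Problem sizes

The test suite and the acceptance script scale the repeated designs
to sizes chosen for tight feedback while keeping Monte-Carlo error
well below the tolerances asserted: calibration fractions use 2000
grains per taxon; the recovery and ordering experiments use 100
seeded end-to-end runs with 10-fold repeated CV inside the procedure;
the stability check and the subset comparison in
`scripts/acceptance.py` use 200 repetitions (the repetition means
stabilise to well under 0.5 pp long before that).

## Known limitations

- Exact recovery of the full six-attribute planted set by the
  *union* rule is intrinsically stochastic: a single tree typically
  needs only four of the six planted attributes (the attribute set is
  deliberately redundant, as in real morphometry), so the union over
  six trees sometimes misses one planted attribute or admits one
  spurious split. Individual inclusion/exclusion properties are much
  stronger than exact set equality; the acceptance suite asserts the
  strict form and documents the observed rate.
- Pruning implements subtree replacement only; WEKA's subtree raising
  and collapsing passes can produce slightly smaller trees on the
  same data.
- ARFF support covers the subset of the format the pipeline emits
  (numeric and nominal attributes, `?` missing, `{w}` instance
  weights); sparse ARFF, dates and strings are not parsed.
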