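# Methods

## Case model

A case is one patient: a problem vector of typed attributes, one solution
label per clinical decision, and free-form outcome fields.  Three attribute
kinds are supported — quantitative (continuous or discrete measurements),
ordinal (expert-graded scales with an ordered category list), and binary
(yes/no flags).  The engine is entirely schema-driven: the attribute
inventory, decision vocabularies and outcome names come from a YAML config,
and the shipped default schema (age, weight, height, body mass index, body
surface area, aortic annulus diameter and area, aortic valve area, LVOT
calcification, per-side ilio-femoral minimal diameters, per-side tortuosity
and calcification grades, prior aneurysm/thrombus) is one such config, not a
hard-coded structure.

Missing values are first-class: empty or `NA` CSV cells load as a missing
marker, and every measure defines its behaviour on them explicitly (below).

**Normalisation ranges.** The quantitative distance divides by `range_a`.
This is taken from the schema bounds when declared, else from the observed
min/max of the *initial* case-base, and is frozen thereafter: progressive
case filtering during hierarchical retrieval never recomputes it, so
per-attribute distances stay comparable across levels and across candidate
cases.  Values outside the frozen range clip the distance at 1.  A
single-value attribute (degenerate range) compares by equality (0 or 1).

## Distance dispatch

Per attribute: quantitative `|v1 − v2|/range_a` clipped to [0, 1]; binary
exact match; ordinal via a symmetric, zero-diagonal, unit-interval distance
matrix built from expert knowledge; and 0.5 — the neutral stance — whenever
either value is missing.  The calcification matrix is shipped verbatim
(grade gaps are deliberately non-linear: No↔Mild costs 0.15 while
Moderate↔Heavy costs 0.2 and No↔Heavy 0.9).  Expert matrices for other
ordinal attributes are rarely published, so attributes without one fall back
to the calcification profile bilinearly interpolated onto their own category
count — at five categories this reproduces the shipped table exactly, and at
other lengths it preserves the profile's geometry (near ends, expensive
middle crossing).  Any fallback can be overridden by a matrix config.

The composite dissimilarity is the weighted mean `Σ wa·da / Σ wa`, hence in
[0, 1]; similarity is its complement, so `sim + diss = 1` exactly.

**Reference measures.** HEOM aggregates per-attribute distances by the root
of the sum of squares over *all* schema attributes (the Wilson–Martinez
form), with overlap (0/1) for all qualitative attributes — ordinal grades
are treated nominally — and distance 1 when either value is missing; it does
no selection and no weighting, making it the unweighted baseline.  GWHSM is
the weighted-mean form with Hamming distance for categorical attributes and
with any attribute missing in either case discarded from both numerator and
denominator; a pair with no informative attribute is an error at the scalar
level and an infinite distance (never a neighbour) in the vectorised
fitness path.

## Hierarchical retrieval

The clinical decision tree orders the attributes relevant to one decision
into L levels.  It contributes three things: attribute selection (level l
uses the cumulative set of levels 1..l), weighting (`w = (L − la + 1)/L`,
so root attributes weigh 1 and the deepest 1/L), and progressive case
selection.  At each level except the last, while `m/2^l > 20` with `m` the
*initial* case-base size, the surviving set is cut to its more similar half.
Numerical conventions, all deterministic:

- odd survivor counts keep `ceil(count/2)` — retaining more evidence;
- ordering for both the cut and the final ranking is by
  (dissimilarity, case id), so ties at the halving boundary are resolved
  stably and cases beyond the cut are dropped even if tied (whether tied
  boundary cases should all be kept is genuinely open; the stable cut was
  chosen for auditability);
- the guard uses the initial `m`, not the current survivor count, so the
  filtering schedule is fixed up front (138 cases → 69 → 35 → rank over 35);
- the floor of 20 surviving cases disables filtering entirely for small
  case-bases: any m ≤ 40 never filters, since m/2 ≤ 20 already fails the
  strict inequality at the first level.

The if/then contraindication rules inside a real decision tree are *not*
executed; the tree is consumed only for leveling, weighting and filtering.
Both shipped trees (vascular access: ilio-femoral diameters at level 1,
vessel quality at level 2, prior femoral disease and patient factors at
level 3; prosthesis: annulus dimensions at level 1) are reconstructions of
common clinical ordering and live in YAML because such rules vary by
hospital and physician.  Prosthesis type and size form one joint decision so
the engine can never suggest an incoherent type/size combination.

## Reuse vote

Each of the k retrieved cases votes for its own solution with weight
`(k + 1 − rank)/diss`.  An exact duplicate has dissimilarity 0; it is
clamped below at `eps = 1e−9`, which keeps scores finite while letting the
duplicate dominate — the desired "more similar ⇒ more weight" limit.  Vote
ties break lexicographically by label.  Confidences are scores normalised to
sum to 100%.  Both conventions are engine decisions (the vote rule itself
does not define them) and are isolated in `reuse.py`.

## Weight learning

The GA evolves floating-point weight chromosomes over the problem
attributes.  Fitness is the leave-one-out 1-NN precision under GWHSM:
remove each case, retrieve its single most similar remaining case, score the
fraction whose neighbour shares the confirmed solution.  Operators follow
the configuration reported to work best for this task: crossover rate 0.75,
mutation rate 0.20, 300 generations, roulette-wheel parent selection, 30%
elitism.  Unstated pieces are engine choices: population 50,
whole-arithmetic crossover (children are convex combinations with a uniform
random mixing coefficient), per-gene Gaussian mutation with σ = 0.1 clipped
to the [0, 1] weight bounds, and a uniform-random fallback for roulette
selection when a whole population has zero fitness.  Elitism makes the
best-of-generation fitness non-decreasing, which the tests assert.  Fitness
evaluation is vectorised through per-attribute pairwise distance matrices
and missing-value masks precomputed once per case-base, so a full GA run on
a 60-case base takes well under a second; nearest-neighbour ties resolve to
the earlier case in case-base order.

## Evaluation harness

Two designs (leave-one-out; train/test holdout with every test case
retrieved against the full training set) × two criteria (retrieve-based: the
confirmed solution appears among the k retrieved; reuse-based: the vote's
suggestion equals the confirmed solution).  Retrieve-hit rate is
non-decreasing in k by construction, and the reuse-correct rate can never
exceed the retrieve-hit rate at the same k — the vote can only pick among
retrieved solutions; both are property-tested.

Multiclass TPR/FPR have no single convention; here TPR is the
micro-averaged 1-NN accuracy and FPR the macro-average of one-vs-rest
false-positive rates over labels present in the test set, isolated in one
aggregation function.  One-vs-rest sensitivity/specificity are reported per
label; a label with no positives (or no negatives) in the test set reports
that metric as absent rather than zero.  The k sweep in reported tables is
conventionally capped near 10% of the training-set size (k = 7 for ~69 real
cases); the harness itself accepts any k below the case-base size.

## Synthetic data

**Augmentation** doubles a case-base: for each real case one generated case
is appended whose solution and result fields are copied unchanged (so
per-label counts exactly double) and whose problem attributes are perturbed
— quantitative values by a uniform ±10% multiplicative jitter clipped to the
schema range; measurement attributes tied to the solution (annulus diameter
and area for the prosthesis decision) resampled uniformly inside the
solution-consistent window of the case's label; ordinal grades moved at most
one step with equal probabilities on {−1, 0, +1}, clipped at scale ends;
binary flags kept.  The jitter distribution (uniform) and the shift
probabilities are engine choices.  The solution-consistent windows ship as
an editable YAML table of plausible per-prosthesis sizing intervals; it is a
synthetic stand-in for manufacturer Instruction-For-Use ranges, which are
not reproduced here.

**Generation** draws a case-base from a profile with no external data.  The
default mixture puts 82% of cases on the two trans-femoral accesses,
matching the clinical predominance of that route, and spreads the remainder
over trans-subclavian/aortic/apical; label counts are allocated by largest
remainder, so they are deterministic given n.  In *separable* mode every
attribute is drawn from a narrow label-specific band — the middle fifth of
the label's equal slice of the schema range for quantitative attributes, a
fixed label-indexed category or flag for ordinal/binary ones — which makes
the maximum within-label distance strictly smaller than the minimum
between-label distance for every measure; nearest-neighbour retrieval then
provably recovers the label, giving the harness a ground-truth regime.  In
*noisy* mode only listed informative attributes carry signal and the rest
are uniform noise.  The planted weight-learning testbed uses one predictive
attribute with *wide* bands (width 0.9 of the label slice): the attribute
alone still classifies perfectly, but uniform weights no longer do, so the
fitness landscape actually rewards concentrating weight on the signal.

What passing tests on these data do **not** show: real clinical case-bases
are not separable, attribute correlations (BMI vs weight/height, diameter vs
area) are not modelled, the synthetic annulus measurements are independent
of the other anatomy, and measured performance on synthetic data says
nothing quantitative about sensitivity/specificity on hospital registries.
Reproducing registry-scale results additionally requires the real case-base,
the site's actual decision trees and the expert matrices for every ordinal
attribute; given those configs the harness computes its tables
deterministically.

## Problem sizes

Unit and property tests run on case-bases of 2–40 cases (plus one 138-case
halving-schedule check); the end-to-end checks use 60-case synthetic bases,
a 10-seed GA recovery study at 40 generations × 30 chromosomes, and a
138-case determinism check.  The full suite completes in a few seconds on
one CPU.

## Known limitations

- The GWHSM/HEOM forms follow the standard literature definitions; sites
  whose reference implementations differ (e.g. HEOM without the final square
  root) will see order-preserving but numerically different distances.
- No approximate nearest-neighbour indexing: retrieval is exact and linear
  in the case-base, by design for case-bases of a few hundred cases.
- The revise/retain workflow is reduced to validated append/remove on the
  case-base; no GUI, database, or FHIR/DICOM ingestion.
- Ordinal fallback matrices inherit the calcification profile's geometry,
  which is a default, not elicited expert knowledge for those attributes.
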