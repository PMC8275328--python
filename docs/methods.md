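# Methods

## Cohort model and timepoint semantics

A cohort is a list of patients; each patient has an ordered list of
dated samples and a list of dated events. Dates are integer days
relative to a per-patient reference (the cBioPortal timeline
convention); no calendar arithmetic is done. A *timepoint* is the
ordinal sample index: by default the i-th sample of every patient sits
in timepoint block i, so patients with fewer samples leave *gap* cells
in later blocks. Gaps (no sample) are distinct from missing values (a
sample exists but the measurement is absent) throughout — in scoring,
grouping and rendering.

Sample dates come from SPECIMEN timeline events carrying a `SAMPLE_ID`
attribute. When a clinical file arrives without specimen events, samples
receive ordinal fallback dates (0, 1, 2, … per patient) that preserve
their file order; interval-based event placement then degenerates
gracefully.

**Event placement.** An event belongs to the interval between the two
samples bracketing its start date, taken left-open right-closed
`(d_j, d_{j+1}]`, so every event has exactly one home. Events on or
before the first sample go to a leading event block, events after the
last sample to a trailing one; both are materialized only when
non-empty, while interior event blocks always exist when events are
shown (so timepoint and event blocks alternate). Events with no stop
date are treated as point events at their start — the timeline format
permits an empty STOP_DATE.

**Realignment.** Shifting moves a patient's whole sample sequence by
whole block positions (never below block 0); the grid is rebuilt from
per-patient offsets, so a shift followed by its reverse restores the
grid exactly. Aligning to an event finds, per matching patient, the
first sample dated on/after the event start and shifts so those samples
share the maximal needed block index (all shifts non-negative). Patients
without a matching event keep their alignment.

**Operation log.** Every feature transform (and every CLI directive)
appends one record with a monotone counter. All operations are
deterministic, so replaying the log against a freshly loaded cohort
reproduces the derived features and any layout built from them. This
serialized log replaces interactive undo/redo: it is exported with every
figure as the view-metadata sidecar.

## Feature transforms

- **Binning** maps value `v` to bin `i` with `edges[i−1] ≤ v < edges[i]`;
  a value equal to an edge goes *up* (150 is "high" for edge 150). The
  output is ordinal with the bin labels as its ordered domain.
- **Log transform**: base 10 by default, configurable, with an optional
  pseudocount; non-positive shifted values raise an error naming the
  offending samples rather than being dropped silently.
- **Boolean combination** of binary features uses a three-valued fold: a
  short-circuit value (1 for OR, 0 for AND) decides the output even if
  other inputs are missing; otherwise any missing input makes the output
  missing, and all-missing is missing. This keeps AND/OR dual and never
  fabricates a value that one unobserved input could overturn.
- **Gene-set aggregation** is the arithmetic mean over non-missing
  inputs. Mean was chosen over median/max because it is the common
  signature-score convention for small sets; the others are easy to add
  behind the same interface.
- Renames and color-scale changes are metadata edits on the feature.

## Variability scores

Let a categorical multiset have `n` non-missing observations, modal
frequency `f_m` and `K` *observed* categories.

- **ModVR** (Freeman's standardized variation ratio):
  `K(n − f_m) / (n(K − 1))`, and 0 when `K = 1`. Using observed rather
  than declared categories keeps a feature with unobserved domain levels
  from being deflated. Bounds: 0 iff constant, 1 iff exactly uniform
  over `K ≥ 2` categories.
- **Unalikeability**: `1 − Σ_k p_k²`, equal to the fraction of ordered
  observation pairs, self-pairs included, that differ (the `n(n−1)`
  variant differs by `n/(n−1)` and is not used). Range `[0, 1 − 1/K]`.
- **CV**: sample standard deviation (n−1) over the mean, returned as an
  absolute value so the CV<1 / CV>1 reading survives negative means;
  undefined (missing) for a zero mean.
- **Variance**: sample variance (n−1).
- **Rate of change**, the only across-timepoint (column) score: for
  categorical series, changed transitions over valid transitions; for
  continuous series, the mean absolute step divided by the cohort-wide
  observed range (0 by convention for a constant feature). A transition
  with either endpoint missing — including gaps from ragged sampling —
  is excluded entirely, never bridged across the gap.

Every score requires at least two observations and is otherwise
*missing*, never 0: a constant feature and an unscorable feature must
not tie.

Row scores are computed once per timepoint block across the patients
present there; column scores once per patient along their timepoint
series. A user-chosen aggregation (min/max/mean) folds the resulting
list to one scalar per feature, skipping missing entries; the same
aggregation is applied at both levels since nothing distinguishes them
structurally. Ranking is descending (most variable = rank 1), ties share
the minimum rank, and missing aggregate scores sort after all scored
features. In a mixed-datatype ranking table, a score that does not apply
to a feature's datatype is recorded as missing rather than raising — the
direct `score_feature` call on a mismatched datatype does raise.

## Layout

Sorting is a stable sort of the existing patient order by the feature's
value (domain order for categorical/ordinal, numeric otherwise), with
missing values and gaps last regardless of direction. Multidimensional
sorting applies single-key sorts from least- to most-significant key;
stability makes this exactly the lexicographic sort with the prior
order as final tiebreaker (property-tested against a brute-force
oracle). Realignment copies a reference block's order into every
ungrouped block, appending patients absent from the reference in their
prior relative order; it is idempotent.

Grouping partitions a block's non-gap patients by the primary feature's
value, in domain order (not by group size, so groups are comparable
across blocks); patients missing the primary value form an explicit
trailing "(missing)" group so that the partition conserves patients.
Continuous primaries are rejected with a message pointing at binning.
Nested summaries per group: categorical features as value→count maps;
continuous features as five-number summaries using linear-interpolation
quartiles (fixed so summaries are bit-reproducible) plus the raw values
for gradient rendering. Grouping never mutates the source block, so
discarding the grouped object restores the heatmap order trivially.

Flows between adjacent visible blocks: per-patient lines when both are
ungrouped, (source group, target group) → patient-set flows when both
are grouped, and per-patient lines anchored to group segments in the
mixed case. Only patients present on both sides participate; one-sided
patients are reported as entries/exits. Row sums of a flow matrix equal
the source group sizes restricted to shared patients, column sums the
target group sizes (property-tested). A grouped event block passes
flows through its groupings; an ungrouped event block is bridged and
the flanking timepoint blocks connect directly. Band order at each
group end follows the opposite end's group order; no crossing
minimization is attempted. The primary-feature colors of both ends are
repeated as small proxy marks at the band ends.

## Synthetic cohorts

The generator emulates a small recurrence cohort: by default 23
patients with 2–4 timepoints (weights 0.5/0.3/0.2), inter-sample
intervals uniform on 180–720 days — sizes and shape chosen to mirror a
typical initial-resection-plus-recurrences glioma cohort.

- Categorical sample features evolve as per-patient first-order Markov
  chains: initial state from the configured within-timepoint
  distribution; at each step the value switches with probability `p`
  and, on a switch, moves uniformly to one of the *other* categories.
  P(adjacent pair differs) is therefore exactly `p`, which is what makes
  mean categorical rate of change a consistent estimator of `p` (the
  parameter-recovery tests check agreement within three binomial
  standard errors).
- Continuous features follow a drifting Gaussian random walk
  (defaults: baseline 45 ± 15, drift +8/step, noise sd 12 — mutation
  counts in the tens for a low-grade tumor).
- With configurable probability a patient receives a treatment event
  (TREATMENT/AGENT=TMZ by default) placed strictly inside a uniformly
  chosen inter-sample interval; with probability `q` the event raises
  the designated continuous feature (mutation burden) into a high range
  (300–1200, above the 150 threshold) at every later sample.
- Unaffected values of the designated feature are reflected into
  (1, threshold−1). This is an identifiability choice: high-bin
  membership then encodes exactly the planted effect, so the
  effect-recovery contract ("all and only post-event samples are high")
  is exact rather than statistical. Real mutation-burden distributions
  have heavier tails; tests passing on this generator demonstrate the
  mechanics of binning/grouping/flows, not robustness to borderline
  burdens near the threshold.
- Binary gene tracks (MLH1, MSH6, MSH3 by default) are positive with a
  high rate (0.9) in effect-bearing samples and a low background rate
  (0.05) elsewhere, emulating the co-occurrence of mismatch-repair
  mutations with treatment-induced hypermutation.

All randomness flows from the single config seed through one
`numpy` generator; no global random state is touched. The generator
returns the ground truth (switch probabilities, event slots, affected
samples, planted gene positives) alongside the cohort.

What the generator does **not** emulate: censoring/dropout correlated
with disease state, measurement batch effects, correlated features,
patient-level covariates driving event assignment, or non-stationary
switch probabilities. Passing tests therefore validate the algorithms'
contracts, not clinical realism.

## Rendering and export

Rendering is a pure function of layout state and a `RenderSpec`; a
scene of primitive shapes is built first and then serialized. The
native SVG writer formats coordinates to fixed precision, so identical
inputs give byte-identical files. PNG and PDF re-draw the same scene
through matplotlib at 96 dpi with file timestamps suppressed. Gap cells
are hatched light rectangles, missing values neutral grey. Connecting
lines and bands are cubic Béziers with control points at the vertical
midpoint between blocks — curvature is a visual default, not a
contract. Default palettes are fixed lists assigned in domain order, so
colors are reproducible run to run; per-feature explicit maps override
them.

## Problem sizes in the test suite

The suite exercises oracle comparisons at small sizes (sorting: 500
random instances, n ≤ 30, ≤ 4 keys; pair-fraction oracle: 1000 vectors,
n ≤ 50), flow conservation over 200 generated 10-patient cohorts,
pattern constructions at 1000 patients × 2 timepoints, and parameter
recovery at 200 patients × 3 transitions — sizes at which the binomial
tolerances above are already tight while the whole suite runs in a few
seconds.

## Known limitations

- Calendar-time binning of timepoints is not implemented; timepoints
  are ordinal sample indices (plus event-relative realignment).
- Event blocks carry only event-level features (e.g. the treatment
  agent), not repeated sample-level features.
- MAF handling is presence/absence per gene; variant classes are
  ignored. CNA/expression matrices beyond numeric per-sample features
  are out of scope.
- The portal client fetches clinical, timeline and per-gene mutation
  data; it does not authenticate, and study-level molecular matrices
  are not downloaded.
- No crossing minimization in Sankey band routing.
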