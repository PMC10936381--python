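# Methods

This note records the statistical model behind `netqc`, the conventions and
numerical choices that were genuinely open, and what the synthetic validation
does and does not establish about real tissue data.

## Neighborhood definition

A neighborhood is the closed Euclidean disk of radius `d` around a cell:
neighbors at exactly distance `d` count. Coordinates carry the user's units
and `d` must be given in the same units; no default is provided because no
radius is meaningful across magnifications. The focal cell never counts
itself — exclusion is by cell identity, not by coordinates, so two distinct
cells segmented at the same centroid do count each other. The same `d` is
used across the whole tissue regardless of local density.

No edge correction is applied at the tissue boundary. Counts near the border
are genuinely smaller, but every permutation replicate re-places cells into
the same window (conditional null) or keeps positions fixed outright (full
shuffle), so the null shares the boundary geometry and the z-score is not
biased by it.

Counting uses a k-d tree (`scipy.spatial.cKDTree`); the test suite holds the
tree path to *exact* equality with an O(n²) all-pairs double loop over
squared distances, across sparse to dense radii.

## The enrichment score and its nulls

For ordered pair (A, B): `x_obs` = mean number of B cells within `d` of each
A cell; `z = (x_obs − μ)/σ` with μ, σ the mean and standard deviation of the
same statistic over `R` randomizations (default `R = 1000`). σ uses the
sample divisor (R − 1); a `sigma_ddof` parameter switches to the population
divisor for cross-checking against other tools. A degenerate null (all
replicates identical) leaves the score undefined — reported as NaN with a
reason, never ±∞ — which is also what happens in a two-class tissue, where
the only candidate positions for B are B's own.

**Conditional null.** A's cells stay fixed; each replicate draws `n_B`
positions uniformly *without replacement* from the positions of all non-A
cells (B's own original positions are part of that pool). Only positions
matter; the labels of the remaining non-A cells are irrelevant to the
statistic and are not tracked. Each replicate costs O(n_B): the number of A
cells within `d` of each pool position is precomputed once, and a replicate's
statistic is the subset sum divided by n_A — algebraically identical to the
double-loop count. The resulting matrix is asymmetric by design and is never
symmetrized.

**Full-shuffle null.** Each replicate permutes all class labels over all
positions and is reused for every ordered pair. Because the close-pair count
between two types is symmetric and the 1/n_A scaling cancels in the z-score,
z[A][B] and z[B][A] are equal up to floating round-off: the full-shuffle
matrix is exactly symmetric, which is precisely why it cannot separate "B
avoids A's territory" from "A avoids B's territory".

**Diagonal.** The conditional randomization is self-contradictory for A = A
(one cannot hold A fixed while relocating it), so diagonal entries are
undefined by default. An explicit `diagonal_policy="full_shuffle"` fills the
diagonal from the full-shuffle null and flags this in the matrix notes.

**Reproducibility.** One master seed drives everything. Each ordered pair of
a matrix run draws from a sub-stream keyed by the *names* of the two classes
(hashed into a `SeedSequence` spawn key), so a pair's scores are unchanged by
re-ordering input rows or by adding/removing unrelated classes. Internally,
candidate pools and the full-shuffle position stream use a canonical
lexicographic ordering of coordinates, making results invariant to record
order; matrices from the same table and seed are bit-identical.

**No p-values.** Only z-scores are reported. Replicate values are retained on
each `NullSummary` so users can form empirical p-values if they want them.

## Winsorization normalization

For each feature, values are clamped into `[P10, P90]` (percentile ranks
configurable) and then mapped affinely so `P10 → 0`, `P90 → 1`. Percentiles
use linear interpolation between order statistics (numpy's default rule);
percentile conventions differ between packages, so the choice is fixed here.
Normalization is per sample/core by default, because each core's percentiles
must anchor its own staining scale — this removes any positive-slope affine
difference between cores exactly (tested to 1e−9).

Pure clamping alone cannot align cores whose intensities differ by an affine
shift, which is the observed failure mode between separately stained cores;
the affine rescale is therefore the default, and `rescale=False` provides
textbook Winsorization. Constant features map to 0 with a warning; missing
values pass through untouched and are excluded from percentile estimation;
groups with fewer than 2 rows pass through with a warning.

The alignment report quantifies what a feature-space scatter shows visually:
the two-sample Kolmogorov–Smirnov statistic per feature between exactly two
cores, before and after normalization, plus the fraction of features whose
divergence decreased.

## Confusion-matrix QC

Cells are matched between two classification runs strictly by cell id —
coordinates are never used for matching — and unmatched ids are an error
listing up to ten offenders. Row (expected) and column (predicted) label
orders are first-appearance and independent, since one method may emit a
class the other never uses. Every matrix element owns a selection: exactly
the cells it counted, in input order, with coordinates for downstream
viewers; selections over all elements partition the matched cells. Agreement
is the matched-label diagonal over the total; per-class recall and precision
with zero denominators, or for classes absent from one axis, are NaN — never
coerced to 0, which would silently deflate or inflate averages.

## Synthetic tissue model

Cell maps are generated on a rectangular window, class by class:

* `Uniform` — binomial point process (optionally on a sub-rectangle).
* `Clustered` — Thomas-style: uniform parents, isotropic-normal offspring
  (sd = `dispersion_sd`). Each cell picks its parent uniformly, so exact
  per-class counts are honored (the standard exact-count conditioning of a
  Thomas process). Out-of-support offspring are resampled rather than
  reflected or truncated, preserving isotropy near edges.
* `AttractedTo` — each cell displaces isotropic-normally from a uniformly
  chosen cell of an earlier class.
* `InhibitedFrom` — uniform proposals rejected inside the exclusion radius of
  every cell of an earlier class, with a resampling cap that raises a clear
  error for infeasible geometries.

Every placement accepts an optional region rectangle; repeating a label
across entries composes mixtures. All generators are pure functions of their
arguments including the seed.

### Canned scenarios (constants pinned in `netqc/synthetic.py`)

* **CSR** — 3 classes × 200 cells uniform on 1000×1000. Calibration
  baseline: across 50 tissues at `d = 50`, `R = 500`, per-ordered-pair scores
  have mean within ±0.3, sd within [0.7, 1.4], and no |z| ≥ 4.
* **Attraction** — B displaced from A with sd = d/5 (d = 50); an uninvolved
  uniform class C keeps the conditional pool non-degenerate. Expected z ≫ 2.
* **Repulsion** — B excluded from a hard-core zone of radius 2d around A
  (d = 25; at this density roughly half the window remains admissible, so
  rejection sampling is comfortably feasible). Expected z ≪ −2.
* **Asymmetry** — the structured-tissue demonstration. Glioma: 100 cells,
  mixture of 40 whole-window + 60 right-half uniform. Other: 700 cells
  anchored on Glioma positions with displacement sd 5 (an order of magnitude
  under d = 50, so anchor and satellite see the same neighborhoods). TAMM:
  120 cells in 4 clusters (sd 25) confined to the left half.

  The construction makes the directional signature sharp for a reason worth
  recording. Because Other tracks Glioma's spatial distribution, the non-TAMM
  pool's neighborhood profile matches Glioma's own, so randomizing Glioma
  over that pool reproduces its true placement: z[TAMM][Glioma] is centered
  on zero and — because the observed subset mean is tied to the pool mean by
  the anchoring — *under*-dispersed, with cross-seed spread ≈ √(n_Glioma /
  pool) ≈ 0.35 (measured 0.37 over 40 seeds). A merely exchangeable (iid)
  pool would give a calibrated N(0,1) score that lands outside (−1, 1) a
  third of the time, which would blur the "randomly placed" half of the
  signature. Meanwhile TAMM's clusters occupy the Glioma-poor compartment, so
  z[Glioma][TAMM] is strongly negative (−18 to −9 across seeds). The
  whole-window mixture component guarantees the null has support near the
  TAMM clusters; with too little of it, occasional seeds have no non-TAMM
  cell within `d` of any TAMM cell and the null degenerates to σ = 0.

### Two-core feature tables

Each feature is a two-component normal mixture (background ≈ 1.0 ± 0.25,
positive population ≈ 3.0 ± 0.5, positive fraction varying across features) —
the canonical shape of a per-cell marker-intensity histogram. Core 2 is drawn
from the same mixture and distorted by `v ↦ a·v + b` plus independent noise
(defaults a = 2, b = 100, noise sd 0.05, 1000 cells/core): a stylized strong
staining difference between cores. Before per-core Winsorization the
two cores' per-feature KS statistic is 1.0 (disjoint supports); after, it
drops to sampling level (≈ 0.04 at n = 1000).

## What the synthetic validation does not show

The generators emulate the *statistical* structure the methods assume —
point-process geometry, affine staining shifts, label corruption. They do not
emulate segmentation errors, spatially varying cell density gradients within
a compartment, intensity-dependent misclassification, or correlated features;
passing tests therefore demonstrate correctness and calibration of the
statistics, not robustness to every failure mode of real imaging pipelines.
Problem sizes in the test and acceptance runs (hundreds of cells per class,
R = 500–5000, 20–50 seeds) were chosen so the full validation runs in
seconds while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* 2-D coordinates only; no 3-D neighborhoods.
* Radius-based neighborhoods only — no k-nearest-neighbor or Delaunay graphs.
* The conditional null is undefined for a class against itself; the optional
  diagonal uses the full-shuffle null and is flagged.
* No multiple-testing control across the K×(K−1) ordered pairs; scores are
  descriptive z-values, not calibrated p-values.
* CSV is the only interchange format, with a documented square named-matrix
  layout for enrichment results.
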