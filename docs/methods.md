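# Methods

This note documents the models, conventions and design choices behind
emr2vec, in the order the pipeline applies them.

## Record model and discretization

One record per patient (the first admission only). Features belong to seven
corpus categories — demographics, admission, resources, diagnosis,
procedure, lab, medication — plus `outcome`, which never contributes tokens.
Each feature yields at most one concept token `feature=value`; a missing
feature yields nothing (the corpus path never imputes — discretization plus
omission is itself the missing-data strategy, since sentences of different
lengths are unproblematic for a word-embedding trainer).

Boundary conventions where reasonable alternatives exist:

* **Age** bins <18, 18–34, 35–44, 45–59, ≥60 years; boundary values (18,
  35, 45, 60) go to the upper bin, as the bin labels read.
* **Labs** compare against a closed reference interval `[lo, hi]`:
  3-class `v < lo → low`, `lo ≤ v ≤ hi → medium`, `v > hi → high`;
  2-class inside → normal, outside → abnormal. Which labs use 2 vs 3
  classes is schema-driven.
* **Quartiles** use the cohort 25/50/75 percentiles, right-closed
  (`v ≤ edge` falls low; ties at edges go to the lower bin). Edges are fit
  once on the training cohort, persisted as JSON, and frozen; unseen values
  clamp to the outer bins. A constant column cannot form quartiles and is
  rejected as degenerate.
* **Token syntax** is the delimiter-safe canonical string
  `feature_id=value` (feature ids may not contain `=` or whitespace), so
  vocabularies are reproducible and every token parses back to its
  (feature, value) pair.

## Corpus and baseline representations

The vocabulary is ordered lexicographically (stable across platforms); its
size is the one-hot dimension. Shuffling permutes tokens within each
sentence only, one spawned RNG stream per sentence from a master seed, so a
shuffled corpus is reproducible and sentence-parallel.

Multi-hot is the bitwise OR of the record's one-hots (popcount = number of
distinct concepts). The mixture representation keeps a multi-hot block over
non-panel tokens plus a continuous block of raw lab values for the panel of
labs observed in at least 90% of cohort records (configurable), with cohort-
median imputation for missing panel entries. The continuous block is
z-scored by default before cosine distance — raw assay scales differ by
orders of magnitude and would otherwise dominate the angle — but this can be
disabled to compare against strictly raw values.

## Skip-gram trainer

Skip-gram with negative sampling: 5 negatives drawn from the unigram^0.75
distribution, sigmoid losses, plain SGD with a linear learning-rate decay
from 0.025 to 0.0001 over all (pair, epoch) steps, 5 epochs by default,
`min_count` 1 (clinical vocabularies are small and every concept is wanted).
The window is fixed at exactly c tokens each side — no random window
shrinking — so that the `window="max"` variant (window = longest sentence)
covers every within-sentence pair exactly. Input-side vectors are returned.
The inner loop is a compiled (numba) kernel in float32, single-threaded and
bit-deterministic given the seed; per-epoch mean loss is recorded in the
embedding's provenance.

**Shuffle ensemble.** Train on `n_shuffles` (default 20) independently
shuffled copies of the corpus and average each token's vectors elementwise.
All runs share one weight initialization: embeddings from independently
initialized runs agree only up to rotation, and averaging rotated solutions
cancels toward zero; with a shared init and only the within-sentence order
varying, the elementwise mean is well-posed and demonstrably stabler than a
single run (the variance test in the suite). Patient vectors are the
arithmetic mean of the record's concept vectors; tokens absent from the
vocabulary are skipped with a warning, and a record with no known token is
an error.

As an independent cross-check of the trainer (there is no second SGNS
implementation among the dependencies), the package carries a count-based
embedding route — positive PMI co-occurrence matrix factorized by truncated
SVD — which SGNS implicitly approximates. On a fixture corpus the Spearman
correlation between the two methods' pairwise-similarity rankings is about
0.84 across trainer seeds; the suite requires ≥ 0.8.

## Distances and clustering

Cosine distance for embedding vectors; Jaccard for multi-hot; and for the
mixture, `w_d · jaccard(discrete) + w_c · (1 − cos(continuous))` with
weights (1, 1) by default. Jaccard is implemented in the Ruzicka form
`1 − Σ min / Σ max`, identical to set Jaccard on binary vectors and defined
for any nonnegative vectors — which lets the Hopkins statistic's uniform
pseudo-points be scored under the same distance without a special case.

"k-means" under these distances means: **spherical k-means** for cosine
(unit-normalized rows, assignment by maximum cosine, centroids =
renormalized means; the within-cluster cosine objective is non-increasing
across iterations) and **k-medoids** for Jaccard/mixed (coordinate means of
sets are undefined). The k-medoids solver uses alternating
assignment/medoid-update iterations on a precomputed distance matrix — the
standard alternating formulation rather than full PAM swap search, chosen
for tractability at cohort scale; on separated data the two agree. Both use
10 restarts, 300 max iterations, relative tolerance 1e-4, and repair empty
clusters by reseeding from the farthest point. k is selected as the
silhouette argmax over 2–15 (ties to the smaller k).

## Validity indices

* **Hopkins** H = Σu / (Σu + Σw) with m = min(n/10, 100) probes: u are
  nearest-real-neighbor distances of uniform pseudo-points in the
  per-dimension bounding box, w of real points sampled without replacement
  (self-distance excluded). H ≈ 0.5 for *uniformly random* data and → 1
  for clustered data. A regular lattice scores well below 0.5 — it is more
  evenly spaced than the uniform-random null — so the null check in the
  suite uses uniformly distributed random points.
* **Silhouette** mean of (b − a)/max(a, b); singleton clusters and the
  a = b = 0 case score 0.
* **Davies–Bouldin** (1/k) Σ_i max_j (σ_i + σ_j)/d(c_i, c_j) with scatter σ
  = mean member-to-center distance. Centers are the solution's own centers
  — centroids for spherical k-means, medoids for k-medoids — keeping the
  index internal to the distance space. The index is reported unbounded
  above (it is not a [0, 1] quantity); coincident centers are an error.
* **Supervised mapping**: each cluster takes its majority true label (ties
  broken lexicographically); per label, precision = correct members /
  cluster size, recall = correct members / label prevalence, F1 = harmonic
  mean. A label that no cluster claims gets recall 0 and its undefined
  precision reported as 0 with a warning.

A worked silhouette example used in the tests: 1-D clusters {0, 0.1} and
{10, 10.1} give a = 0.1 for every point, b = 10.05 for the outer and 9.95
for the inner points, hence SI = (9.95/10.05 + 9.85/9.95)/2 ≈ 0.9900.

## Synthetic cohort generator

The generator emulates the *shape* of a two-class inpatient stroke cohort,
not its medical content: default 8,000 patients, 83/17 ischemic-like vs
hemorrhagic-like mix, 400 diagnosis codes (40 markers per class at 15% vs
2% prevalence, 320 shared background comorbidities at 0.5–3%), 30
procedures, 40 medications, 60 lab items with reference ranges (15 of them
shifted in the minority class) and missing-at-random gaps cycling through
5/8/12% (so roughly two-thirds of labs clear a 90% coverage panel), age and
resource-use distributions separated by class, and class-dependent outcomes
(length of stay ~9 vs ~13 days, cost, mortality 0.65% vs 7%) that never
enter the corpus. One master seed spawns named substreams (class draw,
demographics, concepts, labs, missingness, outcomes) so components are
independently reproducible. Prevalences and ranges are formulaic, not
random, so the spec itself is deterministic.

What the generator does **not** emulate: real ICD code semantics and
hierarchy, correlations between comorbidities, longitudinal/multi-visit
structure, informative (non-random) missingness, and measurement error.
Passing the end-to-end tests therefore shows the pipeline recovers planted
class structure of realistic dimensionality and sparsity — it does not show
clinical validity on real data.

The planted-block corpus is the adversarial-order fixture: each sentence
draws ~6 tokens from one of 4 ten-token blocks and separates consecutive
block tokens with 5 uniform background tokens, so block tokens never
co-occur within a window of 5 in the written order. A single run at window
5 then scores low top-10 neighbor block precision (~0.35–0.4) while the
20-shuffle ensemble reaches ~0.9 (the ceiling with 10-token blocks).

## Problem sizes in the test suite and acceptance script

The suite's end-to-end run uses a 2,000-patient cohort with the otherwise
default generator (and d = 200, window 5, 20 shuffles, 5 epochs), which
finishes in a few minutes on one CPU and leaves the class-recovery
assertions unchanged from cohort scale; the order-robustness experiment
uses the 2,000-sentence block fixture at full d = 200. Unit tests train at
d = 16–50 on toy corpora. The acceptance script regenerates every input
from its `--seed` and reports only quantities it computes in the run.

## Known limitations

* Single-admission records only; no temporal modeling.
* The mean-of-concepts patient vector ignores concept salience (no
  frequency weighting or attention).
* k-medoids uses the alternating heuristic; on pathological geometries PAM
  swap search could find better medoids.
* The Hopkins statistic's bounding-box null becomes diffuse in very high
  dimensions; interpret it comparatively across representations rather than
  absolutely.
* Negative sampling is assumed for the Skip-gram estimator; hierarchical
  softmax is not implemented.
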