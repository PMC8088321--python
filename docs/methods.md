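# Methods

## Objective functions

The ground set Y is the full biosample × assay grid of experiments,
performed and candidate alike. The plain facility location objective

    f(X) = Σ_{y∈Y} max_{x∈X} φ(x, y)

scores a panel X by how well its closest member represents each element
of Y, with φ the squared Pearson correlation between binned signal
tracks. With the convention max over the empty set = 0, f(∅) = 0; f is
monotone and submodular, which gives greedy maximization its
(1 − 1/e)-approximation guarantee. Weights enter as
max_x w(x) φ(x, y) with w(x) ≥ 0; since w is fixed during optimization
the weighted objective stays submodular. Weighted coverage values may
exceed 1 (weights up to 100 are meaningful) and are deliberately not
clamped.

The concentration extension adds λ_a‖a(X)‖₂² + λ_b‖b(X)‖₂², where a(X)
and b(X) are the per-assay and per-biosample selection-count vectors.
The count vectors are taken over the *selected* set X: a ground-set
count would be a constant and could not steer the optimization, whereas
the squared count over X rewards concentrating picks on few assays or
biosamples (its marginal contribution for an element whose category
already holds c picks is λ(2c + 1), growing in c — supermodular). The
mixture is therefore not submodular, and the greedy engine treats it
accordingly (below).

## Greedy engines

Both engines maintain an incremental coverage state: the per-target best
weighted coverage c_y, the category counts, and the running objective,
making one marginal-gain evaluation O(n). Ties break to the lowest label
index in every engine and in the exhaustive oracle, so runs are
bit-reproducible.

* **naive** re-evaluates every candidate each step: O(n²) per step,
  valid for any λ ≥ 0.
* **lazy** (accelerated greedy) keeps stale gains in a max-heap keyed by
  (−gain, index) and re-evaluates only the top until the refreshed key
  again beats the heap top; the lexicographic key makes exact ties
  resolve to the lowest index, matching the naive engine. Stale gains
  are valid upper bounds only under diminishing returns, so the lazy
  engine refuses to run when λ_a or λ_b is positive — correctness over
  speed for the supermodular mixture.

Seeding initializes the coverage state from already-performed
experiments before ranking begins; seed weights default to 1. Seeds
enter the count vectors by default (`penalize_seeds=True`) so that the
mixture objective is the objective of the union; the flag exists because
one may prefer to penalize only new picks. After each run the
incremental objective is checked against a from-scratch recomputation at
1e−9 relative tolerance.

`brute_force_optimum` enumerates all C(n, k) candidate subsets (capped
at 10⁶) under the identical objective and tie-break. It exists as the
independent oracle for the greedy engines and is used that way in the
test suite and acceptance checks.

## Similarity construction

Tracks are −log10 p-value signal, binned over an ordered region list
(BED, 0-based half-open) at 25 bp. The bin value is the
coverage-weighted mean of the bedGraph signal with uncovered base pairs
contributing zero; a trailing partial bin of a region is dropped, and a
region on a chromosome missing from a track yields zero bins plus a
logged warning (missing data, not a format error). The arcsinh
transform ln(v + √(v² + 1)) damps outliers while preserving order.
Plus/minus strand pairs of transcription assays are summed into one
unstranded track before comparison (a single-stranded experiment cannot
be ordered); tracks already on the arcsinh scale are summed as-is.

Correlations are computed in double precision with a two-pass algorithm
(means first, then centered moments) so results do not depend on
summation order. A zero-variance track has undefined correlation; it is
assigned φ = 0 against every other track and φ = 1 with itself — a flat
track carries no shared information, but self-similarity must stay
maximal so each element can cover itself. Matrices are validated on
construction: symmetric within 1e−8 (then symmetrized by averaging,
since floating-point correlation is not exactly symmetric in evaluation
order), entries in [0, 1] up to 1e−8 slack, no NaN.

The assay-averaged baseline similarity is the mean of φ between assays
a and b across biosamples where both were performed, with support counts
recorded. It is biosample-agnostic by construction. When comparing
against a target biosample the average excludes that biosample. Assay
pairs never co-performed have no defined average; when the baseline is
expanded to experiment resolution these cells are filled with the global
mean of the supported off-diagonal entries — a neutral fill that avoids
excluding the pair outright.

## Coverage scoring

An element's (biosample's or assay's) coverage score is the facility
location value of its performed experiments against its full ground set
within the similarity matrix, bounded by the ground-set size. Baselines:
10 random panels of the same size, drawn uniformly without replacement
within the element, each element using an RNG stream derived from the
master seed and the element's position (so adding elements never shifts
another element's draws); and a greedy-optimized panel of the same size.
Rank correlations between experiment counts and scores use Spearman's
rho with average ranks; a constant input vector returns NaN rather than
an arbitrary number.

## Panel evaluation

Bins are split into three disjoint contiguous blocks in genomic order:
selection (similarity and ranking), training (regression fit),
evaluation (reported MSE). Reconstruction is multi-output linear
regression with intercepts, fit in closed form as ridge regression with
stabilizer 1e−6: the model class is exactly a linear map under an MSE
loss, so the closed form is the optimum an iterative optimizer would
approach, without optimizer stochasticity; a full-batch gradient-descent
cross-check in the test suite bounds the substitution error at 1e−4 MSE.
With ridge = 0 a rank-deficient design raises an error instructing a
positive ridge. MSE is averaged over evaluation bins, then over target
tracks, then (in the per-biosample comparison) over biosamples.

## Synthetic data generator

The generator emulates the low-rank structure the method assumes:

    signal(b, a, p) = softplus(u_b · (g_p ∘ v_a)) + N(0, noise_sd)

Per-assay latents v_a are a class centroid plus N(0, 0.25) jitter, so
the four activity-class analogues (transcription, histone, binding,
accessibility) produce correlated within-class tracks. Per-biosample
latents are u_b = 1 + 0.3·N(0, 1): the shared component makes the same
assay correlate strongly across biosamples — the dominant clustering
structure of real epigenomic tracks — while the 0.3-scale modulation
keeps biosamples distinct enough that biosample-tailored selection has
something to gain over the assay-averaged baseline. The softplus link
keeps signal non-negative like −log10 p-values; Gaussian noise is added
after the link. Defaults: 20 biosamples × 12 assays over 2000 bins of
25 bp, 4 classes, latent dimension 6, noise_sd 0.3 (small against the
order-one softplus signal, so class structure survives without being
trivial).

Stranded assays are emitted as a pair of tracks splitting the signal by
a per-position uniform coin, so their sum reproduces the unstranded
track exactly. The performed mask is L-shaped: the first 3 biosamples
are deeply assayed (all assays) and the first 3 assays — the whole
transcription class — are broadly run (all biosamples); every biosample
and assay retains at least one performed experiment, the premise of
imputation-driven selection. One master seed drives everything through
per-(axis, index) sub-streams, so changing only the number of positions
reuses the same latents.

What the generator does *not* emulate: assay-specific signal shapes
(broad versus punctate peaks), mappability artifacts, inter-replicate
variability, or imputation-model error structure. Passing tests
therefore demonstrate the selection machinery's behavior under the
assumed low-rank similarity structure, not performance on any real
compendium.

## Evaluation protocol choices

Problem sizes in the tests and acceptance script: 240-track cohorts,
50-experiment panels for composition effects, 1000/800/200 bin
partitions, and 3–5 replicate cohorts where a directional claim is
averaged. Two protocol details deserve note:

* The biosample-specific versus assay-averaged comparison uses panel
  sizes 4–8 of the 12 assays: at sizes 1–3 the baselines are
  near-tied (too few picks to differ), and near size 12 both methods
  trivially converge because the panel spans almost the whole ground
  set. The directional advantage of biosample-tailored selection holds
  on average across replicate cohorts at the mid-range sizes.
* Selecting on noise-free tracks beats selecting on noisy tracks only
  at large panel sizes (tested at 80–160 of 240). At small sizes the
  noisy-track similarities implicitly encode per-track signal-to-noise,
  which helps when the reconstruction target is itself noisy; the
  denoised ranking pulls ahead once many experiments are selected and
  fine distinctions matter.

## Known limitations

* The dense similarity matrix is held in memory; tens of thousands of
  experiments fit (a 30 800² float64 matrix is ~7.6 GB), but the
  similarity *construction* is designed for region-restricted tracks,
  not genome-wide streaming of >10k tracks.
* The lazy engine's refusal under concentration terms is conservative;
  bounded-staleness variants exist but are not implemented.
* Cost-budget (knapsack) constraints and stochastic greedy variants are
  out of scope.
* The HDF5 similarity dialect (datasets `similarity` and `labels`) is
  this package's own; no attempt is made to read other tools' layouts.
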