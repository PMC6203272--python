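# Methods

This note documents the model behind clustex, the parameters that matter,
the numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Problem statement

Given one or more expression matrices (genes × conditions), find every
group of genes whose profiles genuinely co-vary — in all datasets at once
when several are given — and assign nothing else. The output is a set of
pairwise-disjoint clusters plus the list of unassigned genes. Two
whole-result statistics define "good" here:

* **MSE** — within-cluster dispersion. For a cluster of N genes in a
  D-condition dataset, `MSE = (1/(D·N)) Σ_g ‖x_g − z‖²` with `z` the
  per-condition mean profile; the whole-result MSE is the size-weighted
  average over clusters. Normalizing by both D and N makes values
  comparable across datasets and cluster sizes; on z-scored data the
  whole gene universe as a single cluster has MSE ≈ 1, which is the
  natural "no structure" reference.
* **JI** — a modified Jaccard index of cluster overlap: the fraction of
  clustered genes that also fit inside the *boundary box* of at least one
  other cluster, where a cluster's box at each condition is the
  [1st, 99th] percentile interval of its members' values (the most
  extreme 1 % of values at each point are trimmed so single outliers do
  not inflate the box). The pipeline's contract is JI = 0: a gene in a
  cluster fits no other cluster's profile envelope.

The 1 %-trim is read as a symmetric percentile interval, which is well
defined for any cluster size; an alternative reading (trimming 1 % of
values in total before taking min/max) differs only in the tails and is
not used.

## Pipeline

### 1. Pre-processing

Committed order: quantile normalization → `log2(x + c)` (pseudo-count
`c = 1`, skipped when the data are already log-scale; a warning fires when
the matrix maximum is below 30, a heuristic sign of log-scale input) →
median summarization of replicate columns → low-expression filter →
per-gene z-scores (population σ), or zero-centering for two-colour
microarray data whose log-ratios are already centred on zero.

The filter retains a gene only if its value strictly exceeds the flat
25th percentile of *all* matrix values at ≥ ⌈0.25·D⌉ conditions. It must
run before z-scoring (after z-scoring every gene has unit variance and an
abundance threshold is meaningless) and after replicate summarization (so
"conditions" means biological conditions, not samples). The threshold is
a flat percentile over the whole matrix rather than per-condition: after
quantile normalization all columns share one distribution, so the two
readings coincide up to ties, and the flat version is simpler and scale
invariant. Zero-variance genes are z-scored to all-zero rows and recorded
under `flags["zero_variance"]` rather than dropped.

Percentiles use linear interpolation throughout (numpy default); quantile
normalization resolves ties by averaging the rank means the tied entries
span, which means exact column-distribution equality holds for tie-free
columns and approximate equality under ties.

### 2. Seed pool

k-means (Euclidean, k-means++ seeding, best of `restarts = 10` by
within-cluster SSE, fully seeded) at every K in the grid. Default grid
2, 4, …, 20: bulk expression datasets typically yield a handful to ~15
clusters, and the downstream selection step tolerates a generous grid —
over-clustering only adds candidate fragments. K values at or above the
gene count are skipped with a warning.

For d ≥ 2 datasets the gene universe is the intersection of each
dataset's retained genes (consensus membership is undefined for a gene
absent anywhere). Per K: one partition per dataset, all aligned to the
first dataset's labels by maximum-overlap assignment (solved exactly with
the Hungarian algorithm on the negated K×K overlap matrix; ties resolved
deterministically), averaged into a fuzzy consensus partition matrix
(rows sum to 1), then binarized by the difference-threshold rule at every
δ ∈ {0, 0.1, …, 0.5}: gene g joins cluster k only if
`cpm(g,k) − max_{j≠k} cpm(g,j) > δ` (strict, so exact ties stay
unassigned). Larger δ keeps only genes consistently co-clustered across
datasets — assignment is monotone shrinking in δ — and δ > 0.5 produces
mostly empty seeds, hence the capped grid. Only the difference-threshold
binarization family is implemented; the consensus literature's other
operators (union, value-threshold, top) are not needed by this pipeline.

### 3. M-N elite selection

Each seed is plotted by dispersion `M` (mean per-dataset cluster MSE) and
size `N`. `M` and `log2 N` are min-max scaled over the current pool
(`log2` rather than raw size so a single giant seed cannot flatten the
axis; degenerate pools scale to 0), and the distance to the ideal corner
(`M_scaled = 0`, `N_scaled = 1`) is

    distance = sqrt(w · M_scaled² + (2 − w) · (1 − N_scaled)²),

with `w = 1` by default (`--mn-weight`; w > 1 favours tightness, w < 1
size). The minimum-distance seed becomes an elite, its genes are deleted
from every surviving seed, scalings are recomputed, and the loop repeats.
Ties break deterministically: larger N, then lexicographically smallest
gene tuple.

Two eligibility rules bound the loop:

* **Minimum size** (`--min-cluster-size`, default 10): size-1 "clusters"
  have MSE 0 by construction and would dominate any dispersion ranking.
* **Dispersion cap** (`--dispersion-cap`, default 0.5): a seed is only
  eligible while its M is at most half the MSE of the whole retained gene
  set. Because the M axis is rescaled over the *surviving* pool, the bare
  iteration would eventually elect every leftover seed — including
  k-means cells of genes that merely sit near each other without
  co-varying. The cap states the minimal scientific requirement that a
  reported cluster explain at least half of its members' variance;
  setting it to `None` (CLI: a non-positive value) restores the bare
  iteration. On the synthetic benchmark the cap is what makes cluster
  count and coverage *decrease* as more datasets are added — the
  biologically expected behavior, since consistent co-expression becomes
  rarer as conditions accumulate — instead of growing with the seed pool.

### 4. Refinement

The elites are drafts; refinement learns the within-cluster dispersion
distributions and applies them three ways, alternating (a) and (b) until
a fixed point (at most `--max-iterations = 20` rounds), then running (c):

(a) **Outlier removal.** A gene fits a cluster when, in every dataset, its
value lies within μ_d ± q·s_d of the members' per-condition mean and
population std at every condition (`q = --tightness`, default 3.0 — the
usual ~99.7 % normal envelope; conditions with s_d = 0 admit only exact
equality, so a noise-free cluster accepts precisely its own profile).
Additionally, the per-gene deviations from their cluster mean (Euclidean
distance normalized by √D, averaged over datasets) are pooled over *all*
clusters into a single learned dispersion distribution, and genes above
its robust upper bound, `median + q·1.4826·MAD`, are outliers even when
their own cluster is loose. The pooled gate is what dissolves
pseudo-clusters: a group of mutually unrelated genes always fits its own
wide envelope, but its members are collectively far more dispersed than
members of genuine clusters, so the pooled bound removes them and the
cluster collapses below the minimum size. Both rules iterate, with
envelopes and the pooled distribution recomputed each pass, until stable.

(b) **Completion.** Every retained-but-unassigned gene is tested against
each cluster's envelope (as learned before any additions); it is added
only when it fits *exactly one* cluster. Genes fitting two or more remain
unassigned — by the overlap definition they are ambiguous, and assigning
them would erode distinctness. Completion before outlier removal would
let contaminated envelopes recruit further outliers, hence the order.

(c) **Distinctness.** Boundary boxes are computed for every cluster (in
every dataset); any gene lying inside another cluster's box at all
conditions of all datasets is discarded — not reassigned, since a gene
inside two boxes is ambiguous by definition. Boxes are recomputed and the
pass repeats until no overlap gene remains; each pass removes at least
one assigned gene, so termination is bounded by the assigned-gene count.
This guarantees JI = 0 exactly, not approximately. For multi-dataset
results the overlap test requires containment in every dataset, which
reduces to the single-matrix JI definition when d = 1.

An empty final result (K = 0, PAG = 0) is legal and meaningful: it says
no consistent co-expression survives the evidence threshold — expected,
for example, when many heterogeneous datasets are intersected.

## Comparison metrics

* **ARI** between two results on one gene universe uses the standard
  pair-counting form (via scikit-learn, verified against a brute-force
  pair-counting oracle in the tests). Unassigned genes are treated as one
  extra group, so extraction results with different coverage remain
  comparable.
* **Validation indices.** DB, silhouette and CH use their standard forms
  (scikit-learn); BIC is the spherical-Gaussian mixture form (larger
  better); BH is the mean over clusters of the mean squared member-to-
  centroid distance; Xu is `D·log2(√(W/(D·n²))) + log2 K`; WB is `K·W/B`
  with W/B the within/between sums of squares. Directions: larger is
  better for BIC, silhouette, CH; smaller for DB, BH, Xu, WB. Indices
  needing between-cluster separation are NaN for K < 2 and rank worst
  rather than erroring, so cross-method reports stay total.
* **Rank scores.** Per index, methods are ranked direction-aware with tie
  averaging (two methods sharing the best of eight scores rank 1.5 each;
  each index's ranks sum to n(n+1)/2); the final score is the mean of the
  seven per-index ranks.

## Synthetic data generator

The generator emulates the standard planted-cluster benchmark: 500 genes
× 6 time-points; three clusters of 100 genes with mean profiles a rising
ramp (−1.25 → +1.25), its mirror image, and a symmetric tent peaking
mid-course (the ramp endpoints set a ±1.25 amplitude so that σ = 1.2
noise is comparable to the signal, making the top noise level a genuinely
hard condition); members are mean + N(0, σ²) per point; 200 "unclustered"
genes are standard-normal profiles; everything is z-scored per gene.
The canonical noise series is σ ∈ {0, 0.4, 0.8, 1.2} (intermediate values
linearly interpolated between the endpoints 0 and 1.2).

Unclustered genes are rejection-sampled in z-scored space until they fall
outside every planted cluster's boundary box padded outward by 0.25 at
one or more time-points. Rejecting against the boxes (rather than a
±3σ band around the mean profile) makes the design guarantee exact under
the same machinery JI uses — no unclustered gene can ever be an overlap
gene of a planted cluster — and remains feasible at σ = 1.2, where a 3σ
band would cover essentially all profile space and rejection sampling
could not terminate. The 0.25 pad keeps the exclusion meaningful at
σ = 0, where the boxes are single points. A per-gene retry cap (10 000)
raises an error if the exclusion zones become near-exhaustive.

What the simulation does *not* emulate: count noise (RNA-seq dispersion
is negative-binomial, not Gaussian-on-profile), correlated noise across
genes, batch effects, or missing values. Tests passing on this benchmark
therefore demonstrate the algorithmic contracts (recovery, exclusion,
distinctness, consensus behavior) — not robustness to every artifact of
real data.

## Benchmark behavior and problem sizes

All stochastic checks run at the design's native size (500 genes, 6
time-points) with fixed seeds:

* Noise-free recovery: at σ = 0 the full pipeline returns exactly the
  three planted 100-gene clusters (PAG = 60 %, K = 3) for every seed
  tried — membership is unambiguous without noise, so anything else would
  indicate a defect.
* JI = 0 holds on every completed run at every noise level, by
  construction of the distinctness pass.
* Multi-dataset trend: over d ∈ {1, 2, 4} independently-noised replicate
  datasets at σ = 0.8 (the moderate study noise level) and five seeds,
  median PAG and K are non-increasing in d, reflecting that consistent
  co-expression across more datasets is a strictly stronger requirement.

## Known limitations

* The dispersion cap and the pooled MAD gate are scale-free but assume
  the input is z-scored/centred (as the pre-processing guarantees); on
  raw-scale matrices their thresholds are not meaningful.
* At σ ≥ ~1 (noise comparable to signal), locally co-varying groups of
  "unclustered" genes are statistically indistinguishable from planted
  structure at this problem size and may be reported as clusters; the
  JI = 0 and disjointness guarantees still hold.
* The alternation of outlier removal and completion can in principle
  oscillate; the iteration cap (20) bounds it, and the distinctness pass
  restores all invariants regardless of where the alternation stopped.
* Replicate summarization uses the median only; no variance-weighted
  summaries. Between-dataset normalization and batch correction are out
  of scope — datasets are assumed independently pre-processed.
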