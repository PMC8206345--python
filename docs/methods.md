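# Methods

## Overview

`tracs` clusters genes from a time-series expression matrix into a small
number of temporal patterns, interprets each pattern as a transcriptomic
cell state, and orders the states into a directed path ("state A is
followed by state B"). Three statistical components do the work: a
Gaussian-process (GP) likelihood variant of the gap statistic chooses the
number of clusters; per-cluster GP regression summarizes each state as a
smooth mean curve with uncertainty; shape-based distance plus the
ranked-pairs algorithm order the states, and a two-group hypergeometric
test annotates transitions with shared pathways.

## Model and assumptions

**Input.** A genes × (time × replicate) matrix on an explicit numeric time
grid. Values are assumed library-normalized expression (counts or
intensities); the pipeline log-transforms (`log(x + 1)` by default) and
z-scores each gene across all entries, so clustering compares temporal
*shapes*, not absolute levels. Replicates are averaged per time point
before clustering.

**Cluster model.** Genes in one cluster are treated as noisy draws from a
single latent function with a squared-exponential covariance plus white
noise:

    K(t, t') = exp(-(t - t')^2 / (2 l^2)) + [t = t'] σ_N².

One GP is fitted per cluster to *all* member (time, value) points; the
length scale `l` and noise s.d. `σ_N` maximize the log marginal likelihood
under box bounds, from multiple seeded restarts of L-BFGS-B with an
analytic gradient. The Gaussian assumption is appropriate for log-scale
expression; raw counts (negative-binomial noise) are out of scope.

Because every gene is observed on the same few time points, the n × n
training covariance has the structure `U (D C D) Uᵀ + σ_N² I`, where `C` is
the RBF matrix among the `u` unique times, `D = diag(√m_i)` holds per-time
observation counts, and `U` is the block-normalized indicator. The exact
likelihood, gradient and posterior are computed in O(u³) rather than
O(n³); tests assert equality with a dense GP solver (scikit-learn's
`GaussianProcessRegressor`) to ~1e-8 on small instances. This is an exact
reformulation, not an approximation.

**Posterior summary.** The cluster mean μ̂ and s.d. σ̂ are evaluated on a
dense interpolation grid (every multiple of `interpolation_step`, default
1, spanning the observed range, union the observed points), so unevenly
sampled series are compared on a common clock. σ̂ includes the white-noise
term, matching a predictive (not purely latent) band; nodes report
μ̂ ± 1.96 σ̂ as the 95% interval.

## Choosing the number of clusters

For each k in the scanned range the genes are partitioned by K-means
(k-means++, 10 restarts) or Ward agglomerative clustering on the averaged
profiles, and a dispersion is compared against its expectation under B
structureless reference draws (each time-point feature i.i.d. uniform over
its observed range, clustered with the same pipeline):

* **Euclidean gap** (classic): `Gap(k) = E*[log W_k] − log W_k` with
  `W_k = Σ_r D_r / (2 n_r)`, `D_r` the summed squared pairwise distances
  in cluster r.
* **GP gap**: `W_k^GP = Σ_r L_r`, where `L_r` sums, over member profiles,
  the Gaussian log density under N(μ̂ at observed times, K + σ_N² I).
  Since `W_k^GP` is a sum of log densities and typically negative, the
  outer logarithm of the textbook formula is undefined; the gap is taken
  directly as `Gap^GP(k) = W_k^GP(obs) − E*[W_k^GP(ref)]`, which preserves
  the argmax where both forms are defined. A literal-log variant was
  deliberately not built: it errors on essentially every real input.

`k_opt` is the argmax of the gap (ties → smallest k); the Tibshirani
one-standard-error rule is available (`criterion="tibshirani-se"`). A k
whose observed or reference dispersion is exactly zero (k near the number
of genes) is marked unusable (−inf gap) rather than allowed to win with an
infinite gap. The B reference datasets are drawn once and shared across
all k, the standard gap-statistic practice; reference GP hyperparameters
are refitted per draw so observed and reference likelihoods are computed
identically.

On structureless (uniform) data the GP gap curve is empirically flat
(fluctuations of a few nats against planted-structure rises of hundreds),
but the argmax of a flat noisy curve is close to uniform over k — a null
scan indicates "no structure" through the flatness of the curve, not
through `k_opt` itself.

## Ordering clusters

Shape-based distance between two cluster means on the dense grid:

    SBD(a, b) = 1 − max_w CC_w(μ_a, μ_b) / √(CC_0(μ_a, μ_a) CC_0(μ_b, μ_b)),

`CC_w(a, b) = Σ_t a[t + w] b[t]` with zero padding, shifts
`w ∈ [1 − m, m − 1]` evaluated directly (O(m²); m is at most a few hundred
grid points). If the optimal shift is negative, the second curve is a
delayed copy of the first and cluster *a* precedes cluster *b*. Ties in
the maximal correlation break toward the smallest |w|, then negative w.

Pairwise precedences are merged by ranked pairs (Tideman): each decisive
pair is a victory with strength `1 − SBD` (the sort key is not fixed by
the method's description; larger similarity with a decisive shift is
treated as stronger evidence, with ties broken by larger |w|, then
lexicographic ids); victories are locked strongest-first into a directed
graph, skipping any that would close a cycle, and the lexicographic
topological order of the locked graph is the state sequence. Zero-shift
pairs abstain rather than vote arbitrarily; if *every* pair abstains there
is no ordering signal and the caller gets an error instead of a fabricated
order. The final network is always a simple path: k − 1 candidate edges.

## Pathway tests

All tests use the upper hypergeometric tail `P(X ≥ c)` computed by
`scipy.stats.hypergeom.sf` (log-gamma based, exact to machine precision).
The gene universe N is the analyzed (post-filter) gene set, not the
genome, and pathway genes outside the universe do not count toward N_p;
genes in no pathway still count in N. Two uses:

* **Cluster filtering** (optional): keep clusters with tail ≤ threshold
  (default 0.1) for a user-chosen pathway of interest.
* **Edge annotation**: pathway p is attached to the edge between adjacent
  clusters i and j iff `P(X ≥ C_ijp) ≤ 0.05 < min(P(X ≥ C_ip), P(X ≥ C_jp))`
  and `N_p > 10` — the union of the two clusters is enriched while neither
  alone is. The inequalities are applied exactly as stated (union
  inclusive, singles strict). No multiple-testing correction is applied
  across pathways, matching the raw-0.05 convention of the source method;
  this inflates per-edge discoveries when many pathways are tested and a
  BH-corrected variant would be a one-line extension.

## Evaluation metrics

Pair-based F1, Rand index and adjusted Rand index are computed from the
pair-confusion counts (TP: same cluster in both partitions, etc.) via the
contingency table; ARI uses the permutation-model closed form
`2(TP·TN − FN·FP) / ((TP+FN)(FN+TN) + (TP+FP)(FP+TN))`. Silhouette (on
averaged profiles, Euclidean) and completeness
(`1 − H(pred|truth)/H(pred)`, natural logs) delegate to scikit-learn;
tests pin both to brute-force oracles. `stem_profile_count(N)` returns
`3^(N−1) − 1`, the number of distinct up/down/flat step profiles over N
time points (used to reason about profile-enumeration methods for short
series).

## Synthetic data

The generator plants k clusters as one smooth base curve (sinusoid,
Gaussian impulse, logistic rise, or a seeded GP draw) delayed per cluster
by an integer number of grid steps, with i.i.d. Gaussian noise per gene
and replicate; true labels, the shift-sorted true order, and planted
pathway memberships are returned with the matrix. Presets mirror three
archetypes:

* `scrna_like_fixture`: 5 time points, 3 logistic clusters of 40 genes,
  noise 0.4 — an averaged pseudo-time single-cell series.
* `cellcycle_like_fixture`: 17 points at 10-unit spacing, two sinusoid
  periods, 5 phase-shifted clusters sized (31, 81, 44, 31, 34), noise
  0.4 — a synchronized cyclic series. Cyclic order is recoverable only up
  to rotation within one period; phase shifts (0.2 of a period apart) keep
  the shift-sign ordering well defined between adjacent phases.
* `emt_like_fixture`: 8 uneven points (0, 6, 12, 24, 36, 48, 72, 96),
  3 logistic clusters of 20 genes shifted by 0/30/60 time units, noise
  0.3 — a three-state developmental series.

Noise levels (0.3–0.4 s.d. on the z-score scale) and preset gene counts
were fixed once as moderately noisy, desk-scale conditions. What the
generator does **not** emulate: mean–variance coupling of counts, gene–gene
correlation within a cluster beyond the shared curve, batch effects,
dropout in single-cell data, or clusters that differ in shape rather than
delay. Passing recovery tests therefore demonstrate correctness of the
machinery under the stated generative model, not performance on real data.

## Numerical choices and degenerate inputs

* Length-scale search range [0, t_max] with the degenerate 0 replaced by a
  floor of 1e-3·t_max; noise s.d. bounds [1e-5, 10] on z-scored data.
  Optimization in log-parameter space, 5 random restarts (log-uniform in
  bounds) beyond a fixed start at (t_max/3, σ_N = 0.316).
* A 1e-10 jitter is added to every covariance diagonal; likelihood of a
  profile with zero noise and duplicated times raises an error advising a
  noise floor.
* Zero-variance genes z-score to all-zero rows and are kept (flagged) so
  behavior is deterministic; callers may filter.
* Genes missing all replicates at more than a configurable number of time
  points (default 4) are dropped with a warning; a gene missing an entire
  time point otherwise makes replicate averaging fail loudly.
* Profiles with missing entries enter the GP likelihood through exact
  marginalization (sub-vector, sub-kernel).
* All randomness (K-means init, reference draws, GP restarts, simulation)
  flows from one top-level seed; scans are reproducible bit for bit.

## Problem sizes

Recovery checks run at deliberately small scale: planted-k recovery uses
20 genes/cluster on an 8-point unit grid, shifts 2 steps apart, noise 0.1,
B = 10 reference draws, k scanned over [1, 6], 10 seeds per true
k ∈ {2, 3, 4}; order recovery uses 15 genes/cluster impulse clusters
shifted (0, 2, 4), 20 seeds. These sizes were chosen as the smallest at
which the planted structure is unambiguous to a human eye; the algorithms
have no scale-specific switches.

## Known limitations

* The network is always a path; branching trajectories are out of scope.
* GP noise is shared within a cluster; a single wild gene inflates the
  cluster's σ_N.
* The GP gap compares likelihoods of *averaged* profiles when the pipeline
  averages replicates first (replicate-level vectors are used whenever the
  matrix passed to `gp_dispersion` still carries replicates).
* Uniform-over-range reference sampling only (no PCA-rotated references).
* Cyclic processes: shift-sign precedence is ill-defined across a full
  period boundary; orders are meaningful up to rotation.
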