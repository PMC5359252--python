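# Methods

## Statistical model

The pipeline operates on an undirected weighted graph `G = (V, E)` over
`n` ROIs. For subject `s` in group `g ∈ {A, B}`, the connectivity value on
edge `(i, j)` is modelled as an exchangeable draw around a group-level
mean; the analysis makes no distributional assumption beyond
exchangeability of subjects under the null, which is what the permutation
test requires. The hypotheses are:

- **H0**: no altered network — either no edge differs between groups, or
  differential edges exist but are scattered randomly over `G`;
- **H1**: differential edges are concentrated in organized subnetworks,
  with clique topology (every within-set edge informative) or k-partite
  topology (between-set edges informative, within-set edges not).

### Edgewise stage

Each edge gets a two-sample t statistic and two-sided p-value. Pooled
variance is the default because it is the minimal reading of "two-sample t
test"; Welch is a flag (`welch=True`) since the choice is not forced by
anything upstream. Weights are `W_ij = −log p_ij`. The log base is
natural by default with log10 as an option; the permutation test uses only
weight *ranks* through monotone score comparisons, so the base provably
cannot change any p-value (verified by a test). p-values are clipped
below at the smallest positive normal double (~2.2e−308) before the log
so weights are always finite; the count of clipped edges is recorded on
the evidence object. No edgewise multiplicity correction is applied:
multiplicity is handled entirely at the network level.

Under H0 each p-value is Uniform(0, 1), hence each weight is exactly
Exp(1). This fact anchors the centering constant below.

### Network score and the parsimony constant λ

A candidate network with scoring edges `E_S` scores
`score(S) = Σ_{e∈E_S} (W_e − λ)`. The centered-sum form makes scores of
subgraphs of different sizes comparable on one scale, which the
max-statistic needs. The choice of λ is the one genuinely open design
decision, and it matters:

- `global_mean` (λ = mean of all edge weights) gives the score a null
  expectation of zero, but is too permissive on large graphs: at 90 nodes
  the score-*optimal* subgraph around a planted 8-node clique accretes
  roughly fifteen merely above-average noise nodes (measured Jaccard ≈
  0.35 against the planted truth), because the maximum over thousands of
  candidate extensions of a zero-mean sum is reliably positive. The local
  search is not at fault — every accreted node has strictly positive
  gain — the objective is.
- `null_quantile` (default) sets λ to the q-quantile (default q = 0.95)
  of the *null* weight distribution: the Exp(1) scale is estimated
  robustly as `θ̂ = median(W) / ln 2`, immune to a planted heavy tail of
  up to half the edges, and `λ = −θ̂ ln(1 − q) ≈ 3 θ̂`. Adding a noise
  node to a genuine network then requires its connecting edges to beat
  the 95th null percentile on average, which stops accretion (measured
  Jaccard 1.0 under the same conditions) while leaving genuinely
  differential edges (weights of order 30 at Δ = 0.6, n ≈ 40 per group)
  untouched.
- `fixed` pins λ for noise-free toys and sensitivity analyses.

Because the same score functional is applied to the observed and to every
permuted dataset, *any* λ rule yields valid permutation p-values; the rule
affects power and interpretability, not calibration. This is confirmed by
the type-I calibration test.

### Detection algorithms

**Clique search**: greedy seed-and-grow with multi-restart. Seeds are the
`n_restarts` heaviest edges; from each seed the search alternates
adding the node with the largest score gain and removing the node whose
removal gains most, until no single move improves the score. While the
set is below `min_size` (default 3, the smallest nontrivial clique) the
best node is added even at a loss; above it, every applied move strictly
improves the score, which guarantees termination. Ties break toward the
smaller node index, making the search deterministic. The best
positive-scoring result is extracted, its nodes removed, and the search
repeats on the residual graph (λ stays fixed from the full graph), so
detected networks are node-disjoint.

**k-partite search**: for each k in 2..`k_max`, `n_restarts` random
round-robin initializations are refined by steepest single-node
relabeling (moves that would empty a block are forbidden), maximizing the
centered sum over between-block edges. The largest score over k wins;
exact ties go to the smaller k (parsimony). `detect_all` re-reads each
detected network's own node set this way and keeps the k-partite reading
only when it strictly beats the clique score.

A k-partite pass over the whole residual graph was implemented and
rejected: optimizing a partition of ~80 null nodes maximizes pure noise,
which both inflates the permutation maxima (destroying power) and
produces uninterpretable whole-graph partitions. Re-reading detected node
sets keeps the k-partite hypothesis local, where it is meaningful.

Both searches are pinned to exhaustive enumeration (all subsets of size
≥ 3; all set partitions into ≤ k_max blocks) on 100 random graphs of ≤ 10
nodes in the test suite, with a documented local-search concession of at
most 5% of instances short by less than 1% relative score; in practice
the search has matched the optimum on every tested instance.

### Permutation inference

Group labels are permuted B times preserving group sizes; the full
pipeline (edgewise tests + detection, identical configuration) reruns per
permutation and the maximum detected score (0 if none) is recorded. Every
observed network is compared against the maxima regardless of its rank,
giving `p = (1 + #{max_b ≥ score}) / (B + 1)` — the add-one estimator, so
p ∈ [1/(B+1), 1] and significance at α = 0.05 needs B ≥ 19. Each
permutation draws from an independently spawned RNG stream, so results do
not depend on execution order and are reproducible for a fixed seed.
Default B = 999 for real analyses; tests and calibration studies use
B = 99 to keep Monte-Carlo batches tractable.

### Classification validation

Subjects are classified from their Fisher-Z values on the detected
networks' scoring edges with an SVM (linear or RBF kernel, C = 1, scikit-
learn's `gamma="scale"`; hyperparameters fixed, no search) under
leave-one-out cross-validation, with per-feature standardization fitted
on each training fold. By default the feature edges are the ones detected
on the *full* sample, which leaks the selection step into the folds and
is optimistic — it mirrors the common post-hoc validation practice.
`nested_config` re-detects networks inside every training fold for an
honest estimate; folds where nothing is detected fall back to the
supplied edge list.

## Synthetic generator

The generator emulates the analysis-ready object of a two-group
resting-state study: per subject, a symmetric zero-diagonal Fisher-Z
matrix over a shared node table. Defaults: 90 nodes; 65 reference
("control-like", group A) and 48 shifted ("case-like", group B) subjects;
baseline edge mean μ0 = 0.3 and subject-level noise σ = 0.3 Fisher-Z
units, which keep values in the range typical of resting-state
connectivity. Planted networks shift group B's mean by Δ on exactly the
affected edges (all pairs for a clique; between-set pairs for k-partite),
so Δ < 0 plants hypoconnectivity in the case-like group. Planting sites
are disjoint by construction. No effect-size estimates exist for real
detected networks, so the default Δ = 0.6 used in validation studies is a
calibration choice: large enough that an 8-node clique at 40 + 40
subjects is comfortably detectable, small enough that single edges are
not individually overwhelming.

In the direct-matrix mode, edges are independent given the group means.
This matches the exchangeability the permutation test assumes and keeps
every distributional oracle exact (edgewise p-values are exactly uniform
under the null), but it omits the cross-edge correlation of real
connectomes — shared node effects, distance dependence, global signal.
Passing tests on these samples therefore demonstrates calibration and
power under the method's own null model, not robustness to realistic
dependence; the time-series mode (correlated Gaussian ROI signals whose
population correlation encodes the planted structure, verified
positive-definite before sampling) provides cross-edge dependence through
the Pearson/Fisher-Z front-end for that purpose. Neither mode simulates
scanner artifacts, motion, or preprocessing effects. A planted shift
whose implied population correlation is numerically singular (|r| >
0.999) or breaks positive-definiteness raises a configuration error
naming the offending edge.

## Numerical choices and degenerate inputs

- Matrices with asymmetry below 1e−6 are repaired as `(M + Mᵀ)/2`;
  anything larger is rejected naming the subject. Non-finite entries are
  rejected naming subject and cell. Diagonals are forced to zero.
- `correlation_to_z` rejects constant ROI signals and |r| ≥ 1 − 1e−12
  (no finite Fisher-Z image).
- Edges with zero variance in both groups make the t statistic undefined
  and are rejected naming the edge (atlas indices).
- Score comparisons use a 1e−12 tolerance so float noise cannot flip a
  strictly-improving move; add/remove and k ties break deterministically
  (smaller node index, then smaller k).
- Node-relabeling equivariance of detection holds whenever the optimum is
  unique and reached, which is the generic case for continuous weights;
  the random k-partite initializations are indexed by sorted node order,
  so pathological ties could in principle resolve differently under
  relabeling.

## Problem sizes used in validation

The statistical test batteries use: 100 random graphs of ≤ 10 nodes for
oracle equivalence; 200 pure-null 90-node studies (20 + 20 subjects,
B = 99) for family-wise calibration, judged against the exact binomial
95% interval around α = 0.05; 50 seeds for planted-clique power
(8 nodes, Δ = 0.6, σ = 0.3, 40 + 40 subjects, success = Jaccard ≥ 0.8 and
p < 0.05, required in ≥ 90% of seeds — a regression guard, not an
external claim); 20 seeds for bipartite partition recovery (Rand index ≥
0.9). The acceptance script's study uses 65 + 48 subjects with a planted
20-node clique and an 8 + 11 bipartite network at B = 199, and 100
pure-null studies at B = 99 for the rejection rate.

## Known limitations

- The clique/k-partite family is the only topology family implemented; no
  overlapping networks, rich-club or hypergraph structures.
- The score-based detector is a defined, brute-force-verified stand-in
  for enrichment detection in general; other objectives (density-based,
  likelihood-based) could rank candidates differently.
- Permutations rerun serially; the per-permutation seed streams make the
  loop embarrassingly parallel, but no parallel executor is shipped.
- Default (non-nested) LOOCV inherits selection optimism by design, as
  discussed above.
- No covariate adjustment (age, sex, site): group comparison is marginal.
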