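# Methods

## Model

All UniFrac-family metrics here are branch sums over a rooted phylogeny
with branch lengths *b<sub>i</sub>* ≥ 0. For a sample *a*, the operand is
the *branch profile*: for every branch *i*, the summed abundance
*x<sub>i</sub><sup>a</sup>* of all leaves descending from it. With
relative abundances (p) the weighted form is the familiar normalized
weighted UniFrac; with absolute abundances (c = proportion × total load
N) the same formula becomes Absolute UniFrac:

    U = Σ bᵢ |xᵢᵃ − xᵢᵇ| / Σ bᵢ (xᵢᵃ + xᵢᵇ)

    GU(α) = Σ bᵢ (xᵢᵃ+xᵢᵇ)^α · |xᵢᵃ−xᵢᵇ|/(xᵢᵃ+xᵢᵇ)
            ───────────────────────────────────────,  α ∈ [0, 1]
                     Σ bᵢ (xᵢᵃ+xᵢᵇ)^α

Key algebraic facts the implementation relies on (and tests assert):

- GU(α = 1) equals the weighted form identically.
- If both samples have equal totals, the absolute and relative forms
  coincide (the load factors cancel); jointly rescaling both samples'
  absolute counts leaves U^A and GU^A unchanged.
- If sample *b* = k·a elementwise, every absolute metric equals
  (k−1)/(k+1) and every relative metric 0 — the "equal composition,
  different biomass" contrast that motivates the absolute forms.
- The branch-sum denominator Σ bᵢ(pᵢᵃ+pᵢᵇ) equals the leaf-depth-weighted
  normalization Σⱼ dⱼ(pⱼᵃ+pⱼᵇ) (swap the order of summation), which is why
  skbio's normalized weighted UniFrac serves as an independent oracle for
  the relative mode in the tests.

### Conventions and degenerate cases

- **Branch enumeration.** A fixed postorder over all edges is computed
  once per tree and cached; profiles for any number of samples are one
  vectorized postorder accumulation. This is what makes 100-iteration
  rarefaction loops cheap — nothing re-traverses the tree.
- **Root edge.** The root's own edge participates with its stated length
  (0 when absent, and unrooted exports are adopted with a zero-length
  root edge). Both samples' totals sit on that edge, so with equal totals
  it contributes 0 to the weighted numerator — but *not* when totals
  differ: a positive root-edge length increases U^A between samples of
  unequal load. Published implementations do not document their root
  handling; users comparing outputs should check this convention first.
- **Empty branches in GU.** Branches with xᵢᵃ + xᵢᵇ = 0 are excluded from
  both sums (the difference ratio is undefined there, and 0^α at α = 0 is
  not defined as 1). This matches the exclusion behavior of the reference
  generalized-UniFrac construction and is exactly what makes pruning
  unobserved taxa a no-op (tested to 1e−12).
- **Both profiles all-zero** → an error, not 0 or NaN. α outside [0, 1],
  mode mismatches, and missing loads are errors raised before any
  computation.
- **[0, 1] bound.** Metric values are clipped into [0, 1] with 1e−12
  slack allowed for floating-point accumulation; a larger excursion is a
  bug and raises.

### A qualification on U^A ≤ BC^A under equal branch lengths

When all branch lengths are equal **and all leaves are equidistant from
the root**, U^A ≤ BC^A always: each of the D tree levels then partitions
the leaf set, so the numerator is at most D·b·Σ|δ_leaf| by the triangle
inequality while the denominator is exactly D·b·(N_a + N_b). The balance
condition is necessary, not cosmetic: on the unbalanced equal-length tree
((A:1,B:1):1,C:1) with a = (5, 0, 100) and b = (0, 1, 100),
U^A = 10/212 > BC^A = 6/206. The property suite therefore exercises the
bound on 1000 random *leveled* equal-length trees (the setting in which
the claim is commonly made), and a unit test pins the unbalanced
counterexample.

## Rarefaction workflow

`rarefied_distance` subsamples every sample to equal depth **without
replacement** (multivariate hypergeometric — "subsample" semantics; users
comparing against multinomial implementations should expect small
differences at low depth), divides by the depth (never rounding),
multiplies by each sample's load when the metric is absolute, computes
the matrix, and averages the matrices over iterations. Distances are
averaged, never tables: the estimator is the Monte-Carlo mean of the
per-iteration distance, and the ordering matters.

Defaults: depth = the minimum read total among retained samples;
iterations = 100; samples under `min_depth` are discarded with a logged
warning before the depth is fixed. Iteration *k* draws from
`SeedSequence(master_seed, spawn_key=(k,))`, so any single iteration is
reproducible in isolation.

## Statistics

- **Mantel**: Pearson correlation of strictly-upper-triangle vectors,
  matrices matched by label; two-sided permutation null (simultaneous
  row/column permutation of the second matrix). Monte-Carlo p-values use
  the add-one convention (never exactly 0); `exhaustive=True` enumerates
  all n! relabelings for small n.
- **PERMANOVA** (one-way): SS_total = Σ_{i<j} d²ᵢⱼ/n, SS_within pooled per
  group, pseudo-F = (SS_between/(g−1))/(SS_within/(n−g)),
  R² = SS_between/SS_total. Same permutation conventions as Mantel. The
  test suite checks the SS decomposition identity, exhaustive brute-force
  agreement at n = 6, agreement with skbio, and type-I calibration at
  nominal 0.05 over 500 exchangeable matrices.
- **Load-difference matrix**: raw |N_a − N_b| by default, with an
  optional log10 transform (off by default — the minimal reading of
  "pairwise differences in absolute abundance").
- **Error sensitivity**: each sample's load is perturbed to N·(1+u) with
  u ~ Uniform(−e, +e) per iteration — the minimal reading of "vary by a
  given percentage in either direction"; a truncated-normal alternative
  is a config knob. Reported per error level: mean and max |Δ| over
  off-diagonal entries, averaged over iterations, plus the SD across
  iterations. e ≥ 100% is rejected (loads must stay positive). Expected
  behavior, asserted on synthetic fixtures: zero error ⇒ zero deviation;
  deviation monotone in e; GU^A at α = 0.2 less sensitive than at α = 1
  when loads span ≥ 10-fold.

## Synthetic data

`grid_communities` enumerates every combination of abundance levels
(default 1/10/100 over four taxa: 81 communities, 3240 pairs) in
deterministic lexicographic order; abundances are already absolute, so
per-sample loads are the row totals.

`default_grid_tree` is a **synthetic stand-in**: topology
((ASV_1,ASV_2),(ASV_3,ASV_4)) with unit branch lengths and a zero-length
root edge. The original demonstration tree's branch lengths were never
published in reproducible form, and inventing them as ground truth would
be worse than labeling the placeholder honestly. Cross-metric
correlations on the grid depend on those lengths; on the stand-in the
*ordering* r(U^A,BC^A) > r(U^A,U^R) > r(U^A,BC^R) holds (0.899 > 0.564 >
0.495, printed by `scripts/acceptance.py`), and users holding the
original tree can pass it to `compare_metrics` to reproduce published
values.

`random_fixture` draws a random binary topology (sequential joins),
exponential branch lengths (mean 0.1 substitutions/site — typical 16S
pendant-edge scale), Dirichlet compositions (concentration 1 by default),
lognormal read totals (mean 30 000 reads, a routine MiSeq per-sample
yield), and loads **log-uniform** over a requested log10 range
(default 5.6–12.3, i.e. 4×10⁵ cells/mL to 2×10¹² 16S copies/g, the
extremes reported across published quantitative datasets). Log-uniform
was chosen over lognormal so the stated range is actually covered rather
than merely bracketed. Everything is driven by one integer seed.

What the generator does **not** emulate: taxon co-occurrence structure,
phylogenetic signal in abundances (composition is independent of the
tree), overdispersion beyond multinomial sampling, contamination, or
copy-number variation. A green test on these fixtures establishes
algebraic and statistical correctness of the machinery, not ecological
realism of any particular dataset.

## Known limitations

- No variance-adjusted or information-theoretic UniFrac variants; no
  ordination (PCoA/NMDS) — use skbio/scikit-learn on the exported
  matrices.
- PERMANOVA is one-way only.
- 16S copy-number normalization is out of scope; the pipeline accepts
  pre-normalized tables.
- The generalized-family all-pairs builder loops over pairs in Python
  (vectorized over branches); for very large sample counts at many α
  values this is the slow path.
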