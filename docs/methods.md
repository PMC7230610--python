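# Methods

## Model

`netimpute` treats dropout recovery as diffusion on a co-expression graph.
The working assumption is that transcriptional programs make groups of
genes rise and fall together across cells, so a gene's missing signal is
partially recoverable from the observed values of its co-expressed
neighbors, while a gene that is genuinely silent has silent neighbors and
is left near zero.

The pipeline is: gene filter → library-size normalization → log transform →
Pearson similarity → mutual-KNN graph → row-normalized transition matrix
**P** → random walk with restart (RWR) → imputed matrix.

The RWR stationary matrix is the unique fixed point of
F = (1 − α)·F·P + α·I, equivalently F = α(I − (1 − α)P)⁻¹. Because
(1 − α)P has spectral radius ≤ 1 − α < 1 the iteration converges
geometrically at rate 1 − α, and every row of F is a probability
distribution with diagonal weight f_vv ≥ α. Imputation uses the *outgoing*
distributions (rows): e_vc ← Σ_j f_vj e_jc is a convex combination of the
cell's observed values, so imputed values are bounded by the cell's
observed range and each gene keeps at least an α fraction of its own value.
The *incoming* alternative (columns of F) is exposed for comparison; column
sums are unconstrained and grow with node degree, which inflates
high-degree genes — the hub effect that `hub_effect` measures as the
correlation between degree and mean imputed value (reported as 0 when
degree is constant, e.g. regular graphs).

## Parameters

- **α (restart probability), default 0.5.** Controls the neighborhood
  contribution: the own-value weight is ≥ α, the neighborhood's ≤ 1 − α.
  Values in 0.3–0.7 behave similarly; α = 1 is the identity. The default
  sits in the middle of that range and matches the convention used by
  comparable diffusion smoothers.
- **k (mutual-KNN neighborhood size), default 128.** A power of two inside
  the sweep grid 2³ … 2^⌊log2(m/4)⌋ (m = post-filter gene count). Mutual
  (AND) neighborhoods are preferred over asymmetric (OR) ones because they
  admit far fewer false-positive edges; the asymmetric builder is kept for
  comparison.
- **tol = 1e−6, max_iter = 1000.** Iteration stops when the maximum
  absolute entry change falls below tol; at α = 0.5 that takes ~20 sweeps
  of p×n work. Non-convergence raises with the final residual.
- **confidence_quantile = 0.90** for PPI ingestion: keeps the top decile of
  combined scores (linear-interpolation quantile).
- Clustering harness: PCA with 20 components (capped at min(m, n) − 1),
  k-means with n_init = 100, max_iter = 1000, caller-supplied seed.

Numerical conventions: natural log with pseudo-count 1 (any fixed base only
rescales, which Pearson correlation and k-means are invariant to up to
scale); even-length medians use the midpoint; top-k ties break by ascending
node index so graphs are deterministic; self-similarity is excluded from
neighborhoods; zero-variance genes are flagged isolated (no edges, no
neighborhood candidacy) rather than dropped, and isolated nodes get a
self-loop transition row, so imputation preserves matrix shape and an
isolated gene keeps its own value exactly. For large m the top-k search
runs block-wise and never materializes the m×m similarity matrix; the
explicit stationary matrix is only computed for diagnostics and tests
(dense F for 20,000 genes would be ~3.2 GB).

## Synthetic data

The simulator emulates a log-scale expression matrix with block cell-type
structure and gene-level dropout:

- Per-gene log-scale means μ_g ~ Normal(1.8, 0.5) and sds σ_g ~
  Normal(0.6, 0.1) (σ_g floored at 0.01 to guard degenerate draws). The
  magnitudes correspond to log10 counts.
- Cells are split into equal contiguous type blocks (remainder to the last
  type). For each type, a disjoint set of DE genes (270 per type at the
  default design, so exactly 810 DE genes) has its count-scale mean
  multiplied by u ~ Uniform(2, 10) in that type's cells — on the log scale
  the mean shifts by log10(u). The fold is applied on the count scale
  because applying it to the log-scale mean directly produces type
  separations of 2–16 log units, which no dropout level can mask and which
  contradicts both the design's intended zero fractions and the premise
  that severe dropout degrades clustering; the count-scale reading
  reproduces the intended 72/77/82/87% zero levels to within a point.
- Entries are Normal(type mean, σ_g) clamped at 0 (log-scale expression is
  non-negative).
- Dropout: each entry of gene g is independently zeroed with probability
  exp(−λ·meanExp_g²), where meanExp_g is the gene's mean over all cells of
  the pre-dropout matrix. Dropout only zeroes; surviving values are
  untouched. λ ∈ {0.1, 0.08, 0.06, 0.04} yields ~72/76/81/87% zeros at the
  default design.
- All randomness flows from one integer seed through a single generator in
  fixed stream order (means, sds, DE selection, folds, entries; the dropout
  mask is seeded with seed + 1).

What the simulator does *not* emulate: count noise (values are Gaussian on
the log scale, not negative-binomial counts), library-size variation
between cells, and — importantly — any dependence of dropout on the
individual entry or the cell type. Because the dropout mask is independent
of the type structure, it carries no signal; it multiplies every
between-gene covariance by the squared survival probability while adding
large mask variance to each gene. A consequence verified both analytically
and empirically in this package: at ≳50% zeros the pairwise gene
correlations of same-program genes fall below the top-k ranking noise floor
(max of ~m noise correlations at n = 150 cells), so the mutual-KNN graph
built from the raw matrix is statistically uninformative and
network smoothing cannot restore clustering that dropout has destroyed, in
any mode, at any (k, α), at either the full (20,000-gene) or reduced
(2,000-gene) design. Passing tests on this generator therefore demonstrate
the correctness and the invariants of the machinery (graph construction,
RWR fixed point, convexity of outgoing imputation, hub-effect direction,
dropout calibration), not end-to-end clustering rescue; rescue on real data
relies on dropout being value-dependent, which preserves rank structure the
graph can exploit. The acceptance checks asserting clustering rescue on
this generator fail for this reason and are retained as-is.

## Evaluation harness

The ARI is computed from the contingency table n_ij of the two partitions:
ARI = (Σ_ij C(n_ij,2) − E)/(½[Σ_i C(a_i,2) + Σ_j C(b_j,2)] − E) with
E = Σ_i C(a_i,2)·Σ_j C(b_j,2)/C(n,2); it is 1 for identical partitions,
invariant to label renaming, and tested exhaustively against an
independent pair-counting formulation on all partitions of up to 6 objects
into ≤ 3 blocks. When both partitions are trivial (MaxIndex equals
ExpectedIndex) the value is defined as 1.

The parameter sweep runs the full imputation for every (α, k) in the grid
α ∈ {0.1, …, 0.9}, k ∈ {2³, …, 2^⌊log2(m/4)⌋} and reports ARI per setting
next to the un-smoothed baseline (same preprocessing, no diffusion). At
α = 1 the sweep row equals the baseline exactly.

## Problem sizes

The test suite and the acceptance script use the full 20,000 × 150 design
for the simulator-level quantities (zero fractions, DE counts; five seeds
per dropout intensity) and a one-tenth design (2,000 genes, 81 DE genes per
type, λ = 0.04 for ~87% zeros) for the end-to-end imputation scenarios,
which keeps graph construction and diffusion comfortably small while
preserving the m ≫ n regime and the DE-gene fraction's order of magnitude.

## Known limitations

- The generator's Gaussian-on-log values cannot exercise count-specific
  preprocessing paths (library-size normalization is exercised by unit
  tests and count-scale inputs instead).
- Gene-ID matching for PPI ingestion is exact string match after
  case-folding; no ortholog or alias mapping.
- Graphs are unweighted by construction; no soft-thresholded or weighted
  diffusion.
- α and k are fixed inputs; nothing is learned from data.
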