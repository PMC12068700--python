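# Methods

## Model and procedure

The workflow tests, column by column of a protein multiple sequence
alignment, whether a position's evolutionary divergence predicts species
lifespan once shared ancestry is accounted for.

**RES scoring.** Each column j of an n × L alignment over
Σ = {20 amino acids, gap} yields a probability vector with additive
pseudocount κ: p(a, j) = (c(a, j) + κ)/(n + κ|Σ|). The background is the
same estimator pooled over all columns: q(a) = (C(a) + κ)/(nL + κ|Σ|).
The score of sequence i at column j is log p(aᵢⱼ, j) − log q(aᵢⱼ) in the
configured base. Because the background receives the same pseudocount, all
probabilities are strictly positive (scores are finite everywhere) and a
single-column alignment scores exactly zero — column counts coincide with
global counts. The gap is a first-class 21st symbol: a lineage-specific
deletion is evolutionary change and is scored like a substitution. Upstream
aligner settings (e.g. MUSCLE gap penalties) shape the alignment itself and
are carried only as provenance metadata; they enter no arithmetic here.

**Phylogenetic GLS.** Under Brownian motion, a trait evolving on a rooted
tree has covariance σ²V with V(i, j) the branch length shared between the
root and the MRCA of taxa i and j. Each column is fit as
lifespan = β₀ + β₁·RES + ε, ε ~ N(0, σ²V): with V = LLᵀ (Cholesky), the
whitened regression of L⁻¹y on L⁻¹[1, x] is an ordinary least squares whose
slope, SE, and two-sided t test on n − 2 df are the GLS estimates. No
explicit matrix inverse is formed anywhere. Columns whose RES vector is
constant across species carry no information and are reported with status
`constant_predictor`, never as hits. The screen's default covariance is pure
Brownian motion (λ = 1); the estimated λ̂ is reported descriptively, and a
`--lambda-policy estimated` switch substitutes it in the screen.

**Pagel's λ.** λ multiplies V's off-diagonals; λ = 0 removes phylogenetic
covariance, λ = 1 is pure BM. For a trait y the likelihood
y ~ N(μ1, σ²V(λ)) is profiled: μ̂ and σ̂² have closed forms given λ (σ̂² is
the ML version, RSS/n), leaving a 1-D problem on [0, 1]. The optimizer
evaluates an 11-point grid, then runs bounded scalar minimization (tolerance
1e-6) inside the bracketing grid interval; the final λ̂ is whichever of the
refined point and the best grid point is more likely, and the λ = 0
likelihood is kept as a floor. This guards against the boundary
multimodality the profile can show. The fit is full ML, not REML, so logLik
and AIC are on the same convention as the joint model below.

**Screening and mapping.** Columns with raw p < α (default 0.05) form the
RPLAR set — uncorrected by design, mirroring how such screens are usually
reported; a Benjamini–Hochberg option (`--correction bh`) is available. The
joint model is one GLS of lifespan on all RPLAR columns simultaneously,
with k = (number of columns) + 2 parameters (coefficients' count includes
the intercept; σ² adds one) and AIC = 2k − 2·logLik; this matches
`nlme::gls(..., method="ML")` conventions exactly (verified against frozen
values from that implementation in the test suite). Reference mapping
counts non-gap reference positions up to each column: 1-based residue
numbers, gap columns unmapped.

**Lifespan normalization.** L_avg = αL_max + β is fit by OLS on species
with both values; species with only L_max get L_avg_est = αL_max + β, and
all species get L_norm = L_avg_est + (L_max − L_avg_est)·α. β deliberately
does not reappear in the correction term; the formula is implemented as
printed, and L_max = L_avg_est is a fixed point. When L_max is missing
(observed-average species), the correction term is undefined and L_norm is
set to L_avg_est. Normalization is a flag, intended for heterogeneous
multi-order datasets; order-specific analyses use raw averages.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| pseudocount κ | 1.0 | counts | Laplace smoothing; smallest standard choice that keeps all 21 symbols observable |
| log base | 2 | bits | conventional for log-odds scores; natural log available |
| α_screen | 0.05 | probability | standard screening threshold; raw p by default |
| λ policy | brownian (λ=1) | — | screen under the pure BM covariance; λ̂ reported alongside |
| t df | n − 2 per site | — | two GLS coefficients estimated |

## Tree construction

When no tree is given: p-distance (mismatch fraction over pairwise non-gap
columns), Saitou–Nei neighbor joining with first-minimum tie-breaking
(deterministic), negative branch-length estimates clamped to zero, midpoint
rooting. NJ recovers additive distances exactly — the test suite checks all
11,463 labeled unrooted binary topologies on up to 8 leaves against a
path-length oracle, and cross-checks against scikit-bio's implementation.
Distance-based NJ is a deliberate choice over ML tree inference: it is
deterministic, fast, auditable, and the screen accepts any user-supplied
newick tree for workflows that need a better phylogeny.

## Synthetic data: what it emulates and what it does not

`SimConfig` defaults define the standard evaluation conditions: a 60-taxon
Yule tree (birth rate 1), a lifespan-like trait from N(30·1, σ²V(λ)) with
σ² = 1 and λ = 1, and a 120-column alignment with 6 trait-linked columns at
effect 0.95 against a neutral background with substitution rate 0.5 per
unit branch length. The Yule simulator waits Exp(kb) while k lineages
exist, including one final period after the n-th birth, giving expected
depth Σₖ₌₂ⁿ 1/(kb) (checked in tests). Linked columns use a
threshold-on-trait mechanism — residue K above the median lifespan, E
below, flipped with probability 1 − effect — chosen over a co-evolving
continuous model because it yields unambiguous ground-truth labels for
sensitivity and false-positive accounting. The rates were chosen once as
moderate-divergence values typical of a protein family spanning one
vertebrate order.

What this does not emulate: indels (no gaps are simulated by default),
empirical amino-acid exchangeabilities (the neutral process is symmetric
over 20 states), rate variation across sites, and alignment error. Passing
tests therefore demonstrate the statistics are correct under the model's
own assumptions, not that real alignments meet those assumptions.

## Numerical choices and degenerate inputs

- All GLS solves use Cholesky whitening; a non-positive-definite V raises an
  error carrying the condition number.
- An exactly-fit regression (e.g. constant response) reports t = 0, p = 1
  rather than 0/0.
- NJ Q-matrix ties break at the first minimum in row-major order; heatmap
  lifespan ties break by species id — both make outputs deterministic.
- Identical sequences produce zero p-distances, zero-length NJ tips, and a
  singular BM covariance; the pipeline aborts with a stage-named error
  rather than silently regularizing. Deduplicate or supply a tree with
  positive tip branches in that case.
- Non-canonical residues (B, Z, X, U, O, J, *) map to the gap symbol with a
  warning so the alphabet stays fixed at 21 symbols.
- Trees whose newick root has more than two children are treated as
  unrooted and rejected; the BM covariance needs an explicit root.

## Known limitations

- Per-site tests are marginal: columns are screened independently, and the
  joint model is fit only on the already-selected set (no model selection
  over subsets).
- The uncorrected p < 0.05 screen controls no family-wise error; with ~100
  neutral columns, ~5 false positives are expected (the worked example in
  the README shows exactly this).
- λ estimation at the λ = 0 boundary is reported with a boundary flag;
  standard errors for λ̂ are not computed.
- The trait is modeled untransformed in years; strongly right-skewed
  lifespan distributions may warrant a log transform the defaults do not
  apply.
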