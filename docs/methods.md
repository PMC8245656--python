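# Methods

This note records the models, conventions and design choices behind
`algalmeta`, in the order the pipeline applies them.

## Data model and preprocessing

Community tables are oriented rows = samples/sites, columns = taxa; counts
are cell densities (cells per liter) and must be finite and non-negative.
Binarization uses a strict threshold (`presence = count > t`, default
`t = 0`): no detection floor is imposed because the statistics operate on
incidence and the abundance overlay is handled separately.  Species may be
merged to genus level by summing columns (genus order = first appearance);
unmapped taxa pass through as their own genus with a warning.  Samples with
missing environmental values are dropped (never imputed), together with
their paired community rows.  All-zero rows and columns are removed
iteratively before every ordination — including inside every null-model
replicate — because reciprocal averaging is undefined on zero margins.

## Reciprocal averaging

The first non-trivial correspondence axis is computed by SVD of
`S = (P − r cᵀ)/√(r cᵀ)` where `P` is the relative-frequency matrix and
`r`, `c` its row/column masses.  Site and taxon scores are standard
coordinates (weighted mean 0, weighted variance 1); `eigenvalue_1 = σ₁²`,
clamped to 1 (disconnected block structures attain the bound exactly).  The
classical power iteration (alternately averaging site scores from taxon
scores and back, projecting out the trivial axis) is implemented as an
independent cross-check and agrees to 1e-8.  Conventions, chosen purely
for reproducibility because every downstream statistic is invariant to
them: the axis is oriented so the first input-order site scores no higher
than the last, and ties in scores sort by original index (stable).  Only
axis 1 is extracted; the EMS framework does not use higher axes.

## EMS statistics

**Coherence.** Embedded absences are counted over both columns and rows of
the ordered matrix by default (`mode="columns_only"` is available); both
modes share brute-force oracle tests.  The reference distribution is the
fixed–fixed null: binary matrices with exactly the observed margins, each
re-ordinated from scratch before the statistic is evaluated.

**The swap sampler.** Nulls are drawn by a 2×2 checkerboard swap chain
with two properties worth stating precisely.  (1) *Lazy steps*: a valid
checkerboard is swapped with probability ½; without laziness, small classes
cycle periodically (the 2-state class of a 2×2 identity returns to its
start after every even number of swaps).  (2) *Proposal-clock thinning*:
burn-in and thinning count uniformly random proposals (defaults 20× and
10× the cell count), **not** accepted swaps.  Snapshots taken every k-th
accepted swap oversample states in proportion to their number of swappable
checkerboards — the recorded mass is the uniform occupancy re-weighted by
the state-dependent event rate.  On the enumerable 4×4 class with all
margins 2 (90 matrices), event-clock sampling fails a chi-square uniformity
test catastrophically while the proposal clock passes it.  Margins that
admit no checkerboard at all (e.g. a perfect staircase, which is the unique
member of its class) produce a warning and nulls identical to the input.

**Turnover.** Replacements are counted on the range-filled ordered matrix
(each taxon's embedded absences set to 1) as the sum over taxon pairs of
(sites holding only the first) × (sites holding only the second).  The
default null is the classical *range-shift* null: each taxon keeps its
range length, positions are uniform along the axis.  A fixed–fixed
turnover null is available (`turnover_null="fixed_fixed"`) but is not the
default for a structural reason: a perfectly nested (staircase) matrix
contains no swappable checkerboard, so it is the *only* matrix with its
margins — the fixed–fixed turnover null collapses to zero variance
precisely on the nested structures the statistic must detect.  The huge
relative spread of turnover null SDs compared with coherence null SDs in
published EMS tables (coefficients of variation ≈ 30% vs ≈ 2%) is
consistent with range-shift behaviour.

**Boundary clumping.** Each occupied taxon contributes one range start and
one range end (a single-site range contributes both at that site).  With
per-site boundary counts `x` over `n` sites and `X = Σx`:
`I = n·Σx(x−1)/(X(X−1))`, `χ² = I(X−1)+n−X`, `df = n−1`; the stored `p` is
the upper tail.  Classification treats the test as two-sided at α/2 per
tail: clumped requires `I > 1` with a small upper-tail p, overdispersed
`I < 1` with a small lower-tail p.  The reported `df` counts the sites
actually present in the ordered matrix after degenerate removal.

**z and p conventions.** `z = (sim mean − observed)/sim SD`; this is the
convention under which published per-lake component statistics reproduce
their printed z values (e.g. (1382−1004)/31 = 12.2), whereas the opposite
sign would not.  Both a normal-approximation p (2·Φ(−|z|)) and an empirical
permutation p, `(1 + #{|sims − mean| ≥ |obs − mean|})/(n+1)`, are reported;
classification uses the normal p at α = 0.05, matching the ±1.96
thresholds of the framework.  Null sims with zero variance raise an error
with a margin diagnostic rather than emitting an unusable z.

**Classification.** The decision tree is expressed through sign-free
comparisons: (1) coherence non-significant → Random; significant with
observed above the null mean → Checkerboard; below → continue.  (2)
turnover significant with observed below the null mean → nested family;
above → gradient family; non-significant → family from the sign of the
deviation (a deviation of exactly zero falls to the gradient side) with the
*quasi* flag.  (3) Morisita's I with a significant two-sided χ²: `I > 1` →
Clementsian / nested-clumped, `I < 1` → evenly spaced /
nested-hyperdispersed, otherwise Gleasonian / nested-stochastic.  The
function is total: every consistent component combination yields a label.

## Canonical correspondence analysis

The chi-square residual matrix is regressed, row-mass weighted, onto the
standardized environment matrix; the dominant axis of the fitted values
gives linear-combination (LC) site scores, with weighted-average (WA)
scores derived from the taxon vector.  The constrained eigenvalue is never
above the unconstrained CA eigenvalue.  Variables are screened for zero
variance (relative tolerance 1e-12) and collinearity (Gram condition
number 1e8, with variance-inflation diagnostics in the error).

Per-variable **loadings are weighted correlations with the WA (community-
derived) axis-1 scores**, not with the LC scores: the LC axis lies in the
span of the environment matrix, so even pure-noise variables correlate
strongly with it, which would make the |loading| > 0.5 importance rule
meaningless.  Against WA scores, noise variables load near zero and
genuine drivers retain loadings comparable to published per-variable
values.  Axis sign is set so the largest-|loading| variable loads
positively.  Community input is untransformed abundance by default with a
Hellinger option.  The EMS-rank-versus-axis correlation uses WA scores by
default (LC scores carry the environment measurement noise and correlate
systematically lower with community-derived ranks) and a Shapiro–Wilk gate
(both inputs normal → Pearson, otherwise Spearman); ranks are almost never
normal, so Spearman is the practical default.

## Community statistics

Richness is the incidence row sum.  Group comparisons gate on per-group
Shapiro–Wilk normality at α: ANOVA if every group passes, Kruskal–Wallis
otherwise; pairwise contrasts are rank-based Dunn tests (pooled ranks, tie
correction) with Holm adjustment, displayed as compact letters
(insert-and-absorb; pairwise claims are suppressed when the omnibus is not
significant).  All-pairs contrasts are used because the study design has
no control group; a many-to-one variant would be a thin wrapper over the
same machinery.  Beta diversity clusters per-group *pooled* incidence
vectors (genus present in ≥ 1 sample of the group) by Euclidean distance
and complete linkage, exported as Newick.  Indicator genera come from a
random-forest classifier (131 trees, bootstrap, impurity importance); the
top ceil(10% × genera) are flagged and validation uses out-of-bag
predictions (confusion matrix + accuracy).  Permutation importance is
available for reporting but never drives selection.

## Synthetic generators

All generators place sites on an equally spaced latent gradient in [0, 1],
build taxon ranges, flip each cell with probability ε = 0.02 (observation
noise), then shuffle the site order so structure is only recoverable by
ordination.  Sites left uncovered (and taxa left empty) are dropped, as a
single degenerate-removal pass would; ids keep the original gradient
indices.

- *Clementsian*: k = 3 compartments with shared boundaries at equal
  gradient quantiles, taxa assigned round-robin.
- *Gleasonian*: widths ~ N(0.35, 0.10) clipped to [0.08, 0.96], centers
  uniform **conditional on the range fitting inside the gradient** —
  truncating ranges at the gradient ends piles boundaries onto the
  terminal sites and spuriously mimics Clementsian clumping.
- *Evenly spaced*: constant width, centers equally spaced within the
  fitting interval, so boundaries are maximally separated.
- *Nested*: ranges share the gradient-start anchor with widths from 1.0
  down to 0.15, and cells inside a range drop out with probability 0.2
  (anchor site always kept).  A perfect staircase would be the unique
  matrix of its margin class — degenerate under the fixed–fixed coherence
  null — and real nested communities are imperfectly filled anyway.
- *Checkerboard*: the pattern is defined operationally by its excess of
  embedded absences over the fixed-margin null, so the generator plants
  the anti-coherent extreme of a random Bernoulli(0.3) margin class by
  Metropolis-annealed margin-preserving swaps maximizing the ordinated
  embedded-absence count (exact-SVD scoring; near the optimum the top
  singular values are nearly degenerate, which approximate scores cannot
  track).  Intuitive mutual-exclusion constructions fail: complementary or
  block-paired taxa can always be laid out as prefix/suffix site intervals
  and come out *coherent*.  Cell-flip noise is folded into the Bernoulli
  start rather than applied post hoc, which would walk the matrix back
  toward its class typical set and un-plant the structure.
- *Random*: iid Bernoulli(0.3).

Environment tables add `k_linked` affine transforms of the gradient
(alternating slope sign) with Gaussian noise of SD 0.2 — chosen so linked
variables correlate with the gradient at r ≈ 0.8, the strength typical of
published water-quality drivers — plus iid standard-normal noise
variables, named after the standard nine-variable water-quality panel
where counts permit.  Abundances are log-normal (σ = 0.6) with log-mean
decaying linearly in distance from the range center (peak ≈ 10³ cells/L),
zero exactly where absent.

The **study-shape scenario** reproduces the monitoring design: 6 lakes ×
(9 months × 8 years) samples × 55 genera, lakes placed along the river
gradient with N(0, 0.05) per-sample jitter, three taxon compartments with
boundaries at the region breaks (Down: PD | Mid: CP, UM, CC | Up: SY, HC),
conductivity/COD/BOD linked to the gradient and the remaining six
variables pure noise.  What it does *not* emulate: within-lake assembly
(per-lake subsets carry no internal gradient beyond noise, so individual
lakes classify Random, unlike the real system where seasonal water-quality
variation structures each lake), temporal autocorrelation between monthly
samples, and dispersal limitation.  Recovery tests on this scenario
therefore validate the pooled regional analysis, not per-lake inference.

## Pipeline

The config-driven pipeline runs per-group and pooled EMS (Table-1-style
rows plus per-analysis JSON archives holding the full null-sim vectors, so
every reported number is recomputable), pooled and per-region CCA loadings,
richness letters, the beta-diversity dendrogram, the indicator report, and
optional per-season EMS (group × month-set subsets; subsets under 10
samples or 6 occupied taxa are skipped with a warning).  Subset seeds are
expanded deterministically from the base seed by a CRC-32 hash of the
subset name, so no two analyses share a null stream and any one can be
recomputed in isolation.  Degenerate subsets (margins freezing the null
class) yield an `Indeterminate` row rather than aborting the run.  Reports
are byte-reproducible given the seed; timings are written to a separate
log file for that reason.  Default problem sizes used by the test suite
and the acceptance script — 100-simulation nulls for recovery experiments
and the study-shape integration run, 1000 for the analysis drivers —
reflect the precision each purpose needs: recovery assertions depend on
z-thresholds at |z| ≈ 2, for which 100 sims give ample null-moment
precision, while reported tables use the conventional 1000.

## Known limitations

- The checkerboard generator is an optimizer, not a mechanistic model; it
  demonstrates detectability of anti-coherence, not the ecology of
  competitive exclusion.
- Boundary-clumping power against evenly spaced alternatives is low at
  moderate sizes (40 × 25); evenly spaced generators are reliably
  distinguished from Clementsian but often fall to Gleasonian.
- Reported `df` for boundary clumping counts retained sites; published
  tables from monitoring data may report fewer when samples were dropped
  upstream, and such differences are expected.
- CCA significance is not tested by permutation (out of scope); loadings
  are descriptive with a fixed importance threshold.
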