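# Methods

## Model and test

The object of inference is the change in the correlation of a molecule
pair's expression between two conditions, not the change in expression
level. For a pair (X, Y) with Pearson correlation `r_N` over the K samples
of the reference group and `r_T` over the L samples of the contrast group,
the Fisher transform `z(r) = arctanh(r)` of a bivariate-normal sample
correlation is asymptotically normal with mean `z(ρ)` and variance
`1/(M−3)` at sample size M; the test statistic is

    Z = (z(r_N) − z(r_T)) / sqrt(1/(K−3) + 1/(L−3)),

standard normal under ρ(N) = ρ(T). For Spearman, correlations are Pearson
correlations of within-group midranks and the asymptotic variance
`(1 + ρ²/2)/(M−3)` depends on the unknown ρ; we bound it by `1.5/(M−3)`
and bake the bound into the reported statistic, so the normal tail of the
reported Z upper-bounds the plug-in p-value (a uniformly conservative
test). The rescaling lives in the statistic, not only the p-value, so the
analytic and permutation routes compare the same quantity.

Assumptions worth stating: approximate bivariate normality within each
group for the analytic route (the permutation route drops it, needing only
exchangeability of samples under the null); independent samples; group
sizes above 3 (hard error otherwise, since every variance divides by
M − 3). P-values are two-sided by default — both gained and lost
correlations are of interest — with a one-sided option; the sidedness is a
package design choice, documented here because a one-sided convention also
appears in the literature. BH adjustment is applied across exactly the
pairs of one run, never pooled across runs or modes.

## Permutation p-values

Group labels are shuffled preserving K and L; every relabeling is applied
to the whole matrix (one shared relabeling stream per run), Z is
recomputed for all pairs, and

    p_i = (1 + #{b : |z_i^(b)| ≥ |z_i^(0)|}) / (B + 1).

Design choices: add-one smoothing keeps p > 0 so BH behaves (a
`raw_proportion` flag restores the literal fraction); ties count as
exceedances (conservative); the default budget is `B = ceil(R/α)` for R
simultaneous hypotheses — fewer permutations cannot resolve a BH-adjusted
rejection at level α. The relabeling stream is split into fixed blocks of
250 whose RNG states are spawned from the seed, so results are independent
of how work is distributed and bit-reproducible given the seed.

The pooled comparator compares each observed statistic against the
permuted statistics of *all* R pairs, `p_i = (1 + #{(j,b)}) / (R·B + 1)`.
Pooling is exchangeable only when all pairs share one null distribution;
with heterogeneous changes the strongly-changed pairs dominate the pooled
null and inflate the p-values of weakly-changed pairs. The paired-blocks
experiment (below) demonstrates this; the pooled scheme is provided only
for that comparison.

A known gap, quantified in the test suite: at K = L = 100 the per-pair
permutation p-value differs from the analytic one by ~0.03 (sd) on null
pairs even with large B — the conditional permutation null carries
data-dependent higher-moment terms the asymptotic normal lacks. The
difference is unbiased and shrinks with sample size.

## Aggregation

Per source G: `n_G` network interactions, `s_G` of them with BH-adjusted
pair p-values below α. Under uniform allocation of the S significant
changes over the N network interactions, `s_G ~ Hypergeometric(N, S, n_G)`;
we report the upper tail including the observed value, P(X ≥ s_G).
Aggregation scores are the mean, median or a quantile (linear interpolation
between order statistics) of G's per-target Z statistics, tested against
zero with the same permutation stream as the pair-level test — one seed,
one sequence of relabelings — which makes a single-target source's score
p-value reproduce its pair p-value exactly. Hypergeometric and score
p-values are each BH-adjusted across sources, separately per statistic.

## Synthetic designs

Both generators draw zero-mean multivariate normals with unit variances
and return (matrix, groups, network); they are seeded and deterministic.

**Hub design** (m genes, n per group, k changed correlations of magnitude
ρ). The hub and the k changed genes form an equicorrelated block with
off-diagonal ρ; the contrast condition flips the sign of the hub's row and
column (C_T = D·C_N·D, D = diag(−1, 1, …, 1)), moving each hub–gene
correlation from +ρ to −ρ while leaving all other entries unchanged. A hub
star with mutually uncorrelated leaves is not positive definite unless
k·ρ² < 1 — infeasible at the reference design point (k = 100, ρ = 0.5) —
whereas the sign-flip construction is PD for any ρ ∈ (0, 1) and any k and
realizes the same pairwise change. The block Cholesky factor is computed
explicitly, so an infeasible covariance fails before sampling. k = 0 is an
exact null. The network tests the hub against all other m − 1 genes.

**Paired-blocks design** (2m genes in m independent pairs; K and L per
group). The reference condition has identity covariance; the contrast is
block-diagonal with k strong 2×2 blocks (off-diagonal 1, clamped to
1 − 1e−6 to keep the covariance PD) and m − k weak blocks (off-diagonal
0.5). The network is the m within-block pairs; the last pair is always
weak and is the pair the two permutation schemes are compared on.

What these generators deliberately omit relative to real expression data:
library-size and mean–variance structure, heavy tails, batch effects, and
correlated "null" background. Passing tests therefore establish the
statistical behavior of the method under its own model — calibration,
power ordering, conservatism of pooling — not robustness to those
artifacts; the Spearman route and the permutation p-values are the tools
intended to absorb them in practice.

**Experiment drivers.** The power study sweeps (n, k, ρ) over the hub
design with 10 replicates per cell by default (m = 1000, B = 1000 at the
reference point; examples and tests run reduced grids with m = 40–200 and
5–10 replicates to keep a desk-scale footprint). The scheme comparison
fixes K = 100 and sweeps L with 20 replicates per cell, reporting both
schemes' mean p-value on the weak pair and the count of replicates where
pooled exceeds per-pair. At the reference design (m = 10, k = 9) the
contrast is real but numerically tight: the population mean per-pair
p-value crosses 0.05 near L = 40 and the pooled one near L = 60, so
20-replicate estimates of "rejects at 0.05" near those L carry visible
Monte Carlo error.

## isomiR application layer

5′-isomiRs are written `name|shift` (signed 5′→3′ offset; `|0` canonical);
parsing and formatting are exact inverses. RPM is count/library-size×1e6
with library sizes defaulting to column totals. The highly-expressed
filter ranks isomiRs by read share pooled across all samples (a per-sample
variant is a reasonable alternative; pooled is the documented choice) and
keeps the minimal prefix reaching the target fraction (default 0.95), ties
broken by identifier. AGO2 weighting multiplies an isomiR's RPM by the
sample's Argonaute-2 expression with proportionality constant 1 — within a
fixed isomiR any constant cancels from correlations — followed by
log2(x + 1) (pseudocount configurable). Anticorrelation networks keep
pairs with r strictly below −0.3 in the chosen condition; a target is
"lost" when r_reference < −0.3 ≤ r_contrast and the correlation change is
itself significant (BH-adjusted p < α), "gained" in the mirror case,
"unchanged" otherwise — the three classes partition the input. Boundary
values sit on the "not below threshold" side by decision.

## Numerical conventions

- Correlations with |r| ≥ 1 − 1e−12 are clamped before `arctanh` (with a
  warning in user-facing paths), so collinear inputs cannot produce
  infinities; permutation inner loops clamp silently.
- Zero within-group variance is an error naming the molecule and group —
  never a silent r = 0.
- Spearman ties take midranks.
- BH is the standard step-up with clipping at 1, returned in input order.
- All stochastic components run off `numpy.random.Generator` seeded from a
  single integer; replicate seeds are spawned deterministically.

## Limitations

The analytic Spearman p-value is a bound, not an estimate — it sacrifices
power for validity (up to ~22% inflation of the null sd at |ρ| = 1). The
hypergeometric aggregation inherits the pair-level α and is blind to
coherent sub-threshold changes, which is exactly the niche of the score
tests. Exhaustive mode scales as O(n²) pairs and the permutation route
multiplies that by B; the implementation is vectorized across pairs but
makes no further algorithmic shortcuts. The package does not choose the
interaction network, normalize raw counts beyond RPM, or model mean-level
differential expression.
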