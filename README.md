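# dconet

Differential co-expression network analysis between two conditions.

Most expression studies compare *levels* between groups; `dconet` compares
*correlations*. Given a molecules × samples expression table, a partition of
the samples into two groups (say "Normal" with K samples and "Tumor" with
L), and a list of directed (source, target) interaction pairs, it tests
every pair for a change in co-expression between the groups. Typical users
are systems-biology and regulatory-genomics analysts tracking rewiring of
regulator–target networks (e.g. miRNA-isoform → mRNA anticorrelation
networks) between conditions.

## The statistic

For a pair with correlation `r_N` in one group and `r_T` in the other
(Pearson or Spearman), the Fisher transform `z(r) = arctanh(r)` is
asymptotically normal with a variance that is free of the underlying
correlation in the Pearson case:

```
σ²_p(M) = 1/(M−3),      σ²_s(M) = (1 + ρ²_s/2)/(M−3) ≤ 1.5/(M−3)
```

so under the null hypothesis ρ(N) = ρ(T),

```
Z = (z(r_N) − z(r_T)) / sqrt(σ²(K) + σ²(L))   ~   N(0, 1).
```

For Spearman the variance depends on the unknown ρ, so the statistic is
rescaled with the worst-case bound `1.5/(M−3)`, making the reported
p-value a conservative upper bound. P-values are two-sided by default
(one-sided optional) and BH-adjusted across the tested pairs.

Beyond the analytic test, `dconet` provides:

- **per-pair permutation p-values** — group labels are shuffled (sizes
  preserved), every pair's Z is recomputed, and each observed |Z| is
  compared against that pair's own permuted values,
  `p = (1 + #exceedances)/(B + 1)`; the default `B = ceil(R/α)` for R
  simultaneously tested pairs. A pooled scheme (each observed statistic
  compared against *all* pairs' permuted values, as some other tools do) is
  included as a comparator — it is badly conservative when changes are
  heterogeneous across pairs.
- **source-level aggregation** — for a source G with `n_G` interactions of
  which `s_G` are individually significant, the hypergeometric upper tail
  `P(X ≥ s_G)`, `X ~ H(N, S, n_G)`, tests overrepresentation; and the
  mean/median/quantile of G's per-target Z statistics is tested against
  zero by the same label permutation.
- **synthetic validation designs** — seeded multivariate-normal generators
  for a hub-gene design (k correlations flipping `+ρ → −ρ`) and a
  paired-blocks design (strong 0 → 1 vs weak 0 → 0.5 changes), plus the
  experiment drivers that sweep sample size and change fraction.
- **isomiR application helpers** — `name|shift` 5′-isomiR nomenclature,
  RPM normalization, the 95% cumulative-expression filter, AGO2 weighting,
  r < −0.3 anticorrelation networks and lost/gained target classification.

## Worked example

```python
from dconet import (AggregationScenario, PermutationPlan,
                    generate_aggregation_dataset, run_aggregation)

scenario = AggregationScenario(m=200, n=30, k=20, rho=0.5, seed=2)
matrix, groups, network = generate_aggregation_dataset(scenario)
result = run_aggregation(matrix, groups, network, kind="pearson",
                         score_kinds=("mean",),
                         plan=PermutationPlan(n_permutations=1000, seed=2))
print(result[result.source == "gene1"].round(4).to_string(index=False))
```

prints

```
source  n_G  s_G  hypergeom_pvalue  hypergeom_adjusted score_kind  score_value  score_pvalue  score_adjusted
 gene1  199   22               1.0                 1.0       mean       0.3026         0.001           0.001
```

The hub gene has 199 tested interactions; only 22 survive pair-level BH
correction even though 20 correlations truly flipped from +0.5 to −0.5 —
but the mean of its 199 per-target Z statistics (0.30) is far outside the
permutation null (p = 0.001, the smallest value attainable with B = 1000).
That is the point of aggregation: a source whose many interactions each
change a little is flagged even when most individual pairs are not
significant. (With the single-source network shown here the hypergeometric
test is degenerate — `n_G = N` — and equals 1; see
`examples/aggregation_scores.py` for a multi-source network where it is
informative.)

The `examples/` directory holds one short script per capability
(pairwise testing, permutation schemes, aggregation, power study, isomiR
pipeline, CLI usage); each prints its numbers and says what they mean.

## Command line

```
dconet network.ztest config.yaml          # predefined interaction list
dconet exhaustive.zscore config.yaml      # all molecule pairs + score tests
```

Modes: `{network, exhaustive} × {ztest, hypergeom, zscore}`. The YAML config
names the input tables, output directory, correlation kind, α, permutation
budget (`auto` = ceil(R/α)), seed and workers; `--seed/--permutations/
--alpha/--workers` override it. Outputs are tab-separated tables, byte-identical
across reruns with the same config and seed.

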