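"""Per-pair versus pooled permutation p-values under heterogeneous changes.

Generates the paired-blocks design: 10 independent gene pairs, 9 changing
correlation strongly (0 -> ~1) and one weakly (0 -> 0.5), with 100 'Normal'
and 50 'Tumor' samples.  Both permutation schemes shuffle the same group
labels; they differ only in which permuted statistics each observed
statistic is compared against.
"""

from dconet import (
    PermScenario,
    PermutationPlan,
    generate_perm_dataset,
    permutation_method_comparison,
    perpair_permutation_pvalues,
    pooled_permutation_pvalues,
)

scenario = PermScenario(m=10, k=9, K=100, L=50, seed=5)
matrix, groups, network = generate_perm_dataset(scenario)
plan = PermutationPlan(n_permutations=1000, seed=5)

per_pair = perpair_permutation_pvalues(matrix, groups, network, plan=plan)
pooled = pooled_permutation_pvalues(matrix, groups, network, plan=plan)

print("pair           per-pair p   pooled p")
for (s, t), pp, po in zip(network.pairs, per_pair, pooled):
    print(f"{s}-{t:<10} {pp:10.4f} {po:10.4f}")

print(
    "\nEvery pair truly changes correlation; the last ('weak') pair changes "
    "only 0 -> 0.5 while the rest change 0 -> ~1.\n"
    "A single replicate is noisy, so average the weak pair's p-value over "
    "10 replicate datasets per scheme:"
)
table = permutation_method_comparison(
    L_values=(30, 50), ks=(9,), m=10, K=100, replicates=10,
    n_permutations=1000, seed=5,
)
print(table.round(4).to_string(index=False))
print(
    "\nPooling compares the weak pair's statistic against the permuted "
    "statistics of the 9 strongly-changed pairs as well, which inflates its "
    "mean p-value relative to the per-pair scheme — the per-pair scheme is "
    "the calibrated one when changes are heterogeneous."
)
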