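"""How sample size and effect strength drive the mean aggregation score.

Sweeps the hub design over per-group sample sizes n and correlation levels
rho at a reduced scale (m=200 genes, 10% of hub correlations changed,
5 replicates per cell) and reports the mean permutation p-value per cell.
"""

from dconet import aggregation_power_study

table = aggregation_power_study(
    ns=(10, 20, 40), ks=(20,), rhos=(0.3, 0.5), m=200,
    replicates=5, n_permutations=500, seed=0,
)
print(table.round(4).to_string(index=False))
print(
    "\nEach row: mean (over 5 replicate datasets) of the hub's mean-score "
    "permutation p-value. The p-value falls as either the per-group sample "
    "size n or the flipped-correlation magnitude rho grows; with rho = 0.5 "
    "the hub is already detected (p < 0.05) at small n."
)
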