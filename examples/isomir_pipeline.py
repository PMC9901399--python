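"""End-to-end isomiR-target analysis on synthetic sequencing counts.

Simulates a small-RNA count table over two conditions, then walks the full
application pipeline: RPM normalization, the 95% cumulative-expression
filter, AGO2 weighting, Spearman correlation testing of isomiR-target
pairs, and classification of targets whose anticorrelation (r < -0.3)
significantly appeared or disappeared between conditions.
"""

import numpy as np
import pandas as pd

from dconet import (
    ExpressionMatrix,
    GroupAssignment,
    InteractionNetwork,
    ago2_weight,
    build_correlation_network,
    classify_target_changes,
    highly_expressed_set,
    parse_isomir,
    rpm_normalize,
    run_ztest,
)

rng = np.random.default_rng(3)
K = L = 100
samples = [f"N{j}" for j in range(K)] + [f"T{j}" for j in range(L)]

# skewed isomiR abundances: a few isoforms dominate the library
isomirs = ["hsa-miR-93-5p|0", "hsa-miR-93-5p|+1", "hsa-miR-192-5p|0",
           "hsa-miR-30a-5p|-1", "hsa-miR-10b-5p|0", "hsa-miR-151a-3p|0"]
base = np.array([6000.0, 1500.0, 700.0, 200.0, 8.0, 2.0])
counts = pd.DataFrame(rng.poisson(base[:, None], size=(6, K + L)),
                      index=isomirs, columns=samples)

rpm = rpm_normalize(counts)
kept = highly_expressed_set(rpm, fraction=0.95)
shifts = [parse_isomir(i).shift for i in kept]
print(f"highly expressed (95% of reads): {kept}")
print(f"5'-end shifts of the kept isoforms: {shifts}")

ago2 = pd.Series(rng.uniform(80, 120, K + L), index=samples)
mirna = pd.DataFrame({iso: ago2_weight(rpm.loc[iso], ago2) for iso in kept}).T

# one target anticorrelated with the top isomiR in Normal only
driver = mirna.iloc[0]
is_normal = np.array([s.startswith("N") for s in samples])
target = np.where(is_normal, -driver + 0.15 * rng.standard_normal(K + L),
                  rng.standard_normal(K + L))
matrix = ExpressionMatrix(pd.concat([mirna, pd.DataFrame([target], index=["FBXO31"],
                                                         columns=samples)]))
groups = GroupAssignment(
    labels={s: ("Normal" if s.startswith("N") else "Tumor") for s in samples},
    group_a="Normal", group_b="Tumor",
)
network = InteractionNetwork(tuple((iso, "FBXO31") for iso in kept))
results = run_ztest(matrix, groups, network, kind="spearman")

normal_net = build_correlation_network(results, "Normal", threshold=-0.3)
print(f"\nanticorrelated (r < -0.3) in Normal: {list(normal_net.pairs)}")

classified = classify_target_changes(results, alpha=0.05, threshold=-0.3)
print(classified[["source", "target", "r_Normal", "r_Tumor",
                  "adjusted_pvalue", "status"]].round(4).to_string(index=False))
print(
    "\n'lost' = the target was anticorrelated with its isomiR in Normal "
    "(r < -0.3) but significantly jumped above the threshold in Tumor — "
    "the designed loss of regulation for the top isomiR is recovered."
)
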