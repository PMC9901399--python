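"""Multivariate-normal synthetic datasets for validating the method.

Two covariance designs are generated, each yielding an expression matrix, a
two-group sample assignment and an interaction network, so the whole
pipeline can be exercised without any external data.

**Hub design** (aggregation-score validation).  m genes, n samples per
group, zero means, unit variances.  A hub gene and the k "changed" genes
form an equicorrelated block with off-diagonal rho in the first condition;
in the second condition the hub's row and column of the block are
sign-flipped (C_T = D C_N D with D = diag(-1, 1, ..., 1)), so each of the k
hub-gene correlations moves from +rho to -rho while every other entry is
unchanged.  The sign-flip construction keeps the covariance positive
definite for any rho in (0, 1) and any k — a hub star with mutually
uncorrelated leaves would require k*rho^2 < 1 and is infeasible at the
default design point.  The network tests the hub against all other m-1
genes; k=0 degenerates to an exact null (identity covariance in both
groups).

**Paired-blocks design** (permutation-scheme comparison).  2m genes forming
m independent pairs; the first condition has identity covariance, the second
is block-diagonal with k "strong" 2x2 blocks (off-diagonal 1, clamped to
1 - 1e-6 so the covariance stays positive definite) and m-k "weak" blocks
(off-diagonal 0.5).  The network is the m within-block pairs; the last pair
is always a weak one and is the pair on which the per-pair and pooled
permutation p-values are compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .aggregation import score_permutation_pvalue
from .containers import ExpressionMatrix, GroupAssignment, InteractionNetwork
from .permutation import (
    PermutationPlan,
    perpair_permutation_pvalues,
    pooled_permutation_pvalues,
)

__all__ = [
    "AggregationScenario",
    "PermScenario",
    "generate_aggregation_dataset",
    "generate_perm_dataset",
    "aggregation_power_study",
    "permutation_method_comparison",
]

#: off-diagonal used when a design asks for a perfectly correlated pair
STRONG_RHO_CLAMP = 1.0 - 1e-6


@dataclass(frozen=True)
class AggregationScenario:
    """Hub-design parameters: m genes, n samples per group, k changed
    hub correlations of magnitude rho (+rho in group A, -rho in group B)."""

    m: int = 1000
    n: int = 20
    k: int = 100
    rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least two genes")
        if not 0 <= self.k <= self.m - 1:
            raise ValueError(f"k must lie in [0, m-1], got k={self.k}, m={self.m}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.n < 4:
            raise ValueError("need n >= 4 samples per group")


@dataclass(frozen=True)
class PermScenario:
    """Paired-blocks parameters: m gene pairs, k of them strongly changed
    (0 -> ~1), the rest weakly (0 -> rho_weak); group sizes K and L."""

    m: int = 10
    k: int = 9
    K: int = 100
    L: int = 50
    rho_weak: float = 0.5
    rho_strong: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("need at least one gene pair")
        if not 0 <= self.k <= self.m:
            raise ValueError(f"k must lie in [0, m], got k={self.k}, m={self.m}")
        if self.K < 4 or self.L < 4:
            raise ValueError("group sizes must be >= 4")
        for name, rho in (("rho_weak", self.rho_weak), ("rho_strong", self.rho_strong)):
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rho}")


def _labeled_dataset(
    values_a: np.ndarray, values_b: np.ndarray, gene_ids: list[str]
) -> tuple[ExpressionMatrix, GroupAssignment]:
    n_a, n_b = values_a.shape[1], values_b.shape[1]
    samples = [f"N{j + 1}" for j in range(n_a)] + [f"T{j + 1}" for j in range(n_b)]
    matrix = ExpressionMatrix.from_arrays(
        np.hstack([values_a, values_b]), molecule_ids=gene_ids, sample_ids=samples
    )
    labels = {s: ("Normal" if s.startswith("N") else "Tumor") for s in samples}
    groups = GroupAssignment(labels=labels, group_a="Normal", group_b="Tumor")
    return matrix, groups


def _block_cholesky(size: int, rho: float) -> np.ndarray:
    """Cholesky factor of the equicorrelated matrix, with an explicit PD check."""
    block = np.full((size, size), rho)
    np.fill_diagonal(block, 1.0)
    try:
        return np.linalg.cholesky(block)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by scenarios
        raise ValueError(
            f"covariance block (size {size}, off-diagonal {rho}) is not positive definite"
        ) from exc


def generate_aggregation_dataset(
    scenario: AggregationScenario,
) -> tuple[ExpressionMatrix, GroupAssignment, InteractionNetwork]:
    """Sample the hub design; the hub is gene "gene1", the network tests it
    against every other gene (m - 1 pairs, k of them truly changed)."""
    m, n, k, rho = scenario.m, scenario.n, scenario.k, scenario.rho
    rng = np.random.default_rng(scenario.seed)
    raw_a = rng.standard_normal((m, n))
    raw_b = rng.standard_normal((m, n))
    if k >= 1 and rho > 0.0:
        chol = _block_cholesky(k + 1, rho)
        raw_a[: k + 1] = chol @ raw_a[: k + 1]
        raw_b[: k + 1] = chol @ raw_b[: k + 1]
        raw_b[0] *= -1.0  # flips the hub's correlations: C_T = D C_N D
    gene_ids = [f"gene{i + 1}" for i in range(m)]
    matrix, groups = _labeled_dataset(raw_a, raw_b, gene_ids)
    network = InteractionNetwork(tuple((gene_ids[0], g) for g in gene_ids[1:]))
    return matrix, groups, network


def generate_perm_dataset(
    scenario: PermScenario,
) -> tuple[ExpressionMatrix, GroupAssignment, InteractionNetwork]:
    """Sample the paired-blocks design; the network lists the m within-block
    pairs and its last pair is the weakly-changed one under comparison."""
    m, k = scenario.m, scenario.k
    rng = np.random.default_rng(scenario.seed)
    raw_a = rng.standard_normal((2 * m, scenario.K))
    raw_b = rng.standard_normal((2 * m, scenario.L))
    rho_strong = min(scenario.rho_strong, STRONG_RHO_CLAMP)
    for i in range(m):
        rho = rho_strong if i < k else scenario.rho_weak
        first, second = 2 * i, 2 * i + 1
        raw_b[second] = rho * raw_b[first] + np.sqrt(1.0 - rho * rho) * raw_b[second]
    gene_ids = [f"gene{i + 1}" for i in range(2 * m)]
    matrix, groups = _labeled_dataset(raw_a, raw_b, gene_ids)
    network = InteractionNetwork(
        tuple((gene_ids[2 * i], gene_ids[2 * i + 1]) for i in range(m))
    )
    return matrix, groups, network


def _replicate_seeds(seed: int, count: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=count)


def aggregation_power_study(
    ns: Iterable[int] = (10, 20, 40, 80),
    ks: Iterable[int] = (100,),
    rhos: Iterable[float] = (0.3, 0.5, 0.7),
    m: int = 1000,
    replicates: int = 10,
    n_permutations: int = 1000,
    score_kind: str = "mean",
    kind: str = "pearson",
    seed: int = 0,
) -> pd.DataFrame:
    """Power study of the hub's aggregation-score permutation p-value.

    For every (n, k, rho) grid cell, generates ``replicates`` independent hub
    datasets and records the hub's score permutation p-value.  Returns a
    DataFrame with columns ``n``, ``k``, ``rho``, ``mean_pvalue``,
    ``sd_pvalue``, ``rejected_at_05`` (count of replicates with p < 0.05)
    and ``replicates``.
    """
    cells = [(n, k, rho) for n in ns for k in ks for rho in rhos]
    rows = []
    for ci, (n, k, rho) in enumerate(cells):
        seeds = _replicate_seeds(seed + 7919 * ci, replicates)
        pvals = np.array(
            [
                hub_score_pvalue(
                    AggregationScenario(m=m, n=n, k=k, rho=rho, seed=int(s)),
                    n_permutations=n_permutations,
                    score_kind=score_kind,
                    kind=kind,
                )
                for s in seeds
            ]
        )
        rows.append(
            {
                "n": n,
                "k": k,
                "rho": rho,
                "mean_pvalue": pvals.mean(),
                "sd_pvalue": pvals.std(ddof=1) if replicates > 1 else 0.0,
                "rejected_at_05": int((pvals < 0.05).sum()),
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)


def hub_score_pvalue(
    scenario: AggregationScenario,
    n_permutations: int = 1000,
    score_kind: str = "mean",
    kind: str = "pearson",
) -> float:
    """One replicate of the hub design: the hub gene's aggregation-score
    permutation p-value (the permutation stream is seeded from the scenario)."""
    matrix, groups, network = generate_aggregation_dataset(scenario)
    plan = PermutationPlan(n_permutations=n_permutations, seed=scenario.seed)
    return score_permutation_pvalue(
        matrix, groups, network, network.sources[0], score_kind=score_kind, plan=plan, kind=kind
    )


def permutation_method_comparison(
    L_values: Iterable[int] = tuple(range(10, 101, 10)),
    ks: Iterable[int] = (9,),
    m: int = 10,
    K: int = 100,
    replicates: int = 20,
    n_permutations: int = 1000,
    kind: str = "pearson",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pair versus pooled permutation p-values on the weak pair.

    The first group keeps size K while the second group's size L varies.
    For each (L, k) cell and each replicate, both permutation schemes are
    run with the same seed and the p-value of the weakly-changed (last)
    network pair is recorded.  Returns a long DataFrame with columns ``L``,
    ``k``, ``method`` ("per_pair" / "pooled"), ``mean_pvalue``, ``sd_pvalue``
    and ``replicates``.
    """
    cells = [(L, k) for L in L_values for k in ks]
    rows = []
    for ci, (L, k) in enumerate(cells):
        seeds = _replicate_seeds(seed + 104729 * ci, replicates)
        per_pair = np.empty(replicates)
        pooled = np.empty(replicates)
        for ri, s in enumerate(seeds):
            scenario = PermScenario(m=m, k=k, K=K, L=L, seed=int(s))
            matrix, groups, network = generate_perm_dataset(scenario)
            plan = PermutationPlan(n_permutations=n_permutations, seed=int(s))
            per_pair[ri] = perpair_permutation_pvalues(
                matrix, groups, network, kind=kind, plan=plan
            )[-1]
            pooled[ri] = pooled_permutation_pvalues(
                matrix, groups, network, kind=kind, plan=plan
            )[-1]
        n_pooled_greater = int((pooled > per_pair).sum())
        for method, pvals in (("per_pair", per_pair), ("pooled", pooled)):
            rows.append(
                {
                    "L": L,
                    "k": k,
                    "method": method,
                    "mean_pvalue": pvals.mean(),
                    "sd_pvalue": pvals.std(ddof=1) if replicates > 1 else 0.0,
                    "n_pooled_greater": n_pooled_greater,
                    "replicates": replicates,
                }
            )
    return pd.DataFrame(rows)
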