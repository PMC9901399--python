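"""Group-label permutation null distributions for the correlation-equality test.

Permutation p-values avoid the bivariate-normal assumption behind the
analytic test: group labels are shuffled (preserving the group sizes K and
L), the z statistic of every tested pair is recomputed under each relabeling,
and the p-value of pair i is the smoothed exceedance proportion

    p_i = (1 + #{b : |z_i^(b)| >= |z_i^(0)|}) / (B + 1).

Two counting schemes are provided:

* **per-pair** — each pair's observed statistic is compared only against its
  own permuted statistics (the scheme this package recommends);
* **pooled** — each observed statistic is compared against the permuted
  statistics of *all* pairs, as some differential-correlation tools do.
  Pooling is only exchangeable when every pair has the same null
  distribution; under heterogeneous alternatives it is badly conservative
  for weakly-changed pairs (see :mod:`dconet.synthetic` for the experiment
  demonstrating this), so it is provided as a comparator only.

One seeded relabeling stream is shared by all pairs within a run: every
relabeling is applied to the whole matrix, which is what shuffling sample
labels means physically.  The stream is split into fixed-size blocks with
seeds spawned deterministically from the plan's seed, so results are
independent of the number of worker processes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .containers import ExpressionMatrix, GroupAssignment, InteractionNetwork
from .core import _RunPlan

__all__ = [
    "PermutationPlan",
    "min_permutations",
    "permute_labels",
    "perpair_permutation_pvalues",
    "pooled_permutation_pvalues",
]

#: permutations per RNG block; fixed so results do not depend on worker count
BLOCK_SIZE = 250


def min_permutations(R: int, alpha: float) -> int:
    """Minimum permutation count ceil(R / alpha) for R simultaneous hypotheses.

    With fewer permutations the smallest attainable p-value is too coarse for
    a BH-adjusted rejection at level alpha across R hypotheses.
    """
    if R < 1:
        raise ValueError(f"hypothesis count must be >= 1, got {R}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return math.ceil(R / alpha)


@dataclass
class PermutationPlan:
    """Parameters of a permutation run.

    ``n_permutations=None`` defaults to ceil(R / alpha) once the hypothesis
    count R is known.  ``raw_proportion`` drops the add-one smoothing and
    reports the literal exceedance proportion count/B (which can be zero).
    """

    n_permutations: int | None = None
    seed: int = 0
    alpha: float = 0.05
    n_hypotheses: int | None = None
    raw_proportion: bool = False
    workers: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_permutations is not None and self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def resolve_permutations(self, R: int) -> int:
        if self.n_permutations is not None:
            return self.n_permutations
        return min_permutations(R, self.alpha)

    def smooth(self, counts: np.ndarray, denominator: int) -> np.ndarray:
        counts = np.asarray(counts, dtype=float)
        if self.raw_proportion:
            return counts / denominator
        return (1.0 + counts) / (denominator + 1.0)


def permute_labels(groups: GroupAssignment, rng: np.random.Generator) -> GroupAssignment:
    """A uniformly random relabeling of the samples preserving group sizes."""
    samples = list(groups.labels)
    perm = rng.permutation(len(samples))
    K = groups.K
    labels = {}
    for rank, idx in enumerate(perm):
        labels[samples[idx]] = groups.group_a if rank < K else groups.group_b
    return GroupAssignment(labels=labels, group_a=groups.group_a, group_b=groups.group_b)


def _block_sizes(B: int) -> list[int]:
    sizes = [BLOCK_SIZE] * (B // BLOCK_SIZE)
    if B % BLOCK_SIZE:
        sizes.append(B % BLOCK_SIZE)
    return sizes


def _permuted_index_splits(
    labeled_cols: np.ndarray, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(labeled_cols.size)
    cols = labeled_cols[perm]
    return cols[:K], cols[K:]


def permuted_zstat_blocks(
    run: _RunPlan, kind: str, B: int, seed: int
) -> Iterator[np.ndarray]:
    """Yield (block_size x n_pairs) arrays of z statistics under relabelings.

    The b-th row across all blocks is the statistic vector of the b-th
    relabeling; the sequence of relabelings depends only on ``seed``.
    """
    sizes = _block_sizes(B)
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    for size, child in zip(sizes, children):
        rng = np.random.default_rng(child)
        block = np.empty((size, run.src_idx.size))
        for b in range(size):
            cols_a, cols_b = _permuted_index_splits(run.labeled_cols, run.K, rng)
            block[b] = run.zstats(kind, cols_a, cols_b, warn=False)
        yield block


def _observed_and_run(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    network: InteractionNetwork,
    kind: str,
) -> tuple[_RunPlan, np.ndarray]:
    run = _RunPlan(matrix, groups, network)
    r_a, r_b = run.correlations(kind)
    run.validate_correlations(r_a, r_b)
    return run, run.zstats(kind)


def perpair_permutation_pvalues(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    network: InteractionNetwork,
    kind: str = "pearson",
    plan: PermutationPlan | None = None,
    sidedness: str = "two_sided",
) -> np.ndarray:
    """Per-pair permutation p-values: each pair against its own permuted statistics."""
    plan = plan or PermutationPlan()
    run, z0 = _observed_and_run(matrix, groups, network, kind)
    B = plan.resolve_permutations(len(network))
    counts = np.zeros(z0.size)
    if sidedness == "two_sided":
        ref = np.abs(z0)
        for block in permuted_zstat_blocks(run, kind, B, plan.seed):
            counts += (np.abs(block) >= ref).sum(axis=0)
    elif sidedness == "one_sided_greater":
        for block in permuted_zstat_blocks(run, kind, B, plan.seed):
            counts += (block >= z0).sum(axis=0)
    else:
        raise ValueError(f"unknown sidedness: {sidedness!r}")
    return plan.smooth(counts, B)


def pooled_permutation_pvalues(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    network: InteractionNetwork,
    kind: str = "pearson",
    plan: PermutationPlan | None = None,
    sidedness: str = "two_sided",
) -> np.ndarray:
    """Pooled permutation p-values: each pair against all pairs' permuted statistics.

    p_i = (1 + #{(j,b) : |z_j^(b)| >= |z_i^(0)|}) / (R*B + 1).  Provided as a
    comparator; see the module docstring for why pooling is unreliable under
    heterogeneous correlation changes.
    """
    plan = plan or PermutationPlan()
    run, z0 = _observed_and_run(matrix, groups, network, kind)
    R = len(network)
    B = plan.resolve_permutations(R)
    if sidedness == "two_sided":
        ref = np.abs(z0)
        transform = np.abs
    elif sidedness == "one_sided_greater":
        ref = z0
        transform = np.asarray
    else:
        raise ValueError(f"unknown sidedness: {sidedness!r}")
    counts = np.zeros(z0.size)
    for block in permuted_zstat_blocks(run, kind, B, plan.seed):
        pooled = np.sort(transform(block), axis=None)
        # exceedances with ties counted: total minus strictly-smaller count
        counts += pooled.size - np.searchsorted(pooled, ref, side="left")
    return plan.smooth(counts, R * B)
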