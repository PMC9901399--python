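"""Source-molecule aggregation of per-pair correlation changes.

Pairwise testing can miss a regulator whose many interactions each change a
little.  Two complementary summaries per source molecule G are provided:

* **hypergeometric overrepresentation** — with n_G interactions of G in the
  network (N = sum n_g total) and s_G of them significantly changed
  (BH-adjusted p < alpha; S = sum s_g total), the null that significant
  changes are allocated uniformly over the network makes s_G hypergeometric
  H(N, S, n_G); the reported p-value is the upper tail P(X >= s_G).
* **aggregation scores** — the mean, median or a quantile of the z statistics
  of G's targets, tested against zero by the same label-permutation scheme
  as the pair-level test: p = (1 + #{b : |score_b| >= |score_0|}) / (B + 1).

Both summaries are BH-adjusted across sources (separately per statistic).
"""

from __future__ import annotations

import re
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix, GroupAssignment, InteractionNetwork
from .core import _RunPlan, bh_adjust, run_ztest
from .permutation import PermutationPlan, permuted_zstat_blocks

__all__ = [
    "hypergeom_test",
    "aggregate_score",
    "score_permutation_pvalue",
    "run_aggregation",
]


def hypergeom_test(s_G: int, n_G: int, S: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= s_G), X ~ H(N, S, n_G).

    N = total network interactions, S = total significant changes, n_G =
    interactions of the source, s_G = significant changes of the source.
    The tail includes the observed value.
    """
    if not (0 <= s_G <= n_G <= N and 0 <= S <= N and s_G <= S):
        raise ValueError(
            f"inconsistent counts: s_G={s_G}, n_G={n_G}, S={S}, N={N} "
            "(need 0 <= s_G <= min(n_G, S) and n_G, S <= N)"
        )
    return float(sps.hypergeom.sf(s_G - 1, N, S, n_G))


_QUANTILE_RE = re.compile(r"^quantile\((?P<q>[0-9.eE+-]+)\)$")


def _score_function(score_kind: str) -> Callable[[np.ndarray], np.ndarray]:
    """Map a score-kind name to a row-wise reducer over the last axis."""
    if score_kind == "mean":
        return lambda a: np.mean(a, axis=-1)
    if score_kind == "median":
        return lambda a: np.median(a, axis=-1)
    m = _QUANTILE_RE.match(score_kind)
    if m:
        q = float(m.group("q"))
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"quantile level must lie in [0, 1], got {q}")
        # linear interpolation between order statistics (numpy default)
        return lambda a: np.quantile(a, q, axis=-1)
    raise ValueError(
        f"unknown score kind {score_kind!r}; use 'mean', 'median' or 'quantile(q)'"
    )


def aggregate_score(z_stats: Sequence[float], score_kind: str) -> float:
    """Mean, median or quantile of one source's per-target z statistics."""
    arr = np.asarray(z_stats, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty list of z statistics")
    return float(_score_function(score_kind)(arr))


def _source_indices(network: InteractionNetwork) -> dict[str, np.ndarray]:
    by_source: dict[str, list[int]] = {}
    for i, (s, _) in enumerate(network.pairs):
        by_source.setdefault(s, []).append(i)
    return {s: np.asarray(idx, dtype=np.intp) for s, idx in by_source.items()}


def _score_permutation_counts(
    run: _RunPlan,
    z0: np.ndarray,
    source_idx: dict[str, np.ndarray],
    score_kinds: Sequence[str],
    kind: str,
    B: int,
    seed: int,
) -> np.ndarray:
    """Exceedance counts |score_b| >= |score_0| per (source, score kind)."""
    fns = [_score_function(k) for k in score_kinds]
    sources = list(source_idx)
    ref = np.array(
        [[abs(fn(z0[source_idx[s]])) for fn in fns] for s in sources]
    )  # (n_sources, n_kinds)
    counts = np.zeros_like(ref)
    for block in permuted_zstat_blocks(run, kind, B, seed):
        for gi, s in enumerate(sources):
            sub = block[:, source_idx[s]]
            for ki, fn in enumerate(fns):
                counts[gi, ki] += np.sum(np.abs(fn(sub)) >= ref[gi, ki])
    return counts


def score_permutation_pvalue(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    network: InteractionNetwork,
    source_id: str,
    score_kind: str = "mean",
    plan: PermutationPlan | None = None,
    kind: str = "pearson",
) -> float:
    """Permutation p-value of one source's aggregation score being zero.

    Uses the same seeded relabeling stream as the pair-level permutation
    test, so a single-target source reproduces its per-pair p-value exactly.
    """
    plan = plan or PermutationPlan()
    source_idx = _source_indices(network)
    if source_id not in source_idx:
        raise KeyError(f"source {source_id!r} has no interactions in the network")
    run = _RunPlan(matrix, groups, network)
    r_a, r_b = run.correlations(kind)
    run.validate_correlations(r_a, r_b)
    z0 = run.zstats(kind)
    B = plan.resolve_permutations(len(network))
    counts = _score_permutation_counts(
        run, z0, {source_id: source_idx[source_id]}, [score_kind], kind, B, plan.seed
    )
    return float(plan.smooth(counts, B)[0, 0])


def run_aggregation(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    network: InteractionNetwork,
    kind: str = "pearson",
    alpha: float = 0.05,
    score_kinds: Sequence[str] = ("mean",),
    plan: PermutationPlan | None = None,
) -> pd.DataFrame:
    """Full per-source aggregation: hypergeometric counts plus score p-values.

    Runs the pairwise z-test once (analytic two-sided p-values), derives
    (s_G, n_G, S, N) from the BH-adjusted p-values at level ``alpha``, fills
    the hypergeometric upper-tail p-values, then computes the permutation
    p-value of every requested aggregation score from one shared relabeling
    stream.  BH is applied across sources, separately for the hypergeometric
    test and for each score kind.

    Returns one row per (source, score_kind) — or one row per source with
    NaN score columns when ``score_kinds`` is empty — with columns ``source``,
    ``n_G``, ``s_G``, ``hypergeom_pvalue``, ``hypergeom_adjusted``,
    ``score_kind``, ``score_value``, ``score_pvalue``, ``score_adjusted``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    plan = plan or PermutationPlan(alpha=alpha)
    for score_kind in score_kinds:
        _score_function(score_kind)  # validate names before heavy work

    pairwise = run_ztest(matrix, groups, network, kind=kind, pvalue_kind="analytic")
    significant = pairwise["adjusted_pvalue"].to_numpy() < alpha
    z0 = pairwise["statistic"].to_numpy()

    source_idx = _source_indices(network)
    sources = list(source_idx)
    n_G = np.array([source_idx[s].size for s in sources])
    s_G = np.array([int(significant[source_idx[s]].sum()) for s in sources])
    N = int(n_G.sum())
    S = int(s_G.sum())
    hyper_p = np.array([hypergeom_test(int(s), int(n), S, N) for s, n in zip(s_G, n_G)])
    hyper_adj = bh_adjust(hyper_p)

    per_source = pd.DataFrame(
        {
            "source": sources,
            "n_G": n_G,
            "s_G": s_G,
            "hypergeom_pvalue": hyper_p,
            "hypergeom_adjusted": hyper_adj,
        }
    )

    if score_kinds:
        run = _RunPlan(matrix, groups, network)
        B = plan.resolve_permutations(len(network))
        score0 = np.array(
            [
                [aggregate_score(z0[source_idx[s]], k) for k in score_kinds]
                for s in sources
            ]
        )
        counts = _score_permutation_counts(
            run, z0, source_idx, list(score_kinds), kind, B, plan.seed
        )
        score_p = plan.smooth(counts, B)
        rows = []
        for ki, score_kind in enumerate(score_kinds):
            frame = per_source.copy()
            frame["score_kind"] = score_kind
            frame["score_value"] = score0[:, ki]
            frame["score_pvalue"] = score_p[:, ki]
            frame["score_adjusted"] = bh_adjust(score_p[:, ki])
            rows.append(frame)
        result = pd.concat(rows, ignore_index=True)
    else:
        result = per_source.assign(
            score_kind=pd.NA, score_value=np.nan, score_pvalue=np.nan, score_adjusted=np.nan
        )

    result.attrs.update(
        group_a=groups.group_a,
        group_b=groups.group_b,
        correlation_kind=kind,
        alpha=alpha,
        N=N,
        S=S,
        seed=plan.seed,
    )
    return result
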