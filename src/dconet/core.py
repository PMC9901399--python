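"""Correlation-equality testing between two sample groups.

For a molecule pair (X, Y) with correlation ``r_a`` estimated from the K
samples of one condition and ``r_b`` from the L samples of the other, the
Fisher transform z(r) = arctanh(r) is asymptotically normal with a variance
that does not depend on the underlying correlation (Pearson case), so

    Z = (z(r_a) - z(r_b)) / sqrt(sigma2_a + sigma2_b)

is asymptotically standard normal under the hypothesis that the two
population correlations are equal.  The asymptotic variances are

    Pearson:   sigma2(M) = 1 / (M - 3)
    Spearman:  sigma2(M) = (1 + rho^2 / 2) / (M - 3)  <=  1.5 / (M - 3)

For Spearman the variance depends on the unknown rho, so the statistic is
rescaled with the worst-case bound 1.5 / (M - 3); the analytic p-value then
upper-bounds the plug-in p-value (a conservative test).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix, GroupAssignment, InteractionNetwork

__all__ = [
    "fisher_transform",
    "group_correlation",
    "asymptotic_variance",
    "ztest_statistic",
    "analytic_pvalue",
    "bh_adjust",
    "run_ztest",
]

#: correlations this close to +-1 are clamped before arctanh
CLAMP_TOL = 1e-12


def _clamp_correlations(r: np.ndarray, warn: bool = True) -> np.ndarray:
    """Clamp |r| >= 1 - CLAMP_TOL to the open interval so arctanh stays finite."""
    r = np.asarray(r, dtype=float)
    limit = 1.0 - CLAMP_TOL
    clipped = np.clip(r, -limit, limit)
    if warn and np.any(np.abs(r) >= limit):
        warnings.warn(
            "correlation(s) at or numerically indistinguishable from +-1 "
            f"were clamped to +-{limit} before the Fisher transform",
            RuntimeWarning,
            stacklevel=3,
        )
    return clipped


def fisher_transform(r):
    """Variance-stabilizing transform z(r) = arctanh(r).

    Accepts scalars or arrays. Values with |r| >= 1 - 1e-12 are clamped to
    the open interval (with a warning) so perfectly collinear inputs do not
    produce infinities.
    """
    arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("correlation input to fisher_transform must be finite")
    out = np.arctanh(_clamp_correlations(arr))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def asymptotic_variance(M: int, kind: str, mode: str = "worst_case", r: float | None = None) -> float:
    """Asymptotic variance of the Fisher-transformed correlation at sample size M.

    ``mode`` applies only to Spearman: ``plugin`` uses (1 + r^2/2)/(M-3) with
    the supplied r, ``worst_case`` the bound 1.5/(M-3) (since 1 + rho^2/2 <= 1.5).
    """
    if M <= 3:
        raise ValueError(f"sample size must exceed 3, got M={M}")
    if kind == "pearson":
        return 1.0 / (M - 3)
    if kind == "spearman":
        if mode == "worst_case":
            return 1.5 / (M - 3)
        if mode == "plugin":
            if r is None:
                raise ValueError("plugin variance requires the correlation r")
            return (1.0 + r * r / 2.0) / (M - 3)
        raise ValueError(f"unknown variance mode: {mode!r}")
    raise ValueError(f"unknown correlation kind: {kind!r}")


def ztest_statistic(r_a, r_b, K: int, L: int, kind: str = "pearson"):
    """The correlation-equality test statistic.

    For ``kind='spearman'`` the denominator uses the worst-case variances
    1.5/(M-3), so the reported statistic is exactly the conservatively
    rescaled one whose standard-normal tail bounds the plug-in p-value.
    Antisymmetric under exchange of the two groups (with their sizes).
    """
    var = asymptotic_variance(K, kind) + asymptotic_variance(L, kind)
    z_a = np.asarray(fisher_transform(r_a), dtype=float)
    z_b = np.asarray(fisher_transform(r_b), dtype=float)
    out = (z_a - z_b) / np.sqrt(var)
    return float(out) if out.ndim == 0 else out


def analytic_pvalue(z_stat, sidedness: str = "two_sided"):
    """Standard-normal tail probability of the test statistic.

    ``two_sided`` returns 2*Phi(-|z|); ``one_sided_greater`` returns
    P(xi > z) = Phi(-z). For Spearman statistics the worst-case rescaling is
    already embedded in z, so the returned value upper-bounds the plug-in
    p-value.
    """
    arr = np.asarray(z_stat, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("test statistic must be finite")
    if sidedness == "two_sided":
        out = 2.0 * sps.norm.sf(np.abs(arr))
    elif sidedness == "one_sided_greater":
        out = sps.norm.sf(arr)
    else:
        raise ValueError(f"unknown sidedness: {sidedness!r}")
    out = np.minimum(out, 1.0)
    return float(out) if np.isscalar(z_stat) or arr.ndim == 0 else out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adjusted_i = min_{j >= i, sorted order} p_(j) * m / j, clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out


# ---------------------------------------------------------------------------
# vectorized per-pair correlations
# ---------------------------------------------------------------------------


def _rank_rows(sub: np.ndarray) -> np.ndarray:
    """Average (midrank) ranks along each row."""
    return sps.rankdata(sub, axis=1, method="average")


def _standardize_rows(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit Euclidean norm; returns (Z, zero_mask)."""
    centered = sub - sub.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    zero = norms == 0.0
    norms[zero] = 1.0
    return centered / norms[:, None], zero


def _pair_correlations(
    values: np.ndarray,
    col_idx: np.ndarray,
    src_idx: np.ndarray,
    tgt_idx: np.ndarray,
    kind: str,
) -> np.ndarray:
    """Correlations of (src, tgt) row pairs over the columns ``col_idx``.

    Spearman is computed as Pearson on within-group midranks.  Rows with zero
    within-group variance yield NaN (callers validate and name the offender).
    """
    sub = values[:, col_idx]
    if kind == "spearman":
        sub = _rank_rows(sub)
    elif kind != "pearson":
        raise ValueError(f"unknown correlation kind: {kind!r}")
    z, zero = _standardize_rows(sub)
    r = np.einsum("ij,ij->i", z[src_idx], z[tgt_idx])
    if zero.any():
        bad = zero[src_idx] | zero[tgt_idx]
        r[bad] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


class _RunPlan:
    """Precomputed index arrays binding a matrix, groups and a network."""

    def __init__(
        self,
        matrix: ExpressionMatrix,
        groups: GroupAssignment,
        network: InteractionNetwork,
    ):
        network.check_against(matrix)
        missing = [s for s in groups.labels if s not in set(matrix.sample_ids)]
        if missing:
            raise KeyError(f"labeled sample {missing[0]!r} missing from the expression matrix")
        # restrict to the molecules actually tested: cheaper permutation loops
        molecules = list(dict.fromkeys(m for pair in network.pairs for m in pair))
        row_of = {m: i for i, m in enumerate(molecules)}
        full_row = {m: i for i, m in enumerate(matrix.molecule_ids)}
        self.values = matrix.values[[full_row[m] for m in molecules], :]
        self.molecules = molecules
        self.src_idx = np.array([row_of[s] for s, _ in network.pairs], dtype=np.intp)
        self.tgt_idx = np.array([row_of[t] for _, t in network.pairs], dtype=np.intp)
        col_of = {s: j for j, s in enumerate(matrix.sample_ids)}
        self.cols_a = np.array([col_of[s] for s in groups.samples_a], dtype=np.intp)
        self.cols_b = np.array([col_of[s] for s in groups.samples_b], dtype=np.intp)
        self.labeled_cols = np.concatenate([self.cols_a, self.cols_b])
        self.K = self.cols_a.size
        self.L = self.cols_b.size
        self.network = network
        self.groups = groups

    def correlations(self, kind: str, cols_a=None, cols_b=None) -> tuple[np.ndarray, np.ndarray]:
        if cols_a is None:
            cols_a, cols_b = self.cols_a, self.cols_b
        r_a = _pair_correlations(self.values, cols_a, self.src_idx, self.tgt_idx, kind)
        r_b = _pair_correlations(self.values, cols_b, self.src_idx, self.tgt_idx, kind)
        return r_a, r_b

    def zstats(self, kind: str, cols_a=None, cols_b=None, warn: bool = True) -> np.ndarray:
        r_a, r_b = self.correlations(kind, cols_a, cols_b)
        var = asymptotic_variance(self.K, kind) + asymptotic_variance(self.L, kind)
        za = np.arctanh(_clamp_correlations(r_a, warn=warn))
        zb = np.arctanh(_clamp_correlations(r_b, warn=warn))
        return (za - zb) / np.sqrt(var)

    def validate_correlations(self, r_a: np.ndarray, r_b: np.ndarray) -> None:
        for r, label in ((r_a, self.groups.group_a), (r_b, self.groups.group_b)):
            if np.isnan(r).any():
                i = int(np.argmax(np.isnan(r)))
                s, t = self.network.pairs[i]
                raise ValueError(
                    f"zero within-group variance in group {label!r} for pair "
                    f"({s!r}, {t!r}); constant expression cannot be correlated"
                )


def group_correlation(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    pairs: InteractionNetwork,
    kind: str = "pearson",
) -> pd.DataFrame:
    """Per-pair correlations within each group.

    Returns a DataFrame with columns ``source``, ``target``, ``r_a``, ``r_b``
    (group_a and group_b correlations), in network order.
    """
    plan = _RunPlan(matrix, groups, pairs)
    r_a, r_b = plan.correlations(kind)
    plan.validate_correlations(r_a, r_b)
    return pd.DataFrame(
        {
            "source": [s for s, _ in pairs.pairs],
            "target": [t for _, t in pairs.pairs],
            "r_a": r_a,
            "r_b": r_b,
        }
    )


def run_ztest(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    network: InteractionNetwork,
    kind: str = "pearson",
    pvalue_kind: str = "analytic",
    sidedness: str = "two_sided",
    plan=None,
) -> pd.DataFrame:
    """Test every network pair for equality of correlations between the groups.

    Returns one row per pair, in network order, with columns ``source``,
    ``target``, ``r_<group_a>``, ``r_<group_b>``, ``statistic``, ``pvalue``,
    ``adjusted_pvalue``.  BH adjustment is applied across exactly the tested
    pairs.  ``pvalue_kind='permutation'`` computes per-pair label-permutation
    p-values using ``plan`` (a :class:`~dconet.permutation.PermutationPlan`).

    The DataFrame carries ``attrs``: ``group_a``, ``group_b``,
    ``correlation_kind``, ``pvalue_kind``, ``sidedness``, ``K``, ``L``.
    """
    run = _RunPlan(matrix, groups, network)
    r_a, r_b = run.correlations(kind)
    run.validate_correlations(r_a, r_b)
    var = asymptotic_variance(run.K, kind) + asymptotic_variance(run.L, kind)
    z = (np.arctanh(_clamp_correlations(r_a)) - np.arctanh(_clamp_correlations(r_b))) / np.sqrt(var)

    if pvalue_kind == "analytic":
        pvals = analytic_pvalue(z, sidedness=sidedness)
    elif pvalue_kind == "permutation":
        from .permutation import PermutationPlan, perpair_permutation_pvalues

        if plan is None:
            plan = PermutationPlan(n_hypotheses=len(network))
        pvals = perpair_permutation_pvalues(
            matrix, groups, network, kind=kind, plan=plan, sidedness=sidedness
        )
    else:
        raise ValueError(f"unknown pvalue_kind: {pvalue_kind!r}")

    result = pd.DataFrame(
        {
            "source": [s for s, _ in network.pairs],
            "target": [t for _, t in network.pairs],
            f"r_{groups.group_a}": r_a,
            f"r_{groups.group_b}": r_b,
            "statistic": z,
            "pvalue": pvals,
            "adjusted_pvalue": bh_adjust(pvals),
        }
    )
    result.attrs.update(
        group_a=groups.group_a,
        group_b=groups.group_b,
        correlation_kind=kind,
        pvalue_kind=pvalue_kind,
        sidedness=sidedness,
        K=run.K,
        L=run.L,
    )
    return result
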