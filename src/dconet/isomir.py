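"""miRNA-isoform (isomiR) application helpers.

5'-isomiRs are miRNA isoforms whose 5' end is shifted relative to the
canonical mature sequence; because the seed region (nucleotides 2-7 from the
5' end) determines target recognition, a 5' shift can retarget the molecule.
This module covers the self-contained steps of an isomiR-target
differential-correlation analysis:

* the ``name|shift`` 5'-isomiR nomenclature (shift in the 5'->3' direction;
  e.g. ``hsa-miR-192-5p|+1`` lacks the first nucleotide of the canonical
  5' end, ``|0`` marks the canonical form);
* reads-per-million (RPM) normalization of small-RNA counts;
* the highly-expressed filter keeping the minimal isomiR set that accounts
  for a given fraction (default 95%) of all sequencing reads;
* AGO2 weighting — multiplying an isomiR's RPM by the sample's Argonaute-2
  expression as a proxy for RISC-loaded abundance (the proportionality
  constant is irrelevant for within-isomiR correlations);
* building the anticorrelation network (r < -0.3 in one condition) and
  classifying targets whose correlation significantly jumped over that
  threshold between conditions ("lost" vs "gained" negative regulation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import InteractionNetwork

__all__ = [
    "IsomiRId",
    "parse_isomir",
    "rpm_normalize",
    "highly_expressed_set",
    "ago2_weight",
    "build_correlation_network",
    "classify_target_changes",
]

#: standard anticorrelation cutoff for calling an isomiR-target interaction
DEFAULT_THRESHOLD = -0.3


@dataclass(frozen=True)
class IsomiRId:
    """A 5'-isomiR: canonical miRNA name plus a signed 5'-end shift."""

    mirna_name: str
    shift: int

    def __str__(self) -> str:
        if self.shift == 0:
            return f"{self.mirna_name}|0"
        return f"{self.mirna_name}|{self.shift:+d}"

    @property
    def is_canonical(self) -> bool:
        return self.shift == 0


_ISOMIR_RE = re.compile(r"^(?P<name>.+)\|(?P<shift>[+-]?\d+)$")


def parse_isomir(name_text: str) -> IsomiRId:
    """Parse ``name|shift`` text into an :class:`IsomiRId` (exact round-trip)."""
    m = _ISOMIR_RE.match(name_text)
    if not m:
        raise ValueError(
            f"invalid isomiR identifier {name_text!r}: expected 'name|signed-shift' "
            "(e.g. 'hsa-miR-192-5p|+1' or 'hsa-miR-93-5p|0')"
        )
    return IsomiRId(mirna_name=m.group("name"), shift=int(m.group("shift")))


def rpm_normalize(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads-per-million normalization: count / library_size * 1e6 per sample.

    ``library_sizes`` defaults to the per-sample column sums of ``counts``
    (then RPM columns sum to 1e6 exactly); when given explicitly it must be
    positive and at least the retained column sums.
    """
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("read counts must be nonnegative")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = library_sizes.reindex(counts.columns)
        if library_sizes.isna().any():
            missing = library_sizes.index[library_sizes.isna()][0]
            raise ValueError(f"missing library size for sample {missing!r}")
    if (library_sizes <= 0).any():
        bad = library_sizes.index[(library_sizes <= 0).to_numpy()][0]
        raise ValueError(f"non-positive library size for sample {bad!r}")
    return counts / library_sizes * 1e6


def highly_expressed_set(rpm: pd.DataFrame, fraction: float = 0.95) -> list[str]:
    """Minimal prefix of isomiRs (by pooled read share, descending) whose
    cumulative share reaches ``fraction`` of all reads.

    Shares are pooled across every sample of the project.  Ties in total
    share are broken by identifier so the result is deterministic.  Rows
    with zero total reads are never returned.
    """
    if rpm.empty:
        raise ValueError("empty expression table")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    totals = rpm.sum(axis=1)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("all rows have zero total reads")
    shares = totals / grand
    ordered = shares.sort_values(ascending=False, kind="mergesort")
    ordered = ordered.iloc[np.lexsort((ordered.index.astype(str), -ordered.to_numpy()))]
    cumulative = ordered.cumsum()
    cutoff = int(np.searchsorted(cumulative.to_numpy(), fraction - 1e-12)) + 1
    kept = ordered.iloc[:cutoff]
    kept = kept[kept > 0]
    return list(kept.index)


def ago2_weight(
    rpm_row: pd.Series,
    ago2_expr: pd.Series,
    log2: bool = True,
    pseudocount: float = 1.0,
) -> pd.Series:
    """AGO2-loaded expression proxy: elementwise rpm_i * ago2_i per sample.

    With ``log2=True`` (default) returns log2(product + pseudocount), ready
    for correlation analysis.  A constant AGO2 vector leaves rank
    correlations with any target unchanged.
    """
    if set(rpm_row.index) != set(ago2_expr.index):
        raise ValueError("isomiR and AGO2 profiles cover different sample sets")
    ago2 = ago2_expr.reindex(rpm_row.index)
    if (rpm_row < 0).any() or (ago2 < 0).any():
        raise ValueError("expression inputs must be nonnegative")
    weighted = rpm_row * ago2
    if log2:
        return np.log2(weighted + pseudocount)
    return weighted


def _group_column(results: pd.DataFrame, group: str) -> str:
    column = f"r_{group}"
    if column not in results.columns:
        raise KeyError(
            f"no correlation column for group {group!r}; available: "
            f"{[c for c in results.columns if c.startswith('r_')]}"
        )
    return column


def build_correlation_network(
    results: pd.DataFrame, group: str, threshold: float = DEFAULT_THRESHOLD
) -> InteractionNetwork:
    """Keep pairs whose correlation in ``group`` is strictly below ``threshold``.

    ``results`` is a pairwise-test table (see :func:`dconet.core.run_ztest`)
    with a ``r_<group>`` column; the boundary value itself is excluded.
    """
    column = _group_column(results, group)
    kept = results.loc[results[column] < threshold, ["source", "target"]]
    if kept.empty:
        raise ValueError(
            f"no pair has r < {threshold} in group {group!r}; the network would be empty"
        )
    return InteractionNetwork(tuple(map(tuple, kept.to_numpy())))


def classify_target_changes(
    results: pd.DataFrame,
    group_a: str | None = None,
    group_b: str | None = None,
    alpha: float = 0.05,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Classify each pair as ``lost``, ``gained`` or ``unchanged`` regulation.

    A target is **lost** when the anticorrelation present in the reference
    condition disappears (r_a < threshold <= r_b) and **gained** in the
    opposite case (r_b < threshold <= r_a), in both cases requiring the
    correlation change itself to be significant (BH-adjusted p < alpha).
    Everything else is ``unchanged``; the three classes partition the input.

    Group labels default to the ``attrs`` of the results table.  Returns the
    input columns plus ``status``.
    """
    group_a = group_a or results.attrs.get("group_a")
    group_b = group_b or results.attrs.get("group_b")
    if group_a is None or group_b is None:
        raise ValueError("group labels must be given or carried in results.attrs")
    if "adjusted_pvalue" not in results.columns:
        raise KeyError("results table lacks the 'adjusted_pvalue' column")
    r_a = results[_group_column(results, group_a)].to_numpy()
    r_b = results[_group_column(results, group_b)].to_numpy()
    significant = results["adjusted_pvalue"].to_numpy() < alpha
    lost = significant & (r_a < threshold) & (r_b >= threshold)
    gained = significant & (r_b < threshold) & (r_a >= threshold)
    status = np.where(lost, "lost", np.where(gained, "gained", "unchanged"))
    out = results.copy()
    out["status"] = status
    out.attrs.update(results.attrs)
    out.attrs.update(alpha=alpha, threshold=threshold)
    return out
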