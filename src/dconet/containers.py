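"""Core data containers: expression matrix, two-group sample assignment, interaction network.

The analysis compares, for every (source, target) molecule pair of a network,
the correlation of the pair's expression profiles between two sample groups
(conventionally called "Normal" and "Tumor", but any two conditions work).
These containers validate the structural invariants every downstream
computation relies on: finite values, unique identifiers, exactly two groups,
and group sizes large enough for the Fisher-transform asymptotics
(M - 3 > 0 in every variance denominator).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "GroupAssignment", "InteractionNetwork"]

#: smallest admissible group size; the asymptotic variances divide by M - 3
MIN_GROUP_SIZE = 4


@dataclass(frozen=True)
class ExpressionMatrix:
    """Molecules x samples table of (already normalized, log-scale) expression.

    Parameters
    ----------
    data
        DataFrame indexed by molecule id with sample ids as columns.
        Values must be finite; both axes must carry unique labels.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ValueError("expression matrix is empty")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate molecule id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at molecule "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        molecule_ids: list[str] | None = None,
        sample_ids: list[str] | None = None,
    ) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        n_mol, n_samp = values.shape
        if molecule_ids is None:
            molecule_ids = [f"gene{i}" for i in range(n_mol)]
        if sample_ids is None:
            sample_ids = [f"sample{j}" for j in range(n_samp)]
        return cls(pd.DataFrame(values, index=molecule_ids, columns=sample_ids))

    @property
    def molecule_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_molecules(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class GroupAssignment:
    """Partition of sample ids into exactly two labeled groups.

    ``group_a`` is the reference condition (e.g. "Normal"); ``group_b`` the
    contrast (e.g. "Tumor"). Each group needs at least four samples so that
    the asymptotic variance denominators M - 3 stay positive.
    """

    labels: dict[str, str]
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("the two group labels must differ")
        seen = set(self.labels.values())
        if seen != {self.group_a, self.group_b}:
            raise ValueError(
                f"sample labels {sorted(seen)} do not match the declared "
                f"groups ({self.group_a!r}, {self.group_b!r})"
            )
        if self.K < MIN_GROUP_SIZE or self.L < MIN_GROUP_SIZE:
            raise ValueError(
                f"each group needs >= {MIN_GROUP_SIZE} samples "
                f"(got K={self.K}, L={self.L}); variance denominators need M - 3 > 0"
            )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, group_a: str | None = None
    ) -> "GroupAssignment":
        """Build from a two-column (sample, group) table.

        ``group_a`` defaults to the group of the first row (the reference).
        """
        if frame.shape[1] < 2:
            raise ValueError("sample description table needs (sample, group) columns")
        samples = frame.iloc[:, 0].astype(str)
        groups = frame.iloc[:, 1].astype(str)
        labels = dict(zip(samples, groups))
        if len(labels) != len(frame):
            raise ValueError("duplicate sample id in the sample description table")
        distinct = list(dict.fromkeys(groups))
        if len(distinct) != 2:
            raise ValueError(f"expected exactly two groups, found {distinct}")
        if group_a is None:
            group_a = distinct[0]
        elif group_a not in distinct:
            raise ValueError(f"group {group_a!r} not present in the table")
        group_b = next(g for g in distinct if g != group_a)
        return cls(labels=labels, group_a=group_a, group_b=group_b)

    @property
    def samples_a(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == self.group_a]

    @property
    def samples_b(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == self.group_b]

    @property
    def K(self) -> int:
        """Size of group_a."""
        return sum(1 for g in self.labels.values() if g == self.group_a)

    @property
    def L(self) -> int:
        """Size of group_b."""
        return sum(1 for g in self.labels.values() if g == self.group_b)

    def swapped(self) -> "GroupAssignment":
        """The same partition with the roles of the two groups exchanged."""
        return GroupAssignment(
            labels=self.labels, group_a=self.group_b, group_b=self.group_a
        )


@dataclass(frozen=True)
class InteractionNetwork:
    """Ordered, directed list of (source, target) molecule pairs to test."""

    pairs: tuple[tuple[str, str], ...]
    directed: bool = field(default=True)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple((str(s), str(t)) for s, t in self.pairs))
        if len(self.pairs) == 0:
            raise ValueError("interaction network is empty")
        if len(set(self.pairs)) != len(self.pairs):
            seen: set[tuple[str, str]] = set()
            for p in self.pairs:
                if p in seen:
                    raise ValueError(f"duplicate interaction pair: {p}")
                seen.add(p)
        for s, t in self.pairs:
            if s == t:
                raise ValueError(f"self-interaction not allowed: {s!r}")

    @classmethod
    def exhaustive(cls, molecule_ids) -> "InteractionNetwork":
        """All unordered molecule pairs, each listed once in index order."""
        ids = list(molecule_ids)
        return cls(tuple(itertools.combinations(ids, 2)))

    @property
    def sources(self) -> list[str]:
        """Distinct source molecules, in order of first appearance."""
        return list(dict.fromkeys(s for s, _ in self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def check_against(self, matrix: ExpressionMatrix) -> None:
        known = set(matrix.molecule_ids)
        for s, t in self.pairs:
            if s not in known:
                raise KeyError(f"network molecule {s!r} missing from the expression matrix")
            if t not in known:
                raise KeyError(f"network molecule {t!r} missing from the expression matrix")
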