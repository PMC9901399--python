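"""Table readers/writers and the run configuration.

All tables are plain tab-separated text with a header row: the expression
table has molecule ids in the first column and sample ids as the header;
the sample description table has (sample, group) columns; the interaction
table has (source, target) columns.  The run configuration is a flat YAML
file of key/value pairs whose keys mirror :class:`RunConfig`; unknown keys
are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .aggregation import run_aggregation
from .containers import ExpressionMatrix, GroupAssignment, InteractionNetwork
from .core import run_ztest
from .permutation import PermutationPlan, min_permutations

__all__ = [
    "RunConfig",
    "read_expression",
    "read_groups",
    "read_network",
    "write_table",
    "run_mode",
    "MODES",
]

logger = logging.getLogger("dconet")

MODES = (
    "network.ztest",
    "exhaustive.ztest",
    "network.hypergeom",
    "exhaustive.hypergeom",
    "network.zscore",
    "exhaustive.zscore",
)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a molecules x samples expression table (TSV, '.' decimal point)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.empty:
        raise ValueError(f"expression table {path} is empty")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isna()
    if bad.to_numpy().any():
        i, j = map(int, next(zip(*bad.to_numpy().nonzero())))
        raise ValueError(
            f"non-numeric expression value {raw.iat[i, j]!r} at molecule "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        i, j = map(int, next(zip(*numeric.isna().to_numpy().nonzero())))
        raise ValueError(
            f"missing expression value at molecule {numeric.index[i]!r}, "
            f"sample {numeric.columns[j]!r} in {path}"
        )
    return ExpressionMatrix(numeric.astype(float))


def read_groups(path: str | Path, group_a: str | None = None) -> GroupAssignment:
    """Read a (sample, group) description table; ``group_a`` defaults to the
    group of the first data row (the reference condition)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return GroupAssignment.from_frame(frame, group_a=group_a)


def read_network(path: str | Path) -> InteractionNetwork:
    """Read a (source, target) interaction table."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"interaction table {path} needs (source, target) columns")
    return InteractionNetwork(tuple(map(tuple, frame.iloc[:, :2].to_numpy())))


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


@dataclass
class RunConfig:
    """Flat run configuration; every field maps to one YAML key."""

    data_path: str
    description_path: str
    output_dir: str
    interaction_path: str | None = None
    correlation: str = "spearman"
    score_kinds: list[str] = field(default_factory=lambda: ["mean"])
    alpha: float = 0.05
    permutations: int | str | None = None  # int, "auto" (= ceil(R/alpha)) or None
    seed: int = 0
    workers: int = 1

    def __post_init__(self) -> None:
        if self.correlation not in ("spearman", "pearson"):
            raise ValueError(f"correlation must be 'spearman' or 'pearson', got {self.correlation!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if isinstance(self.permutations, str) and self.permutations != "auto":
            raise ValueError("permutations must be an integer, 'auto' or omitted")
        if isinstance(self.permutations, int) and self.permutations < 1:
            raise ValueError("permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping of key: value pairs")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        missing = {"data_path", "description_path", "output_dir"} - set(raw)
        if missing:
            raise ValueError(f"missing required config key(s): {sorted(missing)}")
        return cls(**raw)

    def resolve_permutations(self, R: int) -> int:
        if self.permutations in (None, "auto"):
            return min_permutations(R, self.alpha)
        return int(self.permutations)


def run_mode(mode: str, config: RunConfig) -> dict[str, Path]:
    """Execute one usage mode and write its output tables.

    Modes combine a network source (``network`` = the configured interaction
    table; ``exhaustive`` = all molecule pairs of the expression table) with
    an analysis (``ztest`` = pairwise correlation-equality test;
    ``hypergeom`` = pairwise test plus per-source overrepresentation;
    ``zscore`` = pairwise test plus aggregation-score permutation tests).
    Returns the written file paths keyed by table name.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose one of {MODES}")
    regime, analysis = mode.split(".")
    if regime == "network" and config.interaction_path is None:
        raise ValueError("network mode requires interaction_path in the config")
    if regime == "exhaustive" and config.interaction_path is not None:
        raise ValueError("exhaustive mode must not set interaction_path")

    start = time.perf_counter()
    matrix = read_expression(config.data_path)
    groups = read_groups(config.description_path)
    if regime == "network":
        network = read_network(config.interaction_path)
    else:
        network = InteractionNetwork.exhaustive(matrix.molecule_ids)

    R = len(network)
    B = config.resolve_permutations(R)
    logger.info(
        "mode=%s R=%d B=%d alpha=%g seed=%d correlation=%s K=%d L=%d",
        mode, R, B, config.alpha, config.seed, config.correlation, groups.K, groups.L,
    )

    plan = PermutationPlan(
        n_permutations=B, seed=config.seed, alpha=config.alpha,
        n_hypotheses=R, workers=config.workers,
    )
    outputs: dict[str, Path] = {}
    out_dir = Path(config.output_dir)

    if analysis == "ztest":
        pvalue_kind = "analytic" if config.permutations is None else "permutation"
        table = run_ztest(
            matrix, groups, network, kind=config.correlation,
            pvalue_kind=pvalue_kind, plan=plan if pvalue_kind == "permutation" else None,
        )
        outputs["ztest"] = write_table(table, out_dir / f"{mode}.tsv")
    else:
        score_kinds = tuple(config.score_kinds) if analysis == "zscore" else ()
        table = run_aggregation(
            matrix, groups, network, kind=config.correlation,
            alpha=config.alpha, score_kinds=score_kinds, plan=plan,
        )
        outputs[analysis] = write_table(table, out_dir / f"{mode}.tsv")

    logger.info("mode=%s finished in %.2fs", mode, time.perf_counter() - start)
    return outputs
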