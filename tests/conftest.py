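import numpy as np
import pytest
from hypothesis import settings

from dconet import ExpressionMatrix, GroupAssignment, InteractionNetwork

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_null_pairs(n_pairs: int, K: int, L: int, rho: float = 0.0, seed: int = 0):
    """Independent bivariate-normal gene pairs with the SAME correlation in
    both groups (an exact null of the correlation-equality hypothesis)."""
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((2 * n_pairs, K + L))
    for i in range(n_pairs):
        a, b = 2 * i, 2 * i + 1
        raw[b] = rho * raw[a] + np.sqrt(1.0 - rho * rho) * raw[b]
    genes = [f"g{i}" for i in range(2 * n_pairs)]
    samples = [f"N{j}" for j in range(K)] + [f"T{j}" for j in range(L)]
    matrix = ExpressionMatrix.from_arrays(raw, molecule_ids=genes, sample_ids=samples)
    groups = GroupAssignment(
        labels={s: ("Normal" if s.startswith("N") else "Tumor") for s in samples},
        group_a="Normal",
        group_b="Tumor",
    )
    network = InteractionNetwork(
        tuple((genes[2 * i], genes[2 * i + 1]) for i in range(n_pairs))
    )
    return matrix, groups, network


def make_changed_pairs(n_pairs, K, L, rho_a, rho_b, seed=0):
    """Independent pairs with correlation rho_a in group A, rho_b in group B."""
    rng = np.random.default_rng(seed)
    raw_a = rng.standard_normal((2 * n_pairs, K))
    raw_b = rng.standard_normal((2 * n_pairs, L))
    for raw, rho in ((raw_a, rho_a), (raw_b, rho_b)):
        for i in range(n_pairs):
            a, b = 2 * i, 2 * i + 1
            raw[b] = rho * raw[a] + np.sqrt(1.0 - rho * rho) * raw[b]
    genes = [f"g{i}" for i in range(2 * n_pairs)]
    samples = [f"N{j}" for j in range(K)] + [f"T{j}" for j in range(L)]
    matrix = ExpressionMatrix.from_arrays(
        np.hstack([raw_a, raw_b]), molecule_ids=genes, sample_ids=samples
    )
    groups = GroupAssignment(
        labels={s: ("Normal" if s.startswith("N") else "Tumor") for s in samples},
        group_a="Normal",
        group_b="Tumor",
    )
    network = InteractionNetwork(
        tuple((genes[2 * i], genes[2 * i + 1]) for i in range(n_pairs))
    )
    return matrix, groups, network


@pytest.fixture
def small_dataset():
    """A 6-gene, 10+10-sample dataset with one strongly changed pair."""
    return make_changed_pairs(3, 10, 10, rho_a=0.8, rho_b=-0.8, seed=42)
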