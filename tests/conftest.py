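from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from scgnmf import ExpressionMatrix, SolverConfig, planted_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cfg():
    return SolverConfig(seed=0)


@pytest.fixture
def small_expr():
    """3 genes x 3 samples, hand-written values."""
    return ExpressionMatrix(
        values=np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0], [2.0, 8.0, 5.0]]),
        gene_ids=("gA", "gB", "gC"),
        sample_ids=("s1", "s2", "s3"),
    )


@pytest.fixture
def planted_clean():
    """Noise-free planted matrix: 120 genes x 8 samples, 4 classes."""
    return planted_matrix(n=120, m=8, r=4, signal_genes_per_class=20,
                          noise_sigma=0.0, seed=7)


def true_partition(labels: dict[str, int]) -> frozenset[frozenset[str]]:
    classes = set(labels.values())
    return frozenset(
        frozenset(s for s, c in labels.items() if c == k) for k in classes
    )
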