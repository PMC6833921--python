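"""Synthetic expression matrices with planted class structure.

The generator emulates the shape of a small-cohort liver transcriptome
study: a nonnegative gene × sample matrix whose samples fall into r
classes, each class marked by a dedicated block of highly expressed
"signal" genes over a low uniform background, optionally replicated across
groups with controllable replicate fidelity and deliberate outliers. The
planted factors are returned so recovery can be scored exactly.

Default fixture dimensions are 500 genes × 8 samples for fast test runs;
pass ``paper_scale=True`` to :func:`planted_matrix` helpers that need the
full 20093-gene shape for timing studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import ExpressionMatrix

__all__ = ["SyntheticTruth", "planted_matrix", "replicate_groups", "PAPER_SCALE_GENES"]

PAPER_SCALE_GENES = 20093

# background expression level relative to signal-block weights
_BACKGROUND = 0.05
_SIGNAL_LO, _SIGNAL_HI = 0.5, 1.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for a generated matrix."""

    W_true: np.ndarray
    H_true: np.ndarray
    labels: dict[str, int]  # sample -> 1-based class
    noise_sigma: float
    seed: int


def _one_hot_ish_column(rng: np.random.Generator, r: int, cls: int) -> np.ndarray:
    """A column whose dominant class holds ≥ 80% of the mass."""
    col = np.zeros(r)
    dominant = rng.uniform(0.8, 1.0)
    col[cls] = dominant
    if r > 1:
        # off-class mass capped at 10% of the dominant weight so the planted
        # ratio gap is at least 10 — well-separated by construction
        off = rng.random(r - 1)
        off_total = rng.uniform(0.0, 0.1) * dominant
        if off.sum() > 0:
            off = off / off.sum() * off_total
        col[np.arange(r) != cls] = off
    return col


def planted_matrix(
    n: int = 500,
    m: int = 8,
    r: int = 6,
    signal_genes_per_class: int = 30,
    noise_sigma: float = 0.02,
    seed: int = 0,
    paper_scale: bool = False,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a matrix A = max(0, W*H* + Gaussian noise).

    W* has one disjoint block of ``signal_genes_per_class`` high-weight
    genes per class over a uniform low background; H* columns are
    near-one-hot (dominant class ≥ 80% of column mass). Sample j is
    planted in class (j mod r) + 1, so every class is occupied whenever
    r ≤ m. Noise is Gaussian truncated at zero — the pipeline consumes
    min–max-normalized values, so a count model would add nothing.
    """
    if paper_scale:
        n = PAPER_SCALE_GENES
    if r > m:
        raise ValueError(f"r = {r} classes cannot all be occupied by m = {m} samples")
    if signal_genes_per_class * r > n:
        raise ValueError(
            f"{r} blocks of {signal_genes_per_class} signal genes do not fit "
            f"into {n} genes"
        )
    rng = np.random.default_rng(seed)

    W = _BACKGROUND * rng.random((n, r))
    for c in range(r):
        block = slice(c * signal_genes_per_class, (c + 1) * signal_genes_per_class)
        W[block, c] = rng.uniform(_SIGNAL_LO, _SIGNAL_HI, signal_genes_per_class)

    H = np.zeros((r, m))
    labels: dict[str, int] = {}
    sample_ids = tuple(f"s{j + 1}" for j in range(m))
    for j in range(m):
        cls = j % r
        H[:, j] = _one_hot_ish_column(rng, r, cls)
        labels[sample_ids[j]] = cls + 1

    A = W @ H
    if noise_sigma > 0:
        A = A + rng.normal(0.0, noise_sigma, A.shape)
    A = np.maximum(A, 0.0)

    gene_ids = tuple(f"g{i + 1:05d}" for i in range(n))
    x = ExpressionMatrix(values=A, gene_ids=gene_ids, sample_ids=sample_ids)
    truth = SyntheticTruth(
        W_true=W, H_true=H, labels=labels, noise_sigma=noise_sigma, seed=seed
    )
    return x, truth


def replicate_groups(
    base: SyntheticTruth,
    groups: int,
    replicate_corr: float,
    outlier_samples: Sequence[str] = (),
    noise_sigma: float | None = None,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Expand a planted truth into replicate groups of samples.

    Each base sample is replicated once per group under names
    ``"<sample>_g<group>"``. A replicate's coordinate column is the convex
    mix ``replicate_corr * h_true + (1 - replicate_corr) * h_random``, so
    expected cross-replicate correlation rises monotonically with
    ``replicate_corr`` (identical columns at 1). Replicates named in
    ``outlier_samples`` instead receive a fully independent column,
    simulating a detection error in that one measurement.
    """
    if not (0.0 < replicate_corr <= 1.0):
        raise ValueError("replicate_corr must lie in (0, 1]")
    rng = np.random.default_rng(base.seed + 1 if seed is None else seed)
    sigma = base.noise_sigma if noise_sigma is None else noise_sigma
    W = base.W_true
    r, m = base.H_true.shape
    n = W.shape[0]
    base_names = list(base.labels)

    cols = []
    names = []
    group_map: dict[str, str] = {}
    for g in range(groups):
        for j, bname in enumerate(base_names):
            name = f"{bname}_g{g + 1}"
            if name in outlier_samples:
                # detection error: an independent column from a *wrong* class
                wrong = [c for c in range(r) if c != base.labels[bname] - 1]
                h = _one_hot_ish_column(rng, r, int(rng.choice(wrong)))
            else:
                h_rand = _one_hot_ish_column(rng, r, int(rng.integers(r)))
                h = replicate_corr * base.H_true[:, j] + (1 - replicate_corr) * h_rand
            col = W @ h
            if sigma > 0:
                col = col + rng.normal(0.0, sigma, n)
            cols.append(np.maximum(col, 0.0))
            names.append(name)
            group_map[name] = bname

    A = np.column_stack(cols)
    gene_ids = tuple(f"g{i + 1:05d}" for i in range(n))
    return ExpressionMatrix(
        values=A,
        gene_ids=gene_ids,
        sample_ids=tuple(names),
        group_of_sample=group_map,
    )
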