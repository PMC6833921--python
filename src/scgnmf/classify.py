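"""Everything downstream of the factorization.

Membership degrees, hard class assignment, rank selection, sample
correlation, and highly-expressed-gene analysis of the basis matrix.

Class labels carry no meaning across runs: NMF is unique only up to
permutation and scaling of the components, so all cross-run comparisons in
this module (and its tests) are made on *partitions* of the samples, never
on label values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .anls import factorize
from .datamodel import ExpressionMatrix
from .errors import UnassignableSampleError, UndefinedMembershipError
from .scg import SolverConfig

__all__ = [
    "MembershipMatrix",
    "ClassificationResult",
    "RankDiagnostics",
    "membership_matrix",
    "assign_classes",
    "select_rank",
    "sample_correlation",
    "top_genes",
    "shared_genes",
]


@dataclass(frozen=True)
class MembershipMatrix:
    """Class × sample matrix of soft membership degrees.

    Entry (i, j) is the average, over genes with nonzero reconstruction
    for sample j, of the fraction of that gene's reconstructed signal
    attributed to class i. Columns sum to 1.
    """

    R: np.ndarray
    included_gene_count: np.ndarray  # per-sample n' (denominator-valid genes)
    sample_ids: tuple[str, ...] | None = None


@dataclass(frozen=True)
class ClassificationResult:
    """Hard assignment derived from a score matrix (H or R).

    ``assignment`` maps sample -> 1-based class index; ``ratio_gap`` is the
    largest over second-largest column entry (inf when the second-largest
    is zero) — a per-sample measure of how clearly the sample is
    classified.
    """

    assignment: dict[str, int]
    source: Literal["H", "R"]
    ratio_gap: dict[str, float]
    partition: frozenset[frozenset[str]]


def membership_matrix(
    W: np.ndarray,
    H: np.ndarray,
    sample_ids: Sequence[str] | None = None,
) -> MembershipMatrix:
    """Gene-averaged class-share ratios.

    For sample j, each gene g with positive reconstructed signal
    Σ_k W_{g,k} h_{k,j} contributes the share vector
    (W_{g,i} h_{i,j} / Σ_k W_{g,k} h_{k,j})_i; the column of R is the mean
    of these vectors over the n'_j contributing genes, so it sums to 1.
    """
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(W < 0) or np.any(H < 0):
        raise ValueError("membership requires nonnegative factors")
    n, r = W.shape
    m = H.shape[1]
    P = W @ H  # reconstructed signal per gene and sample
    R = np.zeros((r, m))
    counts = np.zeros(m, dtype=int)
    for j in range(m):
        mask = P[:, j] > 0
        nprime = int(mask.sum())
        if nprime == 0:
            name = sample_ids[j] if sample_ids else f"column {j}"
            raise UndefinedMembershipError(
                f"sample {name!r} has zero reconstruction for every gene"
            )
        counts[j] = nprime
        inv = np.zeros(n)
        inv[mask] = 1.0 / P[mask, j]
        # Σ_g W_{g,i} / P_{g,j} collapses the gene average to one matvec
        R[:, j] = H[:, j] * (W.T @ inv) / nprime
    ids = tuple(sample_ids) if sample_ids is not None else None
    return MembershipMatrix(R=R, included_gene_count=counts, sample_ids=ids)


def _column_gap(col: np.ndarray) -> float:
    order = np.sort(col)[::-1]
    top, second = order[0], (order[1] if len(order) > 1 else 0.0)
    if top == 0.0:
        return 0.0
    if second == 0.0:
        return float("inf")
    return float(top / second)


def assign_classes(
    scores: MembershipMatrix | np.ndarray,
    sample_ids: Sequence[str] | None = None,
    source: Literal["H", "R"] | None = None,
) -> ClassificationResult:
    """Argmax assignment per sample column; ties go to the lowest class index."""
    if isinstance(scores, MembershipMatrix):
        mat = scores.R
        sample_ids = sample_ids or scores.sample_ids
        source = source or "R"
    else:
        mat = np.asarray(scores, dtype=float)
        source = source or "H"
    r, m = mat.shape
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(m)]

    assignment: dict[str, int] = {}
    gaps: dict[str, float] = {}
    for j, name in enumerate(sample_ids):
        col = mat[:, j]
        if np.all(col == 0):
            raise UnassignableSampleError(f"sample {name!r} has an all-zero column")
        assignment[name] = int(np.argmax(col)) + 1  # argmax takes the first max
        gaps[name] = _column_gap(col)

    groups: dict[int, set[str]] = {}
    for name, cls in assignment.items():
        groups.setdefault(cls, set()).add(name)
    partition = frozenset(frozenset(g) for g in groups.values())
    return ClassificationResult(
        assignment=assignment, source=source, ratio_gap=gaps, partition=partition
    )


@dataclass
class RankDiagnostics:
    """Per-rank evidence collected by :func:`select_rank`."""

    r: int
    clear_counts: list[int] = field(default_factory=list)  # one per seed
    score: int = 0  # worst clear-sample count across the seed set
    gaps_worst_seed: dict[str, float] = field(default_factory=dict)


def select_rank(
    A: ExpressionMatrix | np.ndarray,
    r_range: Sequence[int],
    cfg: SolverConfig | None = None,
    tau: float = 5.0,
    n_seeds: int = 3,
) -> tuple[int, dict[int, RankDiagnostics], bool]:
    """Trial factorizations over a range of class counts.

    For each candidate rank the matrix is factorized from ``n_seeds``
    deterministic seeds (derived from ``cfg.seed``) and each sample's
    ratio gap is read off the coordinate matrix H. A sample is "clearly
    classified" when its gap is ≥ tau. A rank's score is its *worst*
    clear-sample count over the seed set — the right class count should
    classify clearly from any random start, so a rank that only sometimes
    separates the samples is not trusted. The selected rank maximizes the
    score; ties break toward the largest rank — an under-fitted rank that
    merges true classes can still look stably one-hot, an over-fitted one
    rarely does. Returns (r_star,
    diagnostics, all_separated_flag); the flag is False when no rank
    separates every sample, in which case the choice should be reviewed
    against the full diagnostics.
    """
    if len(r_range) == 0:
        raise ValueError("r_range is empty")
    if tau <= 1.0:
        raise ValueError("tau must exceed 1")
    cfg = cfg or SolverConfig()
    mat = A if isinstance(A, ExpressionMatrix) else np.asarray(A, dtype=float)
    m = mat.n_samples if isinstance(mat, ExpressionMatrix) else mat.shape[1]

    diagnostics: dict[int, RankDiagnostics] = {}
    for r in r_range:
        diag = RankDiagnostics(r=r)
        worst = None
        for s in range(n_seeds):
            run_cfg = SolverConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * s + r})
            model = factorize(mat, r, run_cfg)
            gaps = {}
            for j in range(m):
                col = model.H[:, j]
                name = (
                    mat.sample_ids[j]
                    if isinstance(mat, ExpressionMatrix)
                    else f"s{j + 1}"
                )
                gaps[name] = _column_gap(col)
            count = sum(1 for g in gaps.values() if g >= tau)
            diag.clear_counts.append(count)
            if worst is None or count < worst:
                worst = count
                diag.gaps_worst_seed = gaps
        diag.score = min(diag.clear_counts)
        diagnostics[r] = diag

    best = max(d.score for d in diagnostics.values())
    # ties break toward the largest rank: an under-fitted rank that merges
    # two true classes can still be stably all-clear, while an over-fitted
    # one almost never survives the worst-seed filter
    r_star = max(r for r, d in diagnostics.items() if d.score == best)
    return r_star, diagnostics, best == m


def sample_correlation(
    A: ExpressionMatrix | np.ndarray,
    method: Literal["pearson", "spearman"] = "pearson",
) -> np.ndarray:
    """Correlation matrix between sample columns.

    Symmetric with unit diagonal. Zero-variance columns cannot be
    correlated; their rows/columns are NaN (diagonal entry included) so
    they are visible rather than silently dropped.
    """
    import pandas as pd

    df = (
        A.to_frame()
        if isinstance(A, ExpressionMatrix)
        else pd.DataFrame(np.asarray(A, dtype=float))
    )
    corr = df.corr(method=method).to_numpy()
    zero_var = df.std(ddof=0).to_numpy() == 0
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    return corr


def top_genes(
    W: np.ndarray,
    gene_ids: Sequence[str],
    k: int,
) -> list[list[str]]:
    """Per-class lists of the k most heavily weighted genes.

    Each basis column is scaled to unit maximum first, so proportional
    columns yield identical lists; ties break toward the lower gene index.
    """
    W = np.asarray(W, dtype=float)
    n, r = W.shape
    if k > n:
        raise ValueError(f"k = {k} exceeds the gene count {n}")
    lists: list[list[str]] = []
    for c in range(r):
        col = W[:, c]
        peak = col.max()
        scaled = col / peak if peak > 0 else col
        order = np.argsort(-scaled, kind="stable")[:k]
        lists.append([gene_ids[i] for i in order])
    return lists


def shared_genes(
    lists: Sequence[Sequence[str]],
    classes: Sequence[int],
) -> tuple[int, set[str]]:
    """Intersection of the top-gene lists of the selected classes (1-based)."""
    if len(classes) == 0:
        raise ValueError("classes must be non-empty")
    for c in classes:
        if not (1 <= c <= len(lists)):
            raise ValueError(f"unknown class index {c}; have 1..{len(lists)}")
    shared: set[str] = set(lists[classes[0] - 1])
    for c in classes[1:]:
        shared &= set(lists[c - 1])
    return len(shared), shared
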