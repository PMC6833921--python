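"""Outer alternating nonnegative least squares driver.

Alternates the two convex subproblems — solve for W with H fixed, project
onto the nonnegative orthant, solve for H with W fixed, project — until the
projected-gradient KKT residual falls below epsilon times its value at the
random start. The *relative* criterion (rather than an absolute one) keeps
the stopping test meaningful when the iterates crawl along a curved valley
of the nonconvex landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ExpressionMatrix
from .errors import DegenerateStartError
from .objective import kkt_residual, objective
from .scg import SolverConfig, solve_subproblem

__all__ = ["FactorizationModel", "random_init", "project_nonnegative", "factorize"]

# scale of the uniform noise used to revive a dead class
_RESEED_SCALE = 1e-4


@dataclass
class FactorizationModel:
    """Result of one NMF run.

    W is the gene × class basis (each column a class's expression
    signature), H the class × sample coordinate matrix. Both are
    elementwise nonnegative after the final projection.
    """

    W: np.ndarray
    H: np.ndarray
    r: int
    objective_trace: list[float] = field(default_factory=list)
    kkt_ratio_trace: list[float] = field(default_factory=list)
    seed: int = 0
    converged: bool = False
    outer_iters: int = 0
    reseeded_classes: int = 0
    gene_ids: tuple[str, ...] | None = None
    sample_ids: tuple[str, ...] | None = None
    config: SolverConfig | None = None

    def relative_residual(self, A: np.ndarray) -> float:
        """‖A − WH‖_F / ‖A‖_F for the data the model was fit to."""
        A = A.values if isinstance(A, ExpressionMatrix) else np.asarray(A, float)
        return float(np.linalg.norm(A - self.W @ self.H) / np.linalg.norm(A))


def random_init(
    n: int, m: int, r: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """I.i.d. uniform [0, 1) initial factors; identical seed, identical output."""
    if min(n, m, r) < 1:
        raise ValueError("n, m, r must all be >= 1")
    if r > n * m:
        warnings.warn(
            f"rank {r} exceeds the number of data entries {n * m}; "
            "the factorization is over-parameterized",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    return rng.random((n, r)), rng.random((r, m))


def project_nonnegative(x: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0)."""
    return np.maximum(x, 0.0)


def _revive_dead(X: np.ndarray, axis: int, rng: np.random.Generator) -> int:
    """Re-seed all-zero columns (axis=0) or rows (axis=1) with tiny noise.

    A dead class would make every membership denominator it touches
    degenerate, so it is revived rather than carried along as zeros.
    """
    sums = X.sum(axis=axis)
    dead = np.flatnonzero(sums <= 0.0)
    for idx in dead:
        if axis == 0:
            X[:, idx] = _RESEED_SCALE * rng.random(X.shape[0])
        else:
            X[idx, :] = _RESEED_SCALE * rng.random(X.shape[1])
    return len(dead)


def factorize(
    A: ExpressionMatrix | np.ndarray,
    r: int,
    cfg: SolverConfig | None = None,
) -> FactorizationModel:
    """Run the full alternating scheme on a nonnegative matrix.

    Parameters
    ----------
    A
        ExpressionMatrix (normalized or raw) or a plain nonnegative array.
    r
        Number of classes. For classification use r ≤ number of samples;
        larger values are allowed with a warning.
    cfg
        Solver constants; defaults to the published working values.
    """
    cfg = cfg or SolverConfig()
    gene_ids = sample_ids = None
    if isinstance(A, ExpressionMatrix):
        gene_ids, sample_ids = A.gene_ids, A.sample_ids
        A = A.values
    A = np.asarray(A, dtype=float)
    n, m = A.shape
    if r < 1:
        raise ValueError("rank must be positive")
    if r > m:
        warnings.warn(
            f"rank {r} exceeds the sample count {m}; classes cannot all be "
            "occupied",
            stacklevel=2,
        )

    W, H = random_init(n, m, r, cfg.seed)
    kkt0 = kkt_residual(A, W, H)
    if kkt0 == 0.0:
        raise DegenerateStartError(
            "random start is already a KKT point; re-run with another seed"
        )

    reseed_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    eps_outer = cfg.effective_outer_epsilon
    model = FactorizationModel(
        W=W, H=H, r=r, seed=cfg.seed, gene_ids=gene_ids, sample_ids=sample_ids,
        config=cfg,
    )
    model.objective_trace.append(objective(A, W, H))
    model.kkt_ratio_trace.append(1.0)

    for k in range(cfg.max_outer_iter):
        W_new, _ = solve_subproblem(A, H, W, "W", cfg)
        W = project_nonnegative(W_new)
        model.reseeded_classes += _revive_dead(W, axis=0, rng=reseed_rng)

        H_new, _ = solve_subproblem(A, W, H, "H", cfg)
        H = project_nonnegative(H_new)
        model.reseeded_classes += _revive_dead(H, axis=1, rng=reseed_rng)

        model.objective_trace.append(objective(A, W, H))
        ratio = kkt_residual(A, W, H) / kkt0
        model.kkt_ratio_trace.append(ratio)
        model.outer_iters = k + 1
        if ratio <= eps_outer:
            model.converged = True
            break

    model.W, model.H = W, H
    return model
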