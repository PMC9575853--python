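"""Heterogeneous-network propagation of drug-target interaction scores.

The heterogeneous network couples a drug-drug similarity layer W_dd, a
target-target similarity layer W_tt, and a bipartite layer W_dt0 of known
interactions.  Scores spread by iterating

    W(i+1) = alpha * W_dd @ W(i) @ W_tt + (1 - alpha) * W_dt0

from W(0) = W_dt0.  With both similarity layers normalized so their
spectral radius is at most 1 (see :func:`normalize_similarity`) and
alpha < 1, the update is a contraction and converges to a unique fixed
point; the decay factor alpha balances propagated signal against the
original interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import SimilarityMatrix

__all__ = [
    "PropagationConfig",
    "HeterogeneousNetwork",
    "ScoreMatrix",
    "normalize_similarity",
    "propagate",
    "rank_novel_interactions",
]


@dataclass(frozen=True)
class PropagationConfig:
    """Decay factor and stopping rule for the propagation iteration.

    alpha = 0.1 is the published operating point; tol is measured on the
    maximum absolute entry change between iterations.
    """

    alpha: float = 0.1
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"alpha must be within [0, 1], got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class HeterogeneousNetwork:
    """Drug/target similarity layers plus the known-interaction matrix."""

    drug_ids: list[str]
    target_ids: list[str]
    w_dd: np.ndarray
    w_tt: np.ndarray
    w_dt0: np.ndarray

    def __post_init__(self) -> None:
        m, n = len(self.drug_ids), len(self.target_ids)
        self.w_dd = np.asarray(self.w_dd, dtype=float)
        self.w_tt = np.asarray(self.w_tt, dtype=float)
        self.w_dt0 = np.asarray(self.w_dt0, dtype=float)
        if self.w_dd.shape != (m, m):
            raise ValueError(f"w_dd shape {self.w_dd.shape} != ({m}, {m})")
        if self.w_tt.shape != (n, n):
            raise ValueError(f"w_tt shape {self.w_tt.shape} != ({n}, {n})")
        if self.w_dt0.shape != (m, n):
            raise ValueError(f"w_dt0 shape {self.w_dt0.shape} != ({m}, {n})")
        if not np.isin(self.w_dt0, (0.0, 1.0)).all():
            raise ValueError("w_dt0 entries must be 0 or 1")


@dataclass
class ScoreMatrix:
    """Propagation output with convergence metadata."""

    drug_ids: list[str]
    target_ids: list[str]
    scores: np.ndarray
    iterations_used: int
    converged: bool


def normalize_similarity(values: np.ndarray | SimilarityMatrix) -> np.ndarray:
    """Symmetric degree normalization w(i,j) / sqrt(rowsum_i * rowsum_j).

    This is the normalization that makes the propagation update a
    contraction.  Rows (and matching columns) whose sum is zero — isolated
    entities — are left at zero rather than raising; such entities simply
    neither emit nor receive propagated weight.
    """
    w = values.values if isinstance(values, SimilarityMatrix) else np.asarray(values, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {w.shape}")
    if not np.allclose(w, w.T, atol=1e-9, rtol=0):
        raise ValueError("matrix to normalize must be symmetric")
    if w.size and w.min() < 0:
        raise ValueError(f"matrix to normalize has negative entries (min {w.min()})")
    sums = w.sum(axis=1)
    scale = np.where(sums > 0, np.sqrt(np.where(sums > 0, sums, 1.0)), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(scale > 0, 1.0 / np.where(scale > 0, scale, 1.0), 0.0)
    return w * inv[:, None] * inv[None, :]


def propagate(net: HeterogeneousNetwork, cfg: PropagationConfig | None = None) -> ScoreMatrix:
    """Iterate the propagation update to its fixed point.

    ``net.w_dd`` and ``net.w_tt`` are expected to be already normalized
    (see :func:`normalize_similarity`); without normalization the
    iteration may diverge.  Returns the final scores with the iteration
    count and a convergence flag; non-convergence at ``max_iter`` is
    reported through the flag rather than raised, so callers can decide.
    """
    cfg = cfg or PropagationConfig()
    w0 = net.w_dt0
    w = w0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        w_next = cfg.alpha * (net.w_dd @ w @ net.w_tt) + (1 - cfg.alpha) * w0
        delta = np.abs(w_next - w).max()
        w = w_next
        if delta < cfg.tol:
            converged = True
            break
    return ScoreMatrix(
        drug_ids=net.drug_ids,
        target_ids=net.target_ids,
        scores=w,
        iterations_used=iterations,
        converged=converged,
    )


def rank_novel_interactions(
    scores: ScoreMatrix,
    known: np.ndarray,
    top_k: int | None = None,
    drug_id: str | None = None,
    target_id: str | None = None,
) -> list[tuple[str, str, float]]:
    """Rank candidate (drug, target) pairs that are not already known.

    Pairs with a known interaction are excluded; the rest are sorted by
    score descending with ties broken lexicographically by
    (drug_id, target_id).  ``drug_id`` / ``target_id`` restrict the view
    to one entity (the per-case-study view); ``top_k`` truncates.
    """
    known = np.asarray(known)
    if known.shape != scores.scores.shape:
        raise ValueError(
            f"known-interaction shape {known.shape} does not match scores {scores.scores.shape}"
        )
    rows: list[tuple[str, str, float]] = []
    for i, d in enumerate(scores.drug_ids):
        if drug_id is not None and d != drug_id:
            continue
        for j, t in enumerate(scores.target_ids):
            if target_id is not None and t != target_id:
                continue
            if known[i, j]:
                continue
            rows.append((d, t, float(scores.scores[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    if top_k is not None:
        rows = rows[:top_k]
    return rows
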