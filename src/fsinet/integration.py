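"""Combining multiple similarity matrices into one.

Two linear reducers (elementwise mean and extrema) and similarity network
fusion (SNF) are supported.  Multi-matrix integration follows a sequential
pairwise scheme: the first two matrices are combined, then each further
matrix is folded into the running result.  For MIN/MAX this is equivalent
to a simultaneous reduction; for AVG and SNF the fold is order-dependent
(under AVG, three matrices A, B, C yield A/4 + B/4 + C/2), and the
integration order is the order in which the forward-selection wrapper
accepted the measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import SimilarityMatrix

__all__ = [
    "IntegrationMethod",
    "pairwise_combine",
    "integrate_similarity_set",
    "snf_fuse",
]


@dataclass(frozen=True)
class IntegrationMethod:
    """Named integration function with SNF hyperparameters.

    ``K`` is the neighbourhood size of the kNN kernel and ``t`` the number
    of cross-diffusion iterations; both are only consulted when
    ``name == "SNF"``.  ``K`` is capped at n - 1 at fusion time.
    """

    name: str = "AVG"
    K: int = 20
    t: int = 20

    def __post_init__(self) -> None:
        name = self.name.upper()
        object.__setattr__(self, "name", name)
        if name not in ("AVG", "MIN", "MAX", "SNF"):
            raise ValueError(f"unknown integration method {self.name!r}")
        if self.K < 1:
            raise ValueError("SNF neighbourhood size K must be >= 1")
        if self.t < 1:
            raise ValueError("SNF iteration count t must be >= 1")


def _row_normalize(w: np.ndarray) -> np.ndarray:
    s = w.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return w / s


def _dominate_set(w: np.ndarray, k: int) -> np.ndarray:
    """Keep the K largest entries of each row, renormalized to sum 1."""
    n = w.shape[0]
    k = min(k, n)
    out = np.zeros_like(w)
    idx = np.argsort(w, axis=1)[:, -k:]
    rows = np.arange(n)[:, None]
    out[rows, idx] = w[rows, idx]
    return _row_normalize(out)


def snf_fuse(
    matrices: list[np.ndarray], K: int = 20, t: int = 20, alpha: float = 1.0
) -> np.ndarray:
    """Similarity network fusion of M similarity matrices (raw output).

    Follows the published cross-diffusion scheme: each view m is
    row-normalized into a full transition kernel P(m) and restricted to a
    row-normalized kNN kernel S(m); then for ``t`` iterations each view is
    updated as ``P(m) <- S(m) @ mean_of_other_views @ S(m).T``, with the
    identity re-added (scaled by ``alpha``) and the matrix symmetrized
    after every step.  The fused result is the average of the final views,
    row-normalized and symmetrized with half the identity added — so its
    diagonal is not 1 and its rows sum near 1.  Use
    :func:`pairwise_combine` for a result rescaled back to similarity
    conventions.
    """
    if len(matrices) < 2:
        raise ValueError("SNF needs at least two matrices")
    n = matrices[0].shape[0]
    K = max(1, min(K, n - 1)) if n > 1 else 1
    views = []
    kernels = []
    for w in matrices:
        p = _row_normalize(np.asarray(w, dtype=float))
        p = (p + p.T) / 2.0
        views.append(p)
        kernels.append(_dominate_set(p, K))
    m_views = len(views)
    for _ in range(t):
        total = np.sum(views, axis=0)
        new_views = []
        for p, s in zip(views, kernels):
            others = (total - p) / (m_views - 1)
            p_new = s @ others @ s.T
            p_new = p_new + alpha * np.eye(n)
            new_views.append((p_new + p_new.T) / 2.0)
        views = new_views
    fused = np.sum(views, axis=0) / m_views
    fused = _row_normalize(fused)
    fused = (fused + fused.T + np.eye(n)) / 2.0
    return fused


def _rescale_fused(fused: np.ndarray) -> np.ndarray:
    """Map a raw SNF output back onto similarity conventions.

    Off-diagonal entries are divided by their maximum so the result lives
    in [0, 1]; the diagonal is then reset to 1.
    """
    out = fused.copy()
    n = out.shape[0]
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        top = out[off].max()
        if top > 0:
            out[off] = out[off] / top
    out = np.clip(out, 0.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return out


def pairwise_combine(
    A: SimilarityMatrix, B: SimilarityMatrix, method: IntegrationMethod
) -> SimilarityMatrix:
    """Combine two aligned similarity matrices with one integration step."""
    if not A.aligned_with(B):
        raise ValueError(
            f"matrices {A.measure_name!r} and {B.measure_name!r} are not aligned: "
            f"side {A.side}/{B.side}, {A.n} vs {B.n} entities"
        )
    if method.name == "AVG":
        values = (A.values + B.values) / 2.0
    elif method.name == "MIN":
        values = np.minimum(A.values, B.values)
    elif method.name == "MAX":
        values = np.maximum(A.values, B.values)
    else:  # SNF
        fused = snf_fuse([A.values, B.values], K=method.K, t=method.t)
        values = _rescale_fused(fused)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0
    name = f"{method.name}({A.measure_name},{B.measure_name})"
    return SimilarityMatrix(
        side=A.side,
        entity_ids=A.entity_ids,
        values=values,
        measure_name=name,
        dataset_tag="+".join(sorted({A.dataset_tag, B.dataset_tag} - {""})),
    )


def integrate_similarity_set(
    measures: list[SimilarityMatrix], method: IntegrationMethod
) -> SimilarityMatrix:
    """Fold an ordered list of similarity matrices into one.

    A single matrix is returned unchanged.  Otherwise the matrices are
    combined pairwise left to right, so for order-dependent methods the
    earliest measures are diluted most (AVG) or diffused most (SNF).
    """
    if not measures:
        raise ValueError("cannot integrate an empty set of similarity matrices")
    result = measures[0]
    for nxt in measures[1:]:
        result = pairwise_combine(result, nxt, method)
    return result
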