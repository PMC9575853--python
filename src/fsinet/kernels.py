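"""Similarity kernels for drugs and target proteins.

Every kernel maps a raw input (binary profiles, a confidence-filtered
interaction graph, or protein sequences) to a :class:`~fsinet.types.SimilarityMatrix`.
Conventions shared by all kernels:

* the stored diagonal is always 1 (maximal self-similarity), even when the
  raw transform would give another value at distance zero — the raw
  transform stays separately accessible (:func:`isp_transform`);
* any pairwise index involving an all-zero profile vector is defined as 0
  off-diagonal, so no kernel ever emits NaN.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .types import BinaryProfileSet, ConfidenceGraph, ISPParams, SequenceSet, SimilarityMatrix

__all__ = [
    "tanimoto_similarity",
    "jaccard_similarity",
    "cosine_similarity",
    "isp_transform",
    "isp_similarity",
    "common_neighbor_similarity",
    "AlignmentScoring",
    "alignment_similarity",
    "measure_correlations",
]


def _binary_pairwise(
    matrix: np.ndarray, kind: str
) -> np.ndarray:
    """Pairwise Tanimoto/Jaccard or cosine scores between binary row vectors.

    On binary vectors the Tanimoto coefficient u.v / (|u|^2 + |v|^2 - u.v)
    coincides with the Jaccard index |u & v| / |u | v|; cosine divides the
    intersection by the geometric mean of the support sizes.
    """
    x = matrix.astype(float)
    inner = x @ x.T
    sizes = np.diag(inner)  # |u|^2 == support size for binary vectors
    if kind == "jaccard":
        denom = sizes[:, None] + sizes[None, :] - inner
    elif kind == "cosine":
        denom = np.sqrt(sizes[:, None] * sizes[None, :])
    else:  # pragma: no cover - internal misuse
        raise ValueError(kind)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, inner / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    return sim


def _profile_kernel(
    profiles: BinaryProfileSet,
    kind: str,
    side: str,
    measure_name: str,
    dataset_tag: str,
) -> SimilarityMatrix:
    if profiles.n_entities == 0:
        raise ValueError("profile set contains no entities")
    sim = _binary_pairwise(profiles.matrix, kind)
    return SimilarityMatrix(
        side=side,
        entity_ids=profiles.entity_ids,
        values=sim,
        measure_name=measure_name,
        dataset_tag=dataset_tag,
    )


def tanimoto_similarity(
    profiles: BinaryProfileSet,
    side: str = "drug",
    measure_name: str = "Tanimoto",
    dataset_tag: str = "Structures",
) -> SimilarityMatrix:
    """Tanimoto similarity between binary profile rows.

    ``S(r_i, r_j) = r_i.r_j / (|r_i|^2 + |r_j|^2 - r_i.r_j)``.  On binary
    vectors this is identical to the Jaccard index; the two are exposed
    separately because they carry different names in the measure catalog.
    """
    return _profile_kernel(profiles, "jaccard", side, measure_name, dataset_tag)


def jaccard_similarity(
    profiles: BinaryProfileSet,
    side: str = "drug",
    measure_name: str = "Jaccard",
    dataset_tag: str = "",
) -> SimilarityMatrix:
    """Jaccard index ``u.v / (|u|^2 + |v|^2 - u.v)`` between binary rows."""
    return _profile_kernel(profiles, "jaccard", side, measure_name, dataset_tag)


def cosine_similarity(
    profiles: BinaryProfileSet,
    side: str = "drug",
    measure_name: str = "Cosine",
    dataset_tag: str = "",
) -> SimilarityMatrix:
    """Cosine index ``u.v / (|u| |v|)`` between binary rows."""
    return _profile_kernel(profiles, "cosine", side, measure_name, dataset_tag)


def isp_transform(distance: np.ndarray | float, params: ISPParams) -> np.ndarray | float:
    """Raw inverse-shortest-path transform ``S = A * exp(-b * D)``.

    Note that at D = 0 this returns ``A`` (0.9 with the default
    parameters), not 1; :func:`isp_similarity` stores a unit diagonal on
    top of this transform.
    """
    return params.A * np.exp(-params.b * np.asarray(distance, dtype=float))


def _hop_distances(graph: ConfidenceGraph, min_confidence: float) -> np.ndarray:
    """All-pairs hop-count distances on the confidence-filtered graph.

    Edge weights are uniform, so shortest paths reduce to breadth-first
    search; unreachable pairs come back as +inf.
    """
    adj = graph.adjacency(min_confidence)
    return shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)


def isp_similarity(
    graph: ConfidenceGraph,
    params: ISPParams | None = None,
    side: str = "target",
    measure_name: str = "PPI_ISP",
    dataset_tag: str = "PPI",
) -> SimilarityMatrix:
    """Inverse-shortest-path similarity on a confidence-filtered graph.

    Edges below ``params.min_confidence`` are removed, pairwise hop-count
    distances D are measured on what remains, and similarity is
    ``A * exp(-b * D)``.  Unreachable pairs score 0; the stored diagonal
    is forced to 1.
    """
    params = params or ISPParams()
    dist = _hop_distances(graph, params.min_confidence)
    sim = np.where(np.isfinite(dist), isp_transform(np.where(np.isfinite(dist), dist, 0.0), params), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(
        side=side,
        entity_ids=graph.node_ids,
        values=sim,
        measure_name=measure_name,
        dataset_tag=dataset_tag,
    )


def common_neighbor_similarity(
    graph: ConfidenceGraph,
    index: str = "jaccard",
    min_confidence: float = 0.5,
    side: str = "target",
    measure_name: str | None = None,
    dataset_tag: str = "PPI",
) -> SimilarityMatrix:
    """Neighbourhood-overlap similarity on a confidence-filtered graph.

    Each node is represented by its binary adjacency vector after the
    confidence filter, and the Jaccard or cosine index is applied to those
    vectors (the PPI_Jac / PPI_Cos measures).
    """
    if index not in ("jaccard", "cosine"):
        raise ValueError(f"index must be 'jaccard' or 'cosine', got {index!r}")
    adj = graph.adjacency(min_confidence)
    sim = _binary_pairwise(adj, index)
    if measure_name is None:
        measure_name = "PPI_Jac" if index == "jaccard" else "PPI_Cos"
    return SimilarityMatrix(
        side=side,
        entity_ids=graph.node_ids,
        values=sim,
        measure_name=measure_name,
        dataset_tag=dataset_tag,
    )


class AlignmentScoring:
    """Scoring scheme for pairwise alignment similarity.

    Either a named substitution matrix (default BLOSUM62 with gap open 10
    and gap extend 0.5, the classic protein setting) or simple
    match/mismatch scores for toy alphabets.
    """

    def __init__(
        self,
        substitution_matrix: str | None = "BLOSUM62",
        gap_open: float = 10.0,
        gap_extend: float = 0.5,
        match: float | None = None,
        mismatch: float | None = None,
    ) -> None:
        self.substitution_matrix = substitution_matrix
        self.gap_open = float(gap_open)
        self.gap_extend = float(gap_extend)
        self.match = match
        self.mismatch = mismatch
        if match is not None:
            self.substitution_matrix = None

    def build_aligner(self, mode: str):
        from Bio.Align import PairwiseAligner, substitution_matrices

        aligner = PairwiseAligner()
        aligner.mode = mode
        if self.substitution_matrix is not None:
            aligner.substitution_matrix = substitution_matrices.load(
                self.substitution_matrix
            )
        else:
            aligner.match_score = float(self.match)
            aligner.mismatch_score = float(self.mismatch)
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def alphabet(self) -> str | None:
        if self.substitution_matrix is None:
            return None
        from Bio.Align import substitution_matrices

        return str(substitution_matrices.load(self.substitution_matrix).alphabet)


def alignment_similarity(
    seqs: SequenceSet,
    mode: str = "local",
    scoring: AlignmentScoring | None = None,
    side: str = "target",
    measure_name: str | None = None,
    dataset_tag: str = "Seq",
) -> SimilarityMatrix:
    """Normalized pairwise alignment similarity.

    Raw Smith–Waterman (``mode="local"``) or Needleman–Wunsch
    (``mode="global"``) scores s(a, b) are normalized to
    ``s(a, b) / sqrt(s(a, a) * s(b, b))`` and clamped into [0, 1] (global
    scores can be negative).  Identical sequences score exactly 1.
    """
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")
    scoring = scoring or AlignmentScoring()
    alphabet = scoring.alphabet()
    if alphabet is not None:
        for eid, seq in zip(seqs.entity_ids, seqs.sequences):
            bad = set(seq) - set(alphabet)
            if bad:
                raise ValueError(
                    f"sequence {eid!r} contains residue(s) outside the "
                    f"substitution-matrix alphabet: {sorted(bad)}"
                )
    aligner = scoring.build_aligner(mode)
    n = len(seqs.entity_ids)
    raw = np.zeros((n, n))
    for i in range(n):
        raw[i, i] = aligner.score(seqs.sequences[i], seqs.sequences[i])
        for j in range(i + 1, n):
            raw[i, j] = raw[j, i] = aligner.score(seqs.sequences[i], seqs.sequences[j])
    self_scores = np.diag(raw).copy()
    if np.any(self_scores <= 0):
        bad = seqs.entity_ids[int(np.argmin(self_scores))]
        raise ValueError(f"non-positive self-alignment score for {bad!r}")
    denom = np.sqrt(self_scores[:, None] * self_scores[None, :])
    sim = np.clip(raw / denom, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2.0
    if measure_name is None:
        measure_name = "Seq_Loc" if mode == "local" else "Seq_Glo"
    return SimilarityMatrix(
        side=side,
        entity_ids=seqs.entity_ids,
        values=sim,
        measure_name=measure_name,
        dataset_tag=dataset_tag,
    )


def measure_correlations(
    matrices: list[SimilarityMatrix],
) -> np.ndarray:
    """Pearson correlations between similarity measures on one side.

    Each matrix is vectorized over its strict upper triangle (the diagonal
    carries no information — it is 1 by construction) and correlated with
    every other.  A measure whose off-diagonal values are constant has an
    undefined correlation, reported as NaN.
    """
    if not matrices:
        raise ValueError("need at least one similarity matrix")
    ids = matrices[0].entity_ids
    for m in matrices[1:]:
        if m.entity_ids != ids:
            raise ValueError(
                f"matrix {m.measure_name!r} is not aligned with {matrices[0].measure_name!r}"
            )
    iu = np.triu_indices(len(ids), k=1)
    vecs = np.array([m.values[iu] for m in matrices])
    p = len(matrices)
    rho = np.full((p, p), np.nan)
    sd = vecs.std(axis=1)
    for i in range(p):
        for j in range(p):
            if sd[i] == 0 or sd[j] == 0:
                continue  # constant measure: correlation undefined, stays NaN
            rho[i, j] = np.corrcoef(vecs[i], vecs[j])[0, 1]
    return rho
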