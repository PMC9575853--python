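"""Core data containers shared by every stage of the pipeline.

The central object is :class:`SimilarityMatrix`: a labelled, symmetric,
square matrix of pairwise scores in [0, 1] for one entity side (drugs or
target proteins), tagged with the measure that produced it and the
underlying data source.  The raw inputs those measures consume — binary
association profiles, a confidence-weighted interaction graph, and protein
sequences — get thin validated containers of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryProfileSet",
    "ConfidenceGraph",
    "SequenceSet",
    "SimilarityMatrix",
    "ISPParams",
]

#: Tolerance under which a matrix is accepted as symmetric without comment.
SYMMETRY_ATOL = 1e-12


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} must be unique")


@dataclass
class BinaryProfileSet:
    """Entity-by-feature binary incidence table.

    A value of one marks an existing association between an entity (a drug
    or a target protein) and a feature (a fingerprint bit, a disease, an
    interacting drug, a side effect, a pathway, ...).
    """

    entity_ids: list[str]
    feature_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.entity_ids = list(self.entity_ids)
        self.feature_ids = list(self.feature_ids)
        _check_unique(self.entity_ids, "entity_ids")
        _check_unique(self.feature_ids, "feature_ids")
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.entity_ids), len(self.feature_ids)):
            raise ValueError(
                f"profile matrix shape {self.matrix.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.feature_ids)} features"
            )
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("profile matrix entries must be 0 or 1")
        self.matrix = self.matrix.astype(np.int8, copy=False)

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)


@dataclass
class ConfidenceGraph:
    """Undirected graph with per-edge confidence scores in [0, 1].

    Models a protein–protein interaction network in which each edge carries
    a score indicating how likely the interaction is to be real.  Each pair
    is stored once; self-loops are rejected.
    """

    node_ids: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        _check_unique(self.node_ids, "node_ids")
        known = set(self.node_ids)
        seen: set[frozenset[str]] = set()
        cleaned = []
        for a, b, conf in self.edges:
            if a not in known or b not in known:
                missing = a if a not in known else b
                raise ValueError(f"edge references unknown node {missing!r}")
            if a == b:
                raise ValueError(f"self-loop on node {a!r} is not allowed")
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"confidence {conf} for edge ({a}, {b}) outside [0, 1]")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"edge ({a}, {b}) stored more than once")
            seen.add(key)
            cleaned.append((a, b, float(conf)))
        self.edges = cleaned

    def adjacency(self, min_confidence: float = 0.0) -> np.ndarray:
        """Binary adjacency matrix keeping edges with confidence >= threshold."""
        index = {n: i for i, n in enumerate(self.node_ids)}
        adj = np.zeros((len(self.node_ids),) * 2, dtype=np.int8)
        for a, b, conf in self.edges:
            if conf >= min_confidence:
                i, j = index[a], index[b]
                adj[i, j] = adj[j, i] = 1
        return adj


@dataclass
class SequenceSet:
    """Named residue sequences (protein by default)."""

    entity_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        self.entity_ids = list(self.entity_ids)
        self.sequences = [str(s) for s in self.sequences]
        _check_unique(self.entity_ids, "entity_ids")
        if len(self.entity_ids) != len(self.sequences):
            raise ValueError("entity_ids and sequences must have equal length")
        for eid, seq in zip(self.entity_ids, self.sequences):
            if not seq:
                raise ValueError(f"sequence for {eid!r} is empty")


@dataclass
class SimilarityMatrix:
    """Labelled symmetric pairwise-similarity matrix with unit diagonal.

    Parameters
    ----------
    side:
        ``"drug"`` or ``"target"`` — which half of the heterogeneous
        network the matrix belongs to.
    entity_ids:
        Row/column labels, in order.
    values:
        Square array of scores in [0, 1], symmetric, diagonal equal to 1.
    measure_name:
        Name of the similarity measure (e.g. ``DDA_Jac``, ``Seq_Loc``).
    dataset_tag:
        The underlying data source (e.g. ``DDA``, ``PPI``).  Two measures
        sharing a tag are never integrated together when the same-dataset
        exclusion rule is active.
    """

    side: str
    entity_ids: list[str]
    values: np.ndarray
    measure_name: str = ""
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("drug", "target"):
            raise ValueError(f"side must be 'drug' or 'target', got {self.side!r}")
        self.entity_ids = list(self.entity_ids)
        _check_unique(self.entity_ids, "entity_ids")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} entities"
            )
        self.validate()

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=SYMMETRY_ATOL, rtol=0):
            raise ValueError(f"matrix for {self.measure_name!r} is not symmetric")
        if v.size and (v.min() < -SYMMETRY_ATOL or v.max() > 1 + SYMMETRY_ATOL):
            raise ValueError(
                f"matrix for {self.measure_name!r} has values outside [0, 1]: "
                f"range [{v.min()}, {v.max()}]"
            )
        if not np.allclose(np.diag(v), 1.0, atol=SYMMETRY_ATOL):
            raise ValueError(f"matrix for {self.measure_name!r} diagonal is not 1")

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def aligned_with(self, other: "SimilarityMatrix") -> bool:
        return self.side == other.side and self.entity_ids == other.entity_ids

    def with_values(
        self, values: np.ndarray, measure_name: str | None = None
    ) -> "SimilarityMatrix":
        """Copy carrying new values (and optionally a new measure name)."""
        return SimilarityMatrix(
            side=self.side,
            entity_ids=self.entity_ids,
            values=values,
            measure_name=self.measure_name if measure_name is None else measure_name,
            dataset_tag=self.dataset_tag,
        )


@dataclass
class ISPParams:
    """Parameters of the inverse-shortest-path transform ``S = A * exp(-b*D)``.

    ``A`` is the amplitude (value at distance zero), ``b`` the decay rate
    per hop, and ``min_confidence`` the edge-confidence filter applied to
    the interaction graph before distances are measured.  Defaults follow
    the published choice A = 0.9, b = 1 with a 0.5 confidence cutoff.
    """

    A: float = 0.9
    b: float = 1.0
    min_confidence: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.A <= 1:
            raise ValueError(f"A must be in (0, 1], got {self.A}")
        if self.b <= 0:
            raise ValueError(f"b must be positive, got {self.b}")
        if not 0 <= self.min_confidence <= 1:
            raise ValueError(
                f"min_confidence must be in [0, 1], got {self.min_confidence}"
            )
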