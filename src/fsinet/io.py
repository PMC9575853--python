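"""Readers and writers for the pipeline's on-disk formats.

Everything tabular is tab-separated UTF-8 with a header row; sequences are
FASTA; manifests, configs and reports are JSON.  The catalog builder
dispatches each manifest entry to the matching similarity kernel (or the
matrix reader for precomputed measures) and aligns every resulting matrix
onto the entity universe of the interaction list: entities missing from a
source keep a zero profile, so their off-diagonal similarities are zero
and the diagonal stays 1.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import kernels
from .selection import SimilarityCatalog
from .types import BinaryProfileSet, ConfidenceGraph, ISPParams, SequenceSet, SimilarityMatrix

logger = logging.getLogger("fsinet")

__all__ = [
    "read_dti_edges",
    "read_profiles",
    "read_ppi",
    "read_fasta",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "describe",
    "CatalogEntry",
    "CatalogManifest",
    "build_catalog",
    "read_bundle",
    "file_checksum",
]

PROFILE_METHODS = {"tanimoto", "jaccard", "cosine"}
GRAPH_METHODS = {"isp", "cn_jaccard", "cn_cosine"}
SEQUENCE_METHODS = {"align_local", "align_global"}


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_dti_edges(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a known-interaction edge list into ids and a binary matrix.

    The file is a two-column TSV (drug id, target id) with a header line.
    Duplicate edges collapse to a single 1 with a warning; a malformed row
    raises with its line number; a file holding only the header raises.
    """
    drug_ids: list[str] = []
    target_ids: list[str] = []
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1 or not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            d, t = parts
            if (d, t) in seen:
                warnings.warn(f"{path}: duplicate edge ({d}, {t}) collapsed")
                continue
            seen.add((d, t))
            pairs.append((d, t))
            if d not in drug_ids:
                drug_ids.append(d)
            if t not in target_ids:
                target_ids.append(t)
    if not pairs:
        raise ValueError(f"{path}: no interaction rows found after the header")
    di = {d: i for i, d in enumerate(drug_ids)}
    ti = {t: j for j, t in enumerate(target_ids)}
    w = np.zeros((len(drug_ids), len(target_ids)), dtype=np.int8)
    for d, t in pairs:
        w[di[d], ti[t]] = 1
    return drug_ids, target_ids, w


def read_profiles(
    path: str | Path,
    entity_ids: list[str] | None = None,
    feature_ids: list[str] | None = None,
) -> BinaryProfileSet:
    """Read a long-form (entity, feature) association TSV.

    The universes default to the ids seen in the file, in order of first
    appearance; pass explicit lists to pin them (needed to retain all-zero
    entities).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    ents = list(df.iloc[:, 0])
    feats = list(df.iloc[:, 1])
    if entity_ids is None:
        entity_ids = list(dict.fromkeys(ents))
    if feature_ids is None:
        feature_ids = list(dict.fromkeys(feats))
    ei = {e: i for i, e in enumerate(entity_ids)}
    fi = {f: j for j, f in enumerate(feature_ids)}
    mat = np.zeros((len(entity_ids), len(feature_ids)), dtype=np.int8)
    for e, f in zip(ents, feats):
        if e in ei and f in fi:
            mat[ei[e], fi[f]] = 1
    return BinaryProfileSet(entity_ids=entity_ids, feature_ids=feature_ids, matrix=mat)


def read_ppi(path: str | Path) -> ConfidenceGraph:
    """Read a weighted interaction edge list (a, b, confidence).

    Confidences may be floats in [0, 1] or integers in [0, 1000] (the
    latter are divided by 1000, covering the STRING score dialect).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected three tab-separated columns")
    edges = []
    nodes: list[str] = []
    for a, b, conf in df.itertuples(index=False):
        conf = float(conf)
        if conf > 1.0:
            if not 0 <= conf <= 1000:
                raise ValueError(f"{path}: confidence {conf} outside [0, 1] and [0, 1000]")
            conf /= 1000.0
        for n in (a, b):
            if n not in nodes:
                nodes.append(n)
        edges.append((a, b, conf))
    return ConfidenceGraph(node_ids=nodes, edges=edges)


def read_fasta(path: str | Path) -> SequenceSet:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return SequenceSet(
        entity_ids=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
    )


def write_similarity_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Write a full symmetric similarity matrix as TSV with id headers."""
    df = pd.DataFrame(matrix.values, index=matrix.entity_ids, columns=matrix.entity_ids)
    df.to_csv(path, sep="\t", index_label="")


def read_similarity_matrix(
    path: str | Path,
    side: str,
    measure_name: str = "",
    dataset_tag: str = "",
) -> SimilarityMatrix:
    """Read a square similarity-matrix TSV with matching id headers.

    Row and column ids must agree; values must be in [0, 1] (an offending
    cell is named in the error).  Asymmetry up to 1e-9 is repaired by
    averaging with a warning; anything larger raises.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise ValueError(f"{path}: row ids and column ids differ")
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square: {values.shape}")
    bad = np.argwhere((values < 0) | (values > 1))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"{path}: value {values[i, j]} at ({row_ids[i]}, {col_ids[j]}) outside [0, 1]"
        )
    gap = np.abs(values - values.T).max() if values.size else 0.0
    if gap > 1e-9:
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance (max gap {gap:.3g})")
    if gap > 1e-12:
        warnings.warn(f"{path}: symmetrized matrix (max asymmetry {gap:.3g})")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        side=side,
        entity_ids=row_ids,
        values=values,
        measure_name=measure_name or Path(path).stem,
        dataset_tag=dataset_tag,
    )


def describe(drug_ids: list[str], target_ids: list[str], w_dt0: np.ndarray) -> dict:
    """Summary statistics of the drug-target bipartite network.

    Reports entity counts, the number of known interactions, their density
    as a percentage (4 decimals), per-side mean and maximum degrees, the
    fraction of entities with degree below 5, and degree histograms.
    """
    w = np.asarray(w_dt0)
    m, n = len(drug_ids), len(target_ids)
    positives = int(w.sum())
    possible = m * n
    density_pct = round(100.0 * positives / possible, 4) if possible else 0.0
    drug_deg = w.sum(axis=1)
    target_deg = w.sum(axis=0)

    def side_stats(deg: np.ndarray) -> dict:
        values, counts = np.unique(deg.astype(int), return_counts=True)
        return {
            "mean_degree": float(deg.mean()) if deg.size else 0.0,
            "max_degree": int(deg.max()) if deg.size else 0,
            "frac_degree_lt_5": float((deg < 5).mean()) if deg.size else 0.0,
            "degree_histogram": {int(v): int(c) for v, c in zip(values, counts)},
        }

    return {
        "n_drugs": m,
        "n_targets": n,
        "n_interactions": positives,
        "density_pct": density_pct,
        "drugs": side_stats(drug_deg),
        "targets": side_stats(target_deg),
    }


@dataclass
class CatalogEntry:
    """One manifest line: how to build one similarity measure."""

    name: str
    side: str
    dataset_tag: str
    source: str  # profiles | graph | sequences | precomputed
    path: str
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = {
            "profiles": PROFILE_METHODS,
            "graph": GRAPH_METHODS,
            "sequences": SEQUENCE_METHODS,
            "precomputed": {"precomputed"},
        }
        if self.source not in valid:
            raise ValueError(f"unknown source kind {self.source!r} for measure {self.name!r}")
        if self.method not in valid[self.source]:
            raise ValueError(
                f"method {self.method!r} is not valid for source {self.source!r} "
                f"(measure {self.name!r})"
            )


@dataclass
class CatalogManifest:
    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("manifest measure names must be unique")

    @classmethod
    def from_json(cls, path: str | Path) -> "CatalogManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(entries=[CatalogEntry(**e) for e in payload["measures"]])


def _expand_to_universe(matrix: SimilarityMatrix, universe: list[str]) -> SimilarityMatrix:
    """Align a similarity matrix onto the full entity universe.

    Entities absent from the source get zero off-diagonal similarity and a
    unit diagonal (degenerate-profile rule); source entities outside the
    universe are dropped.
    """
    if matrix.entity_ids == universe:
        return matrix
    missing = [e for e in universe if e not in set(matrix.entity_ids)]
    if missing:
        logger.warning(
            "measure %s: %d entities absent from source, zero-filled (e.g. %s)",
            matrix.measure_name, len(missing), missing[0],
        )
    pos = {e: i for i, e in enumerate(matrix.entity_ids)}
    n = len(universe)
    values = np.zeros((n, n))
    idx = [(i, pos[e]) for i, e in enumerate(universe) if e in pos]
    rows = [i for i, _ in idx]
    cols = [j for _, j in idx]
    values[np.ix_(rows, rows)] = matrix.values[np.ix_(cols, cols)]
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        side=matrix.side,
        entity_ids=universe,
        values=values,
        measure_name=matrix.measure_name,
        dataset_tag=matrix.dataset_tag,
    )


def build_catalog(
    manifest: CatalogManifest,
    drug_ids: list[str],
    target_ids: list[str],
    base_dir: str | Path = ".",
    intersect: bool = False,
) -> SimilarityCatalog:
    """Build every manifest measure and align it to the entity universe.

    ``intersect=True`` restricts the universe on each side to entities
    present in every source (the stricter protocol of dropping entities
    that any dataset lacks); the default keeps all interaction-list
    entities with zero-filled similarities where a source lacks them.
    """
    base_dir = Path(base_dir)
    if set(drug_ids) & set(target_ids):
        raise ValueError("drug and target id universes overlap")
    built: list[SimilarityMatrix] = []
    for entry in manifest.entries:
        path = base_dir / entry.path
        universe = drug_ids if entry.side == "drug" else target_ids
        if entry.source == "profiles":
            profiles = read_profiles(path)
            keep = [e for e in profiles.entity_ids if e in set(universe)]
            profiles = BinaryProfileSet(
                entity_ids=keep,
                feature_ids=profiles.feature_ids,
                matrix=profiles.matrix[[profiles.entity_ids.index(e) for e in keep]],
            )
            fn = getattr(kernels, f"{entry.method}_similarity")
            matrix = fn(
                profiles, side=entry.side, measure_name=entry.name, dataset_tag=entry.dataset_tag
            )
        elif entry.source == "graph":
            graph = read_ppi(path)
            params = ISPParams(**entry.params) if entry.params else ISPParams()
            if entry.method == "isp":
                matrix = kernels.isp_similarity(
                    graph, params, side=entry.side,
                    measure_name=entry.name, dataset_tag=entry.dataset_tag,
                )
            else:
                matrix = kernels.common_neighbor_similarity(
                    graph,
                    index=entry.method.removeprefix("cn_"),
                    min_confidence=params.min_confidence,
                    side=entry.side,
                    measure_name=entry.name,
                    dataset_tag=entry.dataset_tag,
                )
        elif entry.source == "sequences":
            seqs = read_fasta(path)
            keep = [i for i, e in enumerate(seqs.entity_ids) if e in set(universe)]
            seqs = SequenceSet(
                entity_ids=[seqs.entity_ids[i] for i in keep],
                sequences=[seqs.sequences[i] for i in keep],
            )
            scoring = kernels.AlignmentScoring(**entry.params) if entry.params else None
            matrix = kernels.alignment_similarity(
                seqs,
                mode=entry.method.removeprefix("align_"),
                scoring=scoring,
                side=entry.side,
                measure_name=entry.name,
                dataset_tag=entry.dataset_tag,
            )
        else:  # precomputed
            matrix = read_similarity_matrix(
                path, side=entry.side, measure_name=entry.name, dataset_tag=entry.dataset_tag
            )
        built.append(matrix)

    if intersect:
        for side, universe in (("drug", drug_ids), ("target", target_ids)):
            present = [set(m.entity_ids) for m in built if m.side == side]
            if present:
                common = set.intersection(*present) & set(universe)
                if side == "drug":
                    drug_ids = [e for e in drug_ids if e in common]
                else:
                    target_ids = [e for e in target_ids if e in common]

    catalog = SimilarityCatalog()
    for matrix in built:
        universe = drug_ids if matrix.side == "drug" else target_ids
        if intersect:
            keep = [e for e in matrix.entity_ids if e in set(universe)]
            pos = {e: i for i, e in enumerate(matrix.entity_ids)}
            sel = [pos[e] for e in universe]
            matrix = SimilarityMatrix(
                side=matrix.side,
                entity_ids=universe,
                values=matrix.values[np.ix_(sel, sel)],
                measure_name=matrix.measure_name,
                dataset_tag=matrix.dataset_tag,
            )
        else:
            matrix = _expand_to_universe(matrix, universe)
        catalog.add(matrix)
    return catalog


def read_bundle(directory: str | Path) -> dict:
    """Read back everything :func:`fsinet.synthetic.write_bundle` wrote.

    Returns a dict of components keyed like the bundle's fields; the
    metadata JSON pins the entity and feature universes so all-zero
    profile rows survive the round trip.
    """
    directory = Path(directory)
    with open(directory / "bundle_meta.json") as fh:
        meta = json.load(fh)
    manifest = CatalogManifest.from_json(directory / "manifest.json")
    drug_ids, target_ids = meta["drug_ids"], meta["target_ids"]
    # re-embed the edge-list matrix into the full universe
    d_seen, t_seen, w_seen = read_dti_edges(directory / "dti.tsv")
    w = np.zeros((len(drug_ids), len(target_ids)), dtype=np.int8)
    di = {d: i for i, d in enumerate(drug_ids)}
    ti = {t: j for j, t in enumerate(target_ids)}
    for a, d in enumerate(d_seen):
        for b, t in enumerate(t_seen):
            if w_seen[a, b]:
                w[di[d], ti[t]] = 1
    profiles = {}
    precomputed = {}
    for entry in manifest.entries:
        if entry.source == "profiles" and entry.dataset_tag not in profiles:
            universe = drug_ids if entry.side == "drug" else target_ids
            profiles[entry.dataset_tag] = read_profiles(
                directory / entry.path,
                entity_ids=universe,
                feature_ids=meta["feature_ids"][entry.dataset_tag],
            )
        elif entry.source == "precomputed":
            precomputed[entry.name] = read_similarity_matrix(
                directory / entry.path, side=entry.side,
                measure_name=entry.name, dataset_tag=entry.dataset_tag,
            )
    return {
        "drug_ids": drug_ids,
        "target_ids": target_ids,
        "drug_classes": np.array(meta["drug_classes"]),
        "target_classes": np.array(meta["target_classes"]),
        "profiles": profiles,
        "ppi": read_ppi(directory / "ppi.tsv"),
        "sequences": read_fasta(directory / "sequences.fasta"),
        "precomputed": precomputed,
        "dti": w,
        "manifest": manifest,
    }
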