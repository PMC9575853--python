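"""Synthetic drug-target data with planted, tunable class structure.

The generator emulates every input the pipeline consumes — binary
association profiles, a confidence-weighted interaction graph, protein
sequences, precomputed similarity matrices, and a known-interaction list —
without any external downloads.  Drugs and targets are partitioned into
latent classes; interactions are sampled from a class-compatibility
matrix, and each data source is informative about the classes to a
controllable degree:

* profile datasets draw each entity's bits from its class prototype with
  probability ``informativeness`` and i.i.d. noise otherwise, followed by
  a small flip noise;
* the interaction graph places a tunable fraction of class-consistent
  edges (confidence above the 0.5 filter) among random edges whose
  confidence is uniform on [0, 1];
* sequences are mutated copies of class-ancestor strings, fully random at
  informativeness 0;
* the "precomputed" matrices blend a class-block similarity with
  symmetric uniform noise (synthetic stand-ins for externally computed
  semantic-similarity matrices such as GO-based ones).

At informativeness 0 every source is pure noise, so downstream
cross-validated AUC sits at chance; at high informativeness the planted
interactions are recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import kernels
from .selection import SimilarityCatalog
from .types import BinaryProfileSet, ConfidenceGraph, ISPParams, SequenceSet, SimilarityMatrix

__all__ = ["SyntheticSpec", "SyntheticBundle", "generate", "write_bundle", "default_catalog"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: drug-side profile datasets and the measures computed from each
DRUG_MEASURES = {
    "Structures": [("Structures", "tanimoto")],
    "DDA": [("DDA_Jac", "jaccard"), ("DDA_Cos", "cosine")],
    "DDI": [("DDI_Jac", "jaccard"), ("DDI_Cos", "cosine")],
    "SE": [("SE_Jac", "jaccard"), ("SE_Cos", "cosine")],
}
#: target-side measures: two alignment modes, three graph measures,
#: two precomputed matrices, two pathway-profile measures
TARGET_PROFILE_MEASURES = {"PW": [("PW_Jac", "jaccard"), ("PW_Cos", "cosine")]}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults are desk scale: 60 drugs x 80 targets in four classes each,
    about 300 planted interactions, so a full forward-selection run
    completes in seconds.
    """

    n_drugs: int = 60
    n_targets: int = 80
    n_drug_classes: int = 4
    n_target_classes: int = 4
    compatibility: np.ndarray | None = None
    p_within: float = 0.22
    p_between: float = 0.01
    informativeness: dict[str, float] = field(
        default_factory=lambda: {
            "Structures": 0.9,
            "DDA": 0.8,
            "DDI": 0.7,
            "SE": 0.6,
            "Seq": 0.9,
            "PPI": 0.7,
            "GO": 0.6,
            "PW": 0.6,
        }
    )
    n_features: dict[str, int] = field(
        default_factory=lambda: {"Structures": 128, "DDA": 100, "DDI": 80, "SE": 90, "PW": 60}
    )
    prototype_density: float = 0.2
    flip_rate: float = 0.02
    sequence_length: int = 80
    mutation_rate: float = 0.08
    ppi_within: float = 0.30
    ppi_between: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drug_classes > self.n_drugs:
            raise ValueError("more drug classes than drugs")
        if self.n_target_classes > self.n_targets:
            raise ValueError("more target classes than targets")
        for tag, gamma in self.informativeness.items():
            if not 0 <= gamma <= 1:
                raise ValueError(f"informativeness[{tag!r}] = {gamma} outside [0, 1]")
        if self.compatibility is None:
            compat = np.full((self.n_drug_classes, self.n_target_classes), self.p_between)
            for c in range(self.n_drug_classes):
                compat[c, c % self.n_target_classes] = self.p_within
            self.compatibility = compat
        else:
            self.compatibility = np.asarray(self.compatibility, dtype=float)
            if self.compatibility.shape != (self.n_drug_classes, self.n_target_classes):
                raise ValueError("compatibility matrix shape does not match class counts")
            if self.compatibility.min() < 0 or self.compatibility.max() > 1:
                raise ValueError("compatibility entries must be probabilities")


@dataclass
class SyntheticBundle:
    """Everything :func:`generate` produces, with ground truth attached."""

    spec: SyntheticSpec
    drug_ids: list[str]
    target_ids: list[str]
    drug_classes: np.ndarray
    target_classes: np.ndarray
    profiles: dict[str, BinaryProfileSet]
    ppi: ConfidenceGraph
    sequences: SequenceSet
    precomputed: dict[str, SimilarityMatrix]
    dti: np.ndarray


def _profile_dataset(
    rng: np.random.Generator,
    entity_ids: list[str],
    classes: np.ndarray,
    n_classes: int,
    n_features: int,
    informativeness: float,
    density: float,
    flip_rate: float,
    tag: str,
) -> BinaryProfileSet:
    prototypes = (rng.random((n_classes, n_features)) < density).astype(np.int8)
    take_proto = rng.random((len(entity_ids), n_features)) < informativeness
    noise = (rng.random((len(entity_ids), n_features)) < density).astype(np.int8)
    mat = np.where(take_proto, prototypes[classes], noise)
    flips = rng.random(mat.shape) < flip_rate
    mat = np.where(flips, 1 - mat, mat).astype(np.int8)
    return BinaryProfileSet(
        entity_ids=entity_ids,
        feature_ids=[f"{tag.lower()}_f{j}" for j in range(n_features)],
        matrix=mat,
    )


def _block_matrix(
    rng: np.random.Generator,
    entity_ids: list[str],
    classes: np.ndarray,
    informativeness: float,
    name: str,
    side: str,
    tag: str,
) -> SimilarityMatrix:
    """Synthetic precomputed similarity: class blocks blended with noise."""
    n = len(entity_ids)
    block = np.where(classes[:, None] == classes[None, :], 0.9, 0.2)
    raw = rng.random((n, n))
    noise = (raw + raw.T) / 2.0
    values = np.clip(informativeness * block + (1 - informativeness) * noise, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        side=side, entity_ids=entity_ids, values=values, measure_name=name, dataset_tag=tag
    )


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Sample one fully consistent synthetic bundle (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    drug_ids = [f"D{i:04d}" for i in range(spec.n_drugs)]
    target_ids = [f"T{j:04d}" for j in range(spec.n_targets)]
    drug_classes = np.arange(spec.n_drugs) % spec.n_drug_classes
    target_classes = np.arange(spec.n_targets) % spec.n_target_classes

    dti = (
        rng.random((spec.n_drugs, spec.n_targets))
        < spec.compatibility[drug_classes][:, target_classes]
    ).astype(np.int8)

    gamma = spec.informativeness
    profiles: dict[str, BinaryProfileSet] = {}
    for tag in ("Structures", "DDA", "DDI", "SE"):
        profiles[tag] = _profile_dataset(
            rng, drug_ids, drug_classes, spec.n_drug_classes, spec.n_features[tag],
            gamma.get(tag, 0.0), spec.prototype_density, spec.flip_rate, tag,
        )
    profiles["PW"] = _profile_dataset(
        rng, target_ids, target_classes, spec.n_target_classes, spec.n_features["PW"],
        gamma.get("PW", 0.0), spec.prototype_density, spec.flip_rate, "PW",
    )

    # interaction graph: class-consistent edges carry confidence >= 0.5,
    # stray edges draw uniform confidences so some fall below the filter
    g = gamma.get("PPI", 0.0)
    p_within = spec.ppi_between + g * (spec.ppi_within - spec.ppi_between)
    edges: list[tuple[str, str, float]] = []
    for i in range(spec.n_targets):
        for j in range(i + 1, spec.n_targets):
            same = target_classes[i] == target_classes[j]
            if same and rng.random() < p_within:
                edges.append((target_ids[i], target_ids[j], float(rng.uniform(0.5, 1.0))))
            elif rng.random() < spec.ppi_between:
                edges.append((target_ids[i], target_ids[j], float(rng.uniform(0.0, 1.0))))
    ppi = ConfidenceGraph(node_ids=target_ids, edges=edges)

    g_seq = gamma.get("Seq", 0.0)
    p_mut = 1.0 - g_seq * (1.0 - spec.mutation_rate)
    ancestors = [
        "".join(rng.choice(list(AMINO_ACIDS), size=spec.sequence_length))
        for _ in range(spec.n_target_classes)
    ]
    seqs = []
    for j in range(spec.n_targets):
        base = list(ancestors[target_classes[j]])
        mutate = rng.random(spec.sequence_length) < p_mut
        for pos in np.flatnonzero(mutate):
            base[pos] = rng.choice(list(AMINO_ACIDS))
        seqs.append("".join(base))
    sequences = SequenceSet(entity_ids=target_ids, sequences=seqs)

    g_go = gamma.get("GO", 0.0)
    precomputed = {
        "GO_A": _block_matrix(rng, target_ids, target_classes, g_go, "GO_A", "target", "GO"),
        "GO_B": _block_matrix(rng, target_ids, target_classes, g_go, "GO_B", "target", "GO"),
    }

    return SyntheticBundle(
        spec=spec,
        drug_ids=drug_ids,
        target_ids=target_ids,
        drug_classes=drug_classes,
        target_classes=target_classes,
        profiles=profiles,
        ppi=ppi,
        sequences=sequences,
        precomputed=precomputed,
        dti=dti,
    )


def default_catalog(
    bundle: SyntheticBundle,
    isp_params: ISPParams | None = None,
    include_alignment: bool = True,
) -> SimilarityCatalog:
    """Build the full 7-drug / 9-target measure catalog from a bundle.

    Mirrors the published measure layout: one structure measure, Jaccard
    and cosine per phenotypic drug dataset, two alignment measures, three
    interaction-graph measures, two precomputed matrices and two pathway
    measures.  ``include_alignment=False`` drops the two (relatively
    expensive) sequence measures for quick tests.
    """
    isp_params = isp_params or ISPParams()
    catalog = SimilarityCatalog()
    for tag, measures in DRUG_MEASURES.items():
        for name, kind in measures:
            fn = getattr(kernels, f"{kind}_similarity")
            catalog.add(fn(bundle.profiles[tag], side="drug", measure_name=name, dataset_tag=tag))
    if include_alignment:
        for name, mode in (("Seq_Loc", "local"), ("Seq_Glo", "global")):
            catalog.add(
                kernels.alignment_similarity(
                    bundle.sequences, mode=mode, measure_name=name, dataset_tag="Seq"
                )
            )
    catalog.add(kernels.isp_similarity(bundle.ppi, isp_params))
    for index in ("jaccard", "cosine"):
        catalog.add(
            kernels.common_neighbor_similarity(
                bundle.ppi, index=index, min_confidence=isp_params.min_confidence
            )
        )
    for matrix in bundle.precomputed.values():
        catalog.add(matrix)
    for tag, measures in TARGET_PROFILE_MEASURES.items():
        for name, kind in measures:
            fn = getattr(kernels, f"{kind}_similarity")
            catalog.add(
                fn(bundle.profiles[tag], side="target", measure_name=name, dataset_tag=tag)
            )
    return catalog


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle in the pipeline's on-disk formats.

    Emits the known-interaction edge list, one long-form profile TSV per
    dataset, the interaction graph TSV, a FASTA of sequences, full-matrix
    TSVs for the precomputed measures, a catalog manifest, and a metadata
    JSON (entity/feature universes and latent classes) that makes the
    round trip exact even for all-zero profile rows.
    """
    from .io import write_similarity_matrix

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    dti_path = directory / "dti.tsv"
    with open(dti_path, "w") as fh:
        fh.write("drug_id\ttarget_id\n")
        for i, j in np.argwhere(bundle.dti == 1):
            fh.write(f"{bundle.drug_ids[i]}\t{bundle.target_ids[j]}\n")
    paths["dti"] = dti_path

    for tag, prof in bundle.profiles.items():
        p = directory / f"{tag.lower()}_profiles.tsv"
        with open(p, "w") as fh:
            fh.write("entity_id\tfeature_id\n")
            for i, j in np.argwhere(prof.matrix == 1):
                fh.write(f"{prof.entity_ids[i]}\t{prof.feature_ids[j]}\n")
        paths[f"profiles:{tag}"] = p

    ppi_path = directory / "ppi.tsv"
    with open(ppi_path, "w") as fh:
        fh.write("protein_a\tprotein_b\tconfidence\n")
        for a, b, conf in bundle.ppi.edges:
            fh.write(f"{a}\t{b}\t{conf:.6f}\n")
    paths["ppi"] = ppi_path

    fasta_path = directory / "sequences.fasta"
    with open(fasta_path, "w") as fh:
        for eid, seq in zip(bundle.sequences.entity_ids, bundle.sequences.sequences):
            fh.write(f">{eid}\n{seq}\n")
    paths["sequences"] = fasta_path

    for name, matrix in bundle.precomputed.items():
        p = directory / f"{name.lower()}_matrix.tsv"
        write_similarity_matrix(matrix, p)
        paths[f"precomputed:{name}"] = p

    manifest = {"measures": []}
    for tag, measures in DRUG_MEASURES.items():
        for name, kind in measures:
            manifest["measures"].append(
                {
                    "name": name,
                    "side": "drug",
                    "dataset_tag": tag,
                    "source": "profiles",
                    "path": f"{tag.lower()}_profiles.tsv",
                    "method": kind,
                }
            )
    for name, method in (("Seq_Loc", "align_local"), ("Seq_Glo", "align_global")):
        manifest["measures"].append(
            {
                "name": name,
                "side": "target",
                "dataset_tag": "Seq",
                "source": "sequences",
                "path": "sequences.fasta",
                "method": method,
            }
        )
    for name, method in (("PPI_ISP", "isp"), ("PPI_Jac", "cn_jaccard"), ("PPI_Cos", "cn_cosine")):
        manifest["measures"].append(
            {
                "name": name,
                "side": "target",
                "dataset_tag": "PPI",
                "source": "graph",
                "path": "ppi.tsv",
                "method": method,
            }
        )
    for name in bundle.precomputed:
        manifest["measures"].append(
            {
                "name": name,
                "side": "target",
                "dataset_tag": "GO",
                "source": "precomputed",
                "path": f"{name.lower()}_matrix.tsv",
                "method": "precomputed",
            }
        )
    for name, kind in TARGET_PROFILE_MEASURES["PW"]:
        manifest["measures"].append(
            {
                "name": name,
                "side": "target",
                "dataset_tag": "PW",
                "source": "profiles",
                "path": "pw_profiles.tsv",
                "method": kind,
            }
        )
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = manifest_path

    meta = {
        "seed": bundle.spec.seed,
        "drug_ids": bundle.drug_ids,
        "target_ids": bundle.target_ids,
        "drug_classes": bundle.drug_classes.tolist(),
        "target_classes": bundle.target_classes.tolist(),
        "feature_ids": {tag: p.feature_ids for tag, p in bundle.profiles.items()},
    }
    meta_path = directory / "bundle_meta.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
    paths["meta"] = meta_path
    return paths
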