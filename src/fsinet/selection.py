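"""Forward similarity integration: greedy wrapper selection of measures.

Given a catalog of drug-drug and target-target similarity measures, the
forward-selection wrapper grows an ordered subset per side, one step at a
time.  Step 1 tries every (drug measure, target measure) pair; later steps
try adding a drug measure and a target measure jointly, a drug measure
alone, or a target measure alone, and keep the best addition only if it
strictly improves the cross-validated criterion (AUC, AUPR or F1).  Two
measures derived from the same underlying dataset are never allowed into
one side together (same-dataset exclusion): measures from one source are
strongly correlated and integrating them adds redundancy, not signal.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import prod

import numpy as np

from .evaluation import FoldAssignment, cross_validate, make_folds
from .integration import IntegrationMethod, integrate_similarity_set
from .propagation import PropagationConfig
from .types import SimilarityMatrix

__all__ = [
    "SimilarityCatalog",
    "FSIConfig",
    "FSIResult",
    "enumerate_valid_combinations",
    "estimate_prf",
    "forward_similarity_integration",
]


class SimilarityCatalog:
    """Ordered, named collection of similarity measures on both sides.

    Declaration order is the canonical order used for tie-breaking in the
    greedy search and for subset enumeration.  All drug-side matrices must
    share entity ids, as must all target-side matrices.
    """

    def __init__(self, measures: list[SimilarityMatrix] | None = None) -> None:
        self._measures: dict[str, SimilarityMatrix] = {}
        for m in measures or []:
            self.add(m)

    def add(self, measure: SimilarityMatrix) -> None:
        name = measure.measure_name
        if not name:
            raise ValueError("catalog measures need a non-empty measure_name")
        if name in self._measures:
            raise ValueError(f"duplicate measure name {name!r}")
        reference = next(
            (m for m in self._measures.values() if m.side == measure.side), None
        )
        if reference is not None and reference.entity_ids != measure.entity_ids:
            raise ValueError(
                f"measure {name!r} is not aligned with the other {measure.side}-side measures"
            )
        self._measures[name] = measure

    def __getitem__(self, name: str) -> SimilarityMatrix:
        return self._measures[name]

    def __contains__(self, name: str) -> bool:
        return name in self._measures

    def __len__(self) -> int:
        return len(self._measures)

    @property
    def names(self) -> list[str]:
        return list(self._measures)

    def side_names(self, side: str) -> list[str]:
        return [n for n, m in self._measures.items() if m.side == side]

    @property
    def drug_names(self) -> list[str]:
        return self.side_names("drug")

    @property
    def target_names(self) -> list[str]:
        return self.side_names("target")

    def tag(self, name: str) -> str:
        return self._measures[name].dataset_tag


def _side_subsets(catalog: SimilarityCatalog, side: str):
    """Non-empty subsets of one side with at most one measure per dataset.

    Measures without a dataset tag count as singleton datasets.  Subsets
    come out in canonical (declaration) order.
    """
    names = catalog.side_names(side)
    groups: dict[str, list[str]] = {}
    for i, n in enumerate(names):
        groups.setdefault(catalog.tag(n) or f"__solo_{i}", []).append(n)
    group_lists = list(groups.values())
    count = prod(1 + len(g) for g in group_lists) - 1
    order = {n: i for i, n in enumerate(names)}

    def gen():
        for picks in itertools.product(*[[None, *g] for g in group_lists]):
            subset = tuple(sorted((p for p in picks if p is not None), key=order.get))
            if subset:
                yield subset

    return count, gen()


def enumerate_valid_combinations(catalog: SimilarityCatalog):
    """All valid (drug subset, target subset) combinations and their count.

    A combination pairs a non-empty drug-measure subset with a non-empty
    target-measure subset such that no two selected measures on one side
    share a dataset tag.  Returns ``(count, iterator)``; the count equals
    the iterator's length.
    """
    if not catalog.drug_names or not catalog.target_names:
        raise ValueError("catalog needs at least one drug and one target measure")
    d_count, d_subsets = _side_subsets(catalog, "drug")
    t_count, t_subsets = _side_subsets(catalog, "target")
    return d_count * t_count, itertools.product(list(d_subsets), list(t_subsets))


@dataclass(frozen=True)
class FSIConfig:
    """Configuration of the forward-selection wrapper."""

    integration: IntegrationMethod = IntegrationMethod("SNF")
    metric: str = "AUPR"
    n_folds: int = 10
    seed: int = 0
    propagation: PropagationConfig = PropagationConfig()
    exclusion: bool = True
    threshold_rule: str | float = "max_f1"

    def __post_init__(self) -> None:
        if self.metric not in ("AUC", "AUPR", "F1"):
            raise ValueError(f"metric must be AUC, AUPR or F1, got {self.metric!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class FSIResult:
    """Selected measure orderings plus the per-step search trace."""

    OD: list[str]
    OT: list[str]
    trace: list[dict]
    final_prf: float
    metric: str
    n_evaluations: int

    def to_json(self, path=None) -> str:
        payload = {
            "OD": self.OD,
            "OT": self.OT,
            "final_prf": self.final_prf,
            "metric": self.metric,
            "n_evaluations": self.n_evaluations,
            "trace": self.trace,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def estimate_prf(
    OD: list[str],
    OT: list[str],
    catalog: SimilarityCatalog,
    w_dt0: np.ndarray,
    cfg: FSIConfig,
    folds: FoldAssignment,
) -> float:
    """Cross-validated criterion value for one candidate model.

    Integrates each side's measures in the given order, normalizes, runs
    the shared-fold cross-validation and returns the mean of the
    configured metric.  Deterministic for fixed folds and config.
    """
    if not OD or not OT:
        raise ValueError("both OD and OT must be non-empty")
    dsim = integrate_similarity_set([catalog[n] for n in OD], cfg.integration)
    tsim = integrate_similarity_set([catalog[n] for n in OT], cfg.integration)
    report = cross_validate(
        dsim, tsim, w_dt0, folds, cfg.propagation, cfg.threshold_rule
    )
    return report.mean(cfg.metric)


def forward_similarity_integration(
    catalog: SimilarityCatalog,
    w_dt0: np.ndarray,
    cfg: FSIConfig | None = None,
    folds: FoldAssignment | None = None,
) -> FSIResult:
    """Greedy forward selection of drug and target similarity measures.

    The same fold assignment (derived from ``cfg.seed``) is reused for
    every candidate model so that criterion values are comparable.  Ties
    in the argmax are broken by canonical catalog order (first declared
    wins), and between the three addition modes the drug-only addition
    wins ties over the target-only addition, which wins over the joint
    addition.  The returned trace has one record per step, accepted or
    not, with strictly increasing accepted criterion values.
    """
    cfg = cfg or FSIConfig()
    if folds is None:
        folds = make_folds(w_dt0, cfg.n_folds, cfg.seed)
    evaluations = 0
    cache: dict[tuple[tuple[str, ...], tuple[str, ...]], float] = {}

    def prf(od: list[str], ot: list[str]) -> float:
        nonlocal evaluations
        key = (tuple(od), tuple(ot))
        if key not in cache:
            cache[key] = estimate_prf(od, ot, catalog, w_dt0, cfg, folds)
            evaluations += 1
        return cache[key]

    def allowed(name: str, chosen: list[str]) -> bool:
        if not cfg.exclusion:
            return True
        tag = catalog.tag(name)
        return not tag or tag not in {catalog.tag(c) for c in chosen}

    OD: list[str] = []
    OT: list[str] = []
    RD = list(catalog.drug_names)
    RT = list(catalog.target_names)
    prf_prev = 0.0
    trace: list[dict] = []
    k = 0
    while True:
        k += 1
        drug_candidates = [x for x in RD if allowed(x, OD)]
        target_candidates = [y for y in RT if allowed(y, OT)]

        best_both: tuple[float, str | None, str | None] = (-np.inf, None, None)
        for x in drug_candidates:
            for y in target_candidates:
                value = prf(OD + [x], OT + [y])
                if value > best_both[0]:
                    best_both = (value, x, y)
        prf_both, x_star, y_star = best_both

        if k == 1:
            if x_star is None:
                raise ValueError("no valid (drug, target) candidate pair at step 1")
            prf_k = prf_both
            X, Y = [x_star], [y_star]
            prf_drug = prf_target = None
        else:
            prf_drug, xd = -np.inf, None
            for x in drug_candidates:
                value = prf(OD + [x], OT)
                if value > prf_drug:
                    prf_drug, xd = value, x
            prf_target, yt = -np.inf, None
            for y in target_candidates:
                value = prf(OD, OT + [y])
                if value > prf_target:
                    prf_target, yt = value, y
            prf_k = max(prf_both, prf_drug, prf_target)
            if prf_k == -np.inf:
                break  # no admissible candidate in any mode
            if prf_k == prf_drug:
                X, Y = [xd], []
            elif prf_k == prf_target:
                X, Y = [], [yt]
            else:
                X, Y = [x_star], [y_star]
        accepted = prf_k > prf_prev
        trace.append(
            {
                "step": k,
                "n_drug_candidates": len(drug_candidates),
                "n_target_candidates": len(target_candidates),
                "prf_both": None if prf_both == -np.inf else prf_both,
                "prf_drug": None if prf_drug in (None, -np.inf) else prf_drug,
                "prf_target": None if prf_target in (None, -np.inf) else prf_target,
                "chosen_drug": X[0] if X else None,
                "chosen_target": Y[0] if Y else None,
                "prf": prf_k,
                "accepted": accepted,
            }
        )
        if not accepted:
            break
        OD += X
        OT += Y
        RD = [x for x in RD if x not in X]
        RT = [y for y in RT if y not in Y]
        prf_prev = prf_k
        if not RD or not RT:
            break
    return FSIResult(
        OD=OD,
        OT=OT,
        trace=trace,
        final_prf=prf_prev,
        metric=cfg.metric,
        n_evaluations=evaluations,
    )
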