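"""Cross-validation protocol and evaluation metrics for DTI link prediction.

The task is heavily imbalanced: known interactions (positives) are a small
fraction of all drug-target pairs, and every unknown pair is treated as a
negative (closed-world assumption).  Positives and negatives are therefore
partitioned into folds separately, each fold's positives are removed from
the training interaction matrix, and metrics are computed on the held-out
fold's pairs only.  Threshold-free metrics (AUPR, AUC) are the primary
criteria; thresholded metrics (PRE/REC/F1/ACC/MCC) use a configurable
threshold rule, by default the threshold maximizing F1 on the fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score

from .propagation import HeterogeneousNetwork, PropagationConfig, normalize_similarity, propagate
from .types import BinaryProfileSet, SimilarityMatrix

__all__ = [
    "FoldAssignment",
    "MetricReport",
    "ComparisonResult",
    "make_folds",
    "confusion_metrics",
    "compute_metrics",
    "cross_validate",
    "decay_factor_sweep",
    "permute_profile_edges",
    "random_integration_baseline",
    "compare_models",
]

METRICS = ("AUPR", "AUC", "PRE", "REC", "F1", "ACC", "MCC")


@dataclass
class FoldAssignment:
    """Fold indices for positive and negative drug-target pairs.

    ``pos_pairs``/``neg_pairs`` are (k, 2) arrays of (drug, target) index
    pairs; ``pos_fold``/``neg_fold`` give each pair's fold.  Positives and
    negatives are partitioned separately so every fold sees both classes.
    """

    n_folds: int
    pos_pairs: np.ndarray
    pos_fold: np.ndarray
    neg_pairs: np.ndarray
    neg_fold: np.ndarray
    seed: int

    def test_mask(self, fold: int, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for pairs, assign in ((self.pos_pairs, self.pos_fold), (self.neg_pairs, self.neg_fold)):
            sel = pairs[assign == fold]
            mask[sel[:, 0], sel[:, 1]] = True
        return mask


def make_folds(w_dt0: np.ndarray, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Randomly partition positive and negative pairs into near-equal folds.

    Fold sizes within each class differ by at most one.  Deterministic for
    a given seed.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    w_dt0 = np.asarray(w_dt0)
    pos = np.argwhere(w_dt0 == 1)
    neg = np.argwhere(w_dt0 == 0)
    if len(pos) < n_folds:
        raise ValueError(
            f"{len(pos)} positive pairs cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)

    def assign(k: int) -> np.ndarray:
        folds = np.arange(k) % n_folds
        rng.shuffle(folds)
        return folds

    return FoldAssignment(
        n_folds=n_folds,
        pos_pairs=pos,
        pos_fold=assign(len(pos)),
        neg_pairs=neg,
        neg_fold=assign(len(neg)),
        seed=seed,
    )


@dataclass
class MetricReport:
    """Per-fold metric table with convenience means."""

    per_fold: pd.DataFrame
    label: str = ""

    def mean(self, metric: str) -> float:
        return float(self.per_fold[metric].mean())

    @property
    def means(self) -> dict[str, float]:
        return {m: self.mean(m) for m in METRICS if m in self.per_fold}


@dataclass
class ComparisonResult:
    """Outcome of a t-test between two models on one metric."""

    metric: str
    mean_difference: float
    t_statistic: float
    p_value: float
    significant_05: bool = field(init=False)
    significant_01: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant_05 = bool(self.p_value < 0.05)
        self.significant_01 = bool(self.p_value < 0.01)


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """PRE/REC/F1/ACC/MCC from confusion-matrix counts.

    Any metric with a zero denominator is defined as 0, which is the
    conservative convention for heavily imbalanced data.
    """
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {"PRE": pre, "REC": rec, "F1": f1, "ACC": acc, "MCC": float(mcc)}


def _best_f1_threshold(labels: np.ndarray, scores: np.ndarray) -> float:
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    # precision/recall have one more entry than thresholds; drop the last
    best = int(np.argmax(f1[:-1])) if len(thresholds) else 0
    return float(thresholds[best]) if len(thresholds) else 0.5


def compute_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold_rule: str | float = "max_f1",
) -> dict[str, float]:
    """Full metric row (AUPR/AUC + thresholded metrics) for one fold.

    ``threshold_rule`` is either ``"max_f1"`` (pick the score threshold
    maximizing F1 on this fold) or a fixed numeric threshold.  Scores at
    or above the threshold are predicted positive.  With single-class
    labels the ranking metrics are undefined and reported as NaN.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    row: dict[str, float] = {}
    single_class = labels.min() == labels.max()
    if single_class:
        row["AUC"] = float("nan")
        row["AUPR"] = float("nan")
        threshold = threshold_rule if isinstance(threshold_rule, (int, float)) else 0.5
    else:
        row["AUC"] = float(roc_auc_score(labels, scores))
        row["AUPR"] = float(average_precision_score(labels, scores))
        if isinstance(threshold_rule, (int, float)):
            threshold = float(threshold_rule)
        elif threshold_rule == "max_f1":
            threshold = _best_f1_threshold(labels, scores)
        else:
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    row.update(confusion_metrics(tp, fp, fn, tn))
    row["threshold"] = float(threshold)
    return row


def cross_validate(
    drug_sim: SimilarityMatrix | np.ndarray,
    target_sim: SimilarityMatrix | np.ndarray,
    w_dt0: np.ndarray,
    folds: FoldAssignment,
    prop_cfg: PropagationConfig | None = None,
    threshold_rule: str | float = "max_f1",
    label: str = "",
) -> MetricReport:
    """K-fold cross-validation of one heterogeneous network model.

    For every fold, the fold's positives are zeroed in the training
    interaction matrix, propagation is run, and metrics are computed on
    the fold's pairs only (its positives plus its negatives).  The
    similarity layers are normalized once up front.
    """
    prop_cfg = prop_cfg or PropagationConfig()
    w_dd = normalize_similarity(drug_sim)
    w_tt = normalize_similarity(target_sim)
    w_dt0 = np.asarray(w_dt0, dtype=float)
    m, n = w_dt0.shape
    drug_ids = drug_sim.entity_ids if isinstance(drug_sim, SimilarityMatrix) else [str(i) for i in range(m)]
    target_ids = target_sim.entity_ids if isinstance(target_sim, SimilarityMatrix) else [str(j) for j in range(n)]
    rows = []
    for fold in range(folds.n_folds):
        test_mask = folds.test_mask(fold, (m, n))
        w_train = w_dt0 * ~test_mask  # zero out held-out positives
        net = HeterogeneousNetwork(drug_ids, target_ids, w_dd, w_tt, w_train)
        result = propagate(net, prop_cfg)
        if not result.converged:
            raise RuntimeError(f"propagation failed to converge in fold {fold}")
        row = compute_metrics(
            result.scores[test_mask], w_dt0[test_mask], threshold_rule
        )
        row["fold"] = fold
        row["iterations"] = result.iterations_used
        rows.append(row)
    return MetricReport(per_fold=pd.DataFrame(rows), label=label)


def decay_factor_sweep(
    models: dict[str, tuple[SimilarityMatrix | np.ndarray, SimilarityMatrix | np.ndarray]],
    w_dt0: np.ndarray,
    folds: FoldAssignment,
    alphas: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1)),
    metrics: tuple[str, ...] = ("AUC", "AUPR", "F1"),
    prop_cfg: PropagationConfig | None = None,
    threshold_rule: str | float = "max_f1",
) -> pd.DataFrame:
    """Count, per decay factor, how many models peak there on each metric.

    Every model is cross-validated at every alpha on the shared folds; for
    each model and metric the alpha attaining the maximum mean is
    credited.  Ties credit every tied alpha, so percentage columns can sum
    above 100.  Returns a table indexed by alpha with count and percentage
    columns per metric.
    """
    base = prop_cfg or PropagationConfig()
    means: dict[str, dict[float, dict[str, float]]] = {}
    for name, (dsim, tsim) in models.items():
        means[name] = {}
        for alpha in alphas:
            cfg = PropagationConfig(alpha=alpha, tol=base.tol, max_iter=base.max_iter)
            report = cross_validate(dsim, tsim, w_dt0, folds, cfg, threshold_rule)
            means[name][alpha] = report.means
    counts = pd.DataFrame(0, index=list(alphas), columns=list(metrics), dtype=int)
    for name in models:
        for metric in metrics:
            values = np.array([means[name][a][metric] for a in alphas])
            best = values.max()
            for a, v in zip(alphas, values):
                if np.isclose(v, best, rtol=0, atol=1e-12):
                    counts.loc[a, metric] += 1
    table = counts.copy()
    for metric in metrics:
        table[f"{metric}_pct"] = 100.0 * counts[metric] / max(len(models), 1)
    table.index.name = "alpha"
    return table


def permute_profile_edges(profiles: BinaryProfileSet, seed: int = 0) -> BinaryProfileSet:
    """Randomly reassign a profile table's associations, keeping their count.

    The existing 1-entries are moved to uniformly random (entity, feature)
    cells without collision, destroying any class structure while
    conserving density.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    m, f = profiles.matrix.shape
    k = int(profiles.matrix.sum())
    new = np.zeros(m * f, dtype=np.int8)
    if k:
        cells = rng.choice(m * f, size=k, replace=False)
        new[cells] = 1
    return BinaryProfileSet(
        entity_ids=profiles.entity_ids,
        feature_ids=profiles.feature_ids,
        matrix=new.reshape(m, f),
    )


def random_integration_baseline(
    catalog,
    n_models: int,
    w_dt0: np.ndarray,
    folds: FoldAssignment,
    method,
    prop_cfg: PropagationConfig | None = None,
    threshold_rule: str | float = "max_f1",
    seed: int = 0,
) -> list[MetricReport]:
    """Evaluate uniformly sampled valid similarity combinations.

    Samples ``n_models`` (drug subset, target subset) combinations without
    replacement from the valid-combination enumeration (same-dataset
    exclusion applied) and cross-validates each on the shared folds.
    """
    from .selection import enumerate_valid_combinations
    from .integration import integrate_similarity_set

    count, combos = enumerate_valid_combinations(catalog)
    combos = list(combos)
    if n_models > count:
        raise ValueError(f"requested {n_models} models but only {count} combinations exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(count, size=n_models, replace=False)
    reports = []
    for idx in chosen:
        drug_names, target_names = combos[idx]
        dsim = integrate_similarity_set([catalog[n] for n in drug_names], method)
        tsim = integrate_similarity_set([catalog[n] for n in target_names], method)
        label = f"{'+'.join(drug_names)} & {'+'.join(target_names)}"
        reports.append(
            cross_validate(dsim, tsim, w_dt0, folds, prop_cfg, threshold_rule, label=label)
        )
    return reports


def compare_models(
    report_a: MetricReport,
    report_b: MetricReport,
    metric: str = "AUPR",
    sided: str = "greater",
    paired: bool = True,
) -> ComparisonResult:
    """t-test whether model A outperforms model B on a metric across folds.

    Paired by default (the folds are shared between candidate models) and
    one-sided testing A > B; ``paired=False`` falls back to Welch's
    unequal-variance test.
    """
    a = report_a.per_fold[metric].to_numpy(dtype=float)
    b = report_b.per_fold[metric].to_numpy(dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError(
                f"paired comparison needs equal fold counts, got {len(a)} and {len(b)}"
            )
        if np.allclose(a, b):
            t, p = 0.0, 1.0 if sided != "two-sided" else 1.0
        else:
            t, p = stats.ttest_rel(a, b, alternative=sided)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative=sided)
    return ComparisonResult(
        metric=metric,
        mean_difference=float(a.mean() - b.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )
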