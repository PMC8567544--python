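"""Cross-validation, ranking metrics, and per-disease case-study ranking.

Known positive associations are dealt into k folds; each fold in turn is
zeroed out of a training copy of the association matrix, the GIP kernels
are recomputed from that masked copy (so held-out labels never leak into
the similarity networks), the model is retrained, and the held-out
positives are scored against every pair that is unknown (0) in the FULL
association matrix.

AUROC is the Mann-Whitney statistic (probability a random positive
outscores a random negative, ties counting one half); AUPRC is the
precision-recall step integral.  Accuracy and F-measure require a score
threshold, which is chosen to maximise F on the training fold's own scores
and then applied unchanged to the test scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .io_datasets import DatasetBundle, LabeledMatrix
from .completion import TrainConfig, fit_joint, predict_bundle

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "RankedList",
    "UndefinedMetricError",
    "make_folds",
    "auroc",
    "auprc",
    "confusion_metrics",
    "best_f_threshold",
    "roc_curve_points",
    "cross_validate",
    "rank_drugs_for_disease",
]

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """A ranking metric was requested with only one class present."""


@dataclass
class FoldPlan:
    """Disjoint k-way split of the positive cells of an association matrix."""

    k: int
    seed: int
    folds: list[list[tuple[int, int]]]

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for f in self.folds:
            for cell in f:
                if cell in seen:
                    raise ValueError(f"cell {cell} appears in more than one fold")
                seen.add(cell)
        sizes = [len(f) for f in self.folds]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than 1")


@dataclass
class MetricsReport:
    auroc: float
    auprc: float
    acc: float
    f_measure: float
    threshold: float
    per_fold: list[dict] = field(default_factory=list)
    pooled: dict | None = None
    pooled_scores: tuple[np.ndarray, np.ndarray] | None = None  # (scores, labels)

    def __post_init__(self) -> None:
        for name in ("auroc", "auprc", "acc", "f_measure"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")


@dataclass
class RankedList:
    disease_id: str
    drug_ids: list[str]
    scores: list[float]
    k_requested: int

    def __post_init__(self) -> None:
        if len(self.drug_ids) != len(set(self.drug_ids)):
            raise ValueError("ranked list repeats a drug")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("ranked scores are not non-increasing")


def make_folds(O: LabeledMatrix, k: int, seed: int) -> FoldPlan:
    """Shuffle the positive cells with a seeded RNG and deal them round-robin."""
    Ov = np.asarray(O.values)
    pos = [tuple(map(int, c)) for c in np.argwhere(Ov == 1)]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(pos):
        raise ValueError(f"k = {k} exceeds the {len(pos)} positive cells")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos))
    folds: list[list[tuple[int, int]]] = [[] for _ in range(k)]
    for rank, idx in enumerate(order):
        folds[rank % k].append(pos[idx])
    return FoldPlan(k, seed, folds)


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise UndefinedMetricError(
            "metric undefined: labels contain a single class"
        )


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(random positive > random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(np.float64)
    _check_two_classes(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step integral)."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F-measure) at ``score >= threshold``.

    Precision, recall and F fall back to 0 when their denominators vanish.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    pred = scores >= threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    acc = (tp + tn) / max(tp + fp + fn + tn, 1)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return acc, precision, recall, f


def best_f_threshold(scores: np.ndarray, labels: np.ndarray, max_candidates: int = 512) -> float:
    """Threshold maximising F-measure over the candidate score values."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    uniq = np.unique(scores)
    if uniq.size > max_candidates:
        qs = np.linspace(0.0, 1.0, max_candidates)
        uniq = np.unique(np.quantile(uniq, qs))
    best_t, best_f = uniq[0], -1.0
    for t in uniq:
        _, _, _, f = confusion_metrics(scores, labels, t)
        if f > best_f:
            best_t, best_f = t, f
    return float(best_t)


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) pairs swept over all score thresholds, for curve dumps."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    _check_two_classes(labels.astype(float))
    order = np.argsort(-scores, kind="stable")
    lab = labels[order]
    tp = np.concatenate([[0], np.cumsum(lab)])
    fp = np.concatenate([[0], np.cumsum(~lab)])
    return np.column_stack([fp / fp[-1], tp / tp[-1]])


def _train_matrix(O: LabeledMatrix, held_out: list[tuple[int, int]]) -> LabeledMatrix:
    Ot = O.values.copy()
    for i, j in held_out:
        Ot[i, j] = 0.0
    return LabeledMatrix(Ot, O.row_ids, O.col_ids)


def cross_validate(
    bundle: DatasetBundle,
    plan: FoldPlan,
    config: TrainConfig | None = None,
    neg_sample: int | None = None,
) -> MetricsReport:
    """k-fold cross-validation over the known positive associations.

    Per fold: held-out positives are zeroed in a training copy of O, both
    GIP kernels are rebuilt from the masked copy, the model is retrained
    (:func:`fit_joint`), and metrics are computed on the held-out positives
    against the cells that are 0 in the FULL O (optionally subsampled to
    ``neg_sample`` negatives with the fold seed).  The report carries
    per-fold metrics, their mean (primary), and the pooled-over-folds
    aggregation.
    """
    cfg = config or TrainConfig()
    O = bundle.associations
    Ov = O.values
    neg_cells = np.argwhere(Ov == 0)
    per_fold: list[dict] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for fold_idx, held_out in enumerate(plan.folds):
        O_train = _train_matrix(O, held_out)
        assert all(O_train.values[i, j] == 0.0 for i, j in held_out)
        # entities stripped of their last positive keep an all-zero GIP
        # profile; the global-mean bandwidth stays defined, so warn and keep
        empty_rows = int(((O_train.values.sum(1) == 0) & (Ov.sum(1) > 0)).sum())
        empty_cols = int(((O_train.values.sum(0) == 0) & (Ov.sum(0) > 0)).sum())
        if empty_rows or empty_cols:
            logger.warning(
                "fold %d: %d disease(s) and %d drug(s) have no trainable "
                "positives; retained with all-zero profiles",
                fold_idx, empty_rows, empty_cols,
            )
        fold_cfg = TrainConfig(**{**cfg.to_dict(), "seed": cfg.seed})
        fd, fg, model, _ = fit_joint(bundle, fold_cfg, assoc=O_train)
        S = predict_bundle(
            bundle, fd, fg, model, assoc=O_train, gamma_prime=cfg.gamma_prime
        ).values

        negs = neg_cells
        if neg_sample is not None and neg_sample < len(neg_cells):
            rng = np.random.default_rng(
                np.random.SeedSequence([plan.seed, fold_idx])
            )
            negs = neg_cells[rng.choice(len(neg_cells), neg_sample, replace=False)]
        pos_idx = np.array(held_out)
        test_scores = np.concatenate(
            [S[pos_idx[:, 0], pos_idx[:, 1]], S[negs[:, 0], negs[:, 1]]]
        )
        test_labels = np.concatenate(
            [np.ones(len(pos_idx)), np.zeros(len(negs))]
        )

        # threshold from the training fold's own scores
        train_pos = np.argwhere(O_train.values == 1)
        train_scores = np.concatenate(
            [S[train_pos[:, 0], train_pos[:, 1]], S[negs[:, 0], negs[:, 1]]]
        )
        train_labels = np.concatenate(
            [np.ones(len(train_pos)), np.zeros(len(negs))]
        )
        thr = best_f_threshold(train_scores, train_labels)

        acc, _, _, f = confusion_metrics(test_scores, test_labels, thr)
        per_fold.append(
            {
                "fold": fold_idx,
                "auroc": auroc(test_scores, test_labels),
                "auprc": auprc(test_scores, test_labels),
                "acc": acc,
                "f_measure": f,
                "threshold": thr,
                "n_test_pos": int(len(pos_idx)),
                "n_test_neg": int(len(negs)),
            }
        )
        pooled_scores.append(test_scores)
        pooled_labels.append(test_labels)
        logger.debug("fold %d: %s", fold_idx, per_fold[-1])

    mean = {
        k: float(np.mean([f[k] for f in per_fold]))
        for k in ("auroc", "auprc", "acc", "f_measure", "threshold")
    }
    ps, pl = np.concatenate(pooled_scores), np.concatenate(pooled_labels)
    thr_pool = float(np.mean([f["threshold"] for f in per_fold]))
    pool_acc, _, _, pool_f = confusion_metrics(ps, pl, thr_pool)
    pooled = {
        "auroc": auroc(ps, pl),
        "auprc": auprc(ps, pl),
        "acc": pool_acc,
        "f_measure": pool_f,
    }
    return MetricsReport(
        auroc=mean["auroc"],
        auprc=mean["auprc"],
        acc=mean["acc"],
        f_measure=mean["f_measure"],
        threshold=mean["threshold"],
        per_fold=per_fold,
        pooled=pooled,
        pooled_scores=(ps, pl),
    )


def rank_drugs_for_disease(
    bundle: DatasetBundle,
    disease_id: str,
    top_k: int = 10,
    config: TrainConfig | None = None,
) -> RankedList:
    """Case-study protocol: hide one disease's row, retrain, rank its drugs.

    Every association of the target disease is removed from the training
    matrix, the model is retrained, and all drugs are ranked for that
    disease by score (ties broken by drug id for determinism).
    """
    cfg = config or TrainConfig()
    O = bundle.associations
    row = O.row_index(disease_id)
    Ot = O.values.copy()
    Ot[row, :] = 0.0
    O_train = LabeledMatrix(Ot, O.row_ids, O.col_ids)
    fd, fg, model, _ = fit_joint(bundle, cfg, assoc=O_train)
    S = predict_bundle(
        bundle, fd, fg, model, assoc=O_train, gamma_prime=cfg.gamma_prime
    ).values
    scores = S[row]
    order = sorted(
        range(len(scores)), key=lambda j: (-scores[j], O.col_ids[j])
    )[: min(top_k, len(scores))]
    return RankedList(
        disease_id=disease_id,
        drug_ids=[O.col_ids[j] for j in order],
        scores=[float(scores[j]) for j in order],
        k_requested=top_k,
    )
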