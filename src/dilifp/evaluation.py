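"""Cross-validation, threshold metrics, grid search and independent testing.

Folds are stratified and seeded.  By default the substructure weights are
re-estimated inside every training fold, so the held-out compounds never
contribute to their own feature weighting; the optimistic alternative
(weights from the full dataset, a common source of leakage in
fingerprint-weighting pipelines) is available behind the explicit
``global_weights_leakage`` flag for comparison experiments.

Cross-validated metrics are reported both pooled over all held-out scores
and as per-fold values (fold means are available too, since conventions
differ between studies).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data_io import LabeledFingerprintDataset
from .models import ModelConfig, TrainedModel, _as_binary, predict_scores, train

__all__ = [
    "Metrics",
    "EvaluationReport",
    "GridResult",
    "compute_metrics",
    "crossvalidate",
    "grid_search",
    "independent_test",
]


@dataclass
class Metrics:
    """Ranking and confusion-matrix metrics at a decision cutoff."""

    auc_roc: float
    aupr: float
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_metrics(scores, labels, cutoff: float) -> Metrics:
    """AUC-ROC (rank statistic, ties counted 1/2), AUPR (step rule), and
    confusion metrics with the rule ``score >= cutoff -> positive``.

    Both classes must be present; ranking metrics are undefined otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if scores.shape[0] != y.shape[0]:
        raise ValueError("scores and labels differ in length")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("AUC-ROC/specificity need both classes present")
    pred = scores >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return Metrics(
        auc_roc=float(roc_auc_score(y, scores)),
        aupr=float(average_precision_score(y, scores)),
        accuracy=(tp + tn) / y.size,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        tp=tp, fp=fp, tn=tn, fn=fn,
        cutoff=float(cutoff),
    )


@dataclass
class EvaluationReport:
    config: ModelConfig
    pooled: Metrics
    fold_metrics: list[Metrics] = field(default_factory=list)
    fold_assignment: dict[str, int] = field(default_factory=dict)
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None

    @property
    def fold_mean(self) -> dict[str, float]:
        """Mean of each scalar metric over folds (empty if no folds)."""
        if not self.fold_metrics:
            return {}
        keys = ("auc_roc", "aupr", "accuracy", "sensitivity", "specificity")
        return {k: float(np.mean([getattr(m, k) for m in self.fold_metrics])) for k in keys}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "pooled": self.pooled.as_dict(),
            "fold_metrics": [m.as_dict() for m in self.fold_metrics],
            "fold_mean": self.fold_mean,
            "fold_assignment": self.fold_assignment,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _stratified_folds(ids, y, n_folds, seed) -> dict[str, int]:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            assignment[ids[i]] = fold
    return assignment


def crossvalidate(
    ds: LabeledFingerprintDataset,
    config: ModelConfig,
    n_folds: int = 10,
    seed: int | None = None,
    calibrate: bool = True,
    global_weights_leakage: bool = False,
    fold_assignment: dict[str, int] | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the full weighting+model pipeline.

    Per fold, the weight vector and learner are fitted on the training
    subsamples only and scored on the held-out subsample (unless
    ``global_weights_leakage`` requests global weights).  A precomputed
    ``fold_assignment`` (compound_id -> fold) lets a grid share one split.
    """
    labels = ds.labels
    mask = labels != "unlabeled"
    sub = ds.subset(np.flatnonzero(mask))
    X, y, ids = sub.labeled_subset()
    n_min = min(int(y.sum()), int((y == 0).sum()))
    if n_folds < 2 or n_folds > n_min:
        raise ValueError(
            f"n_folds={n_folds} must be in [2, {n_min}] (smallest class size)"
        )
    if seed is None:
        seed = config.seed
    if fold_assignment is None:
        fold_assignment = _stratified_folds(ids, y, n_folds, seed)

    global_ds = sub if global_weights_leakage else None

    fold_ids = np.array([fold_assignment[c] for c in ids])
    all_scores = np.full(len(ids), np.nan)
    fold_metrics: list[Metrics] = []
    for fold in range(n_folds):
        test_mask = fold_ids == fold
        train_ds = sub.subset(np.flatnonzero(~test_mask))
        test_ds = sub.subset(np.flatnonzero(test_mask))
        fold_config = dataclasses.replace(config, seed=seed * 1000 + fold)
        if global_weights_leakage:
            # weights from the full dataset, learner from the training folds
            from .weighting import build_weight_vector, count_substructures, smoothed_stats

            stats = smoothed_stats(count_substructures(global_ds), k=config.k)
            wv = build_weight_vector(stats, config.theta, config.n_mult)
            model = _train_with_fixed_weights(train_ds, fold_config, wv, calibrate)
        else:
            model = train(train_ds, fold_config, calibrate=calibrate)
        s = predict_scores(model, test_ds)
        all_scores[test_mask] = s
        fold_metrics.append(
            compute_metrics(s, test_ds.labels, model.decision_cutoff)
        )

    pooled = _pool(all_scores, y, fold_metrics)
    return EvaluationReport(
        config=config,
        pooled=pooled,
        fold_metrics=fold_metrics,
        fold_assignment=fold_assignment,
        scores=all_scores,
        labels=labels[mask],
    )


def _train_with_fixed_weights(ds, config, wv, calibrate) -> TrainedModel:
    """Train a learner on externally supplied weights (leakage mode)."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import cross_val_predict
    from sklearn.svm import SVC

    from .kernel import kernel_matrix
    from .models import _fit_svm, _quiet_svc, calibrate_cutoff
    from .weighting import apply_weights, count_substructures, smoothed_stats

    X, y, ids = ds.labeled_subset()
    Xw = apply_weights(X, wv)
    if config.algorithm == "rf":
        clf = RandomForestClassifier(
            n_estimators=config.n_trees, max_features="sqrt",
            oob_score=calibrate, random_state=config.seed, n_jobs=1,
        ).fit(Xw, y)
        if calibrate:
            pos_col = list(clf.classes_).index(1)
            calib = np.nan_to_num(clf.oob_decision_function_[:, pos_col], nan=0.5)
            cutoff = calibrate_cutoff(calib, y, config.target_sensitivity)
        else:
            cutoff = 0.5
    else:
        Xk = X.astype(float) if config.kernel_variant == "binary" else Xw
        K = kernel_matrix(Xk, variant=config.kernel_variant).K
        clf = _fit_svm(K, y, config)
        if calibrate:
            n_splits = min(5, int(y.sum()), int((y == 0).sum()))
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
            inner = SVC(C=config.cost, kernel="precomputed", probability=True,
                        random_state=config.seed)
            with _quiet_svc():
                proba = cross_val_predict(inner, K, y, cv=cv, method="predict_proba")
            cutoff = calibrate_cutoff(proba[:, 1], y, config.target_sensitivity)
        else:
            cutoff = 0.5
    out = TrainedModel(
        config=config, weight_vector=wv, learner=clf, decision_cutoff=cutoff,
        training_ids=ids,
        train_Xw=Xw if config.algorithm == "rf" else Xk,
        n_bits=ds.n_bits,
    )
    out.stats_ = smoothed_stats(count_substructures(ds), k=config.k)
    return out


def _pool(scores: np.ndarray, y: np.ndarray, fold_metrics: list[Metrics]) -> Metrics:
    tp = sum(m.tp for m in fold_metrics)
    fp = sum(m.fp for m in fold_metrics)
    tn = sum(m.tn for m in fold_metrics)
    fn = sum(m.fn for m in fold_metrics)
    n = tp + fp + tn + fn
    return Metrics(
        auc_roc=float(roc_auc_score(y, scores)),
        aupr=float(average_precision_score(y, scores)),
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        tp=tp, fp=fp, tn=tn, fn=fn,
        cutoff=float("nan"),  # per-fold cutoffs differ
    )


# ---------------------------------------------------------------------------
# Grid search over (theta, n_mult)
# ---------------------------------------------------------------------------

DEFAULT_THETAS = (0.5, 1.0, 1.5, 2.0, 2.5)
DEFAULT_N_MULTS = (5.0, 10.0, 15.0, 20.0)


@dataclass
class GridResult:
    entries: list[dict]  # {"theta", "n_mult", "algorithm", "report"}
    best: dict
    selection_metric: str = "auc_roc"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            r: EvaluationReport = e["report"]
            rows.append(
                {
                    "algorithm": e["algorithm"],
                    "theta": e["theta"],
                    "n_mult": e["n_mult"],
                    **{f"pooled_{k}": v for k, v in r.pooled.as_dict().items()
                       if k not in ("tp", "fp", "tn", "fn", "cutoff")},
                    **{f"foldmean_{k}": v for k, v in r.fold_mean.items()},
                }
            )
        return pd.DataFrame(rows)


def grid_search(
    ds: LabeledFingerprintDataset,
    algorithm: str,
    thetas: Sequence[float] = DEFAULT_THETAS,
    n_mults: Sequence[float] = DEFAULT_N_MULTS,
    n_folds: int = 10,
    seed: int = 0,
    base_config: ModelConfig | None = None,
    selection_metric: str = "auc_roc",
    calibrate: bool = True,
) -> GridResult:
    """Cross-validate every (theta, n_mult) cell on one shared fold split.

    The best entry maximizes the pooled selection metric (default AUC).
    """
    if not thetas or not n_mults:
        raise ValueError("theta and n_mult grids must be non-empty")
    if base_config is None:
        base_config = ModelConfig(algorithm=algorithm, seed=seed)
    X, y, ids = ds.labeled_subset()
    fold_assignment = _stratified_folds(ids, y, n_folds, seed)

    entries = []
    for theta in thetas:
        for n_mult in n_mults:
            cfg = dataclasses.replace(
                base_config, algorithm=algorithm, theta=theta, n_mult=n_mult, seed=seed
            )
            try:
                report = crossvalidate(
                    ds, cfg, n_folds=n_folds, seed=seed,
                    calibrate=calibrate, fold_assignment=fold_assignment,
                )
            except Exception as exc:  # tag the failing cell
                raise RuntimeError(
                    f"grid cell theta={theta}, n_mult={n_mult} failed: {exc}"
                ) from exc
            entries.append(
                {"theta": theta, "n_mult": n_mult, "algorithm": algorithm,
                 "report": report}
            )
    best = max(entries, key=lambda e: getattr(e["report"].pooled, selection_metric))
    return GridResult(entries=entries, best=best, selection_metric=selection_metric)


# ---------------------------------------------------------------------------
# Independent test
# ---------------------------------------------------------------------------

def independent_test(
    model: TrainedModel,
    test_ds: LabeledFingerprintDataset,
    allow_overlap: bool = False,
) -> EvaluationReport:
    """Evaluate a frozen model (weights + cutoff from training only).

    By default any compound ID shared with the training set is an error;
    pass ``allow_overlap=True`` for deliberate resubstitution checks.
    """
    overlap = set(model.training_ids) & set(test_ds.ids)
    if overlap and not allow_overlap:
        raise ValueError(
            f"test set shares {len(overlap)} compound IDs with training "
            f"(e.g. {sorted(overlap)[:3]}); deduplicate first or pass allow_overlap=True"
        )
    mask = test_ds.labels != "unlabeled"
    sub = test_ds.subset(np.flatnonzero(mask))
    scores = predict_scores(model, sub)
    pooled = compute_metrics(scores, sub.labels, model.decision_cutoff)
    return EvaluationReport(
        config=model.config, pooled=pooled, scores=scores, labels=sub.labels
    )
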