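"""Classifiers on weighted fingerprints: Random Forest and Tanimoto-kernel SVM.

Both learners consume the weighted feature matrix produced by the
weighting stage.  The Random Forest is trained directly on the weighted
columns and scores a compound by the fraction of trees voting positive;
the SVM is trained on a precomputed Tanimoto similarity matrix of the
weighted rows, which keeps the model size at the number of compounds
rather than the number of bits.

Each trained model carries a decision cutoff calibrated so that a target
sensitivity (default 0.8) is met on held-out-style training scores:
out-of-bag votes for the forest, inner 5-fold cross-validated scores for
the SVM.  The rule ``score >= cutoff -> positive`` deliberately trades
specificity for sensitivity — in hepatotoxicity screening a missed toxic
compound is costlier than a false alarm.
"""

from __future__ import annotations

import contextlib
import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .data_io import LabeledFingerprintDataset
from .kernel import kernel_matrix
from .weighting import (
    WeightVector,
    apply_weights,
    build_weight_vector,
    count_substructures,
    smoothed_stats,
)

ALGORITHMS = ("rf", "svm")


@dataclass
class ModelConfig:
    """Hyperparameters for one weighted-fingerprint classifier.

    ``theta`` is the log-odds selection threshold, ``n_mult`` the
    amplification multiplier, ``k`` the Laplace pseudo-count.  ``theta =
    inf`` disables weighting.  RF-specific: ``n_trees``; SVM-specific:
    ``cost`` and ``kernel_variant``.
    """

    algorithm: str = "rf"
    theta: float = 1.5
    n_mult: float = 15.0
    k: float = 1.0
    n_trees: int = 500
    cost: float = 1.0
    kernel_variant: str = "continuous"
    target_sensitivity: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if not 0 < self.target_sensitivity <= 1:
            raise ValueError("target_sensitivity must be in (0, 1]")
        if self.cost <= 0:
            raise ValueError("cost must be > 0")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class TrainedModel:
    config: ModelConfig
    weight_vector: WeightVector
    learner: object
    decision_cutoff: float
    training_ids: list[str]
    train_Xw: np.ndarray  # weighted training rows; needed for test-vs-train kernels
    n_bits: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.decision_cutoff) and self.decision_cutoff != -math.inf:
            raise ValueError("decision_cutoff must be finite (or the -inf sentinel)")


def calibrate_cutoff(scores, labels, target_sensitivity: float = 0.8) -> float:
    """Largest cutoff whose positive-capture fraction meets the target.

    Returns the largest ``c`` such that the fraction of positives with
    ``score >= c`` is at least ``target_sensitivity``; this is the
    ``ceil(target * n_pos)``-th largest positive score.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    pos = scores[y == 1]
    if pos.size == 0:
        raise ValueError("cutoff calibration requires at least one positive label")
    if not 0 < target_sensitivity <= 1:
        raise ValueError("target_sensitivity must be in (0, 1]")
    m = max(1, math.ceil(target_sensitivity * pos.size - 1e-12))
    return float(np.sort(pos)[::-1][m - 1])


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iub" or labels.dtype.kind == "f":
        return labels.astype(int)
    return (labels == "positive").astype(int)


@contextlib.contextmanager
def _quiet_svc():
    """Silence the sklearn-1.9 deprecation notice for SVC(probability=True).

    Platt-scaled SVC probabilities are the standard score-to-probability
    mapping for a precomputed-kernel SVM and remain supported here.
    """
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*probability.*deprecated.*", category=FutureWarning
        )
        yield


def _fit_svm(K: np.ndarray, y: np.ndarray, config: ModelConfig) -> SVC:
    clf = SVC(
        C=config.cost,
        kernel="precomputed",
        probability=True,
        random_state=config.seed,
    )
    with _quiet_svc():
        clf.fit(K, y)
    return clf


def _positive_proba(clf, X: np.ndarray) -> np.ndarray:
    proba = clf.predict_proba(X)
    pos_col = list(clf.classes_).index(1)
    return proba[:, pos_col]


def train(
    ds: LabeledFingerprintDataset,
    config: ModelConfig,
    calibrate: bool = True,
) -> TrainedModel:
    """Fit weights + learner on the labeled records of ``ds``.

    The weight vector is computed from ``ds`` only; the decision cutoff
    is calibrated on out-of-bag votes (RF) or inner 5-fold
    cross-validated scores (SVM) rather than resubstitution scores.  With
    ``calibrate=False`` the cutoff is fixed at 0.5.
    """
    counts = count_substructures(ds)
    stats = smoothed_stats(counts, k=config.k)
    wv = build_weight_vector(stats, config.theta, config.n_mult)

    X, y, ids = ds.labeled_subset()
    Xw = apply_weights(X, wv)
    # binary kernel variant = similarity on the raw 0/1 fingerprints;
    # continuous = similarity on the weighted rows
    Xk = X.astype(float) if config.kernel_variant == "binary" else Xw

    if config.algorithm == "rf":
        clf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features="sqrt",
            oob_score=calibrate,
            random_state=config.seed,
            n_jobs=1,
        )
        clf.fit(Xw, y)
        if calibrate:
            pos_col = list(clf.classes_).index(1)
            calib_scores = np.nan_to_num(clf.oob_decision_function_[:, pos_col], nan=0.5)
            cutoff = calibrate_cutoff(calib_scores, y, config.target_sensitivity)
        else:
            cutoff = 0.5
    else:
        K = kernel_matrix(Xk, variant=config.kernel_variant).K
        clf = _fit_svm(K, y, config)
        if calibrate:
            n_splits = min(5, int((y == 1).sum()), int((y == 0).sum()))
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
            inner = SVC(
                C=config.cost, kernel="precomputed", probability=True,
                random_state=config.seed,
            )
            with _quiet_svc():
                proba = cross_val_predict(inner, K, y, cv=cv, method="predict_proba")
            calib_scores = proba[:, 1]
            cutoff = calibrate_cutoff(calib_scores, y, config.target_sensitivity)
        else:
            cutoff = 0.5

    model = TrainedModel(
        config=config,
        weight_vector=wv,
        learner=clf,
        decision_cutoff=cutoff,
        training_ids=ids,
        train_Xw=Xw if config.algorithm == "rf" else Xk,
        n_bits=ds.n_bits,
    )
    model.stats_ = stats  # kept for alert reporting
    return model


def predict_scores(model: TrainedModel, ds: LabeledFingerprintDataset) -> np.ndarray:
    """Score each compound in ``ds``; higher means more likely hepatotoxic."""
    if ds.n_bits != model.n_bits:
        raise ValueError(
            f"bit-dimension mismatch: model expects {model.n_bits}, dataset has {ds.n_bits}"
        )
    if ds.n_compounds == 0:
        return np.empty(0, dtype=float)
    if model.config.algorithm == "rf":
        Xw = apply_weights(ds.X, model.weight_vector)
        return _positive_proba(model.learner, Xw)
    if model.config.kernel_variant == "binary":
        Xk = ds.X.astype(float)
    else:
        Xk = apply_weights(ds.X, model.weight_vector)
    K = kernel_matrix(Xk, model.train_Xw, variant=model.config.kernel_variant).K
    return _positive_proba(model.learner, K)


def predict_labels(model: TrainedModel, ds: LabeledFingerprintDataset) -> np.ndarray:
    """Classify each compound: positive iff ``score >= decision_cutoff``."""
    scores = predict_scores(model, ds)
    return np.where(scores >= model.decision_cutoff, "positive", "negative")


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, out_dir: str | Path) -> None:
    """Persist to a directory: weight CSV, config JSON, learner blob, ID list."""
    from .weighting import write_weight_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_weight_table(model.weight_vector, model.stats_, out / "weights.csv",
                       out / "weights.json")
    cfg = asdict(model.config)
    cfg["decision_cutoff"] = model.decision_cutoff
    cfg["n_bits"] = model.n_bits
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
    (out / "training_ids.txt").write_text("\n".join(model.training_ids) + "\n")
    joblib.dump({"learner": model.learner, "train_Xw": model.train_Xw,
                 "stats": model.stats_}, out / "learner.joblib")


def load_model(out_dir: str | Path) -> TrainedModel:
    """Reload a persisted model; predictions are reproduced bit-identically."""
    from .weighting import read_weight_table

    out = Path(out_dir)
    cfg = json.loads((out / "config.json").read_text())
    cutoff = cfg.pop("decision_cutoff")
    n_bits = cfg.pop("n_bits")
    config = ModelConfig(**cfg)
    wv = read_weight_table(out / "weights.csv", out / "weights.json")
    blob = joblib.load(out / "learner.joblib")
    ids = (out / "training_ids.txt").read_text().splitlines()
    model = TrainedModel(
        config=config,
        weight_vector=wv,
        learner=blob["learner"],
        decision_cutoff=cutoff,
        training_ids=ids,
        train_Xw=blob["train_Xw"],
        n_bits=n_bits,
    )
    model.stats_ = blob["stats"]
    return model
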