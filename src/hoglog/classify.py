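"""Multiclass SVM behaviour classification with a probability gate.

A one-vs-one RBF support-vector machine with pairwise-coupled probability
calibration is trained on labelled bursts of three classes (immobile,
balling, locomotion).  At prediction time the winning class is accepted only
when its calibrated probability strictly exceeds a threshold tau (default
0.7); otherwise the burst is labelled "other", absorbing behaviours the
training set does not represent.

Evaluation is leave-one-out per burst: each labelled burst is predicted by a
model refit on the remaining bursts, and per-class recall, precision and the
"other" fraction are reported.  Per-individual cross-validation is available
as an option for deployments where bursts within an animal are not
exchangeable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FEATURE_COLUMNS

CLASSES = ("immobile", "balling", "locomotion")
OTHER = "other"
DEFAULT_TAU = 0.7


@dataclass
class BehaviorModel:
    """Fitted SVM plus the training standardization and the gate threshold."""

    svc: SVC
    feature_names: list[str]
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    classes: tuple[str, ...]
    tau: float = DEFAULT_TAU

    def metadata(self) -> dict:
        return {
            "classes": list(self.classes),
            "tau": self.tau,
            "feature_names": self.feature_names,
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
        }

    def save(self, path) -> None:
        """Serialize model (joblib) next to a JSON metadata sidecar."""
        import joblib

        joblib.dump(self, path)
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


@dataclass
class EvaluationReport:
    """Confusion matrix and the derived per-class recall/precision."""

    confusion: pd.DataFrame  # rows: true class, cols: predicted (incl. other)
    recall: dict[str, float]
    precision: dict[str, float]
    other_count: int
    other_fraction: float
    n: int = 0
    extras: dict = field(default_factory=dict)


def _as_matrix(features, feature_names: list[str]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[feature_names].to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def train(
    features,
    labels,
    tau: float = DEFAULT_TAU,
    feature_names: list[str] | None = None,
    random_state: int = 0,
) -> BehaviorModel:
    """Fit the gated multiclass SVM.

    ``features`` is a DataFrame containing the predictor columns (or a plain
    matrix); rows with missing predictor values must already be excluded.
    Raises on single-class input.
    """
    if feature_names is None:
        feature_names = list(FEATURE_COLUMNS)
    X = _as_matrix(features, feature_names)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training requires at least 2 behaviour classes")
    if np.isnan(X).any():
        raise ValueError("training features contain missing values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0.0, sd, 1.0)
    Xz = (X - mean) / sd
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates probability=True; the pairwise-coupled
        # Platt calibration it performs is exactly the method wanted here
        warnings.simplefilter("ignore", FutureWarning)
        svc = SVC(
            kernel="rbf",
            probability=True,
            decision_function_shape="ovo",
            random_state=random_state,
        )
        svc.fit(Xz, y)
    return BehaviorModel(
        svc=svc,
        feature_names=feature_names,
        scale_mean=mean,
        scale_sd=sd,
        classes=tuple(svc.classes_),
        tau=tau,
    )


def predict_proba(model: BehaviorModel, features) -> pd.DataFrame:
    """Per-class calibrated probabilities (rows sum to 1)."""
    X = _as_matrix(features, model.feature_names)
    Xz = (X - model.scale_mean) / model.scale_sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        proba = model.svc.predict_proba(Xz)
    return pd.DataFrame(proba, columns=list(model.svc.classes_))


def gate_probabilities(proba: pd.DataFrame, tau: float) -> pd.Series:
    """Apply the probability gate: argmax class if its probability strictly
    exceeds tau, else "other"."""
    win = proba.idxmax(axis=1)
    pmax = proba.max(axis=1)
    return pd.Series(np.where(pmax > tau, win, OTHER), index=proba.index, name="label")


def predict_gated(model: BehaviorModel, features, tau: float | None = None) -> pd.Series:
    """Gated class labels; rows with missing predictors become "other"."""
    if tau is None:
        tau = model.tau
    X = _as_matrix(features, model.feature_names)
    bad = np.isnan(X).any(axis=1)
    labels = pd.Series(OTHER, index=range(len(X)), name="label", dtype=object)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} feature rows with missing values classified as 'other'",
            stacklevel=2,
        )
    if (~bad).any():
        proba = predict_proba(model, X[~bad])
        labels.loc[np.nonzero(~bad)[0]] = gate_probabilities(proba, tau).to_numpy()
    if isinstance(features, pd.DataFrame):
        labels.index = features.index
    return labels


def evaluate_predictions(y_true, y_pred, classes=CLASSES) -> EvaluationReport:
    """Confusion matrix, per-class recall and precision, and "other" share.

    Recall counts gated-away ("other") bursts as misses of their true class;
    precision is computed over bursts assigned to the class.
    """
    y_true = pd.Series(np.asarray(y_true, dtype=object))
    y_pred = pd.Series(np.asarray(y_pred, dtype=object))
    pred_classes = list(classes) + [OTHER]
    conf = pd.DataFrame(0, index=list(classes), columns=pred_classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    recall, precision = {}, {}
    for c in classes:
        tp = conf.loc[c, c]
        recall[c] = tp / max(1, conf.loc[c].sum())
        precision[c] = tp / max(1, conf[c].sum()) if conf[c].sum() else float("nan")
    other_count = int(conf[OTHER].sum())
    return EvaluationReport(
        confusion=conf,
        recall=recall,
        precision=precision,
        other_count=other_count,
        other_fraction=other_count / max(1, len(y_true)),
        n=len(y_true),
    )


def loocv(
    features,
    labels,
    tau: float = DEFAULT_TAU,
    gated: bool = True,
    groups=None,
    feature_names: list[str] | None = None,
    random_state: int = 0,
) -> EvaluationReport:
    """Leave-one-out cross-validation of the gated classifier.

    Per burst by default; pass ``groups`` (e.g. individual ids) for
    leave-one-group-out.  With ``gated=False`` the raw argmax label is scored
    instead (the gate applied only in deployment).
    """
    if feature_names is None:
        feature_names = list(FEATURE_COLUMNS)
    X = _as_matrix(features, feature_names)
    y = np.asarray(labels)
    if len(y) < 3:
        raise ValueError("leave-one-out needs at least 3 bursts")
    if groups is None:
        folds = [(np.arange(len(y)) != i, np.array([i])) for i in range(len(y))]
    else:
        groups = np.asarray(groups)
        folds = [(groups != g, np.nonzero(groups == g)[0]) for g in np.unique(groups)]
    y_pred = np.empty(len(y), dtype=object)
    for train_mask, test_idx in folds:
        m = train(
            X[train_mask], y[train_mask], tau=tau,
            feature_names=list(range(X.shape[1])), random_state=random_state,
        )
        proba = predict_proba(m, X[test_idx])
        if gated:
            y_pred[test_idx] = gate_probabilities(proba, tau).to_numpy()
        else:
            y_pred[test_idx] = proba.idxmax(axis=1).to_numpy()
    return evaluate_predictions(y, y_pred, classes=tuple(np.unique(y)))


def daily_budget(
    predictions: pd.DataFrame, min_bursts: int = 1430
) -> pd.DataFrame:
    """Daily behaviour budgets: per individual-day counts of each label.

    ``predictions`` needs individual_id, timestamp and label columns.  Days
    (00:00-23:59) whose kept-burst count falls below ``min_bursts`` are
    excluded — the completeness filter guarding against time-of-day bias.
    """
    df = predictions.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    all_labels = list(CLASSES) + [OTHER]
    counts = (
        df.groupby(["individual_id", "date"])["label"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=all_labels, fill_value=0)
        .reset_index()
    )
    counts["n_bursts"] = counts[all_labels].sum(axis=1)
    kept = counts[counts["n_bursts"] >= min_bursts].reset_index(drop=True)
    kept.columns.name = None
    return kept
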