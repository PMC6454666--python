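"""End-to-end evidential ensemble: calibrate, weight, fuse, evaluate.

`EvidentialEnsembleClassifier` is a scikit-learn-style estimator over a
patient x base-model score matrix.  Fitting (i) picks a per-model ROC
top-left threshold, (ii) min-max normalizes unbounded channels, (iii)
derives rough-set weights from the dichotomized table, and (iv) calibrates
a threshold on the fused decision values.  Prediction rescales each
channel so its threshold sits at 0.5, builds weighted basic probability
assignments, combines them with Dempster's rule and thresholds the
resulting decision value R = m(1)/(m(0)+m(1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .calibration import ModelCalibration, top_left_threshold
from .evidence import (
    belief_plausibility,
    classify,
    combine_all,
    decision_value,
    weighted_bpa,
)
from .rough_set import DecisionTable, compute_weights

__all__ = [
    "ScoreMatrix",
    "EvidentialEnsembleClassifier",
    "EvaluationReport",
    "auc",
    "accuracy",
    "cross_validate",
]


@dataclass(frozen=True)
class ScoreMatrix:
    """Patient ids x base-model raw scores, with optional binary outcomes.

    ``scores`` is a DataFrame indexed by patient id with one column per
    model; ``labels`` is an aligned 0/1 Series or None.
    """

    scores: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self):
        if self.scores.index.has_duplicates:
            raise ValueError("patient identifiers must be unique")
        if self.scores.columns.has_duplicates:
            raise ValueError("model identifiers must be unique")
        if self.scores.isna().any().any():
            raise ValueError("score matrix contains missing values")
        if not all(np.issubdtype(dt, np.number) for dt in self.scores.dtypes):
            raise ValueError("scores must be numeric")
        if self.labels is not None:
            if not self.labels.index.equals(self.scores.index):
                raise ValueError("labels must align with the score matrix index")
            bad = ~self.labels.isin([0, 1])
            if bad.any():
                raise ValueError(
                    f"labels must be 0/1; offending patients: "
                    f"{list(self.labels.index[bad][:5])}"
                )

    @property
    def patient_ids(self) -> list:
        return list(self.scores.index)

    @property
    def model_ids(self) -> list[str]:
        return [str(c) for c in self.scores.columns]

    def subset(self, row_positions) -> "ScoreMatrix":
        scores = self.scores.iloc[row_positions]
        labels = None if self.labels is None else self.labels.iloc[row_positions]
        return ScoreMatrix(scores, labels)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, ScoreMatrix):
        return X.scores
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be a 2-D score matrix")
    return pd.DataFrame(arr, columns=[f"model_{j}" for j in range(arr.shape[1])])


class EvidentialEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Evidential fusion of base-model risk scores on a binary outcome.

    Parameters
    ----------
    normalize : "auto" or dict
        "auto" fits min-max bounds (training min/max) for every channel
        whose training scores leave [0, 1]; a dict maps model id to
        explicit ``(min, max)`` bounds and disables auto-detection for
        the listed channels.  Probability-like channels pass through.
    entropy_direction : {"decision-given-attrs", "as-printed"}
        Conditioning direction of the rough-set dependence measure used
        for the model weights.  The default conditions the outcome
        partition on the attribute partition, H(R|A); "as-printed" swaps
        the roles (an alternative reading kept for auditability).

    Attributes
    ----------
    model_ids_ : list of str
    calibrations_ : dict of model id -> ModelCalibration
    weights_ : ndarray on the simplex, one entry per model
    decision_threshold_ : float
        Cut-off on the fused decision value (strict: R > t is positive).
    classes_ : ndarray([0, 1])
    """

    def __init__(self, normalize="auto", entropy_direction="decision-given-attrs"):
        self.normalize = normalize
        self.entropy_direction = entropy_direction

    # -- construction from known parameters (e.g. a persisted model) ------

    @classmethod
    def from_parameters(
        cls,
        calibrations,
        weights,
        decision_threshold: float,
        entropy_direction: str = "decision-given-attrs",
    ) -> "EvidentialEnsembleClassifier":
        """Assemble a ready-to-predict ensemble from explicit parameters.

        ``calibrations`` is an ordered iterable of :class:`ModelCalibration`;
        ``weights`` aligns with it and must lie on the simplex.
        """
        calibrations = list(calibrations)
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(calibrations):
            raise ValueError("one weight per calibration required")
        # rounded published weight vectors (4 decimals) may miss the simplex
        # by ~1e-4; accept small slack and use the weights exactly as given
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-3:
            raise ValueError("weights must be non-negative and sum to 1")
        if not 0.0 < decision_threshold < 1.0:
            raise ValueError("decision threshold must lie in (0, 1)")
        est = cls(entropy_direction=entropy_direction)
        est.model_ids_ = [c.model_id for c in calibrations]
        est.calibrations_ = {c.model_id: c for c in calibrations}
        est.weights_ = weights
        est.decision_threshold_ = float(decision_threshold)
        est.classes_ = np.array([0, 1])
        return est

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        df = _as_frame(X)
        y = np.asarray(y)
        if y.shape != (len(df),):
            raise ValueError("y must have one label per row of X")
        if not np.isin(y, [0, 1]).all():
            raise ValueError("y must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("threshold undefined for single-class data")
        if df.shape[1] < 1:
            raise ValueError("need at least one base model")

        model_ids = [str(c) for c in df.columns]
        explicit = self.normalize if isinstance(self.normalize, dict) else {}

        calibrations: dict[str, ModelCalibration] = {}
        for mid in model_ids:
            col = df[mid].to_numpy(dtype=float)
            if np.unique(col).size < 2:
                raise ValueError(
                    f"model {mid!r} has constant scores; threshold undefined"
                )
            raw_t = top_left_threshold(col, y)
            if mid in explicit:
                bounds = tuple(float(b) for b in explicit[mid])
            elif self.normalize == "auto" and (col.min() < 0.0 or col.max() > 1.0):
                bounds = (float(col.min()), float(col.max()))
            else:
                bounds = None
            calibrations[mid] = ModelCalibration(mid, float(raw_t), bounds)

        dich = np.column_stack(
            [calibrations[mid].dichotomize(df[mid].to_numpy(float)) for mid in model_ids]
        )
        table = DecisionTable(model_ids, dich, y)
        weights = compute_weights(table, direction=self.entropy_direction)

        self.model_ids_ = model_ids
        self.calibrations_ = calibrations
        self.weights_ = weights
        self.classes_ = np.array([0, 1])

        train_r = self._decision_values(df)
        self.decision_threshold_ = top_left_threshold(train_r, y)
        return self

    # -- prediction --------------------------------------------------------

    def _check_fitted_frame(self, X) -> pd.DataFrame:
        if not hasattr(self, "calibrations_"):
            raise AttributeError("estimator is not fitted")
        df = _as_frame(X)
        cols = [str(c) for c in df.columns]
        if cols != self.model_ids_:
            raise ValueError(
                f"model/data column mismatch: fitted on {self.model_ids_}, got {cols}"
            )
        return df

    def _decision_values(self, df: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(df))
        for i, (_, row) in enumerate(df.iterrows()):
            bpas = [
                weighted_bpa(float(self.calibrations_[mid].adjust(row[mid])), w)
                for mid, w in zip(self.model_ids_, self.weights_)
            ]
            out[i] = decision_value(combine_all(bpas))
        return out

    def decision_function(self, X) -> np.ndarray:
        """Fused decision value R in [0, 1] per patient."""
        return self._decision_values(self._check_fitted_frame(X))

    def predict(self, X) -> np.ndarray:
        r = self.decision_function(X)
        return (r > self.decision_threshold_).astype(int)

    def predict_detail(self, X) -> pd.DataFrame:
        """Full per-patient evidence trace, for explanation output.

        One row per patient with raw, normalized and adjusted outputs,
        the per-model and combined masses, the decision value, the
        predicted label and the belief/plausibility interval for the
        positive outcome.
        """
        df = self._check_fitted_frame(X)
        records = []
        for _, row in df.iterrows():
            rec: dict[str, float] = {}
            bpas = []
            for mid, w in zip(self.model_ids_, self.weights_):
                cal = self.calibrations_[mid]
                raw = float(row[mid])
                unit = float(cal.to_unit(raw))
                a_star = float(cal.adjust(raw))
                m = weighted_bpa(a_star, w)
                bpas.append(m)
                rec[f"raw_{mid}"] = raw
                rec[f"norm_{mid}"] = unit
                rec[f"adjusted_{mid}"] = a_star
                rec[f"m_pos_{mid}"] = m.m_pos
                rec[f"m_neg_{mid}"] = m.m_neg
                rec[f"m_theta_{mid}"] = m.m_theta
            combined = combine_all(bpas)
            r = decision_value(combined)
            bel, pl = belief_plausibility(combined)
            rec.update(
                combined_m_pos=combined.m_pos,
                combined_m_neg=combined.m_neg,
                combined_m_theta=combined.m_theta,
                decision_value=r,
                prediction=classify(r, self.decision_threshold_),
                belief=bel,
                plausibility=pl,
            )
            records.append(rec)
        out = pd.DataFrame.from_records(records, index=df.index)
        out.index.name = "patient_id"
        return out


# -- evaluation ------------------------------------------------------------


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for single-class data")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def accuracy(predictions, labels) -> float:
    """Fraction of exact matches between predicted and actual labels."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    return float(np.mean(predictions == labels))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold AUC/accuracy plus mean and sample (n-1) standard deviation."""

    per_fold: pd.DataFrame  # columns: fold, auc, accuracy

    @property
    def summary(self) -> pd.DataFrame:
        metrics = self.per_fold[["auc", "accuracy"]]
        return pd.DataFrame(
            {"mean": metrics.mean(), "sd": metrics.std(ddof=1)}
        ).T

    @classmethod
    def from_fold_values(cls, aucs, accuracies) -> "EvaluationReport":
        aucs = list(aucs)
        accuracies = list(accuracies)
        if len(aucs) != len(accuracies):
            raise ValueError("need one accuracy per AUC value")
        return cls(
            pd.DataFrame(
                {"fold": range(1, len(aucs) + 1), "auc": aucs, "accuracy": accuracies}
            )
        )


def cross_validate(
    data: ScoreMatrix, k: int = 5, seed: int = 0, **estimator_params
) -> EvaluationReport:
    """Stratified k-fold evaluation of the evidential ensemble.

    Each fold fits a fresh ensemble on the remaining k-1 folds and scores
    the held-out fold by AUC (of the decision values) and accuracy (of
    the thresholded labels).  Fully reproducible given ``seed``.
    """
    if data.labels is None:
        raise ValueError("cross-validation requires labels")
    if k < 2:
        raise ValueError("k must be >= 2")
    y = data.labels.to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(data.scores, y), start=1):
        train, test = data.subset(train_idx), data.subset(test_idx)
        est = EvidentialEnsembleClassifier(**estimator_params).fit(
            train.scores, train.labels.to_numpy()
        )
        r = est.decision_function(test.scores)
        y_test = test.labels.to_numpy()
        rows.append(
            {
                "fold": fold,
                "auc": auc(r, y_test),
                "accuracy": accuracy((r > est.decision_threshold_).astype(int), y_test),
            }
        )
    return EvaluationReport(pd.DataFrame(rows))
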