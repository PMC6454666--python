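"""Embedded reference data: the 10-patient worked example and fold metrics.

The worked example is a small ACS cohort excerpt with the raw outputs of
four base models -- an SVM, an L1-regularized logistic regression, a
classification tree (all probabilities) and the integer GRACE risk score
-- together with the calibration parameters fitted on the full original
cohort and every intermediate quantity of the fusion pipeline (dichotomized
calls, adjusted outputs, per-model and combined masses, decision values,
predicted and actual MACE labels).  It serves as the golden fixture for
the whole pipeline.

``reference_fold_metrics`` carries the 5-fold AUC and accuracy values
reported for each single model and the evidential ensemble on the original
2930-patient cohort; only the aggregation arithmetic (mean, sample SD) is
reproducible from them, not the underlying predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ModelCalibration
from .ensemble import ScoreMatrix

__all__ = ["WorkedExample", "worked_example", "reference_fold_metrics"]

MODEL_IDS = ["SVM", "L1-LR", "CART", "GRACE"]

_RAW = [
    # SVM     L1-LR   CART    GRACE  actual MACE
    (0.7434, 0.6032, 0.6716, 201, 1),
    (0.1250, 0.1884, 0.1890, 85, 0),
    (0.2651, 0.1798, 0.1890, 56, 0),
    (0.1735, 0.3272, 0.3277, 92, 0),
    (0.1608, 0.3347, 0.3277, 119, 0),
    (0.7260, 0.6531, 0.6716, 132, 0),
    (0.1601, 0.3104, 0.3346, 133, 1),
    (0.1171, 0.1927, 0.1890, 137, 0),
    (0.4829, 0.3041, 0.3346, 92, 1),
    (0.1743, 0.2050, 0.3277, 97, 0),
]

_THRESHOLDS = {"SVM": 0.2348, "L1-LR": 0.2689, "CART": 0.2584, "GRACE": 106.5}
_WEIGHTS = {"SVM": 0.5363, "L1-LR": 0.1765, "CART": 0.1177, "GRACE": 0.1696}
_GRACE_BOUNDS = (37.0, 201.0)
_DECISION_THRESHOLD = 0.4759

_DICHOTOMIZED = [
    (1, 1, 1, 1),
    (0, 0, 0, 0),
    (1, 0, 0, 0),
    (0, 1, 1, 0),
    (0, 1, 1, 1),
    (1, 1, 1, 1),
    (0, 1, 1, 1),
    (0, 0, 0, 1),
    (1, 1, 1, 0),
    (0, 0, 1, 0),
]

_ADJUSTED = [
    (0.8323, 0.7286, 0.7786, 1.0000),
    (0.2663, 0.3503, 0.3658, 0.3453),
    (0.5198, 0.3344, 0.3658, 0.1367),
    (0.3695, 0.5399, 0.5468, 0.3957),
    (0.3424, 0.5450, 0.5468, 0.5661),
    (0.8210, 0.7628, 0.7786, 0.6349),
    (0.3409, 0.5284, 0.5514, 0.6402),
    (0.2494, 0.3583, 0.3658, 0.6614),
    (0.6621, 0.5241, 0.5514, 0.3957),
    (0.3712, 0.3812, 0.5468, 0.4317),
]

_M_POS = [
    (0.2905, 0.1093, 0.0820, 0.1450),
    (0.0929, 0.0525, 0.0385, 0.0501),
    (0.1814, 0.0502, 0.0385, 0.0198),
    (0.1290, 0.0810, 0.0576, 0.0574),
    (0.1195, 0.0817, 0.0576, 0.0821),
    (0.2866, 0.1144, 0.0820, 0.0921),
    (0.1190, 0.0793, 0.0581, 0.0928),
    (0.0870, 0.0537, 0.0385, 0.0959),
    (0.2311, 0.0786, 0.0581, 0.0574),
    (0.1296, 0.0572, 0.0576, 0.0626),
]

_M_NEG = [
    (0.0585, 0.0407, 0.0233, 0.0000),
    (0.2561, 0.0975, 0.0668, 0.0949),
    (0.1676, 0.0998, 0.0668, 0.1252),
    (0.2201, 0.0690, 0.0477, 0.0876),
    (0.2296, 0.0683, 0.0477, 0.0629),
    (0.0625, 0.0356, 0.0233, 0.0529),
    (0.2301, 0.0707, 0.0472, 0.0522),
    (0.2620, 0.0962, 0.0668, 0.0491),
    (0.1180, 0.0714, 0.0472, 0.0876),
    (0.2195, 0.0928, 0.0477, 0.0824),
]

# per-model m(Θ) = 1/(w+1) is instance-independent
_M_THETA = (0.6509, 0.8500, 0.8947, 0.8550)

_COMBINED = [
    # m(1)   m(0)    m(Θ)   decision value  prediction
    (0.4806, 0.0762, 0.4432, 0.8631, 1),
    (0.1549, 0.3894, 0.4557, 0.2845, 0),
    (0.2046, 0.3360, 0.4594, 0.3785, 0),
    (0.2260, 0.3133, 0.4607, 0.4190, 0),
    (0.2371, 0.3012, 0.4617, 0.4404, 0),
    (0.4396, 0.1100, 0.4504, 0.7999, 1),
    (0.2433, 0.2947, 0.4620, 0.4523, 0),
    (0.1834, 0.3564, 0.4603, 0.3397, 0),
    (0.3146, 0.2242, 0.4611, 0.5839, 1),
    (0.2124, 0.3278, 0.4598, 0.3931, 0),
]


@dataclass(frozen=True)
class WorkedExample:
    """The 10-patient example with calibration inputs and expected outputs."""

    score_matrix: ScoreMatrix
    thresholds: dict[str, float]
    weights: dict[str, float]
    grace_bounds: tuple[float, float]
    decision_threshold: float
    expected_dichotomized: pd.DataFrame
    expected_adjusted: pd.DataFrame
    expected_m_pos: pd.DataFrame
    expected_m_neg: pd.DataFrame
    expected_m_theta: pd.Series
    expected_combined: pd.DataFrame  # m_pos, m_neg, m_theta per instance
    expected_decision_values: pd.Series
    expected_predictions: pd.Series

    def calibrations(self) -> list[ModelCalibration]:
        """ModelCalibration objects in model order (GRACE min-max normalized)."""
        return [
            ModelCalibration(
                mid,
                self.thresholds[mid],
                self.grace_bounds if mid == "GRACE" else None,
            )
            for mid in MODEL_IDS
        ]

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[mid] for mid in MODEL_IDS])


def worked_example() -> WorkedExample:
    """The embedded 10-patient fixture, exactly as printed."""
    ids = pd.RangeIndex(1, 11, name="patient_id")
    raw = pd.DataFrame(
        [r[:4] for r in _RAW], columns=MODEL_IDS, index=ids, dtype=float
    )
    labels = pd.Series([r[4] for r in _RAW], index=ids, name="label")

    def frame(rows, dtype=float):
        return pd.DataFrame(rows, columns=MODEL_IDS, index=ids, dtype=dtype)

    combined = pd.DataFrame(
        [(c[0], c[1], c[2]) for c in _COMBINED],
        columns=["m_pos", "m_neg", "m_theta"],
        index=ids,
    )
    return WorkedExample(
        score_matrix=ScoreMatrix(raw, labels),
        thresholds=dict(_THRESHOLDS),
        weights=dict(_WEIGHTS),
        grace_bounds=_GRACE_BOUNDS,
        decision_threshold=_DECISION_THRESHOLD,
        expected_dichotomized=frame(_DICHOTOMIZED, dtype=int),
        expected_adjusted=frame(_ADJUSTED),
        expected_m_pos=frame(_M_POS),
        expected_m_neg=frame(_M_NEG),
        expected_m_theta=pd.Series(_M_THETA, index=MODEL_IDS),
        expected_combined=combined,
        expected_decision_values=pd.Series(
            [c[3] for c in _COMBINED], index=ids, name="decision_value"
        ),
        expected_predictions=pd.Series(
            [c[4] for c in _COMBINED], index=ids, name="prediction"
        ),
    )


# 5-fold AUC / accuracy per model on the original cohort (reported values;
# inputs to the aggregation conventions, not reproducible from data here)
_FOLD_AUC = {
    "SVM": (0.742, 0.696, 0.704, 0.682, 0.711),
    "L1-LR": (0.724, 0.715, 0.689, 0.702, 0.704),
    "CART": (0.644, 0.664, 0.594, 0.604, 0.645),
    "GRACE": (0.641, 0.629, 0.635, 0.640, 0.636),
    "ensemble": (0.736, 0.713, 0.707, 0.700, 0.717),
}

_FOLD_ACC = {
    "SVM": (0.715, 0.662, 0.635, 0.695, 0.676),
    "L1-LR": (0.725, 0.703, 0.684, 0.659, 0.677),
    "CART": (0.693, 0.679, 0.715, 0.734, 0.696),
    "GRACE": (0.625, 0.592, 0.560, 0.679, 0.601),
    "ensemble": (0.724, 0.717, 0.674, 0.671, 0.686),
}


def reference_fold_metrics() -> dict[str, pd.DataFrame]:
    """Reported per-fold AUC and accuracy for each model (5 folds).

    Keys are model ids plus "ensemble"; each value is a DataFrame with
    columns ``fold``, ``auc``, ``accuracy``.
    """
    out = {}
    for mid in _FOLD_AUC:
        out[mid] = pd.DataFrame(
            {
                "fold": range(1, 6),
                "auc": _FOLD_AUC[mid],
                "accuracy": _FOLD_ACC[mid],
            }
        )
    return out
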