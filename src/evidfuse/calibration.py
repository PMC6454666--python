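"""Per-model threshold calibration and output rescaling.

Each base model (a probabilistic classifier or an integer risk score such
as GRACE) gets an operating threshold chosen from the ROC curve: the
observed score whose (FPR, TPR) point lies closest to the ideal top-left
corner (0, 1).  Unbounded scores are min-max normalized to [0, 1]; every
channel is then rescaled by a piecewise-linear map so that its own
threshold lands exactly at 0.5, putting all channels on a common scale
before evidence construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelCalibration",
    "top_left_threshold",
    "dichotomize",
    "minmax_normalize",
    "adjust_to_half",
]


def top_left_threshold(scores, labels) -> float:
    """Observed score minimizing the ROC distance to the top-left corner.

    A case is called positive iff ``score > t`` (strict).  The candidate
    set is the observed score values; among ties the smallest threshold
    (most sensitive operating point) wins.

    Raises
    ------
    ValueError
        If the labels contain a single class -- the ROC point is then
        degenerate and the threshold undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold undefined for single-class data")

    candidates = np.unique(scores)  # ascending, so argmin tie-breaks small
    # predicted positive iff score > t, for every candidate t at once
    pred = scores[None, :] > candidates[:, None]
    tp = np.sum(pred & (labels == 1)[None, :], axis=1)
    fp = np.sum(pred & (labels == 0)[None, :], axis=1)
    tpr = tp / n_pos
    fpr = fp / n_neg
    dist2 = fpr**2 + (1.0 - tpr) ** 2
    return float(candidates[int(np.argmin(dist2))])


def dichotomize(score, threshold):
    """Binary call under the strict rule: 1 iff score > threshold."""
    return (np.asarray(score, dtype=float) > threshold).astype(int)[()]


def minmax_normalize(score, min_bound: float, max_bound: float):
    """Map a raw score affinely onto [0, 1] using fitted bounds.

    Scores outside the fitted bounds (possible at predict time, since the
    bounds come from the training cohort) are clipped to [0, 1].
    """
    if not min_bound < max_bound:
        raise ValueError(
            f"min_bound must be < max_bound, got ({min_bound}, {max_bound})"
        )
    a = (np.asarray(score, dtype=float) - min_bound) / (max_bound - min_bound)
    return np.clip(a, 0.0, 1.0)[()]


def adjust_to_half(a, unit_threshold: float):
    """Piecewise-linear rescaling sending a channel's threshold to 0.5.

    Below the threshold the unit interval [0, t] maps linearly onto
    [0, 0.5]; above, [t, 1] maps onto [0.5, 1].  Monotone non-decreasing,
    fixes 0 and 1, and sends ``unit_threshold`` to exactly 0.5, so the
    strict dichotomization ``a > t`` is equivalent to ``A*(a) > 0.5``.
    """
    if not 0.0 < unit_threshold < 1.0:
        raise ValueError(
            f"unit_threshold must lie strictly inside (0, 1), got {unit_threshold}"
        )
    a = np.asarray(a, dtype=float)
    if np.any((a < 0.0) | (a > 1.0)):
        raise ValueError("adjusted inputs must lie in [0, 1]")
    below = 0.5 * a / unit_threshold
    above = 0.5 * (a - unit_threshold) / (1.0 - unit_threshold) + 0.5
    return np.where(a < unit_threshold, below, np.where(a > unit_threshold, above, 0.5))[()]


@dataclass(frozen=True)
class ModelCalibration:
    """Fitted calibration for one base model.

    ``raw_threshold`` lives on the model's raw output scale; when
    ``normalization`` bounds are present the raw score is min-max mapped
    to [0, 1] first and the threshold travels through the same map.
    """

    model_id: str
    raw_threshold: float
    normalization: tuple[float, float] | None = None

    def __post_init__(self):
        if self.normalization is not None:
            lo, hi = self.normalization
            if not lo < hi:
                raise ValueError(
                    f"normalization bounds must satisfy min < max, got ({lo}, {hi})"
                )
        t = self.unit_threshold
        if not 0.0 < t < 1.0:
            raise ValueError(
                f"model {self.model_id!r}: unit threshold {t} outside (0, 1)"
            )

    @property
    def unit_threshold(self) -> float:
        """The raw threshold on the normalized [0, 1] scale."""
        if self.normalization is None:
            return float(self.raw_threshold)
        lo, hi = self.normalization
        return float((self.raw_threshold - lo) / (hi - lo))

    def to_unit(self, score):
        """Raw score -> [0, 1] scale (min-max normalized when configured)."""
        if self.normalization is None:
            a = np.asarray(score, dtype=float)
            if np.any((a < 0.0) | (a > 1.0)):
                raise ValueError(
                    f"model {self.model_id!r}: score outside [0, 1] on an "
                    "un-normalized channel"
                )
            return a[()]
        return minmax_normalize(score, *self.normalization)

    def adjust(self, score):
        """Raw score -> adjusted output A* with the threshold at 0.5."""
        return adjust_to_half(self.to_unit(score), self.unit_threshold)

    def dichotomize(self, score):
        """Raw score -> binary call at the raw-scale threshold."""
        return dichotomize(score, self.raw_threshold)
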