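"""Basic probability assignments and Dempster-Shafer combination.

The frame of discernment is the two-state outcome {positive, negative};
focal elements are {positive}, {negative} and the whole frame Θ.  Each
base model contributes one evidence source: its adjusted output A* in
[0, 1], discounted by its rough-set weight w, becomes the mass assignment

    m(1) = w·A* / (w + 1),   m(0) = w·(1 - A*) / (w + 1),   m(Θ) = 1 / (w + 1).

Low-weight models are pushed toward the vacuous assignment (all mass on
Θ, i.e. total ignorance), so Dempster's rule lets the better-performing
models dominate the fused verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging
import math

logger = logging.getLogger(__name__)

__all__ = [
    "MassAssignment",
    "VACUOUS",
    "weighted_bpa",
    "belief_plausibility",
    "dempster_combine",
    "combine_all",
    "decision_value",
    "classify",
]

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class MassAssignment:
    """Masses on {positive}, {negative}, Θ for one evidence source.

    The empty set implicitly carries zero mass; the three masses are
    non-negative and sum to one.
    """

    m_pos: float
    m_neg: float
    m_theta: float

    def __post_init__(self):
        if min(self.m_pos, self.m_neg, self.m_theta) < -_MASS_TOL:
            raise ValueError(f"negative mass in {self}")
        total = self.m_pos + self.m_neg + self.m_theta
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"masses must sum to 1, got {total!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.m_pos, self.m_neg, self.m_theta)


#: total ignorance -- the identity element of Dempster's rule
VACUOUS = MassAssignment(0.0, 0.0, 1.0)


def weighted_bpa(a_star: float, weight: float) -> MassAssignment:
    """Weighted basic probability assignment from one adjusted output.

    ``weight`` discounts the evidence: weight 0 yields the vacuous
    assignment regardless of the score, weight → ∞ approaches the
    categorical assignment (A*, 1 - A*, 0).
    """
    if not 0.0 <= a_star <= 1.0:
        raise ValueError(f"adjusted output must lie in [0, 1], got {a_star}")
    if not (math.isfinite(weight) and weight >= 0.0):
        raise ValueError(f"weight must be finite and >= 0, got {weight}")
    denom = weight + 1.0  # = w*A* + w*(1-A*) + 1
    return MassAssignment(
        m_pos=weight * a_star / denom,
        m_neg=weight * (1.0 - a_star) / denom,
        m_theta=1.0 / denom,
    )


def belief_plausibility(m: MassAssignment) -> tuple[float, float]:
    """(Bel, Pl) for the positive outcome: minimal and maximal support."""
    return (m.m_pos, m.m_pos + m.m_theta)


def dempster_combine(m1: MassAssignment, m2: MassAssignment) -> MassAssignment:
    """Dempster's rule of combination for two sources on the binary frame.

    The conflict K is the mass landing on contradictory intersections
    ({positive} ∩ {negative} = ∅); the surviving masses are renormalized
    by 1/(1-K).  Fully conflicting sources (K = 1) cannot be combined.
    """
    k = m1.m_pos * m2.m_neg + m1.m_neg * m2.m_pos
    if k >= 1.0 - 1e-15:
        raise ValueError("evidences fully conflicting, combination undefined")
    norm = 1.0 / (1.0 - k)
    pos = (m1.m_pos * m2.m_pos + m1.m_pos * m2.m_theta + m1.m_theta * m2.m_pos) * norm
    neg = (m1.m_neg * m2.m_neg + m1.m_neg * m2.m_theta + m1.m_theta * m2.m_neg) * norm
    theta = m1.m_theta * m2.m_theta * norm
    # renormalize away accumulated rounding so invariants hold exactly
    total = pos + neg + theta
    return MassAssignment(pos / total, neg / total, theta / total)


def combine_all(bpas) -> MassAssignment:
    """Left fold of Dempster's rule over an ordered list of sources.

    The rule is commutative and associative, so the order is immaterial
    up to floating point; conventionally sources are combined in model
    order.
    """
    bpas = list(bpas)
    if not bpas:
        raise ValueError("need at least one mass assignment to combine")
    combined = bpas[0]
    for m in bpas[1:]:
        combined = dempster_combine(combined, m)
    return combined


def decision_value(m: MassAssignment) -> float:
    """Continuous risk output R = m(1) / (m(0) + m(1)) of a combined BPA.

    If all committed mass vanishes (every source vacuous) the ratio is
    undefined; maximal ignorance is reported as 0.5 with a warning.
    """
    committed = m.m_pos + m.m_neg
    if committed <= 0.0:
        logger.warning("all evidence vacuous; decision value defaults to 0.5")
        return 0.5
    return m.m_pos / committed


def classify(r: float, decision_threshold: float) -> int:
    """Positive call iff the decision value strictly exceeds the threshold."""
    return int(r > decision_threshold)
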