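"""Rough-set attribute weighting for classifier-output fusion.

A dichotomized score matrix together with the observed outcomes forms a
rough-set *decision table*: each base model contributes one categorical
condition attribute, the outcome is the decision attribute.  The weight of
a base model is its normalized *significance* -- the change in conditional
entropy of the decision partition when that model's column is removed from
the attribute set.  Models whose dichotomized output carries no information
beyond the remaining models receive weight 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DecisionTable",
    "Partition",
    "partition_by",
    "conditional_entropy",
    "attribute_significance",
    "compute_weights",
]

#: valid conditioning conventions for the entropy computation
ENTROPY_DIRECTIONS = ("decision-given-attrs", "as-printed")


@dataclass(frozen=True)
class DecisionTable:
    """An information system: objects x condition attributes plus a decision.

    Parameters
    ----------
    attributes : sequence of str
        Ordered, unique condition-attribute identifiers.
    values : 2-D array-like
        Categorical value per (object, attribute); any hashable dtype that
        numpy can compare works (typically 0/1 integers here).
    decision : 1-D array-like
        Binary outcome per object.
    """

    attributes: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    decision: np.ndarray = field(repr=False)

    def __init__(self, attributes: Sequence[str], values, decision):
        attributes = tuple(str(a) for a in attributes)
        if len(set(attributes)) != len(attributes):
            raise ValueError("attribute identifiers must be unique")
        values = np.asarray(values)
        decision = np.asarray(decision)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (objects x attributes) array")
        if values.shape[1] != len(attributes):
            raise ValueError(
                f"values has {values.shape[1]} columns for {len(attributes)} attributes"
            )
        if decision.shape != (values.shape[0],):
            raise ValueError("decision must have one entry per object")
        if values.shape[0] < 1:
            raise ValueError("decision table needs at least one object")
        object.__setattr__(self, "attributes", attributes)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "decision", decision)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def column(self, attr: str) -> np.ndarray:
        try:
            j = self.attributes.index(attr)
        except ValueError:
            raise KeyError(f"unknown attribute {attr!r}") from None
        return self.values[:, j]


@dataclass(frozen=True)
class Partition:
    """Disjoint blocks of row indices covering all objects."""

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        seen: set[int] = set()
        for block in self.blocks:
            if not block:
                raise ValueError("empty partition block")
            if seen.intersection(block):
                raise ValueError("partition blocks must be disjoint")
            seen.update(block)

    @property
    def n_objects(self) -> int:
        return sum(len(b) for b in self.blocks)


def _block_codes(table: DecisionTable, attrs: Sequence[str]) -> np.ndarray:
    """Integer block label per row under the indiscernibility relation on attrs."""
    if len(attrs) == 0:
        return np.zeros(table.n_rows, dtype=np.intp)
    cols = [table.column(a) for a in attrs]
    # rows sharing every attribute value land in the same block
    stacked = np.rec.fromarrays(cols)
    _, codes = np.unique(stacked, return_inverse=True)
    return codes


def partition_by(table: DecisionTable, attrs: Iterable[str]) -> Partition:
    """Partition the objects by the indiscernibility relation IND(attrs).

    Two rows share a block iff they agree on every attribute in ``attrs``;
    the empty subset yields the single block of all objects.
    """
    attrs = list(attrs)
    codes = _block_codes(table, attrs)
    blocks: dict[int, list[int]] = {}
    for i, c in enumerate(codes):
        blocks.setdefault(int(c), []).append(i)
    return Partition(tuple(tuple(b) for b in blocks.values()))


def _decision_codes(table: DecisionTable) -> np.ndarray:
    _, codes = np.unique(table.decision, return_inverse=True)
    return codes


def conditional_entropy(
    table: DecisionTable,
    attrs: Iterable[str],
    direction: str = "decision-given-attrs",
) -> float:
    """Entropy (nats) of one partition conditional on the other.

    With ``direction="decision-given-attrs"`` (default) this is H(R | A):
    the expected entropy of the decision partition within each attribute
    block,

        H(R|A) = - sum_{b in U/IND(A)} p(b) sum_{d in U/IND(R)} p(d|b) ln p(d|b),

    with the convention 0*ln 0 = 0.  ``direction="as-printed"`` swaps the
    roles of the two partitions (outer sum over decision blocks), retained
    for auditability of the alternative reading of the dependence measure.
    """
    if direction not in ENTROPY_DIRECTIONS:
        raise ValueError(
            f"direction must be one of {ENTROPY_DIRECTIONS}, got {direction!r}"
        )
    attr_codes = _block_codes(table, list(attrs))
    dec_codes = _decision_codes(table)
    if direction == "as-printed":
        attr_codes, dec_codes = dec_codes, attr_codes

    n = table.n_rows
    n_attr = int(attr_codes.max()) + 1
    n_dec = int(dec_codes.max()) + 1
    joint = np.zeros((n_attr, n_dec))
    np.add.at(joint, (attr_codes, dec_codes), 1.0)
    block_sizes = joint.sum(axis=1, keepdims=True)
    cond = joint / block_sizes
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint / n * np.log(cond), 0.0)
    return float(max(0.0, -terms.sum()))


def attribute_significance(
    table: DecisionTable, attr: str, direction: str = "decision-given-attrs"
) -> float:
    """Significance of one attribute: |H(R | A - {attr}) - H(R | A)|.

    Zero when the attribute never refines the partition induced by the
    remaining attributes (constant columns, duplicated columns).
    """
    if attr not in table.attributes:
        raise KeyError(f"unknown attribute {attr!r}")
    rest = [a for a in table.attributes if a != attr]
    h_without = conditional_entropy(table, rest, direction=direction)
    h_full = conditional_entropy(table, table.attributes, direction=direction)
    sig = abs(h_without - h_full)
    # entropy roundoff (~1e-16) must not survive normalization: a truly
    # redundant attribute has significance exactly 0
    return sig if sig >= 1e-12 else 0.0


def compute_weights(
    table: DecisionTable, direction: str = "decision-given-attrs"
) -> np.ndarray:
    """Normalized significance of every attribute, in attribute order.

    Returns a vector on the probability simplex.  If every attribute has
    zero significance the weights fall back to uniform (with a warning);
    the normalization would otherwise divide by zero.
    """
    sig = np.array(
        [attribute_significance(table, a, direction=direction) for a in table.attributes]
    )
    total = sig.sum()
    if total <= 0.0:
        warnings.warn(
            "all attribute significances are zero; falling back to uniform weights",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("zero total significance; using uniform weights")
        return np.full(len(table.attributes), 1.0 / len(table.attributes))
    return sig / total
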