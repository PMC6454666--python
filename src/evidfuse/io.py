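"""CSV/JSON input-output for score matrices, predictions and models.

Score matrices travel as RFC-4180 CSV (UTF-8, '.' decimal separator):
an id column, one numeric column per base model and an optional 0/1
label column.  Fitted ensembles persist as a small versioned JSON
document; floats are serialized with shortest-round-trip precision so
``load(save(m))`` reproduces the model exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ModelCalibration
from .ensemble import EvidentialEnsembleClassifier, ScoreMatrix

__all__ = [
    "read_scores",
    "write_scores",
    "write_predictions",
    "read_predictions",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def read_scores(
    path, id_column: str = "patient_id", label_column: str = "label"
) -> ScoreMatrix:
    """Read a score matrix CSV; row order is preserved.

    Every column other than the id and (optional) label columns is taken
    as a base-model score channel.  Malformed cells are reported with
    their 1-based data row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r}")
    model_cols = [c for c in df.columns if c not in (id_column, label_column)]
    if not model_cols:
        raise ValueError("no model score columns found")
    if len(df) == 0:
        raise ValueError("empty data section")

    def numeric(col: str) -> pd.Series:
        # float() is correctly rounded, so %.17g output round-trips exactly
        vals = np.empty(len(df))
        for i, v in enumerate(df[col].to_numpy()):
            try:
                vals[i] = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value in column {col!r} at data row {i + 1}"
                ) from None
        if not np.all(np.isfinite(vals)):
            row = int(np.flatnonzero(~np.isfinite(vals))[0]) + 1
            raise ValueError(f"non-finite value in column {col!r} at data row {row}")
        return pd.Series(vals)

    ids = df[id_column]
    if ids.duplicated().any():
        row = int(np.flatnonzero(ids.duplicated())[0]) + 1
        raise ValueError(f"duplicate patient id at data row {row}")
    scores = pd.DataFrame({c: numeric(c) for c in model_cols})
    scores.index = pd.Index(ids.to_numpy(), name=id_column)

    labels = None
    if label_column in df.columns:
        lab = numeric(label_column)
        bad = ~lab.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(f"label outside {{0, 1}} at data row {row}")
        labels = pd.Series(
            lab.astype(int).to_numpy(), index=scores.index, name=label_column
        )
    return ScoreMatrix(scores, labels)


def write_scores(matrix: ScoreMatrix, path) -> None:
    """Write a score matrix (and labels, when present) as CSV."""
    df = matrix.scores.copy()
    if matrix.labels is not None:
        df[matrix.labels.name or "label"] = matrix.labels
    # shortest-round-trip float rendering so reading back is lossless
    df.to_csv(
        path, index_label=matrix.scores.index.name or "patient_id", float_format="%.17g"
    )


def write_predictions(detail: pd.DataFrame, path) -> None:
    """Write a prediction trace (from ``predict_detail``) as CSV.

    Full float precision is retained so the records round-trip exactly;
    presentation rounding happens only in console output.
    """
    detail.to_csv(
        path, index_label=detail.index.name or "patient_id", float_format="%.17g"
    )


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    return df.set_index(df.columns[0])


def save_model(model: EvidentialEnsembleClassifier, path) -> None:
    """Persist a fitted ensemble as a versioned JSON document."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "entropy_direction": model.entropy_direction,
        "models": [
            {
                "id": mid,
                "raw_threshold": model.calibrations_[mid].raw_threshold,
                "normalization": (
                    list(model.calibrations_[mid].normalization)
                    if model.calibrations_[mid].normalization is not None
                    else None
                ),
            }
            for mid in model.model_ids_
        ],
        "weights": [float(w) for w in model.weights_],
        "decision_threshold": float(model.decision_threshold_),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_model(path) -> EvidentialEnsembleClassifier:
    """Load a persisted ensemble, enforcing schema and invariants."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    for key in ("models", "weights", "decision_threshold"):
        if key not in doc:
            raise ValueError(f"model file missing required field {key!r}")
    calibrations = [
        ModelCalibration(
            str(m["id"]),
            float(m["raw_threshold"]),
            tuple(m["normalization"]) if m.get("normalization") else None,
        )
        for m in doc["models"]
    ]
    return EvidentialEnsembleClassifier.from_parameters(
        calibrations,
        doc["weights"],
        doc["decision_threshold"],
        entropy_direction=doc.get("entropy_direction", "decision-given-attrs"),
    )
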