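"""JSON serialization of fitted PLS-DA models.

A model is one self-contained JSON document: dimensions, matrices (row-major
nested lists), class encoding, stored scaling parameters and the selected
feature list. Round-tripping through JSON is bit-faithful for float64 (Python
serializes the shortest repr that reparses exactly).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from dilimet.chemometrics import PlsModel
from dilimet.tables import ScalingParams


def model_to_dict(model: PlsModel) -> dict:
    d = {
        "n_components": int(model.n_components),
        "classes": list(model.classes),
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "T": model.T.tolist(),
        "Q": model.Q.tolist(),
        "B": model.B.tolist(),
        "R": model.R.tolist(),
        "y_mean": model.y_mean.tolist(),
        "ssy": model.ssy.tolist(),
        "total_ssy": float(model.total_ssy),
        "train_labels": list(model.train_labels),
        "feature_names": list(model.feature_names) if model.feature_names else None,
        "scaling": model.scaling.to_dict() if model.scaling is not None else None,
    }
    return d


def model_from_dict(d: dict) -> PlsModel:
    scaling = ScalingParams.from_dict(d["scaling"]) if d.get("scaling") else None
    return PlsModel(
        n_components=int(d["n_components"]),
        classes=list(d["classes"]),
        W=np.asarray(d["W"], dtype=float),
        P=np.asarray(d["P"], dtype=float),
        T=np.asarray(d["T"], dtype=float),
        Q=np.asarray(d["Q"], dtype=float),
        B=np.asarray(d["B"], dtype=float),
        R=np.asarray(d["R"], dtype=float),
        y_mean=np.asarray(d["y_mean"], dtype=float),
        ssy=np.asarray(d["ssy"], dtype=float),
        total_ssy=float(d["total_ssy"]),
        train_labels=list(d["train_labels"]),
        feature_names=list(d["feature_names"]) if d.get("feature_names") else None,
        scaling=scaling,
    )


def save_model(model: PlsModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path) -> PlsModel:
    return model_from_dict(json.loads(Path(path).read_text()))
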