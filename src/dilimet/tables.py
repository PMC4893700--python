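"""In-memory containers for feature tables and entity matrices.

The pipeline moves data through two shapes: a :class:`FeatureTable` holds one
analytical block at the injection (sample) level, with QC/blank rows and the
per-sample internal-standard (IS) response and protein amount needed for
normalization; an :class:`EntityMatrix` holds the fused, replicate-averaged
drug-concentration entities that all modeling operates on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: metadata columns every sample table carries, in canonical order
SAMPLE_META_COLS = [
    "entity_id", "compound", "concentration_uM", "class", "replicate",
    "role", "injection_order", "protein_mg", "is_response",
]

FEATURE_META_COLS = ["block", "metabolite", "monoisotopic_mass"]

MECHANISM_CLASSES = ("control", "oxidative_stress", "phospholipidosis", "steatosis")


@dataclass
class FeatureTable:
    """One analytical block: sample x feature intensities plus metadata.

    ``state`` tracks the preprocessing stage (``raw`` -> ``blank_filtered``
    -> ``normalized``); operations refuse to run out of order.
    """

    intensities: pd.DataFrame  # index: sample_id, columns: feature_id
    samples: pd.DataFrame      # index: sample_id, columns: SAMPLE_META_COLS
    features: pd.DataFrame     # index: feature_id, columns include FEATURE_META_COLS
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            raise ValueError("duplicated sample_id in intensity table")
        if self.intensities.columns.duplicated().any():
            raise ValueError("duplicated feature_id in intensity table")
        if not self.intensities.index.equals(self.samples.index):
            raise ValueError("intensities and sample metadata indexes differ")
        missing = [f for f in self.intensities.columns if f not in self.features.index]
        if missing:
            raise ValueError(f"features without metadata: {missing[:5]}")
        study = self.samples[self.samples["role"] == "study"]
        if (study["protein_mg"] <= 0).any():
            bad = study.index[study["protein_mg"] <= 0].tolist()
            raise ValueError(f"study samples with non-positive protein amount: {bad[:5]}")
        if (study["is_response"] <= 0).any():
            bad = study.index[study["is_response"] <= 0].tolist()
            raise ValueError(f"study samples with non-positive IS response: {bad[:5]}")

    @property
    def study_mask(self) -> pd.Series:
        return self.samples["role"] == "study"

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.samples.copy(), self.features.copy(), self.state
        )

    def write_csv(self, path: str | Path) -> None:
        """Write the block as a single CSV (metadata columns first)."""
        path = Path(path)
        out = pd.concat([self.samples[SAMPLE_META_COLS], self.intensities], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path)

    @staticmethod
    def read_csv(table_path: str | Path, features: pd.DataFrame,
                 state: str = "raw") -> "FeatureTable":
        df = pd.read_csv(table_path, index_col="sample_id")
        samples = df[SAMPLE_META_COLS]
        feats = [c for c in df.columns if c not in SAMPLE_META_COLS]
        return FeatureTable(df[feats].astype(float), samples,
                            features.loc[features.index.intersection(feats)], state)


@dataclass
class ScalingParams:
    """Frozen column transform: impute -> log -> center -> unit variance.

    Estimated once on training data and re-applied verbatim when projecting
    new samples; never re-estimated in projection mode.
    """

    columns: list[str]
    impute_value: np.ndarray   # per-column replacement for non-positive entries
    mean: np.ndarray           # per-column mean on the log scale
    sd: np.ndarray             # per-column sd on the log scale
    log_base: float = 10.0

    def apply(self, values: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in values.columns]
        if missing:
            raise ValueError(f"input lacks trained feature columns: {missing[:5]}")
        x = values[self.columns].to_numpy(dtype=float).copy()
        bad = x <= 0
        if bad.any():
            x[bad] = np.broadcast_to(self.impute_value, x.shape)[bad]
        x = np.log(x) / np.log(self.log_base)
        x = (x - self.mean) / self.sd
        return pd.DataFrame(x, index=values.index, columns=self.columns)

    def inverse(self, scaled: pd.DataFrame) -> pd.DataFrame:
        x = scaled[self.columns].to_numpy(dtype=float)
        x = x * self.sd + self.mean
        return pd.DataFrame(self.log_base ** x, index=scaled.index, columns=self.columns)

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "impute_value": [float(v) for v in self.impute_value],
            "mean": [float(v) for v in self.mean],
            "sd": [float(v) for v in self.sd],
            "log_base": float(self.log_base),
        }

    @staticmethod
    def from_dict(d: dict) -> "ScalingParams":
        return ScalingParams(
            columns=list(d["columns"]),
            impute_value=np.asarray(d["impute_value"], dtype=float),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            log_base=float(d["log_base"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @staticmethod
    def from_json(path: str | Path) -> "ScalingParams":
        return ScalingParams.from_dict(json.loads(Path(path).read_text()))


@dataclass
class EntityMatrix:
    """Entity x metabolite matrix: one row per drug-concentration entity."""

    values: pd.DataFrame    # index: entity_id, columns: feature_id
    entities: pd.DataFrame  # index: entity_id, columns: compound, concentration_uM, class
    transform: str = "linear"   # linear | log | log_scaled
    scaling: ScalingParams | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated entity_id")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated feature_id in entity matrix")
        if not self.values.index.equals(self.entities.index):
            raise ValueError("values and entity metadata indexes differ")

    @property
    def classes(self) -> pd.Series:
        return self.entities["class"]

    def subset(self, entity_ids) -> "EntityMatrix":
        ids = list(entity_ids)
        return EntityMatrix(self.values.loc[ids], self.entities.loc[ids],
                            self.transform, self.scaling)

    def copy(self) -> "EntityMatrix":
        return EntityMatrix(self.values.copy(), self.entities.copy(),
                            self.transform, self.scaling)

    def write_csv(self, path: str | Path) -> None:
        out = pd.concat([self.entities, self.values], axis=1)
        out.index.name = "entity_id"
        out.to_csv(path)

    @staticmethod
    def read_csv(path: str | Path, transform: str = "linear") -> "EntityMatrix":
        df = pd.read_csv(path, index_col="entity_id")
        meta_cols = ["compound", "concentration_uM", "class"]
        feats = [c for c in df.columns if c not in meta_cols]
        return EntityMatrix(df[feats].astype(float), df[meta_cols], transform)
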