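"""Feature-table preprocessing: QC monitoring, blank filtering, IS/protein
normalization, block fusion, replicate averaging and scaling.

The stages mirror standard untargeted-metabolomics practice: background ions
are identified against blank injections and removed; intensities are divided
by each sample's internal-standard response and protein amount; the four
analytical blocks are joined into one matrix per sample; biological
replicates are averaged into drug-concentration entities; and the entity
matrix is log10-transformed, mean-centered and unit-variance scaled before
any multivariate modeling. The scaling parameters are stored so external
samples can be projected through exactly the training transform.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from dilimet.tables import EntityMatrix, FeatureTable, ScalingParams

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# quality assurance
# ---------------------------------------------------------------------------

def qc_monitor(table: FeatureTable, cv_threshold: float = 0.3,
               observed_masses: pd.Series | None = None,
               mass_tol_ppm: float = 10.0) -> pd.DataFrame:
    """Per-channel stability report over the pooled-QC injections.

    Computes the coefficient of variation (sd/mean, ddof=1) of every feature
    channel and of the IS response across QC injections, and flags channels
    whose CV exceeds ``cv_threshold``. When ``observed_masses`` (feature_id ->
    measured m/z) is given, the mass-accuracy deviation in ppm against the
    catalog's monoisotopic masses is reported and checked against
    ``mass_tol_ppm``.
    """
    qc = table.samples["role"] == "qc"
    if qc.sum() < 2:
        raise ValueError("QC monitoring needs at least 2 QC injections")
    x = table.intensities.loc[qc]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = (sd / mean).fillna(0.0)
    is_vals = table.samples.loc[qc, "is_response"]
    is_cv = float(is_vals.std(ddof=1) / is_vals.mean())
    report = pd.DataFrame({"mean": mean, "cv": cv})
    report.loc["__IS__"] = [float(is_vals.mean()), is_cv]
    report["passed"] = report["cv"] <= cv_threshold
    if observed_masses is not None:
        ref = table.features["monoisotopic_mass"]
        ppm = (observed_masses - ref).abs() / ref * 1e6
        report["mass_ppm"] = ppm.reindex(report.index)
        ok = report["mass_ppm"].isna() | (report["mass_ppm"] <= mass_tol_ppm)
        report["passed"] &= ok
    return report


def blank_filter(table: FeatureTable, min_ratio: float = 3.0) -> FeatureTable:
    """Remove background ions: keep a feature only when its mean study
    intensity is at least ``min_ratio`` times its mean blank intensity.

    With no blank injections the table passes through unchanged (with a
    warning); removed features are logged.
    """
    if min_ratio <= 0:
        raise ValueError("min_ratio must be positive")
    if table.state not in ("raw",):
        raise ValueError(f"blank filtering expects a raw table, got state={table.state!r}")
    blanks = table.samples["role"] == "blank"
    out = table.copy()
    if blanks.sum() == 0:
        warnings.warn("no blank injections present; blank filter passed through",
                      stacklevel=2)
        out.state = "blank_filtered"
        return out
    study = table.study_mask
    study_mean = table.intensities.loc[study].mean(axis=0)
    blank_mean = table.intensities.loc[blanks].mean(axis=0)
    keep = study_mean >= min_ratio * blank_mean
    removed = list(table.intensities.columns[~keep])
    if removed:
        logger.info("blank filter removed %d background features: %s",
                    len(removed), removed)
    out.intensities = out.intensities.loc[:, keep]
    out.features = out.features.loc[keep[keep].index]
    out.state = "blank_filtered"
    return out


def normalize(table: FeatureTable) -> FeatureTable:
    """Divide each sample's intensities by its IS response and protein amount.

    Double normalization is a state error, not a silent no-op.
    """
    if table.state == "normalized":
        raise ValueError("table is already normalized")
    bad = table.samples.index[
        (table.samples["is_response"] <= 0) | (table.samples["protein_mg"] <= 0)
    ].tolist()
    if bad:
        raise ValueError(f"non-positive IS response or protein amount in samples: {bad[:5]}")
    out = table.copy()
    denom = (table.samples["is_response"] * table.samples["protein_mg"]).to_numpy()
    out.intensities = table.intensities.div(denom, axis=0)
    out.state = "normalized"
    return out


def match_mass(observed_mass: float, compound_masses: pd.DataFrame,
               tol_ppm: float = 10.0) -> pd.DataFrame:
    """Candidate identities within ``tol_ppm`` of an observed monoisotopic mass.

    ``compound_masses`` needs a ``monoisotopic_mass`` column; matches are
    returned sorted by absolute ppm error.
    """
    if len(compound_masses) == 0:
        raise ValueError("empty reference mass table")
    if observed_mass <= 0:
        raise ValueError("observed mass must be positive")
    ref = compound_masses["monoisotopic_mass"].to_numpy(dtype=float)
    ppm = np.abs(observed_mass - ref) / ref * 1e6
    hits = compound_masses.loc[ppm <= tol_ppm].copy()
    hits["ppm_error"] = ppm[ppm <= tol_ppm]
    return hits.sort_values("ppm_error")


# ---------------------------------------------------------------------------
# fusion and entity averaging
# ---------------------------------------------------------------------------

def fuse_blocks(tables: list[FeatureTable] | dict[str, FeatureTable]) -> FeatureTable:
    """Join the per-block tables column-wise on sample_id into one table.

    All blocks must be normalized and must cover the same samples; block
    provenance stays in the feature metadata. The join is key-based, so the
    sample order of individual blocks is irrelevant.
    """
    if isinstance(tables, dict):
        tables = [tables[k] for k in sorted(tables)]
    if not tables:
        raise ValueError("no tables to fuse")
    for t in tables:
        if t.state != "normalized":
            raise ValueError("all blocks must be normalized before fusion")
    ref_ids = set(tables[0].intensities.index)
    for t in tables[1:]:
        ids = set(t.intensities.index)
        if ids != ref_ids:
            only_a = sorted(ref_ids - ids)[:5]
            only_b = sorted(ids - ref_ids)[:5]
            raise ValueError(
                f"sample sets differ across blocks (e.g. missing {only_b or only_a})")
    order = tables[0].intensities.index
    intens = pd.concat([t.intensities.loc[order] for t in tables], axis=1)
    if intens.columns.duplicated().any():
        dups = intens.columns[intens.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature ids across blocks: {dups[:5]}")
    feats = pd.concat([t.features for t in tables])
    return FeatureTable(intens, tables[0].samples.copy(), feats, state="normalized")


def average_replicates(fused: FeatureTable) -> EntityMatrix:
    """Collapse study replicates to one row per drug-concentration entity
    (arithmetic mean); QC and blank injections are dropped."""
    study = fused.samples[fused.samples["role"] == "study"]
    if study.empty:
        raise ValueError("no study samples to average")
    counts = study.groupby("entity_id").size()
    if (counts < 1).any():
        raise ValueError("entity with zero replicates")
    values = fused.intensities.loc[study.index].groupby(study["entity_id"]).mean()
    meta = (study[["entity_id", "compound", "concentration_uM", "class"]]
            .drop_duplicates("entity_id").set_index("entity_id"))
    values = values.loc[meta.index]
    values.index.name = None
    meta.index.name = None
    return EntityMatrix(values=values, entities=meta, transform="linear")


def transform_scale(matrix: EntityMatrix,
                    params: ScalingParams | None = None,
                    log_base: float = 10.0) -> EntityMatrix:
    """Log-transform, mean-center and unit-variance scale the entity matrix.

    Fresh mode (``params is None``) estimates and stores per-column
    imputation values (half the minimum positive value), means and sds;
    zero-variance columns are dropped with a warning. Projection mode applies
    the stored transform verbatim and never re-estimates anything.
    """
    if matrix.transform != "linear":
        raise ValueError("transform_scale expects a linear-scale matrix")
    if params is not None:
        scaled = params.apply(matrix.values)
        return EntityMatrix(scaled, matrix.entities.copy(), "log_scaled", params)

    x = matrix.values.to_numpy(dtype=float).copy()
    with np.errstate(invalid="ignore"):
        pos_min = np.where(x > 0, x, np.nan)
        col_min = np.nanmin(pos_min, axis=0)
    if np.isnan(col_min).any():
        bad = matrix.values.columns[np.isnan(col_min)].tolist()
        raise ValueError(f"columns with no positive values: {bad[:5]}")
    impute = col_min / 2.0
    bad_cells = x <= 0
    if bad_cells.any():
        x[bad_cells] = np.broadcast_to(impute, x.shape)[bad_cells]
    x = np.log(x) / np.log(log_base)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = matrix.values.columns[~keep].tolist()
        warnings.warn(f"dropping {len(dropped)} zero-variance columns: {dropped[:5]}",
                      stacklevel=2)
    cols = matrix.values.columns[keep]
    params = ScalingParams(columns=list(cols), impute_value=impute[keep],
                           mean=mean[keep], sd=sd[keep], log_base=log_base)
    scaled = pd.DataFrame((x[:, keep] - mean[keep]) / sd[keep],
                          index=matrix.values.index, columns=cols)
    return EntityMatrix(scaled, matrix.entities.copy(), "log_scaled", params)


def log_matrix(matrix: EntityMatrix, log_base: float = 10.0) -> EntityMatrix:
    """Impute non-positive cells (half minimum positive per column) and
    log-transform, without centering or scaling — the input to fold-wise
    scaled cross-validation."""
    if matrix.transform != "linear":
        raise ValueError("log_matrix expects a linear-scale matrix")
    x = matrix.values.to_numpy(dtype=float).copy()
    with np.errstate(invalid="ignore"):
        pos_min = np.where(x > 0, x, np.nan)
        col_min = np.nanmin(pos_min, axis=0)
    if np.isnan(col_min).any():
        bad = matrix.values.columns[np.isnan(col_min)].tolist()
        raise ValueError(f"columns with no positive values: {bad[:5]}")
    impute = col_min / 2.0
    bad_cells = x <= 0
    if bad_cells.any():
        x[bad_cells] = np.broadcast_to(impute, x.shape)[bad_cells]
    x = np.log(x) / np.log(log_base)
    values = pd.DataFrame(x, index=matrix.values.index, columns=matrix.values.columns)
    return EntityMatrix(values, matrix.entities.copy(), "log")


def preprocess_pipeline(tables: dict[str, FeatureTable],
                        blank_min_ratio: float | None = 3.0) -> EntityMatrix:
    """Convenience chain: blank filter -> normalize -> fuse -> average.

    Returns the linear-scale entity matrix; pass ``blank_min_ratio=None`` to
    skip blank filtering.
    """
    processed = []
    for block in sorted(tables):
        t = tables[block]
        if blank_min_ratio is not None:
            t = blank_filter(t, min_ratio=blank_min_ratio)
        elif t.state == "raw":
            t = t.copy()
            t.state = "blank_filtered"
        processed.append(normalize(t))
    return average_replicates(fuse_blocks(processed))
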