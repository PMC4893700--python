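"""End-to-end predictive-model construction and validation.

The sequence mirrors how such classifiers are built in practice: a stratified
80/20 split reserves an external validation set untouched by any modeling
decision; on the development set, features are ranked by VIP from a
full-feature PLS-DA and models of increasing size are compared by
cross-validated figures of merit; the winning configuration is refit on the
whole development set; model significance is assessed by a response
permutation test (class labels shuffled, model refit and cross-validated at
the fixed configuration, empirical p = (b+1)/(n_perm+1)); finally the
held-out entities are projected through the frozen training transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dilimet.chemometrics import (
    CvResult,
    PlsModel,
    cross_validate,
    fit_plsda,
    predict,
    vip,
)
from dilimet.preprocess import log_matrix, transform_scale
from dilimet.tables import EntityMatrix


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# development / validation split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Stratified development/validation partition of the entities."""

    development: list[str]
    validation: list[str]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.development) & set(self.validation)
        if overlap:
            raise ValueError(f"development/validation overlap: {sorted(overlap)[:5]}")


def split_dev_validation(matrix: EntityMatrix, fraction: float = 0.20,
                         seed: int = 0) -> SplitSpec:
    """Per class, draw round(fraction x class size) entities (minimum 1) into
    the validation set, so every class is represented there."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    classes = matrix.classes
    rng = np.random.default_rng(seed)
    val: list[str] = []
    for cls in sorted(set(classes)):
        ids = classes.index[classes == cls].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 entities; cannot split")
        n_val = max(1, int(np.floor(fraction * len(ids) + 0.5)))
        val.extend(rng.choice(ids, size=n_val, replace=False).tolist())
    val_set = set(val)
    dev = [e for e in matrix.values.index if e not in val_set]
    return SplitSpec(development=dev, validation=sorted(val), fraction=fraction,
                     seed=seed)


# ---------------------------------------------------------------------------
# VIP-ranked variable selection
# ---------------------------------------------------------------------------

def default_size_grid(n_features: int) -> list[int]:
    """Candidate model sizes: 2..30 by 2, then 35..60 by 5, capped at p."""
    sizes = list(range(2, 31, 2)) + list(range(35, 61, 5))
    sizes = [s for s in sizes if s <= n_features]
    if not sizes or sizes[-1] != n_features:
        if n_features <= 60:
            sizes.append(n_features)
    return sizes


@dataclass
class SelectionTrace:
    """Everything needed to re-derive the variable-selection choice."""

    ranking: list[str]                  # features in descending VIP order
    records: pd.DataFrame               # size, n_components, q2, error mean/sd, auroc mean/sd
    chosen_size: int
    chosen_components: int

    def to_dict(self) -> dict:
        return {
            "ranking": list(self.ranking),
            "records": self.records.to_dict(orient="list"),
            "chosen_size": int(self.chosen_size),
            "chosen_components": int(self.chosen_components),
        }


def rank_by_vip(X_log: pd.DataFrame, classes, n_components: int = 3) -> list[str]:
    """Feature ranking by VIP of a full-feature PLS-DA (autoscaled);
    descending VIP, ties broken by feature id for stability."""
    X = X_log.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    a = min(n_components, X.shape[0] - 1, X.shape[1])
    model = fit_plsda((X - mean) / sd, list(classes), a)
    vips = vip(model)
    order = sorted(range(len(vips)), key=lambda j: (-vips[j], X_log.columns[j]))
    return [X_log.columns[j] for j in order]


def select_variables(
    matrix_dev: EntityMatrix,
    component_grid=range(1, 6),
    size_grid: list[int] | None = None,
    *,
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
    ranking_components: int = 3,
) -> tuple[SelectionTrace, PlsModel]:
    """VIP-ranked incremental variable selection on the development set.

    For every candidate (size, component count) a PLS-DA on the top-k ranked
    features is cross-validated (scaling re-estimated inside folds). The
    winner maximizes mean CV AUROC, with ties broken by lower
    misclassification error, then higher Q² (error and AUROC saturate on
    well-separated data, and a purely parsimony-based tie-break would
    under-size the model), then smaller size, then fewer components. The
    final model is refit on all development entities at the winning
    configuration, with its scaling stored for projection.

    ``matrix_dev`` must be linear-scale; log-transform/imputation happens
    here so the same path serves CLI and tests.
    """
    component_grid = list(component_grid)
    if not component_grid:
        raise ValueError("empty component grid")
    logm = log_matrix(matrix_dev)
    X_log = logm.values
    classes = logm.classes
    n, p = X_log.shape
    if size_grid is None:
        size_grid = default_size_grid(p)
    size_grid = [s for s in size_grid if 1 <= s <= p]
    if not size_grid:
        raise ValueError("empty size grid")

    ranking = rank_by_vip(X_log, classes, ranking_components)
    records = []
    for k in size_grid:
        feats = ranking[:k]
        Xk = X_log[feats].to_numpy(dtype=float)
        for a in component_grid:
            if a > min(k, n - 2):
                continue
            cv = cross_validate(Xk, list(classes), a, n_folds=n_folds,
                                n_repeats=n_repeats, seed=seed)
            records.append({
                "size": k, "n_components": a, "q2": cv.q2,
                "error_mean": cv.error_mean, "error_sd": cv.error_sd,
                "auroc_mean": cv.auroc_mean, "auroc_sd": cv.auroc_sd,
            })
    if not records:
        raise ValueError("no feasible (size, components) configuration")
    rec = pd.DataFrame(records)
    best = rec.sort_values(
        by=["auroc_mean", "error_mean", "q2", "size", "n_components"],
        ascending=[False, True, False, True, True], kind="stable",
    ).iloc[0]
    k_star, a_star = int(best["size"]), int(best["n_components"])

    chosen = ranking[:k_star]
    sub = EntityMatrix(matrix_dev.values[chosen], matrix_dev.entities.copy(),
                       "linear")
    scaled = transform_scale(sub)
    final = fit_plsda(scaled.values.to_numpy(), list(classes), a_star,
                      feature_names=chosen)
    final.scaling = scaled.scaling
    trace = SelectionTrace(ranking=ranking, records=rec, chosen_size=k_star,
                           chosen_components=a_star)
    return trace, final


# ---------------------------------------------------------------------------
# response permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Null distribution of a CV figure of merit under label permutation."""

    metric: str                  # "misclassification_error" | "auroc"
    observed: float
    permuted: np.ndarray
    n_perm: int
    seed: int
    b: int = field(init=False)
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        if self.metric == "misclassification_error":
            self.b = int((self.permuted <= self.observed).sum())
        elif self.metric == "auroc":
            self.b = int((self.permuted >= self.observed).sum())
        else:
            raise ValueError(f"unknown metric: {self.metric}")
        self.p_value = (self.b + 1) / (self.n_perm + 1)


def permutation_test(
    matrix_dev: EntityMatrix,
    features: list[str],
    n_components: int,
    metric: str = "misclassification_error",
    *,
    n_perm: int = 1000,
    n_folds: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
) -> PermutationResult:
    """Response permutation test at a fixed model configuration.

    Class labels are shuffled over entities; for each permutation the model
    is refit and cross-validated at the *fixed* configuration (the feature
    set and component count chosen on real labels — selection is not re-run
    per permutation). The observed metric is computed with identical CV
    settings, so real and permuted figures are exchangeable under the null.
    b counts permuted models at least as good as the observed one
    (direction-aware) and p = (b+1)/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if metric not in ("misclassification_error", "auroc"):
        raise ValueError(f"unknown metric: {metric}")
    logm = log_matrix(matrix_dev)
    X = logm.values[list(features)].to_numpy(dtype=float)
    classes = list(logm.classes)
    rng = np.random.default_rng(seed)

    def run_cv(labels, cv_seed) -> float:
        cv = cross_validate(X, labels, n_components, n_folds=n_folds,
                            n_repeats=n_repeats, seed=cv_seed)
        return cv.error_mean if metric == "misclassification_error" else cv.auroc_mean

    observed = run_cv(classes, _child_seed(rng))
    permuted = np.zeros(n_perm)
    lab_arr = np.asarray(classes)
    for i in range(n_perm):
        perm_labels = rng.permutation(lab_arr).tolist()
        permuted[i] = run_cv(perm_labels, _child_seed(rng))
    return PermutationResult(metric=metric, observed=observed, permuted=permuted,
                             n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    table: pd.DataFrame     # per entity: true class, predicted, grade, correct
    accuracy: float


def external_validate(model: PlsModel, matrix_val: EntityMatrix,
                      train_ids=None) -> ValidationReport:
    """Project held-out entities through the frozen training transform and
    report per-entity assignment, confidence grade and overall accuracy.

    ``train_ids`` (the development entity ids), when given, guards against
    accidental overlap between the two sets.
    """
    if model.scaling is None or model.feature_names is None:
        raise ValueError("model lacks stored scaling/feature list; "
                         "fit it via select_variables")
    if train_ids is not None:
        overlap = set(matrix_val.values.index) & set(train_ids)
        if overlap:
            raise ValueError(f"validation entities overlap training: {sorted(overlap)[:5]}")
    pred = predict(model, matrix_val.values, scaling=model.scaling)
    truth = matrix_val.classes
    table = pd.DataFrame({
        "true_class": truth,
        "predicted_class": pred.labels,
        "grade": pred.grades,
    }, index=matrix_val.values.index)
    table["correct"] = table["true_class"] == table["predicted_class"]
    return ValidationReport(table=table, accuracy=float(table["correct"].mean()))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    matrix: EntityMatrix,
    *,
    fraction: float = 0.20,
    component_grid=range(1, 6),
    size_grid: list[int] | None = None,
    n_folds: int = 5,
    selection_repeats: int = 5,
    report_repeats: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Split -> select -> cross-validate -> permutation tests -> external
    projection, under one master seed. Returns a JSON-serializable report
    plus the fitted model (key ``model``).
    """
    rng = np.random.default_rng(seed)
    split = split_dev_validation(matrix, fraction, seed=_child_seed(rng))
    dev = matrix.subset(split.development)
    val = matrix.subset(split.validation)

    trace, model = select_variables(
        dev, component_grid, size_grid, n_folds=n_folds,
        n_repeats=selection_repeats, seed=_child_seed(rng))

    logm = log_matrix(dev)
    X_final = logm.values[model.feature_names].to_numpy(dtype=float)
    cv_final: CvResult = cross_validate(
        X_final, list(logm.classes), model.n_components, n_folds=n_folds,
        n_repeats=report_repeats, seed=_child_seed(rng))

    perms = {}
    for metric in ("misclassification_error", "auroc"):
        perms[metric] = permutation_test(
            dev, model.feature_names, model.n_components, metric,
            n_perm=n_perm, n_folds=n_folds, seed=_child_seed(rng))

    validation = external_validate(model, val, train_ids=split.development)

    report = {
        "seed": seed,
        "split": {"development": split.development,
                  "validation": split.validation,
                  "fraction": fraction},
        "selection": trace.to_dict(),
        "final_model": {
            "n_components": model.n_components,
            "n_features": len(model.feature_names),
            "features": list(model.feature_names),
            "r2y": model.r2y,
        },
        "cross_validation": {
            "q2": cv_final.q2,
            "error_mean": cv_final.error_mean, "error_sd": cv_final.error_sd,
            "auroc_mean": cv_final.auroc_mean, "auroc_sd": cv_final.auroc_sd,
            "n_folds": n_folds, "n_repeats": report_repeats,
        },
        "permutation": {
            m: {"observed": r.observed, "b": r.b, "p_value": r.p_value,
                "n_perm": r.n_perm}
            for m, r in perms.items()
        },
        "external_validation": {
            "accuracy": validation.accuracy,
            "assignments": validation.table.reset_index()
                .rename(columns={"index": "entity_id"}).to_dict(orient="records"),
        },
        "model": model,
    }
    return report
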