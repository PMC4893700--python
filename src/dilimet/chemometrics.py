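"""Multivariate core: NIPALS PCA and PLS2-DA, VIP scores, Hotelling T²
confidence regions, projection of new samples, and cross-validated figures of
merit (R²Y, Q², misclassification error, binary/multiclass AUROC).

PLS-DA regresses a column-centered one-hot class membership matrix Y on the
scaled feature matrix X with the classical NIPALS PLS2 algorithm (X and Y
both deflated per component). Class assignment is the argmax of the predicted
Y; ties break lexicographically by class name. All score/weight vectors carry
a deterministic sign convention (largest-magnitude weight entry positive) so
serialized models are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

# ---------------------------------------------------------------------------
# PCA (NIPALS power iteration; tested against an SVD oracle)
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    scores: np.ndarray            # n x A
    loadings: np.ndarray          # p x A, orthonormal columns
    explained_variance_ratio: np.ndarray
    mean: np.ndarray              # column means removed before extraction


def fit_pca(X: np.ndarray, n_components: int, *, tol: float = 1e-12,
            max_iter: int = 1000) -> PcaModel:
    """Principal components of the column-centered matrix by NIPALS.

    Components are extracted one at a time by power iteration with deflation;
    the sign convention makes the largest-magnitude loading entry positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(f"n_components must be in [1, min(n-1, p)] = "
                         f"[1, {min(n - 1, p)}]")
    mean = X.mean(axis=0)
    Xd = X - mean
    total_ss = float((Xd ** 2).sum())
    if total_ss == 0:
        raise ValueError("degenerate (constant) matrix")
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    evr = np.zeros(n_components)
    for a in range(n_components):
        j = int(np.argmax((Xd ** 2).sum(axis=0)))
        t = Xd[:, j].copy()
        if float(t @ t) == 0:
            raise ValueError("matrix rank below requested number of components")
        for _ in range(max_iter):
            pvec = Xd.T @ t
            pvec /= np.linalg.norm(pvec)
            t_new = Xd @ pvec
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        jmax = int(np.argmax(np.abs(pvec)))
        if pvec[jmax] < 0:
            pvec = -pvec
            t = -t
        T[:, a] = t
        P[:, a] = pvec
        evr[a] = float(t @ t) / total_ss
        Xd = Xd - np.outer(t, pvec)
    return PcaModel(T, P, evr, mean)


# ---------------------------------------------------------------------------
# PLS2-DA by NIPALS
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """Fitted PLS-DA model.

    Matrices follow the usual chemometric notation: X-weights ``W`` (unit
    norm), X-loadings ``P``, X-scores ``T``, Y-loadings ``Q``, regression
    coefficients ``B`` (scaled X space -> centered Y), rotation
    ``R = W (P'W)^-1`` so new scores are ``Xs @ R``.
    """

    n_components: int
    classes: list[str]
    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    Q: np.ndarray
    B: np.ndarray
    R: np.ndarray
    y_mean: np.ndarray            # column means of the one-hot Y
    ssy: np.ndarray               # explained Y sum of squares per component
    total_ssy: float
    train_labels: list[str] = field(default_factory=list)
    feature_names: list[str] | None = None
    scaling: object | None = None  # ScalingParams when fitted via the pipeline

    @property
    def r2y(self) -> float:
        return float(self.ssy.sum() / self.total_ssy)

    @property
    def r2y_per_component(self) -> np.ndarray:
        return self.ssy / self.total_ssy


def one_hot(labels, classes: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    labels = list(labels)
    if classes is None:
        classes = sorted(set(labels))
    idx = {c: k for k, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    return Y, classes


def fit_plsda(X: np.ndarray, labels, n_components: int, *,
              tol: float = 1e-10, max_iter: int = 500,
              feature_names: list[str] | None = None) -> PlsModel:
    """NIPALS PLS2 on scaled X against column-centered one-hot Y.

    Per component: iterate w ∝ X'u (normalized), t = Xw, q = Y't/(t't),
    u = Yq/(q'q) to convergence; then p = X't/(t't) and both X and Y are
    deflated by t. Explained Y sum of squares per component is
    SSY_a = Σ_k q_ka² (t_a't_a).
    """
    X = np.ascontiguousarray(X, dtype=float)
    labels = list(labels)
    n, p = X.shape
    if len(labels) != n:
        raise ValueError("label count does not match row count")
    Y01, classes = one_hot(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = Y01.sum(axis=0)
    if (counts == 0).any():
        raise ValueError("class with zero rows")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    y_mean = Y01.mean(axis=0)
    Y = Y01 - y_mean
    total_ssy = float((Y ** 2).sum())

    k = Y.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros((k, n_components))
    ssy = np.zeros(n_components)
    Xd = X.copy()
    Yd = Y.copy()
    for a in range(n_components):
        u = Yd[:, int(np.argmax((Yd ** 2).sum(axis=0)))].copy()
        t = np.zeros(n)
        converged = False
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError(
                    f"X exhausted after {a} components; reduce n_components")
            w /= nw
            t_new = Xd @ w
            q = Yd.T @ t_new / (t_new @ t_new)
            u = Yd @ q / (q @ q)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                converged = True
                break
            t = t_new
        if not converged:
            # stopping rule: score change < tol OR max_iter sweeps; later
            # components on small matrices can oscillate between
            # near-degenerate directions, and the max_iter iterate is used
            warnings.warn(f"NIPALS stopped at max_iter for component {a + 1}",
                          stacklevel=2)
        jmax = int(np.argmax(np.abs(w)))
        if w[jmax] < 0:
            w, t = -w, -t
        tt = float(t @ t)
        if tt == 0:
            raise ValueError("zero-variance score; matrix rank too low")
        pvec = Xd.T @ t / tt
        q = Yd.T @ t / tt
        Xd -= np.outer(t, pvec)
        Yd -= np.outer(t, q)
        W[:, a], P[:, a], T[:, a], Q[:, a] = w, pvec, t, q
        ssy[a] = float((q ** 2).sum() * tt)
    R = W @ np.linalg.inv(P.T @ W)
    B = R @ Q.T
    return PlsModel(
        n_components=n_components, classes=classes, W=W, P=P, T=T, Q=Q,
        B=B, R=R, y_mean=y_mean, ssy=ssy, total_ssy=total_ssy,
        train_labels=labels, feature_names=list(feature_names) if feature_names
        is not None else None,
    )


def vip(model: PlsModel) -> np.ndarray:
    """Variable importance in the projection.

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/||w_a||)² / Σ_a SSY_a ); the mean of
    the squared VIPs is exactly 1.
    """
    total = float(model.ssy.sum())
    if total <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    p = model.W.shape[0]
    wnorm2 = (model.W ** 2).sum(axis=0)  # = 1 by construction, kept for safety
    contrib = (model.W ** 2) / wnorm2
    return np.sqrt(p * (contrib @ model.ssy) / total)


# ---------------------------------------------------------------------------
# Hotelling T² regions
# ---------------------------------------------------------------------------

@dataclass
class Ellipse:
    """95% (or 1-alpha) confidence region in a 2-component score plane."""

    t2_crit: float
    semi_axes: tuple[float, float]
    center: tuple[float, float] = (0.0, 0.0)


def hotelling_limit(n: int, n_components: int, alpha: float = 0.05) -> float:
    """Critical T² value: A(n-1)/(n-A) · F_{1-alpha}(A, n-A)."""
    a = n_components
    if a < 1:
        raise ValueError("n_components must be >= 1")
    if n <= a:
        raise ValueError("need n > n_components for a Hotelling limit")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    return a * (n - 1) / (n - a) * float(sps.f.ppf(1 - alpha, a, n - a))


def hotelling_t2(scores: np.ndarray, score_var: np.ndarray,
                 center: np.ndarray | None = None) -> np.ndarray:
    """T² statistic of score rows against per-component variances."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if center is not None:
        scores = scores - center
    return (scores ** 2 / score_var).sum(axis=1)


def hotelling_ellipse(scores: np.ndarray, alpha: float = 0.05) -> Ellipse:
    """95% Hotelling ellipse of a 2-column score matrix (centered scores)."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] != 2:
        raise ValueError("ellipse needs exactly 2 score columns")
    n = scores.shape[0]
    t2 = hotelling_limit(n, 2, alpha)
    var = scores.var(axis=0, ddof=1)
    return Ellipse(t2_crit=t2, semi_axes=(float(np.sqrt(t2 * var[0])),
                                          float(np.sqrt(t2 * var[1]))))


# ---------------------------------------------------------------------------
# prediction / projection
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    y_pred: np.ndarray          # predicted (uncentered) class-membership values
    classes: list[str]
    labels: list[str]           # argmax class per row
    scores: np.ndarray          # projected X-scores
    grades: list[str]           # high | medium | low confidence


def _class_regions(model: PlsModel, alpha: float = 0.05):
    """Per-class score centers/variances and the global T² limit."""
    T = model.T
    n, a = T.shape
    global_var = T.var(axis=0, ddof=1)
    global_lim = hotelling_limit(n, a, alpha)
    regions = {}
    lab = np.asarray(model.train_labels)
    for cls in model.classes:
        Tc = T[lab == cls]
        if Tc.shape[0] > a + 1:
            regions[cls] = (Tc.mean(axis=0), Tc.var(axis=0, ddof=1),
                            hotelling_limit(Tc.shape[0], a, alpha))
        else:
            regions[cls] = None  # too few members; fall back to global region
    return regions, global_var, global_lim


def predict(model: PlsModel, X_new, scaling=None, alpha: float = 0.05) -> Prediction:
    """Project new rows through a fitted PLS-DA model.

    ``X_new`` is either already in the model's scaled space (``scaling=None``)
    or a raw linear-scale matrix together with the stored training
    :class:`~dilimet.tables.ScalingParams` — the transform is applied, never
    re-estimated. Confidence grades: ``high`` when the projected scores fall
    inside the predicted class's own 1-alpha score ellipse, ``medium`` when
    only inside the global T² limit, ``low`` outside both.
    """
    if scaling is not None:
        import pandas as pd
        if not isinstance(X_new, pd.DataFrame):
            raise ValueError("raw input with scaling must be a DataFrame with "
                             "feature columns")
        Xs = scaling.apply(X_new).to_numpy()
    else:
        Xs = np.asarray(X_new, dtype=float)
        if Xs.ndim != 2:
            raise ValueError("X_new must be 2-D")
    if Xs.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"expected {model.W.shape[0]} feature columns, got {Xs.shape[1]}")
    scores = Xs @ model.R
    y_pred = Xs @ model.B + model.y_mean
    # argmax with lexicographic tie-break: classes are stored sorted, and
    # np.argmax returns the first maximum
    labels = [model.classes[int(np.argmax(row))] for row in y_pred]
    regions, gvar, glim = _class_regions(model, alpha)
    grades = []
    for i, cls in enumerate(labels):
        region = regions[cls]
        inside_class = False
        if region is not None:
            center, var, lim = region
            inside_class = float(hotelling_t2(scores[i], var, center)[0]) <= lim
        if inside_class:
            grades.append("high")
        elif float(hotelling_t2(scores[i], gvar)[0]) <= glim:
            grades.append("medium")
        else:
            grades.append("low")
    return Prediction(y_pred=y_pred, classes=list(model.classes), labels=labels,
                      scores=scores, grades=grades)


# ---------------------------------------------------------------------------
# figures of merit
# ---------------------------------------------------------------------------

def _binary_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney rank form of the AUC (ties counted half)."""
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty for AUC")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def auroc(y_scores: np.ndarray, labels, classes: list[str] | None = None) -> float:
    """Binary AUROC, or multiclass AUROC as the unweighted mean of all
    pairwise binary AUCs computed from the two classes' predicted-value
    contrast (Hand-and-Till style)."""
    labels = np.asarray(list(labels))
    y_scores = np.asarray(y_scores, dtype=float)
    if classes is None:
        classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    present = set(labels.tolist())
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"classes absent from labels: {missing}")
    if y_scores.ndim == 1:
        if len(classes) != 2:
            raise ValueError("1-D scores only valid for binary problems")
        pos = y_scores[labels == classes[1]]
        neg = y_scores[labels == classes[0]]
        return _binary_auc(pos, neg)
    aucs = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            mask_i = labels == classes[i]
            mask_j = labels == classes[j]
            contrast = y_scores[:, i] - y_scores[:, j]
            aucs.append(_binary_auc(contrast[mask_i], contrast[mask_j]))
    return float(np.mean(aucs))


@dataclass
class CvResult:
    """Cross-validation figures of merit across seeded repeats."""

    q2: float
    errors: np.ndarray          # misclassification error per repeat
    aurocs: np.ndarray          # (multiclass) AUROC per repeat
    fold_assignments: list[np.ndarray]  # per repeat: fold index per entity
    n_folds: int
    n_components: int

    @property
    def error_mean(self) -> float:
        return float(self.errors.mean())

    @property
    def error_sd(self) -> float:
        return float(self.errors.std(ddof=1)) if len(self.errors) > 1 else 0.0

    @property
    def auroc_mean(self) -> float:
        return float(self.aurocs.mean())

    @property
    def auroc_sd(self) -> float:
        return float(self.aurocs.std(ddof=1)) if len(self.aurocs) > 1 else 0.0


def stratified_folds(labels, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Per-class round-robin assignment into folds; returns fold index per row.

    Singleton classes are kept in training for every fold (fold index -1)
    with a warning.
    """
    labels = np.asarray(list(labels))
    folds = np.full(len(labels), -1, dtype=int)
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) == 1 and n_folds > 1:
            warnings.warn(f"class {cls!r} has a single member; kept in training",
                          stacklevel=2)
            continue
        perm = rng.permutation(idx)
        offset = int(rng.integers(n_folds))
        for k, row in enumerate(perm):
            folds[row] = (k + offset) % n_folds
    return folds


def _scale_train_test(X_train: np.ndarray, X_test: np.ndarray):
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns carry no information
    return (X_train - mean) / sd, (X_test - mean) / sd


def cross_validate(X: np.ndarray, labels, n_components: int, *,
                   n_folds: int = 5, n_repeats: int = 20, seed: int = 0,
                   scale: bool = True) -> CvResult:
    """Repeated stratified k-fold cross-validation of a PLS-DA model.

    ``X`` is the unscaled (log-transformed) matrix: centering and
    unit-variance scaling are re-estimated inside every training fold and
    applied to its test fold, so no test information leaks into the model.
    Q² is pooled: 1 − ΣPRESS / (n_repeats × total centered Y sum of squares).
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    Y01, classes = one_hot(labels)
    lab_arr = np.asarray(labels)
    tss = float(((Y01 - Y01.mean(axis=0)) ** 2).sum())
    rng = np.random.default_rng(seed)
    press_total = 0.0
    errors = np.zeros(n_repeats)
    aurocs = np.zeros(n_repeats)
    assignments = []
    n = len(labels)
    for r in range(n_repeats):
        folds = stratified_folds(labels, n_folds, rng)
        assignments.append(folds)
        y_hat = np.full((n, len(classes)), np.nan)
        for k in range(n_folds):
            test = folds == k
            train = ~test
            if not test.any():
                continue
            if len(set(lab_arr[train])) < 2:
                raise ValueError("training fold lost all but one class")
            if scale:
                Xtr, Xte = _scale_train_test(X[train], X[test])
            else:
                Xtr, Xte = X[train], X[test]
            a = min(n_components, Xtr.shape[0] - 1, Xtr.shape[1])
            model = fit_plsda(Xtr, lab_arr[train].tolist(), a)
            pred = Xte @ model.B + model.y_mean
            cols = [model.classes.index(c) if c in model.classes else -1
                    for c in classes]
            full = np.zeros((pred.shape[0], len(classes)))
            for ci, c in enumerate(cols):
                full[:, ci] = pred[:, c] if c >= 0 else 0.0
            y_hat[test] = full
        tested = ~np.isnan(y_hat[:, 0])
        press_total += float(((Y01[tested] - y_hat[tested]) ** 2).sum())
        pred_lab = [classes[int(np.argmax(row))] for row in y_hat[tested]]
        errors[r] = float(np.mean(np.asarray(pred_lab) != lab_arr[tested]))
        try:
            aurocs[r] = auroc(y_hat[tested], lab_arr[tested].tolist(), classes)
        except ValueError:
            aurocs[r] = np.nan
    q2 = 1.0 - press_total / (n_repeats * tss)
    return CvResult(q2=q2, errors=errors, aurocs=aurocs,
                    fold_assignments=assignments, n_folds=n_folds,
                    n_components=n_components)
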