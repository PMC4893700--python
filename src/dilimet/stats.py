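"""Univariate testing and the dual discriminant-metabolite criterion.

A metabolite is called discriminant when it satisfies at least one of:
FDR-adjusted q < 0.05 (Mann-Whitney for pairwise contrasts, one-way ANOVA for
the four-group contrast, Benjamini-Hochberg correction across the comparison
family) or VIP > 1.2 from the comparison's PLS-DA model. The Mann-Whitney
test is exact (full enumeration of the U null distribution) for tie-free
samples with min(n1, n2) <= 8 — the regime of the study's 6-9 entity groups —
and a tie/continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from dilimet.chemometrics import PlsModel, fit_plsda, vip
from dilimet.tables import EntityMatrix

EXACT_MAX_N = 8


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Exact null distribution when min(n1, n2) <= 8 and there are no ties,
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # all values identical: any labeling is as extreme as any other
        return float(len(x) * len(y) / 2), 1.0
    method = "exact" if (min(len(x), len(y)) <= EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def anova_oneway(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F test with (k-1, N-k) degrees of freedom."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs at least two values")
    grand = np.concatenate(arrs)
    if np.ptp(grand) == 0:
        raise ValueError("all values identical; F is undefined")
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs)
    if ssw == 0:
        warnings.warn("zero within-group variance with unequal means; p set to 0",
                      stacklevel=2)
        return float("inf"), 0.0
    f, p = sps.f_oneway(*arrs)
    return float(f), float(p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values: q_(i) = min_{j>=i} (m p_(j) / j), capped
    at 1, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DiscriminantResult:
    """Per-metabolite p/q/VIP/direction table for one comparison."""

    table: pd.DataFrame     # index feature_id: p, q, vip, direction, flagged
    comparison: str         # e.g. "control_vs_oxidative_stress" / "four_group"
    test: str               # "mann_whitney" | "anova"
    model: PlsModel
    q_threshold: float
    vip_threshold: float

    @property
    def flagged(self) -> pd.Index:
        return self.table.index[self.table["flagged"]]


def discriminant_features(matrix: EntityMatrix, comparison: str,
                          q_threshold: float = 0.05,
                          vip_threshold: float = 1.2,
                          n_components: int | None = None) -> DiscriminantResult:
    """Apply the dual discriminant criterion to a log-scale entity matrix.

    ``comparison`` is ``"four_group"`` (one-way ANOVA over the four mechanism
    classes) or a toxic class name (pairwise control vs that class,
    Mann-Whitney). The VIP arm comes from a PLS-DA fitted on the same
    comparison's entities (1 latent variable for pairwise contrasts, 3 for
    the four-group model, unless overridden); the OR of the two arms flags a
    metabolite as discriminant.
    """
    if matrix.transform != "log":
        raise ValueError("discriminant testing expects a log-scale entity matrix "
                         "(see preprocess.log_matrix)")
    classes = matrix.classes
    X = matrix.values
    if comparison == "four_group":
        groups = sorted(set(classes))
        if len(groups) < 3:
            raise ValueError("four-group comparison needs >=3 classes present")
        keep = classes.index
        test_name = "anova"
        a_default = 3
    else:
        if comparison not in set(classes) or comparison == "control":
            raise ValueError(f"unknown comparison class: {comparison!r}")
        keep = classes.index[classes.isin(["control", comparison])]
        test_name = "mann_whitney"
        a_default = 1
    sub = X.loc[keep]
    sub_classes = classes.loc[keep]
    counts = sub_classes.value_counts()
    if (counts < 2).any():
        raise ValueError(f"comparison group with <2 entities: {dict(counts)}")

    pvals = np.empty(sub.shape[1])
    direction = np.empty(sub.shape[1])
    ctrl_mask = (sub_classes == "control").to_numpy()
    for j, col in enumerate(sub.columns):
        v = sub[col].to_numpy()
        if test_name == "mann_whitney":
            _, pvals[j] = mann_whitney(v[~ctrl_mask], v[ctrl_mask])
        else:
            _, pvals[j] = anova_oneway(
                *[v[(sub_classes == g).to_numpy()] for g in sorted(set(sub_classes))])
        direction[j] = np.sign(v[~ctrl_mask].mean() - v[ctrl_mask].mean())
    qvals = bh_fdr(pvals)

    # VIP arm: per-comparison PLS-DA on the autoscaled submatrix
    Xs = sub.to_numpy()
    mean = Xs.mean(axis=0)
    sd = Xs.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    a = n_components if n_components is not None else a_default
    model = fit_plsda((Xs - mean) / sd, sub_classes.tolist(), a,
                      feature_names=list(sub.columns))
    vips = vip(model)

    table = pd.DataFrame({
        "p": pvals, "q": qvals, "vip": vips, "direction": direction,
    }, index=sub.columns)
    table["flagged"] = (table["q"] < q_threshold) | (table["vip"] > vip_threshold)
    name = "four_group" if comparison == "four_group" else f"control_vs_{comparison}"
    return DiscriminantResult(table=table, comparison=name, test=test_name,
                              model=model, q_threshold=q_threshold,
                              vip_threshold=vip_threshold)
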