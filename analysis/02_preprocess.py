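#!/usr/bin/env python
"""Preprocess the raw block tables into the modeling entity matrix.

Steps: QC stability report per block; blank filtering (min study/blank ratio
3); IS + protein normalization; column-wise fusion of the four blocks;
replicate averaging to one row per drug-concentration entity. Writes
results/entity_matrix.csv and results/qc_report.csv.
"""

import pandas as pd

from dilimet.preprocess import (
    average_replicates,
    blank_filter,
    fuse_blocks,
    normalize,
    qc_monitor,
)
from dilimet.synth import read_dataset

IN = "results/dataset"
MATRIX_OUT = "results/entity_matrix.csv"
QC_OUT = "results/qc_report.csv"


def main() -> None:
    tables, truth = read_dataset(IN)

    qc_rows = []
    processed = []
    for block in sorted(tables):
        raw = tables[block]
        qc = qc_monitor(raw, cv_threshold=0.3)
        qc_rows.append(pd.DataFrame({
            "block": block,
            "median_feature_cv": [qc.drop(index="__IS__")["cv"].median()],
            "is_cv": [qc.loc["__IS__", "cv"]],
            "frac_passed": [qc["passed"].mean()],
        }))
        filtered = blank_filter(raw, min_ratio=3.0)
        removed = raw.intensities.shape[1] - filtered.intensities.shape[1]
        print(f"{block}: QC median feature CV "
              f"{qc_rows[-1]['median_feature_cv'].iloc[0]:.3f}, "
              f"blank filter removed {removed} background ions")
        processed.append(normalize(filtered))

    fused = fuse_blocks(processed)
    matrix = average_replicates(fused)
    matrix.write_csv(MATRIX_OUT)
    pd.concat(qc_rows, ignore_index=True).to_csv(QC_OUT, index=False)

    bg_left = set(matrix.values.columns) & set(truth.index[truth["is_background"]])
    print(f"fused matrix: {fused.intensities.shape[1]} metabolites; "
          f"entity matrix {matrix.values.shape[0]} x {matrix.values.shape[1]} "
          f"({len(bg_left)} background ions remaining)")

    # unsupervised overview: PCA of the scaled entity matrix
    from dilimet.chemometrics import fit_pca
    from dilimet.plotting import scores_plot
    from dilimet.preprocess import transform_scale

    scaled = transform_scale(matrix)
    pca = fit_pca(scaled.values.to_numpy(), 3)
    evr = pca.explained_variance_ratio
    print("PCA explained variance: "
          + ", ".join(f"PC{i + 1} {v:.1%}" for i, v in enumerate(evr)))
    scores_plot(pca.scores, matrix.classes, path="results/pca_scores.png",
                title="PCA scores (entities)")
    print(f"wrote {MATRIX_OUT}, {QC_OUT} and results/pca_scores.png")


if __name__ == "__main__":
    main()
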