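#!/usr/bin/env python
"""Identify discriminant metabolites per toxicity mechanism and run ORA.

For each pairwise contrast (control vs mechanism) and the four-group
contrast, applies the dual criterion (BH q < 0.05 by Mann-Whitney/ANOVA, or
VIP > 1.2 from the contrast's PLS-DA), then tests each mechanism's hit list
for over-represented metabolite sets. Writes results/discriminant_*.csv and
results/ora_*.csv.
"""

import pandas as pd

from dilimet.enrichment import default_metabolite_sets, ora
from dilimet.preprocess import log_matrix
from dilimet.stats import discriminant_features
from dilimet.synth import build_feature_catalog
from dilimet.tables import EntityMatrix

MATRIX = "results/entity_matrix.csv"


def main() -> None:
    matrix = EntityMatrix.read_csv(MATRIX)
    lg = log_matrix(matrix)
    catalog = build_feature_catalog()
    sets = default_metabolite_sets(catalog, universe=matrix.values.columns)

    for comparison in ("oxidative_stress", "phospholipidosis", "steatosis",
                       "four_group"):
        res = discriminant_features(lg, comparison)
        res.table.rename_axis("metabolite").to_csv(
            f"results/discriminant_{res.comparison}.csv")
        n_q = int((res.table["q"] < 0.05).sum())
        n_vip = int((res.table["vip"] > 1.2).sum())
        print(f"{res.comparison}: {len(res.flagged)} discriminant metabolites "
              f"({n_q} by q<0.05, {n_vip} by VIP>1.2)")
        if comparison != "four_group":
            enr = ora(set(res.flagged), sets)
            enr.to_csv(f"results/ora_{res.comparison}.csv")
            top = enr.index[0]
            print(f"  top enriched set: {top} "
                  f"(overlap {enr.loc[top, 'overlap']}/{enr.loc[top, 'set_size']}, "
                  f"p={enr.loc[top, 'p']:.2e})")


if __name__ == "__main__":
    main()
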