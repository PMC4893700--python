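#!/usr/bin/env python
"""Generate the synthetic hepatotoxicity metabolomics study.

Emulates the study design (12 compounds + 2 vehicle controls -> 30
drug-concentration entities, 3 biological replicates, pooled QC every 10
injections, blanks, 4 analytical blocks / 272 identified metabolites) with
planted mechanism signatures, and writes the raw per-block feature tables
plus the ground truth under results/dataset/.
"""

import sys

from dilimet.synth import (
    build_default_design,
    build_feature_catalog,
    default_signatures,
    simulate,
    write_dataset,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = "results/dataset"


def main() -> None:
    design = build_default_design()
    catalog = build_feature_catalog()
    signatures = default_signatures(catalog)
    tables, truth = simulate(design, catalog, signatures, seed=SEED)
    write_dataset(tables, truth, OUT)

    ents = design.entities()
    print(f"design: {len(ents)} entities "
          f"({ents['class'].value_counts().to_dict()})")
    print(f"catalog: {len(catalog)} features "
          f"({int(catalog['is_background'].sum())} background) in 4 blocks")
    print(f"signatures: {len(signatures)} metabolites with planted effects")
    for block, t in tables.items():
        print(f"  {block}: {t.intensities.shape[0]} injections x "
              f"{t.intensities.shape[1]} features")
    print(f"wrote {OUT}/ (seed={SEED})")


if __name__ == "__main__":
    main()
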