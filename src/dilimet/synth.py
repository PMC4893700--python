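"""Synthetic LC-MS feature tables emulating a hepatotoxicity metabolomics study.

The generator reproduces the structure of the in-vitro study the pipeline was
designed for: 12 compounds (2 non-hepatotoxic controls, 2 oxidative-stress
inducers, 5 phospholipidogenic and 3 steatogenic drugs) assayed at 1-4
sub-lethal concentrations each, plus medium-only and DMSO vehicle controls —
30 drug-concentration "entities" in all, 3 biological replicates per entity,
pooled-QC injections every 10 study samples and blank injections, measured in
four analytical blocks that together cover 272 identified metabolites.

Mechanism signatures are planted multiplicatively on top of log-normal
baseline abundances: glutathione-cycle depletion/oxidation markers for all
toxic classes (strongest under oxidative stress), lysophospholipid depletion
for phospholipidosis, and triacylglyceride/diacylglyceride/phospholipid
accumulation with fatty-acid depletion for steatosis. Ratio markers
(GSH/GSSG, LysoPL/PL) are emergent from the component metabolites rather than
simulated directly. A truth table records every planted effect so downstream
recovery can be scored.

Simulation starts at the integrated feature-intensity level; no raw spectra,
chromatograms or peak shapes are modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from dilimet.tables import (
    FeatureTable,
    MECHANISM_CLASSES,
    SAMPLE_META_COLS,
)

TOXIC_CLASSES = ("oxidative_stress", "phospholipidosis", "steatosis")


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

@dataclass
class CompoundRecord:
    """One test compound with its mechanism class and assay concentrations."""

    name: str
    abbreviation: str
    mechanism_class: str
    concentrations: tuple[float, ...]
    ic10: float | None = None
    cmax: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism_class not in MECHANISM_CLASSES:
            raise ValueError(f"unknown mechanism class: {self.mechanism_class}")
        conc = tuple(float(c) for c in self.concentrations)
        if not conc:
            raise ValueError(f"{self.name}: concentrations must be non-empty")
        if any(c <= 0 for c in conc):
            raise ValueError(f"{self.name}: concentrations must be positive")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError(f"{self.name}: concentrations must be strictly increasing")
        self.concentrations = conc


@dataclass
class StudyDesign:
    """Compound panel plus replication/QC layout."""

    compounds: list[CompoundRecord]
    n_replicates: int = 3
    qc_interval: int = 10
    n_blanks: int = 3
    include_vehicle_controls: bool = True

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.qc_interval < 1:
            raise ValueError("qc_interval must be positive")
        if self.n_blanks < 0:
            raise ValueError("n_blanks must be non-negative")

    def entities(self) -> pd.DataFrame:
        """One row per drug-concentration entity (plus vehicle controls).

        ``dose_rank``/``n_doses`` drive dose-dependent effect scaling:
        the top concentration of a compound carries the full planted effect.
        """
        rows = []
        for comp in self.compounds:
            n = len(comp.concentrations)
            for rank, conc in enumerate(comp.concentrations, start=1):
                eid = f"{comp.abbreviation}_{conc:g}"
                rows.append((eid, comp.name, conc, comp.mechanism_class, rank, n))
        if self.include_vehicle_controls:
            rows.append(("C", "medium", 0.0, "control", 1, 1))
            rows.append(("DMSO", "DMSO 0.5%", 0.0, "control", 1, 1))
        df = pd.DataFrame(
            rows, columns=["entity_id", "compound", "concentration_uM",
                           "class", "dose_rank", "n_doses"]
        ).set_index("entity_id")
        if df.index.duplicated().any():
            raise ValueError("duplicated entity ids in design")
        return df


#: compound panel: mechanism class, IC10 (uM) and assay concentrations (uM)
_DEFAULT_PANEL = [
    ("Citrate", "Cit", "control", (500, 1000), None, None),
    ("Ketotifen", "Ket", "control", (50, 100), 130.0, 0.0014),
    ("Cumene hydroperoxide", "Cum", "oxidative_stress", (50, 100, 250), 480.0, None),
    ("tert-Butyl hydroperoxide", "Tert", "oxidative_stress", (50, 100, 250), 280.0, None),
    ("Amiodarone", "Am", "phospholipidosis", (5, 10, 20), 26.0, 2.2),
    ("Clozapine", "Clo", "phospholipidosis", (10, 20), 41.0, 1.09),
    ("Fluoxetine", "Fluo", "phospholipidosis", (20,), 12.0, 0.93),
    ("Tilorone", "Til", "phospholipidosis", (5, 20), 14.0, None),
    ("Tamoxifen", "Tam", "phospholipidosis", (15,), 32.0, 0.27),
    ("Doxycycline", "Dox", "steatosis", (250, 500), 600.0, 8.77),
    ("Tetracycline", "Tet", "steatosis", (50, 100, 200, 400), 640.0, 14.2),
    ("Valproate", "Val", "steatosis", (2000, 4000, 8000), 8870.0, 481.0),
]


def build_default_design(include_vehicle_controls: bool = True) -> StudyDesign:
    """The study's compound panel: 28 drug-concentration entities plus the
    medium and DMSO vehicle controls (30 entities; class counts 6/6/9/9)."""
    compounds = [CompoundRecord(*row) for row in _DEFAULT_PANEL]
    return StudyDesign(compounds=compounds,
                       include_vehicle_controls=include_vehicle_controls)


# ---------------------------------------------------------------------------
# feature catalog and planted signatures
# ---------------------------------------------------------------------------

#: mandatory marker metabolites: (metabolite, monoisotopic mass, class, block)
DEFAULT_MARKERS: list[tuple[str, float, str, str]] = [
    # glutathione / gamma-glutamyl cycle (polar block B1)
    ("glutathione", 307.0838, "glutathione_gamma_glutamyl", "B1"),
    ("glutathione disulfide", 612.1520, "glutathione_gamma_glutamyl", "B1"),
    ("cysteine-glutathione disulfide", 426.0883, "glutathione_gamma_glutamyl", "B1"),
    ("ophthalmic acid", 289.1274, "glutathione_gamma_glutamyl", "B1"),
    ("gamma-glutamylcysteine", 250.0623, "glutathione_gamma_glutamyl", "B1"),
    ("gamma-glutamylglutamine", 275.1117, "glutathione_gamma_glutamyl", "B1"),
    ("gamma-glutamylleucine", 260.1372, "glutathione_gamma_glutamyl", "B1"),
    ("gamma-glutamylvaline", 246.1216, "glutathione_gamma_glutamyl", "B1"),
    ("glutamate", 147.0532, "amino_acid", "B1"),
    ("glutamine", 146.0691, "amino_acid", "B1"),
    # fatty acids and acylcarnitines (block B2)
    ("palmitic acid", 256.2402, "fatty_acid", "B2"),
    ("stearic acid", 284.2715, "fatty_acid", "B2"),
    ("oleic acid", 282.2559, "fatty_acid", "B2"),
    ("linoleic acid", 280.2402, "fatty_acid", "B2"),
    ("palmitoleic acid", 254.2246, "fatty_acid", "B2"),
    ("myristic acid", 228.2089, "fatty_acid", "B2"),
    ("arachidonic acid", 304.2402, "fatty_acid", "B2"),
    ("docosahexaenoic acid", 328.2402, "fatty_acid", "B2"),
    ("eicosapentaenoic acid", 302.2246, "fatty_acid", "B2"),
    ("alpha-linolenic acid", 278.2246, "fatty_acid", "B2"),
    ("acetylcarnitine", 203.1158, "acylcarnitine", "B2"),
    ("octanoylcarnitine", 287.2097, "acylcarnitine", "B2"),
    ("myristoylcarnitine", 371.3036, "acylcarnitine", "B2"),
    ("palmitoylcarnitine", 399.3349, "acylcarnitine", "B2"),
    ("oleoylcarnitine", 425.3505, "acylcarnitine", "B2"),
    ("stearoylcarnitine", 427.3662, "acylcarnitine", "B2"),
    # phospholipids and lysophospholipids (block B3)
    ("LysoPC(14:0)", 467.3012, "lysophospholipid", "B3"),
    ("LysoPC(16:0)", 495.3325, "lysophospholipid", "B3"),
    ("LysoPC(18:0)", 523.3638, "lysophospholipid", "B3"),
    ("LysoPC(18:1)", 521.3481, "lysophospholipid", "B3"),
    ("LysoPC(18:2)", 519.3325, "lysophospholipid", "B3"),
    ("LysoPC(20:4)", 543.3325, "lysophospholipid", "B3"),
    ("LysoPE(16:0)", 453.2855, "lysophospholipid", "B3"),
    ("LysoPE(18:0)", 481.3168, "lysophospholipid", "B3"),
    ("LysoPE(18:1)", 479.3012, "lysophospholipid", "B3"),
    ("LysoPE(18:2)", 477.2855, "lysophospholipid", "B3"),
    ("PC(30:0)", 705.5309, "phospholipid", "B3"),
    ("PC(32:0)", 733.5622, "phospholipid", "B3"),
    ("PC(34:1)", 759.5778, "phospholipid", "B3"),
    ("PC(34:2)", 757.5622, "phospholipid", "B3"),
    ("PC(36:2)", 785.5935, "phospholipid", "B3"),
    ("PC(36:4)", 781.5622, "phospholipid", "B3"),
    ("PC(38:4)", 809.5935, "phospholipid", "B3"),
    ("PE(34:1)", 717.5309, "phospholipid", "B3"),
    ("PE(34:2)", 715.5152, "phospholipid", "B3"),
    ("PE(36:2)", 743.5465, "phospholipid", "B3"),
    ("PE(36:4)", 739.5152, "phospholipid", "B3"),
    ("PE(38:4)", 767.5465, "phospholipid", "B3"),
    # neutral lipids (block B4)
    ("TG(46:0)", 778.7050, "triacylglyceride", "B4"),
    ("TG(48:0)", 806.7363, "triacylglyceride", "B4"),
    ("TG(50:1)", 832.7520, "triacylglyceride", "B4"),
    ("TG(50:2)", 830.7363, "triacylglyceride", "B4"),
    ("TG(52:1)", 860.7833, "triacylglyceride", "B4"),
    ("TG(52:2)", 858.7676, "triacylglyceride", "B4"),
    ("TG(52:3)", 856.7520, "triacylglyceride", "B4"),
    ("TG(54:2)", 886.7989, "triacylglyceride", "B4"),
    ("TG(54:3)", 884.7833, "triacylglyceride", "B4"),
    ("TG(54:4)", 882.7676, "triacylglyceride", "B4"),
    ("DG(32:0)", 568.5067, "diacylglyceride", "B4"),
    ("DG(34:1)", 594.5223, "diacylglyceride", "B4"),
    ("DG(34:2)", 592.5067, "diacylglyceride", "B4"),
    ("DG(36:1)", 622.5536, "diacylglyceride", "B4"),
    ("DG(36:2)", 620.5380, "diacylglyceride", "B4"),
    ("DG(36:4)", 616.4754, "diacylglyceride", "B4"),
]

BLOCK_NAMES = ("B1", "B2", "B3", "B4")


@dataclass
class SignatureSpec:
    """Planted per-class multiplicative effect for one metabolite.

    ``effects`` maps a toxic mechanism class to the log2 fold change applied
    at a compound's top assay concentration; with ``dose_dependent`` the
    effect is scaled by (dose rank / number of doses).
    """

    metabolite_id: str
    effects: dict[str, float]
    dose_dependent: bool = True

    def __post_init__(self) -> None:
        if "control" in self.effects:
            raise ValueError("control class cannot carry a planted effect")
        for cls, lfc in self.effects.items():
            if cls not in TOXIC_CLASSES:
                raise ValueError(f"unknown class in signature: {cls}")
            if not math.isfinite(lfc) or lfc == 0:
                raise ValueError(
                    f"{self.metabolite_id}: fold change for {cls} must be finite, non-zero")

    @property
    def affected_classes(self) -> tuple[str, ...]:
        return tuple(sorted(self.effects))


#: class-wide planted log2 fold changes at top dose, from the mechanism
#: fingerprints the pipeline is meant to recover
_CLASS_EFFECTS: dict[str, dict[str, float]] = {
    "lysophospholipid": {"phospholipidosis": -1.0, "steatosis": 0.8},
    "phospholipid": {"phospholipidosis": 0.2, "steatosis": 0.8},
    "triacylglyceride": {"oxidative_stress": 0.3, "phospholipidosis": 0.4, "steatosis": 1.2},
    "diacylglyceride": {"steatosis": 0.8},
    "fatty_acid": {"oxidative_stress": 0.4, "steatosis": -0.8},
    "acylcarnitine": {"steatosis": 0.6},
}

#: metabolite-specific effects (redox markers altered in all toxic classes,
#: strongest under oxidative stress)
_NAMED_EFFECTS: dict[str, dict[str, float]] = {
    "glutathione": {"oxidative_stress": -2.0, "phospholipidosis": -0.8, "steatosis": -0.8},
    "glutathione disulfide": {"oxidative_stress": 1.0, "phospholipidosis": 0.5, "steatosis": 0.5},
    "cysteine-glutathione disulfide": {"oxidative_stress": 1.5, "phospholipidosis": 0.8,
                                       "steatosis": 0.8},
    "ophthalmic acid": {"oxidative_stress": 1.5},
    "gamma-glutamylcysteine": {"oxidative_stress": 1.2},
    "gamma-glutamylglutamine": {"oxidative_stress": 1.2},
    "gamma-glutamylleucine": {"oxidative_stress": 1.2},
    "gamma-glutamylvaline": {"oxidative_stress": 1.2},
    "glutamate": {"oxidative_stress": 0.8, "steatosis": 0.4},
    "glutamine": {"oxidative_stress": -0.8},
}


def build_feature_catalog(
    n_features: int = 272,
    block_sizes: tuple[int, int, int, int] = (120, 60, 50, 42),
    *,
    markers: list[tuple[str, float, str, str]] | None = None,
    n_background: int = 16,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a feature catalog of ``n_features`` identified metabolites split
    across four analytical blocks, plus ``n_background`` solvent-derived
    background ions (flagged, removable by blank filtering).

    The mandatory marker metabolites are always included; the remainder are
    anonymous fillers with plausible monoisotopic masses. Deterministic for a
    given seed.
    """
    if len(block_sizes) != 4:
        raise ValueError("exactly four analytical blocks are expected")
    if sum(block_sizes) != n_features:
        raise ValueError(f"block sizes {block_sizes} do not sum to n_features={n_features}")
    markers = DEFAULT_MARKERS if markers is None else markers
    if n_features < len(markers):
        raise ValueError(
            f"n_features={n_features} below the {len(markers)} mandatory markers")

    per_block_markers: dict[str, list[tuple[str, float, str]]] = {b: [] for b in BLOCK_NAMES}
    for name, mass, mclass, block in markers:
        per_block_markers[block].append((name, mass, mclass))
    rng = np.random.default_rng(seed)
    rows = []
    for block, size in zip(BLOCK_NAMES, block_sizes):
        marks = per_block_markers[block]
        if len(marks) > size:
            raise ValueError(f"block {block} too small for its {len(marks)} markers")
        for name, mass, mclass in marks:
            rows.append((name, block, name, mass, mclass, False))
        for i in range(size - len(marks)):
            fid = f"metab_{block}_{i + 1:03d}"
            mass = float(np.round(rng.uniform(100.0, 900.0), 4))
            rows.append((fid, block, fid, mass, "other", False))
    for i in range(n_background):
        block = BLOCK_NAMES[i % 4]
        fid = f"bg_{block}_{i // 4 + 1:02d}"
        mass = float(np.round(rng.uniform(100.0, 900.0), 4))
        rows.append((fid, block, fid, mass, "background", True))
    catalog = pd.DataFrame(
        rows, columns=["feature_id", "block", "metabolite", "monoisotopic_mass",
                       "metabolite_class", "is_background"],
    ).set_index("feature_id")
    if catalog.index.duplicated().any():
        raise ValueError("duplicated feature ids in catalog")
    return catalog


def default_signatures(catalog: pd.DataFrame,
                       dose_dependent: bool = False) -> list[SignatureSpec]:
    """Planted mechanism signatures for every marker in the catalog.

    By default the fingerprints are planted at full strength at every tested
    concentration: the emulated study used sub-lethal concentrations chosen
    to elicit the toxic effect at each tested dose. Pass
    ``dose_dependent=True`` to scale effects by concentration rank instead.
    """
    sigs = []
    for fid, row in catalog.iterrows():
        if row["is_background"]:
            continue
        effects = _NAMED_EFFECTS.get(fid, _CLASS_EFFECTS.get(row["metabolite_class"]))
        if effects:
            sigs.append(SignatureSpec(fid, dict(effects),
                                      dose_dependent=dose_dependent))
    return sigs


def truth_table(catalog: pd.DataFrame, signatures: list[SignatureSpec]) -> pd.DataFrame:
    """Per-feature ground truth: planted log2 fold change per toxic class,
    affected flags, metabolite-set membership and background status."""
    seen = set()
    for sig in signatures:
        if sig.metabolite_id not in catalog.index:
            raise ValueError(f"signature for unknown metabolite: {sig.metabolite_id}")
        if sig.metabolite_id in seen:
            raise ValueError(f"duplicate signature for {sig.metabolite_id}")
        seen.add(sig.metabolite_id)
    truth = catalog[["metabolite_class", "is_background"]].copy()
    for cls in TOXIC_CLASSES:
        truth[f"lfc_{cls}"] = 0.0
    truth["dose_dependent"] = False
    for sig in signatures:
        for cls, lfc in sig.effects.items():
            truth.loc[sig.metabolite_id, f"lfc_{cls}"] = lfc
        truth.loc[sig.metabolite_id, "dose_dependent"] = sig.dose_dependent
    for cls in TOXIC_CLASSES:
        truth[f"affected_{cls}"] = truth[f"lfc_{cls}"] != 0.0
    return truth


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class NoiseParams:
    """Noise/abundance model for the simulator.

    Baselines are log-normal with log10 mean 4 and sd 0.5 (typical LC-MS
    dynamic range); replicate noise is multiplicative log-normal at 15% CV;
    instrument drift over injection order is off by default.
    """

    baseline_log10_mean: float = 4.0
    baseline_log10_sd: float = 0.5
    replicate_cv: float = 0.15
    qc_cv: float = 0.05
    is_cv: float = 0.05
    protein_cv: float = 0.05
    drift_per_injection: float = 0.0

    def __post_init__(self) -> None:
        for name in ("replicate_cv", "qc_cv", "is_cv", "protein_cv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline_log10_sd <= 0:
            raise ValueError("baseline_log10_sd must be positive")


def _lognorm_sigma(cv: float) -> float:
    # exact sigma of a log-normal with the requested coefficient of variation
    return math.sqrt(math.log1p(cv * cv))


def simulate(
    design: StudyDesign,
    catalog: pd.DataFrame,
    signatures: list[SignatureSpec],
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> tuple[dict[str, FeatureTable], pd.DataFrame]:
    """Simulate one raw feature table per analytical block.

    Returns ``(tables, truth)`` where ``tables`` maps block name to a raw
    :class:`FeatureTable` containing study, pooled-QC and blank injections,
    and ``truth`` is the planted ground truth. Identical inputs and seed give
    bit-identical output.
    """
    noise = noise or NoiseParams()
    truth = truth_table(catalog, signatures)
    entities = design.entities()
    rng = np.random.default_rng(seed)

    fids = catalog.index.to_numpy()
    n_feat = len(fids)
    is_bg = catalog["is_background"].to_numpy()

    # per-feature baseline abundance (shared across blocks by feature)
    baseline = 10.0 ** rng.normal(noise.baseline_log10_mean,
                                  noise.baseline_log10_sd, n_feat)

    # entity x feature true concentration = baseline * 2**(dose-scaled lfc)
    lfc = np.zeros((len(entities), n_feat))
    col_of = {f: j for j, f in enumerate(fids)}
    for sig in signatures:
        j = col_of[sig.metabolite_id]
        for i, (eid, ent) in enumerate(entities.iterrows()):
            eff = sig.effects.get(ent["class"], 0.0)
            if eff and sig.dose_dependent:
                eff *= ent["dose_rank"] / ent["n_doses"]
            lfc[i, j] = eff
    true_conc = baseline * 2.0 ** lfc
    true_conc[:, is_bg] = 0.0  # background ions carry no biology
    pooled = true_conc.mean(axis=0)  # pooled QC mixture

    # injection sequence: blanks up front, then replicates in design order
    # with a pooled QC before every qc_interval-th study injection and at the end
    sample_rows: list[tuple] = []  # (sample_id, entity_id, compound, conc, class, rep, role)
    study_seq = [
        (f"{eid}_r{rep}", eid, ent["compound"], ent["concentration_uM"], ent["class"], rep)
        for eid, ent in entities.iterrows()
        for rep in range(1, design.n_replicates + 1)
    ]
    for b in range(design.n_blanks):
        sample_rows.append((f"blank_{b + 1}", "", "blank", 0.0, "", 0, "blank"))
    n_qc = 0
    for i, row in enumerate(study_seq):
        if i % design.qc_interval == 0:
            n_qc += 1
            sample_rows.append((f"QC_{n_qc}", "", "pooled QC", 0.0, "", 0, "qc"))
        sample_rows.append(row + ("study",))
    n_qc += 1
    sample_rows.append((f"QC_{n_qc}", "", "pooled QC", 0.0, "", 0, "qc"))

    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "entity_id", "compound", "concentration_uM",
                 "class", "replicate", "role"],
    ).set_index("sample_id")
    samples["injection_order"] = np.arange(1, len(samples) + 1)
    n_samp = len(samples)
    role = samples["role"].to_numpy()
    study_idx = np.flatnonzero(role == "study")

    protein = np.ones(n_samp)
    protein[study_idx] = np.clip(
        rng.normal(1.0, noise.protein_cv, len(study_idx)), 0.1, None)
    samples["protein_mg"] = protein

    sig_rep = _lognorm_sigma(noise.replicate_cv)
    sig_qc = _lognorm_sigma(noise.qc_cv)
    drift = 1.0 + noise.drift_per_injection * (samples["injection_order"].to_numpy() - 1)

    tables: dict[str, FeatureTable] = {}
    for block in BLOCK_NAMES:
        bmask = (catalog["block"] == block).to_numpy()
        bfids = fids[bmask]
        if bfids.size == 0:
            continue
        response = np.exp(rng.normal(0.0, _lognorm_sigma(noise.is_cv), n_samp))
        intens = np.zeros((n_samp, bfids.size))
        for i in range(n_samp):
            if role[i] == "blank":
                expect = np.zeros(n_feat)
                noise_mult = np.exp(rng.normal(0.0, sig_rep, n_feat))
            elif role[i] == "qc":
                expect = pooled * protein[i]
                noise_mult = np.exp(rng.normal(0.0, sig_qc, n_feat))
            else:
                e = entities.index.get_loc(samples["entity_id"].iloc[i])
                expect = true_conc[e] * protein[i]
                noise_mult = np.exp(rng.normal(0.0, sig_rep, n_feat))
            # background ions come from solvents: same expectation everywhere,
            # independent of protein amount
            full = expect.copy()
            full[is_bg] = baseline[is_bg]
            vals = full * noise_mult * response[i] * drift[i]
            intens[i] = vals[bmask]
        block_samples = samples.copy()
        block_samples["is_response"] = response
        tables[block] = FeatureTable(
            intensities=pd.DataFrame(intens, index=samples.index, columns=bfids),
            samples=block_samples[SAMPLE_META_COLS],
            features=catalog.loc[bfids],
            state="raw",
        )
    return tables, truth


def write_dataset(tables: dict[str, FeatureTable], truth: pd.DataFrame,
                  outdir: str | Path) -> None:
    """Write per-block feature-table CSVs, feature metadata and the truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    feats = []
    for block, table in tables.items():
        table.write_csv(outdir / f"features_{block}.csv")
        feats.append(table.features)
    feature_meta = pd.concat(feats)
    feature_meta.index.name = "feature_id"
    feature_meta.to_csv(outdir / "feature_metadata.csv")
    truth.rename_axis("feature_id").to_csv(outdir / "truth.csv")


def read_dataset(indir: str | Path) -> tuple[dict[str, FeatureTable], pd.DataFrame]:
    """Read a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    feature_meta = pd.read_csv(indir / "feature_metadata.csv", index_col="feature_id")
    tables = {}
    for path in sorted(indir.glob("features_*.csv")):
        block = path.stem.replace("features_", "")
        tables[block] = FeatureTable.read_csv(path, feature_meta, state="raw")
    truth_path = indir / "truth.csv"
    truth = pd.read_csv(truth_path, index_col="feature_id") if truth_path.exists() else None
    return tables, truth
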