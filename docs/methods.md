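# Methods

`dilimet` implements an end-to-end cell-metabolomics workflow for
classifying drug-induced hepatotoxicity mechanisms, together with a
synthetic-data generator that reproduces the study design the workflow was
built for. This note records the models, the defaults and why they were
chosen, and what the synthetic benchmark does and does not demonstrate.

## Study design emulated by the generator

The unit of modeling is the *entity*: one drug at one concentration,
obtained by averaging three biological replicates. The default design
(`synth.build_default_design`) contains 12 compounds — 2 non-hepatotoxic
controls (citrate, ketotifen), 2 oxidative-stress inducers (cumene and
tert-butyl hydroperoxide), 5 phospholipidosis inducers (amiodarone,
clozapine, fluoxetine, tilorone, tamoxifen) and 3 steatosis inducers
(doxycycline, tetracycline, valproate) — at 1–4 sub-lethal concentrations
each, plus medium-only and DMSO vehicle-control entities: 30 entities with
class counts control 6 / oxidative stress 6 / phospholipidosis 9 /
steatosis 9. Each analytical block carries a pooled-QC injection before
every 10 study injections (plus a closing QC) and 3 blank injections.

The feature catalog holds 272 identified metabolites split over four
analytical blocks (120/60/50/42) — a polar block carrying the
glutathione/γ-glutamyl-cycle markers, a fatty-acid/acylcarnitine block, a
phospholipid/lysophospholipid block and a neutral-lipid (TG/DG) block — plus
16 background ions used to exercise blank filtering.

## Abundance and noise model

Intensities are multiplicative:

    raw_ij = baseline_j · 2^(planted lfc) · protein_i · response_i ·
             drift_i · lognormal replicate noise

* baselines: log-normal, log10 mean 4, sd 0.5 (typical LC-MS dynamic range);
* replicate noise: log-normal at 15% CV; pooled-QC noise 5% CV;
* per-sample internal-standard (IS) response factor: log-normal, 5% CV;
  protein amount: normal(1.0 mg, 5%), floored at 0.1;
* injection-order drift: linear multiplicative, 0 by default;
* background ions: equal expected intensity in blanks and study samples and
  independent of protein; biological features are absent from blanks;
* pooled QC: the mean of all study-sample concentrations.

Planted signatures follow the mechanism fingerprints the pipeline is meant
to recover. At the compound's top dose (log2 fold changes): oxidative stress
— GSH −2.0, GSSG +1.0, CSSG +1.5, ophthalmate +1.5, γ-glutamyl dipeptides
+1.2, glutamate +0.8, glutamine −0.8, plus mild lipid remodeling (FA +0.4,
TG +0.3); phospholipidosis — lysophospholipids −1.0 with phospholipids near
unchanged (+0.2), so the LysoPL/PL ratio falls, plus attenuated redox
markers (GSH −0.8, GSSG +0.5, CSSG +0.8) and TG +0.4; steatosis — TG +1.2,
DG +0.8, PL +0.8, LysoPL +0.8, FA −0.8, acylcarnitines +0.6, plus attenuated
redox markers. Ratio markers (GSH/GSSG, LysoPL/PL) are emergent from the
component metabolites, not planted directly.

**Dose dependence.** `SignatureSpec.dose_dependent` scales an effect by
(concentration rank / number of doses), so the top dose carries the full
effect. The *default* signature set plants fingerprints at full strength at
every tested concentration (`dose_dependent=False`): the emulated study
deliberately used sub-lethal concentrations at which the toxic effect is
already manifest, and its external validation assigned every held-out sample
correctly — conditions incompatible with lowest-dose entities carrying only
a quarter of the class signature. With fully dose-scaled defaults the
lowest-dose entities fall on the control side of any linear decision
boundary *regardless of effect magnitude* (a class centroid sits at ~0.65 of
the full effect, the argmax boundary vs control at ~half of that), which no
classifier of this family can repair. Dose scaling remains available per
signature and is unit-tested.

The paper-derived quantities in the generator (design, class counts,
concentrations, QC cadence, block count, 272 metabolites) are fixed; the
noise magnitudes and effect sizes are the package's own defaults, since the
source study reports neither within-class biological variance nor effect
magnitudes numerically.

## Preprocessing

Order of operations: blank filter (keep a feature iff mean study intensity
≥ 3 × mean blank intensity; pass-through with a warning when no blanks
exist) → normalization (divide by per-sample IS response, then protein;
re-normalization is a state error) → column-wise fusion of the blocks keyed
on sample id → replicate averaging (arithmetic mean per entity; QC/blank
rows dropped). Mass-based identity lookup (`match_mass`) uses a ±10 ppm
relative window against a local reference table.

Before modeling, matrices are log10-transformed, mean-centered and
unit-variance scaled. Non-positive cells are imputed as half the feature's
minimum positive value (common metabolomics practice; the choice only
matters for features near the detection floor). Zero-variance columns are
dropped with a logged warning rather than erroring the run. Scaling
parameters are stored and re-applied verbatim when projecting new samples —
never re-estimated.

## Chemometrics

* **PCA** by NIPALS power iteration with deflation; tested against an SVD
  oracle to 1e-8. Sign convention everywhere: the largest-magnitude
  loading/weight entry is positive, so serialized models are reproducible.
* **PLS2-DA** by classical NIPALS (X and Y both deflated). Convergence:
  relative score change < 1e-10 or 500 iterations — later components on
  small matrices can oscillate between near-degenerate directions, in which
  case the iterate at the cap is used and a warning emitted. Y is one-hot
  with column centering; class assignment is the argmax of predicted Y, ties
  broken lexicographically. Explained Y sum of squares per component is
  SSY_a = Σ_k q_ka²·(t_a't_a); R²Y = ΣSSY_a / total centered Y SS.
* **VIP** with the standard normalization, so mean(VIP²) = 1 exactly.
* **Hotelling T²**: T²crit = A(n−1)/(n−A)·F₁₋α(A, n−A). Projection
  confidence grades: *high* = inside the predicted class's own 95% score
  ellipse (skipped for classes with ≤ A+1 members), *medium* = inside the
  global 95% limit only, *low* = outside.
* **AUROC**: binary by the Mann-Whitney rank form (ties counted half);
  multiclass as the unweighted mean over class pairs of the binary AUC of
  the two classes' predicted-value contrast (Hand-and-Till style — the
  source study cites a definition without formula, so the pairwise-mean
  convention is fixed here).
* **Cross-validation**: stratified 5-fold, repeated (default 20 repeats for
  reported mean ± sd; the repeat count behind the study's reported sd is
  unstated, so repeated CV is this package's convention). Centering/scaling
  are re-estimated inside every training fold — the study is silent on this;
  fold-internal scaling avoids leakage. Q² is pooled:
  1 − ΣPRESS/(repeats × total centered Y SS). Singleton classes stay in
  training with a warning.

## Model pipeline

1. **Split**: per class, round(0.2 × class size) entities (min 1) go to the
   external validation set; the default design yields 24 development + 6
   validation entities (1/1/2/2 per class).
2. **Variable selection**: features ranked by VIP of a full-feature PLS-DA
   (3 components; ties by feature id); for each candidate size (2–30 by 2,
   35–60 by 5) and component count (1–5), repeated CV on the development set
   only (5 repeats by default — a tractability choice; the final model's
   reported figures use 20). Winner: highest mean AUROC, ties by lower
   misclassification error, then **higher Q²**, then smaller size, then
   fewer components. The Q² tie-break exists because error and AUROC
   saturate on well-separated data and a purely parsimony-first rule
   selects models too small to generalize (observed as occasional
   phospholipidosis/steatosis swaps of held-out entities).
3. **Permutation test**: class labels shuffled over development entities;
   the model is refit and cross-validated at the *fixed* selected
   configuration (selection is not re-run per permutation — tractable and
   conservative about selection bias); b counts permuted models at least as
   good (≤ observed error, or ≥ observed AUROC); p = (b+1)/(n_perm+1), so
   p = 1/1001 < 0.001 at n = 1000 with zero exceedances. Observed and
   permuted models use identical CV settings (one 5-fold round each by
   default), keeping the comparison exchangeable under the null.
4. **External validation**: held-out entities are projected through the
   stored training transform; per-entity assignment, confidence grade and
   accuracy are reported. Corrupting validation rows provably cannot change
   the fitted model (tested).

Models serialize to a single JSON document; floats survive the round trip
bit-exactly.

## Discriminant testing and enrichment

Pairwise contrasts (control vs one mechanism) use the Mann-Whitney test —
exact by full enumeration of the U distribution when min(n₁,n₂) ≤ 8 without
ties (the study's 6–9 entity groups sit in this regime), otherwise the
tie/continuity-corrected normal approximation. The four-group contrast uses
one-way ANOVA. Tests are two-sided throughout. BH-FDR is applied within each
comparison family. A metabolite is discriminant when q < 0.05 or VIP > 1.2
(the VIP from the comparison's own PLS-DA: 1 latent variable for pairwise
contrasts, 3 for the four-group model).

Over-representation uses the hypergeometric upper tail against GMT metabolite
sets, BH-corrected across sets; the universe is the metabolites surviving
preprocessing. The default set collection mirrors the catalog's chemical
classes. The study's own pathway tools are external services; hypergeometric
ORA is this package's stated substitute, not a claim about those tools.

## What the synthetic benchmark shows — and does not

Passing tests demonstrate that the pipeline recovers planted structure under
the emulated design: correct discriminant calls and directions, planted-set
enrichment, permutation p at its minimum attainable value, and correct
external projection of held-out entities. They do not demonstrate
performance on real LC-MS data, where peak-integration artifacts, retention
drift, batch effects, missingness patterns and correlated biology are richer
than this generator's independent log-normal noise. The generator also
starts at integrated feature intensities: no spectra, chromatograms or
adducts.

## Problem sizes and numerical choices

Test batteries run at the sizes stated in their docstrings (e.g. 50 seeded
pipeline runs for projection/recovery rates, 200 repetitions at 99
permutations for null-p uniformity, 20 runs × 272 features for FDR
calibration); driver scripts and the acceptance script use the full
1000-permutation test. NIPALS tolerance 1e-10; scaling guards: sd = 1 for
constant columns inside CV folds, dropped columns with warning in the
user-facing transform; empirical p uses the add-one rule to remain positive;
all random draws descend from explicit integer seeds (child seeds < 2³¹).

## Known limitations

* Linear boundaries only (no OPLS, kernel or sparse PLS).
* Argmax class assignment inherits PLS-DA's sensitivity to class imbalance.
* The exact Mann-Whitney switch point (min n ≤ 8, no ties) is conservative;
  tied data always use the asymptotic path.
* The generator's independence across features understates the correlation
  structure of real lipidomes; enrichment p-values on real data would be
  anti-conservative under set-internal correlation.
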