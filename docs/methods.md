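# Methods

## The problem

The acid dissociation constant (pKa) of a small molecule governs its
charge state at physiological pH and, through that, solubility, membrane
permeability and protein binding. `monopka` implements a complete workflow
for *macroscopic* pKa of *monoprotic* compounds — molecules with exactly
one ionization event inside the pH window 2–12: curation of pKa-annotated
SDF data into a clean training set, a cross-validated regression benchmark
over descriptor/fingerprint feature sets, external validation, and an
SDF-in/SDF-out prediction tool. Molecules are identified throughout by
their canonical isomeric SMILES.

## Curation pipeline

Raw records (an RDKit molecule plus one or more experimental pKa values)
pass through eight ordered stages:

1. **Salt stripping.** Multi-fragment structures keep the largest organic
   fragment (most heavy atoms; ties broken by molecular weight, then by
   canonical SMILES). Structures with no carbon-containing fragment are
   dropped.
2. **Element/group filter.** Structures containing boron, selenium,
   silicon, or a nitro group are removed. Nitro matching covers both the
   charge-separated `[N+](=O)[O-]` and the pentavalent `N(=O)=O`
   depictions, because public files mix conventions.
3. **Lipinski filter.** Violations of MW ≤ 500 Da, logP ≤ 5 (Crippen
   atom-contribution estimate), H-bond donors ≤ 5 (N–H/O–H count) and
   acceptors ≤ 10 (N+O count) are counted; up to one violation is allowed.
4. **pKa window.** Only measurements with 2 ≤ pKa ≤ 12 survive. The bounds
   are treated as inclusive: "between 2 and 12" is ambiguous, and the
   inclusive reading retains printed boundary values.
5. **Tautomer standardization** — RDKit's canonical-tautomer picker by
   default, or a user-supplied adapter (see below).
6. **Protonation at pH 7.4** — by default a SMARTS rule set that
   deprotonates carboxylic/sulfonic/sulfinic acids and protonates
   aliphatic amines and amidine/guanidine imine nitrogens; groups whose
   class pKa is near 7.4 (anilines, pyridines, phenols, imidazoles) are
   left in their neutral form. The rules match only neutral depictions, so
   the operation is idempotent.
7. **Monoprotic filter.** A reference predictor reports the pKa values it
   finds inside the window; molecules with more than one are removed. The
   rule is applied literally: zero in-window predictions also passes.
8. **Outlier removal and duplicate merging**, in two steps. First, any
   measurement differing from the reference prediction by *strictly more*
   than 4 log units is removed (molecules without an in-window reference
   pass unfiltered — the rule is defined only where a comparison exists).
   Then measurements are grouped by canonical isomeric SMILES; within a
   group, values more than 2 standard deviations from the group mean are
   removed in a single (non-iterated) pass and the survivors are
   arithmetically averaged. Population SD (n denominator) is used; groups
   of one or two values skip the SD step, where it is degenerate. The
   value nearest the mean always survives a >k·SD cut, so a group never
   empties.

Every stage records its input/output counts and attributes every drop to
a reason; the counts telescope, and with the default adapters the whole
pipeline is deterministic.

### Adapters

Tautomer standardization, pH protonation and the reference pKa predictor
were historically performed with proprietary engines. They are pluggable
here: any callable (for the standardizers) or any object with
`predict_in_window(mol, lo, hi)` (for the predictor) can be configured,
and its output is used verbatim. The open defaults are the RDKit tautomer
canonicalizer, the SMARTS protonation rules above, and a SMARTS
ionizable-site estimator that assigns each matched group its textbook
class pKa (carboxylic acid ≈ 4.0, phenol ≈ 9.9, aliphatic amine ≈ 10.5,
aniline ≈ 4.6, pyridine ≈ 5.2, …). The estimator is deliberately coarse:
it is used to *count* ionization events in the window and to back the
4-log-unit sanity cut, not to predict pKa. Consequently, absolute record
counts obtained on the public corpora with the open defaults differ from
counts obtained with the original proprietary adapters; the pipeline
semantics and every numeric threshold are identical, and correctness is
demonstrated on constructed fixtures whose fate at every stage is known
in advance (below).

## Features

* **Descriptors** — a frozen, ordered list of 196 RDKit whole-molecule
  descriptors. The four partial-charge descriptors (Max/Min/MaxAbs/MinAbs)
  are excluded because they evaluate to NaN for many molecules; the eight
  BCUT2D descriptors plus AvgIpc and SPS, added to RDKit after this list
  was fixed, are also excluded so the column order is stable across
  toolkit versions. Any residual non-finite value raises per molecule.
* **Fingerprints** — 4096-bit Morgan *feature* fingerprints with radius 3
  (FCFP6-like pharmacophoric invariants).
* Six feature configurations: descriptors, fingerprints, both combined,
  each raw and z-transformed. Scaling statistics are learned from training
  rows only (held-out rows never influence them) and fit once on the full
  training set, not per CV fold — this matches a single "(scaled)"
  configuration label; constant columns are centred but not divided.

## Learning

`CVRegressor(X, y, config).fit()` returns a `CVResults` object carrying
k trained fold models, the fold assignment, one out-of-fold prediction per
row, per-fold MAE/RMSE/r² and a `summary()`. Folds are a seeded
Fisher–Yates shuffle driven by an internal splitmix64 stream (seed 24 by
default), so fold membership is bit-reproducible across ML-library
versions. Prediction on new data is the arithmetic mean of the k fold
models — exactly the trained artifacts are reused for external
validation; a refit-on-all-rows variant is deliberately not the default.

Seven regressor families are configured: random forest (1000 trees), SVR
(default kernel parameters; and gamma='auto'), three multilayer
perceptrons ((500,500); (500,500) with early stopping; (250,250,250) with
early stopping — early stopping holds out 10 % of training rows and stops
after 10 epochs without a 0.001 improvement), and XGBoost at library
defaults. With the six feature configurations this yields the 42-cell
benchmark grid (`run_grid`). A cell whose training fails — e.g. a network
diverging on unscaled, wide-range descriptors — is recorded as
unavailable, never a crash; non-finite predictions are treated as failure.

Metrics: MAE, RMSE, and the empirical coefficient of determination
r² = 1 − SS_res/SS_tot (negative for poor models). Fold summaries report
mean and population SD across folds. Cross-source concordance instead
reports squared Pearson correlation, which is symmetric in the two
sources; both conventions are exposed. The concordance report inner-joins
two curated sets on canonical SMILES and flags pairs deviating by strictly
more than 2 log units.

## Synthetic data

Two generators make every stage testable without any download.

* **Curation fixture.** Real, hand-curated structures (phenols, pyridines,
  anilines, naphthols, …) chosen to be fixed points of the default
  tautomer and protonation rules are decorated by construction: appended
  counter-ions, nitro/B/Se/Si structures, long-alkane Lipinski violators,
  out-of-window pKa values, molecules flagged multiprotic in a lookup
  stub predictor, measurements displaced beyond the 4-log-unit cut, and
  replicate groups with Gaussian noise (SD 0.05) plus an injected
  2-SD-rule outlier. The accompanying manifest states each record's
  expected fate at each stage and the expected merged pKa; it is computed
  entirely at construction time, never by running the pipeline, so it is
  an independent oracle. Byte-identical output under a fixed seed.
* **Regression fixture.** A grammar over ring cores and substituents
  yields unique, valid molecules; the synthetic pKa is
  `clip(7 + w·z(d) + ε, 2, 12)` where `d` is a sparse subset of simple
  descriptors (MolWt, MolLogP, TPSA, rotatable bonds, donors, ring count)
  standardized over the generated set, weights are scaled to a noise-free
  signal SD of 2 log units (the spread of a realistic pKa collection),
  and ε is Gaussian with SD 0.3 log units — the scale of inter-source
  scatter seen when replicate measurements of the same compound are
  compared. The generator record stores the true weights for recovery
  tests.

What the fixtures do *not* emulate: the descriptor distribution, scaffold
population and measurement-error structure of the real public corpora.
Passing the fixture suite therefore demonstrates that every rule,
threshold and bookkeeping step behaves exactly as specified, and that the
learning machinery recovers known signal — not that the open-default
pipeline reproduces the absolute counts or benchmark errors obtained on
the deposited datasets with the proprietary adapters.

## Problem sizes and numerical choices

The test suite and the acceptance script run the parameter-recovery
benchmark at n = 1000 molecules with the full 1000-tree forest, and the
remaining checks on fixtures of 40–400 molecules with smaller forests —
sizes chosen so the whole suite completes in minutes on a single core
while keeping the recovery targets (out-of-fold r² > 0.8 at noise SD 0.3,
> 0.95 noise-free) statistically comfortable. Ties, degenerate inputs and
edge cases are pinned down explicitly: inclusive pKa-window bounds, strict
(>) outlier and discordance comparisons, population-SD convention in the
duplicate merge, constant columns under scaling, zero-variance targets
(r² reported as NaN with a warning), and fold sizes differing by at most
one.

## Reproducing the published benchmark numbers

The deposited public datasets (`chembl25.sdf`, `datawarrior.sdf`,
`combined_training_datasets_unique.sdf`, and the Novartis and literature
external test sets, available from the public Zenodo archive of the
original benchmark) are multi-megabyte files not shipped with this
package. The dedicated acceptance test loads them from
`data/zenodo/` when present and verifies the published quantities (5994
curated entries with the original adapters, the 187-pair two-source
concordance at MAE 0.275 with three >2-unit discordances, the Novartis
summary of 280 molecules / 228 scaffolds / MW mean 348.68, the CV cell
MAE 0.682 / RMSE 1.032 and the external MAEs 1.147 / 0.532). Where the
files are absent that test fails with a message saying how to supply
them; all other tests are self-contained.

## Known limitations

* The model is only valid for monoprotic structures in the 2–12 window;
  predictions for multiprotic molecules are unreliable (the predict CLI
  prints this warning).
* The open rule-based predictor and protonation rules cover the common
  ionizable groups, not exotic chemistries; records they mishandle are
  dropped with a logged reason rather than silently kept.
* No per-fold scaling option is enabled by default (scaling is fit on the
  full training set once); the `z_transform` primitive supports any mask,
  so fold-internal scaling can be composed if leakage-free protocol
  variants are needed.
* No significance testing between grid cells is performed.
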