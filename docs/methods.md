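# Methods

## The study design

The package compares two molecular representations for regression of logS
(log10 molar aqueous solubility): a pruned table of 2D physicochemical
descriptors, and 2048-bit folded Morgan circular fingerprints of radius 2
(ECFP4). Both feed the same two model families — a random forest and
ordinary least squares on standardized features — trained on one shared
random 80/20 split so that representation, not modelling choices, explains
metric differences. RMSE and MAE (log units) are the primary accuracy
measures; R² is reported but treated as secondary because it rewards model
complexity rather than predictive error.

## Curation model

Merged literature solubility tables contain three kinds of redundancy:
exact repeats, near-identical re-measurements, and genuinely conflicting
values for one molecule. Records are grouped on full canonical SMILES
(stereochemistry retained — the least destructive grouping, recorded in the
config). Within a group, if the logS spread is within the conflict
tolerance (default 0.01 log units) the molecule is kept once at the mean;
otherwise it is dropped entirely. The tolerance exists because two sources
can report the identical measurement; treating numerically identical
repeats as conflicts would make merged sources unable to share a molecule.
Salts/mixtures (SMILES containing `.`) and unparseable strings are routed
to the provenance report, never raised. The provenance identity
`inputs = kept + collapsed + conflict-dropped + parse-failures` is asserted
on every curation pass and fuzz-tested over 1000 randomized fixtures.
A carbon count outside 1–12 triggers a validation warning, not a filter:
the low-molecular-weight window is a property of the intended data, not a
rule about all data.

## Descriptor engine and pruning cascade

The descriptor engine is RDKit's full 2D descriptor list (~210 columns);
3D descriptors are out of scope by design (conformer-dependent values are
slow and poorly repeatable). The cascade:

1. **drop_non_numeric** — only columns whose every value is a finite real
   survive. Columns with any failed (NaN/inf) computation are dropped, not
   imputed: the simplest reproducible rule, and each drop is logged.
2. **low_variance_filter** — sample variance < 0.1 on raw values. The
   threshold applies to raw (unscaled) descriptor values; descriptors are
   left unscaled for the RF and standardized internally for MLR/LASSO-style
   fits, with coefficients reported on the standardized scale.
3. **pairwise_correlation_prune** — greedy scan in the engine's canonical
   column order; a column is removed if |Pearson r| > 0.95 (configurable)
   against any already-kept earlier column. Keeping the earlier column is
   the deterministic tie-break. The output provably contains no offending
   pair; tests verify both that property and the justification of every
   removal by exhaustive O(p²) checking.
4. **exclude_named** — removal of known leakage columns (e.g. another
   model's solubility estimate such as FilterItLogS, when an engine provides
   one); absent names are logged rather than errors.

Each stage appends `(stage, columns before, columns after, removed)` to a
chained stage log, so the final width is auditable back to the raw engine
width. Cascade endpoint counts are engine-specific; with the RDKit engine
the synthetic study lands near 210 → ~99 → ~62 columns.

## Fingerprints and the bit atlas

Folded fingerprints are many-to-one, so interpretation requires inverting
the hash empirically: scanning a dataset, the atlas records for every
observed bit the (molecule, center atom, radius ≤ 2) environments that set
it, with each environment's fragment SMILES. The defining property — the
recorded environment re-hashes to the recorded bit — is asserted by
re-fingerprinting in the tests, as is invariance of the whole fingerprint
under random atom renumbering. A bit's *representative fragment* is its
most frequently observed fragment SMILES.

LASSO bit selection fits L1-penalized regression on the raw 0/1 bits (they
share a scale, so standardization is unnecessary), with intercept, solver
tolerance 1e-6 and a bounded iteration count, over the penalty grid
1e-5, 1e-4, 1e-3, 1e-2, 0.1, 1, 10. The working selection is taken at
alpha = 0.001; the full grid's selection sizes are always reported. The
selected subset also caps the width of the fingerprint MLR: an
unregularized OLS needs p < n, so the full-width 2048-bit MLR is fitted
only when the training partition exceeds 2048 rows, and `train_mlr`
signals rank deficiency otherwise.

## Outlier diagnostics

Local Outlier Factor (n_neighbors = 20, Euclidean) runs on standardized
descriptors and on raw bits, on the training partition only; rows with LOF
score > 1.5 are flagged. All three parameters are configurable — there is
no canonical setting, and conclusions should be read as diagnostics, not
inference. Flagged vs unflagged groups are contrasted per descriptor with
Welch two-sided t-tests; p-values are reported raw (no multiplicity
correction) because the table is a screening report. The rare-bit ratio of
a fingerprint is the fraction of its set bits whose whole-dataset
occurrence count is below 100; an empty fingerprint is defined to have
ratio 0 with a warning. The with/without-outlier comparison refits the
same model factory on inliers only and evaluates on the untouched test
partition (verified by hashing). The default pipeline keeps outliers;
removal is opt-in.

## Exact tree-SHAP

No external SHAP engine is used: `aqsol.treeshap` implements exact
path-dependent tree-SHAP for scikit-learn regression trees and forests.
For a feature subset S the value function follows the sample's split where
the node feature is in S and averages children by training cover
elsewhere; attributions are the exact Shapley values of that game. The
implementation evaluates the standard polynomial-weight (EXTEND/UNWIND)
recursion leaf-by-leaf over duplicate-merged paths — algebraically
identical to the recursive formulation, but independent per leaf, which
makes it trivially JIT-compiled (numba) and easy to test. Correctness is
established two ways: equality with a brute-force subset-enumeration
Shapley oracle on small trees (1e-10), and local accuracy
(base + Σφ = prediction) on deep forests. One subtlety: scikit-learn casts
inputs to float32 before traversal, so the attribution code applies the
same cast; without it, near-threshold rows can take a different branch
than `model.predict`.

Feature direction is summarized as the sign of the Pearson correlation
between feature value and its SHAP value (0 when either is constant). The
explained sample is the training partition, subsampled with a seeded draw
above a configurable cap.

## Fragment thermodynamics

Top-ranked bits are mapped to representative fragments and scored with the
Perlovich hydration-energy relation
ΔG²⁹⁸ = −0.5 − 1.37·α + 3.84·ΣCa − 2.97·ΣCd, evaluated exactly at the
central coefficients; the published uncertainties (±1.6, ±0.06, ±0.25,
±0.26) are carried as metadata and not propagated. Inputs are computed on
the hydrogen-capped fragment: α as an atomic-polarizability sum (standard
atomic values, including capping hydrogens), ΣCa as the count of N/O
acceptor sites, ΣCd as the count of N/O sites bearing hydrogen. The
site-count definition is deliberately simpler than druglikeness H-bond
filters, which exclude water and would score a bare hydroxyl fragment as
zero. Aromatic environment fragments with open valences are sanitized with
kekulization relaxed so sp² character survives capping.

Interpretation of the ΔG–SHAP relationship is reported as a computed
Spearman correlation, never a pass/fail gate. Note the built-in tension:
the relation's polarizability term makes large alkyl fragments strongly
negative in ΔG while their solubility effect is negative, so on
alkane-rich data the correlation can come out positive; it is a reported
statistic precisely because its sign is data-composition-dependent.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical shape of a curated low-MW organic
solubility collection: 1–12 carbons (mean MW ≈ 180), alkyl chains and
benzene rings decorated with OH/COOH/NH₂/F/Cl/Br, an additive
group-contribution logS (intercept 0.5; per-count coefficients
carbon −0.55, hydroxyl +0.9, carboxyl +1.0, amine +0.7, halogen −0.4,
aromatic ring −0.6 — signs follow the expected physical directions, polar
H-bonding groups up, hydrophobic bulk down), Gaussian noise of 0.5 log
units (typical inter-laboratory solubility scatter; 0.3 in the recovery
experiments), and injected duplicates/conflicts for the curation stage.
Grammar-based construction guarantees every emitted SMILES is valid —
invalid strings would test the parser, not the pipeline — and outputs are
de-duplicated canonical SMILES.

What it does not emulate: real solubility physics (no crystal-packing,
melting-point or conformational effects), correlated measurement error
between sources, tautomers/stereoisomer ambiguity, or the heavy-tailed
structural diversity of real libraries. Passing tests therefore demonstrate
that the pipeline's machinery is correct and recovers a known planted
signal under realistic noise — not that any model here predicts real logS
at literature accuracy.

## Problem sizes and numerical choices

- Analysis scripts: n = 1200 molecules, 200-tree forests, SHAP over 400
  explained rows — sizes chosen so each script reads as an interactive
  narrative run.
- Acceptance script: n = 1500, 300-tree forests, SHAP over 300 seeded
  rows; every stage seed derives from the single `--seed`.
- Recovery experiment: n = 2000, noise 0.3, 100 noise realizations over one
  fixed molecule set (regenerating molecules each time would add cost but
  no statistical content — the randomness under test is the measurement
  noise); each planted coefficient must fall within 3 OLS standard errors
  in ≥ 95 realizations.
- RF defaults: 500 trees, unlimited depth, library-default feature
  subsampling, seed 42; all in `RunConfig` and logged. Splits use
  `round(0.8·n)` training rows from a seeded permutation.
- Degenerate inputs: constant targets make R² undefined (NaN + warning);
  constant features get direction 0 in importance tables; empty
  fingerprints get rare-ratio 0 with a warning; zero-variance columns pass
  through standardization unscaled.

## Known limitations

- Descriptor-cascade endpoint counts depend on the descriptor engine and
  its version; only the cascade's structure and invariants are portable.
- Path-dependent SHAP attributes with respect to the forest's own training
  distribution; it is not the interventional variant.
- The LOF score threshold (1.5) and neighborhood size are conventions, not
  fitted quantities; flagged sets should be inspected, not trusted blindly.
- The Gibbs relation is a linear free-energy model imported from the
  hydration literature; its absolute scale is not calibrated to this
  study's data and is used only to rank fragments.
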