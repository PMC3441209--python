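# Methods

## The prediction problem

Alpha-helical channel and transporter proteins enclose a solvent-filled
cavity; the residues whose side chains face it form chemically distinct
helix faces — enriched in D, E and H, recurring every 3–4 positions (one
helical turn) — because they interact with water and permeating ions
rather than lipid. `tmpore` learns that signature from evolutionary
profiles and predicts, from sequence alone: (i) which transmembrane
residues line the pore, (ii) which helices line the pore, and (iii) how
many subunits form the pore.

## Residue classifier

**Features.** For each residue inside an annotated transmembrane helix,
the 20-column PSSM rows of a `window_size = 15` window centred on the
residue are concatenated (300 features); window positions outside the
sequence contribute all-zero rows (a neutral, information-free context —
mirroring is not used because termini genuinely lack context). Features
are standardized per dimension, z = (x − μ)/σ. μ and σ are computed over
the *training* residues only and frozen into the model, so jackknife
folds cannot leak test statistics; the population (divide-by-n) standard
deviation convention is used and recorded in the model bundle.
Zero-variance features get σ = 1 and a flag, mapping them to exactly 0.

**Classifier.** A C-support-vector classifier with RBF kernel
exp(−γ‖u−v‖²). Class imbalance is removed by weighting positive-class
errors with a cost factor j, default n_negative/n_positive, which is
exactly the SVM-Light `-j` semantics (it multiplies C for positive
examples). Defaults γ = 0.1, C = 1 are the values that performed best on
the curated 52-chain crystal-structure benchmark; for other data the
grid search (γ ∈ {0.001, 0.01, 0.1, 1} × C ∈ {0.1, 1, 10, 100}) should
be re-run — kernel width must match the data's feature-distance scale,
and for the synthetic generator's i.i.d. background the useful regime is
γ ≈ 1/n_features ≈ 0.003 rather than 0.1. Grid selection maximises
pooled per-residue MCC under 5-fold cross-validation grouped by chain
(residues of one chain never straddle a split); ties break to the
smaller γ, then the smaller C. A residue is called pore-lining when its
margin is ≥ 0 (ties positive).

**Labels.** Geometric pore-detection labels are post-processed two ways,
deliberately in this order:

* helix-level classes use the *original* labels: a helix is pore-lining
  iff it contains ≥ 6 labelled residues (`min_pore_residues`, about a
  quarter of a typical transmembrane helix);
* the training positive class is then *expanded* by i±1 within the same
  helix, compensating for side-chain dynamics a single crystal structure
  cannot capture and near-equalising the classes. The wider one-turn
  variant (i±4) is available (`offsets=(1, 4)`) but off by default; it
  degrades performance.

Per-residue predictions are scored against the expanded label set by
default (the set the classifier is trained to reproduce); a flag rescores
against the original labels.

**Jackknife protocol.** Each chain is predicted by a model trained with
the chain itself and all chains of > 25% sequence identity to it removed.
Identity is computed from a Needleman–Wunsch global alignment (match 1,
mismatch 0, gap open −10, extend −1) as identities / alignment length
including gap columns — the threshold is standard, the scoring is this
package's pinned convention and is configurable. Folds whose training
set loses a class are skipped with a warning rather than silently scored.

## Helix scoring and calibration

A helix's score is the arithmetic mean of the raw margins over its
residues (annotated or predicted spans only; re-entrant helices are out
of scope because including them degrades accuracy). The pore-lining call
uses an elevated threshold of 0.3 rather than 0: between 0 and 0.3,
residue-level false positives contribute disproportionately to false
helix calls, so the raised threshold trades recall for a much lower
false-positive rate. For a likelihood in [0, 1], mean scores are
converted to Z-scores using the mean and population SD of the prediction
batch and passed through the standard logistic, p = 1/(1 + e^−z). The
"standard logistic of the z-score" reading is the default; a
two-parameter logistic fitted against known labels is provided
(`fit_logistic_calibration`) but non-default. Batches too small (or too
degenerate) to estimate their own statistics fall back to the training
batch's stored helix-score statistics; with no fallback available the
degenerate batch is an error rather than a silent NaN.

## Stoichiometry regression

Four features per chain — sequence length, predicted pore-lining residue
count, transmembrane helix count ("topology", the only scalar encoding
consistent with the other count features), predicted pore-lining helix
count — predict the observed subunit count with an ε-insensitive
RBF-kernel SVR (ε = 0.1). Features are intentionally left unstandardized.
Because the dominant feature scale is the sequence length (hundreds),
squared feature distances are O(10⁴–10⁵) and the useful kernel widths
are small: the grid is C ∈ {1, 10, 100} × γ ∈ {10⁻⁶ … 10⁻¹}, selected by
the leave-one-out total absolute error of the *rounded* predictions,
ties to smaller values. Rounding is half away from zero with a floor of
1 subunit and is the only discretization anywhere in the regression
path. A chain predicted as 1 subunit is classified monomeric, otherwise
multimeric.

## Evaluation rules

* Confusion metrics use the standard definitions; MCC is defined as 0
  whenever a denominator factor vanishes (degenerate single-class sets).
* Predicted helices are matched one-to-one to known helices greedily by
  descending overlap (shared residue positions, 1-based inclusive),
  requiring ≥ 10 shared residues; ties break by earlier known start,
  then earlier predicted start. Unpaired predicted helices count as
  false positives only when called pore-lining — never as true
  negatives — and unpaired known helices count as false negatives only
  when labelled pore-lining. Topology is correct for a chain iff
  predicted and known helix counts agree and every known helix is
  matched.
* Stoichiometry aggregates (exact matches, MAE, Pearson r on the integer
  columns as printed, monomer/multimer discrimination, false-positive
  monomers, multimeric exact matches) are computed by
  `stoichiometry_summary`; the packaged 52-chain benchmark table
  (`data/table2.tsv`) is the reference input. Its per-chain over/under
  column is reported as-is without asserting a chain-level total, since
  over- and under-prediction tallies can be counted per chain or per
  helix.

## Synthetic generator

`SyntheticConfig` defaults define the generator's study conditions:
12 chains, 3–6 helices of 17–25 residues per chain, half pore-lining,
pore faces at period 3–4 with phase chosen so every pore-lining helix
carries ≥ 6 labelled positions, background PSSM scores i.i.d. integer-
rounded N(0, noise_sd = 1), D/E/H columns at pore-facing positions
boosted by signal_strength = 5 (five noise SDs — cleanly learnable),
sequence letters biased towards D/E/H at those positions whenever signal
is present, and observed stoichiometry = max(1, n_pore_helices) (slope
1, intercept 0, no noise — a recoverable planted relation for the
regression stage). Everything derives from one seed; identical configs
are byte-identical.

What the generator does *not* emulate: correlated PSSM columns from real
substitution processes, sequence homology between chains (generated
chains are mutually < 25% identical, so jackknife exclusion lists are
empty unless duplicates are planted), helix tilting/shielding that makes
real pore faces intermittent, re-entrant helices, and labelling noise
from pore detection on a single conformation. Passing the synthetic
checks therefore demonstrates that the machinery — features,
standardization, cost weighting, homology exclusion, aggregation,
calibration, regression, rounding — is implemented correctly and
recovers a planted signal of realistic shape; it does not predict the
accuracy achievable on real proteomes, which is bounded by profile
quality and conformational variability.

## Problem sizes and numerical conventions

Self-contained checks run at 12 chains (~1,100 transmembrane residues)
for planted-signal recovery, 20 chains (> 2,000 residues) for the
null-signal chance-level check, and 40 chains for stoichiometry
recovery — sizes at which results are stable across seeds while a full
run completes in well under a minute per stage on one core. The SVC
tolerance is 1e-4; identical inputs, configuration and seed reproduce
scores to 1e-9. All residue indices are 1-based inclusive at every
interface; PSSM columns are normalised to the PSI-BLAST header order
(A R N D C Q E G H I L K M F P S T W Y V) on read; X residues carry
all-zero profile rows when absent from a PSSM file.

## Known limitations

* The real 52-chain training corpus (structures, UniRef90 profiles,
  geometric pore labels) is not redistributable here; absolute benchmark
  metrics are represented by the packaged per-target results table, and
  model quality on real data must be re-established by the user's own
  training run.
* Helix boundaries are consumed as annotations; the package does not
  predict topology itself.
* The polar alphabet of the naive baselines (D E H K R N Q S T C Y) is a
  documented convention, configurable and recorded in every report.
* Single-helix prediction batches rely on stored training statistics for
  calibration; their posteriors are comparable only within one model.
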