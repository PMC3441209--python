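# tmpore

Sequence-based prediction of pore-lining residues and helices in
alpha-helical transmembrane proteins, and of the pore's stoichiometry
(the number of subunits whose transmembrane regions line the channel).

Channel and transporter proteins carry a solvent-filled cavity through
the lipid bilayer. The residues whose side chains face that cavity — the
*pore-lining* residues — can be identified geometrically when a crystal
structure is available, but most channel sequences have no structure.
`tmpore` predicts them from sequence alone, for structural biologists and
bioinformaticians characterising channels, and provides the building
blocks to retrain and re-evaluate the whole pipeline.

## Method

Each transmembrane residue *i* is represented by the rows of a PSI-BLAST
position-specific scoring matrix (PSSM) in a 15-residue window centred on
*i*, flattened to a 300-dimensional vector and standardized per feature,

  z = (x − μ) / σ,

with μ, σ estimated on the training residues and frozen. An RBF-kernel
support-vector classifier (kernel exp(−γ‖u−v‖²), soft-margin trade-off
C, positive-class errors weighted by a cost factor j = n_neg/n_pos to
equalise the classes) scores each residue; a residue is called
pore-lining when its margin is ≥ 0. A helix is called pore-lining when
the *mean* margin over its residues is ≥ 0.3 — the elevated threshold
suppresses helix-level false positives caused by residue-level errors.
Mean scores are converted to Z-scores within the prediction batch and
mapped through the standard logistic to a posterior in [0, 1].

Training labels come from geometric pore detection on crystal
structures; residues adjacent (i±1, same helix) to a labelled residue
join the positive class, and a helix counts as pore-lining when it holds
≥ 6 original labels. Evaluation uses a homology-aware jackknife: each
target chain is scored by a model trained with the target *and every
chain over 25% global sequence identity to it* excluded. Hyper-parameters
are grid-searched by cross-validated Matthews correlation (MCC).

Pore stoichiometry is regressed from four unstandardized features —
sequence length, number of predicted pore-lining residues, number of
transmembrane helices, number of predicted pore-lining helices — with an
RBF-kernel support-vector regressor whose output is rounded to the
nearest integer (min 1); hyper-parameters minimise the cross-validated
total absolute error of the rounded predictions.

## Worked example

The synthetic generator plants the signal the method exploits in real
channels: pore-lining helices carry a face of residues every 3–4
positions (one helical turn) with boosted D/E/H conservation. Train and
cross-validate on 12 generated chains:

```python
from tmpore import SyntheticConfig, generate, PoreLiningModel

records, profiles, _ = generate(SyntheticConfig(n_chains=12, seed=1))
model = PoreLiningModel(records, profiles, gamma=0.001, trade_off=10.0, seed=1)
print(model.jackknife().summary())
```

```
Jackknife cross-validation (pore-lining residues)
==================================================
chains scored        12 (skipped 0)
identity threshold   25%
scored against       expanded labels
confusion            tp=519 fp=5 tn=591 fn=7
precision/recall     0.990 / 0.987
TPR/FPR              0.987 / 0.008
MCC                  0.979
accuracy             98.9%
```

Every chain is scored by a model that never saw it (nor any close
homolog); with the planted signal at five noise standard deviations the
classifier recovers almost every pore-lining residue (MCC 0.98; real
profiles are far harder). Helix-level calls with calibrated posteriors:

```python
results = model.fit()
for c in results.predict_helices(records[0], profiles[records[0].chain_id]):
    print(f"{c.chain_id}  {c.span.start:>3}-{c.span.end:<3}  mean={c.mean_score:+.2f}  "
          f"z={c.zscore:+.2f}  posterior={c.posterior:.3f}  "
          f"call={'pore' if c.call else 'nonpore'}")
```

```
SYN000_A   11-33   mean=-1.22  z=-1.01  posterior=0.267  call=nonpore
SYN000_A   44-60   mean=+1.43  z=+1.11  posterior=0.752  call=pore
SYN000_A   65-88   mean=-1.19  z=-0.99  posterior=0.272  call=nonpore
SYN000_A   99-117  mean=+1.15  z=+0.89  posterior=0.708  call=pore
```

The two planted pore-lining helices get mean margins above the 0.3
threshold and posteriors above 0.7. The same workflows are available
from the shell — `tmpore synth`, `train`, `cv`, `predict-residues`,
`predict-helices`, `predict-stoichiometry`, `baseline`, `evaluate` — and
`tmpore evaluate` aggregates the packaged 52-chain benchmark table:

```
Stoichiometry over 52 chains: 32 exact (62%), MAE 0.75 subunits, Pearson r 0.72,
mono/multi accuracy 90%, 3 false-positive monomers, 9/27 multimeric exact
Topology correct for 39/52 chains (75%)
```

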