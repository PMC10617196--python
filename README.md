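# biodrop

A biologically guided dual-modality neural classifier for genotype–phenotype
prediction, with cross-modal latent imputation and integrated-gradients
feature prioritization.

## The problem

Predicting a phenotype (disease status, a clinical score, a cellular class)
from molecular data usually has to reconcile three difficulties at once:
the signal flows through intermediate regulatory layers (variants act on
phenotypes largely by perturbing gene expression), cohorts rarely have every
modality measured for every sample, and a black-box classifier is of little
use to a geneticist who needs to know *which* variants, genes, and
regulatory links carried the prediction.

`biodrop` addresses all three with a single model:

1. **Biological DropConnect encoders.** Each modality (e.g., SNP dosages
   `X_a ∈ R^{K×l}`, transcription-factor expression `X_b ∈ R^{K×n}`) feeds a
   dense layer whose weight matrix is elementwise-masked by a prior network —
   eQTL SNP→gene edges for the genotype side, GRN TF→target edges for the
   expression side:

   ```
   C_a = σ(X_a (W₁ ⊙ M_eQTL) + b₁)        C_b = σ(X_b (W₂ ⊙ M_GRN) + b₂)
   ```

   Only biologically supported connections exist; masked-out weights carry
   no signal and receive exactly zero gradient. The shared latent layer is
   the set of target genes common to both prior networks.

2. **Auxiliary cross-modal imputation.** A linear transfer
   `Ĉ_b = α C_a + β` is trained jointly via an auxiliary mean-squared-error
   loss, so the model can *impute* the missing modality's latent space and
   still predict when only one modality is available (single-modality mode).

3. **A feed-forward softmax classifier** on the concatenation `[C_a | C_b]`,
   trained with Adam (β₁ = 0.9, β₂ = 0.999) on the joint objective

   ```
   L = L_CE(y, ŷ) + λ · MSE(C_b, α C_a + β)
   ```

   with early stopping on a validation split and best-epoch restoration.

4. **Integrated gradients** attribute predictions to input features, latent
   genes, and — via gate augmentation — to individual prior-network edges,
   yielding ranked SNPs/TFs/genes and prioritized regulatory subnetworks.

Performance is reported as balanced accuracy (BACC, mean of per-class
recalls) and ROC AUC (macro one-vs-rest beyond two classes), both robust to
class imbalance; SMOTE oversampling is available for skewed training sets.

## Worked example

The built-in generator plants a known causal structure (masks, causal SNPs,
effect sizes), so recovery can be verified end to end:

```python
import numpy as np
from biodrop import (SimConfig, simulate_cohort, TrainConfig, train_model,
                     balanced_accuracy, auc_score, fit_scaler, apply_scaler,
                     split_train_test, node_importance)

cfg = SimConfig(n_samples=600, n_snps=80, n_tfs=20, n_genes=25,
                density_eqtl=0.08, density_grn=0.25,
                n_causal_genes=2, n_causal_snps=8, seed=42)
cohort = simulate_cohort(cfg)
y = cohort["labels"]
ids = cohort["genotypes"].sample_ids
train_ids, _ = split_train_test(ids, y, ratio=0.8, seed=42)
tr = np.isin(ids, train_ids)

scaler_a = fit_scaler(cohort["genotypes"].values[tr])
scaler_b = fit_scaler(cohort["expression"].values[tr])
Xa = apply_scaler(cohort["genotypes"].values, scaler_a)
Xb = apply_scaler(cohort["expression"].values, scaler_b)

config = TrainConfig(seed=42, lambda_aux=10.0, dropout_rate=0.3)
model, log = train_model(Xa[tr], Xb[tr], y[tr],
                         (cohort["mask_a"], cohort["mask_b"]), config)

te = ~tr
X_test = np.concatenate([Xa[te], Xb[te]], axis=1)
print(f"held-out dual BACC:   {balanced_accuracy(y[te], model.predict(X_test)):.3f}")
print(f"held-out single BACC: {balanced_accuracy(y[te], model.predict(Xa[te], mode='single')):.3f}")

nodes = node_importance(model, Xa[te], Xb[te], "C1", n_steps=50)
print(nodes[nodes.layer == "input_a"].head(5)[["feature_id", "score", "rank"]])
```

Output:

```
held-out dual BACC:   0.800
held-out single BACC: 0.700

feature_id    score  rank
      rs00 0.647444     1
      rs08 0.522346     2
      rs70 0.428751     3
      rs43 0.343372     4
      rs37 0.342531     5
```

The planted causal SNPs in this cohort are rs00, rs08, rs16, rs32, rs37,
rs43, rs53, rs70 — all five top-ranked SNPs are causal. The dual-modality
model uses both measured modalities; the single-modality number is obtained
from genotypes alone, with the expression latent space imputed through the
fitted transfer function.

`BioDropClassifier` follows the scikit-learn estimator API (`fit`,
`predict`, `predict_proba`, `get_params`/`set_params`), taking
`X = [X_a | X_b]` as one concatenated matrix, so it composes with sklearn
pipelines and model selection.

## Command line

```bash
biodrop simulate  --seed 7 --outdir cohort/
biodrop preprocess --modality-a cohort/genotypes.csv --modality-b cohort/expression.csv \
    --labels cohort/labels.csv --edges-a cohort/eqtl_edges.csv --edges-b cohort/grn_edges.csv \
    --outdir prep/ --seed 7
biodrop train --modality-a prep/modality_a.csv --modality-b prep/modality_b.csv \
    --labels prep/labels.csv --edges-a prep/edges_a.csv --edges-b prep/edges_b.csv \
    --outdir run/ --seed 7 --cv-folds 5
biodrop predict --model run/model.npz --modality-a prep/modality_a.csv --mode single --outdir pred/
biodrop explain --model run/model.npz --modality-a prep/modality_a.csv \
    --modality-b prep/modality_b.csv --outdir attr/
```

Every run writes a manifest (input digests, config, seed); identical seeds
give byte-identical outputs.

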