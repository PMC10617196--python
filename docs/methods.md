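# Methods

## Model

The classifier maps two sample-aligned modality matrices to class
probabilities through four stages.

**Masked encoders.** Each modality has one dense encoder whose weight
matrix is elementwise-multiplied by a fixed binary mask derived from a
prior network: `C_a = σ(X_a (W₁ ⊙ M_a) + b₁)` and likewise for modality B.
In the genotype/expression application, `M_a` holds eQTL SNP→gene edges and
`M_b` GRN TF→target edges; the latent layer is the ordered set of target
genes shared by both networks, so every latent unit is an identifiable gene.
Masks are fixed before training; the mask enters the forward product and
the backward chain rule identically, so weights at mask-zero positions
contribute nothing and receive exactly zero gradient (they remain at their
initialization and are excluded from any interpretation). Multi-level
chains (S₁→S₂→T₁) are represented as two separate edges with the
intermediate gene appearing on both the input and latent sides; self-edges
are never encoded. When no prior network exists, an all-ones mask of
configurable latent width is used instead (full connectivity).

The encoder nonlinearity σ defaults to ReLU, consistent with the classifier
stack; sigmoid, tanh, and identity are available through configuration.
Nothing downstream assumes a particular σ — the backpropagation is shared —
and tanh is convenient wherever a twice-differentiable surface is wanted
(e.g., finite-difference verification).

**Linear transfer.** The auxiliary task learns `Ĉ_b = α C_a + β` with
scalar α, β (a per-latent-dimension vector variant is available behind
`vector_transfer`, off by default). The transfer is trained jointly from
the first epoch through the auxiliary loss; with λ = 0 its parameters
provably receive zero gradient and stay at their initialization (α = 1,
β = 0), because the primary task consumes the true `C_b`, not the imputed
one. At prediction time with modality B missing, `Ĉ_b` replaces `C_b`.

**Classifier.** `[C_a | C_b]` (modality A block first — fixed so edge and
node attributions are reproducible) feeds a fully connected stack with ReLU
hidden units, inverted dropout active only during training and only inside
this stack (the encoders are already sparsified by biology), and a softmax
output. Class labels are ordered lexicographically; probability columns
follow that order everywhere, including checkpoints.

**Objective and optimization.** `L = L_CE + λ·L_MSE`, where `L_CE` is the
mean cross-entropy (log arguments clamped at 1e-12) and `L_MSE` averages the
squared imputation error over every sample × latent entry. The entrywise
averaging convention keeps λ's meaning independent of the latent width;
the alternative (per-sample vector norms) differs by a factor of p and was
rejected for scale stability. Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with
minibatches (default 32; full batch available) runs to at most 100 epochs
with early stopping: a stratified validation fraction (default 0.15) is
monitored on the *total* loss with patience 10, and the best-epoch
parameters are restored. Monitoring the total rather than the primary loss
keeps the stopping rule aligned with the objective actually minimized. All
randomness (initialization, shuffling, dropout, splits) derives from one
integer seed through spawned generators; identical seed and configuration
give bitwise-identical parameters on CPU.

## Training protocol

Data are split 80/20 stratified (train/held-out). On the training portion,
hyperparameters are chosen by stratified five-fold cross-validated grid
search; each fold refits its own scaler (and any feature selection) on the
fold-training portion only. The default search space is deliberately small
(λ ∈ {0.1, 1, 10} with the other defaults fixed) and documented as
replaceable; the grid scorer can evaluate dual-modality CV BACC alone or the
mean of the dual and single-modality CV BACCs (`selection_metric`), the
latter being appropriate when the model is deployed for both prediction
modes. Ties break deterministically: higher mean AUC, lower λ, smaller
latent width, then lexicographic candidate order. λ defaults to 1.0 when
not searched. Metrics: balanced accuracy generalizes to multi-class as the
unweighted mean of per-class recalls; AUC as macro one-vs-rest (AUC is most
interpretable for two classes; the multi-class extension is reported but
weighted less in interpretation).

## Preprocessing

Univariate selection uses Welch's two-sample t-test for binary labels and a
one-way ANOVA F-test for three or more classes, keeping features with
p < α (default α = 0.05, no multiple-testing correction by default; a
Benjamini–Hochberg option exists). Welch was chosen over the pooled-variance
test because no variance assumption is justified across dosage-coded and
continuous features. Selection statistics are always computed on training
samples only. Prior-network intersection restricts the latent layer to
genes targeted by both networks and drops input features without edges into
that shared set; all identifier lists are emitted lexicographically sorted.
Scaling options: standard (population sd, ddof = 0), minmax (constant
features map to 0 with a flag), and log1p (the pseudocount makes zero
counts representable). SMOTE oversampling (k = 5 neighbors by default)
balances every class up to the majority count by sampling
`x_i + u·(x_nn − x_i)`, `u ~ U(0,1)`, among same-class nearest neighbors,
applied to the concatenated per-sample feature vector on the training
partition only so paired modalities stay consistent. LD structure among
SNPs is deliberately ignored.

## Attribution

Integrated gradients are computed with a midpoint Riemann rule (default 50
steps; 200 in verification contexts) against the class's pre-softmax logit
(numerically more stable than the post-softmax probability). The baseline
is the zero vector in scaled space — i.e., the cohort mean after
standardization — and is stated in every report. Per-sample attributions
are aggregated as the mean of absolute values over the evaluation samples;
absolute aggregation was chosen because samples on opposite sides of a
decision boundary carry opposite signs that would otherwise cancel.

Node importance is computed at two depths: raw inputs (SNPs, TFs), and the
concatenated latent layer, where IG is applied to the classifier
sub-network so each latent gene receives a score (its two blocks are
summed). Edge (link) importance uses gate augmentation: every permitted
edge is multiplied by a gate fixed at 1, and IG runs over the gate vector
with baseline 0 (edge absent). Gates turn edge *presence* into an input the
attribution integral applies to; only mask-one edges are scored, and a
single-edge linear chain attributes exactly w·x. Prioritized gene sets are
the distinct latent genes touched by the top ⌈fraction·E⌉ edges (default
10%), with per-gene counts of prioritized incident links; ties break by
score then (source, target) lexicographic order.

## Synthetic cohorts

The generator emulates the input structure the model consumes, with full
ground truth for recovery scoring.

* **Masks:** independent Bernoulli edges (defaults: eQTL density 0.05, GRN
  density 0.2) with every latent gene guaranteed ≥ 1 incoming edge
  (deficient columns are redrawn, up to 1000 attempts). A designated set of
  causal SNPs (default 10) is wired round-robin and *exclusively* into the
  causal genes' eQTL columns, so genotype signal reaches the label only
  through known edges.
* **Genotypes:** per-SNP MAF ~ U(0.05, 0.5); dosages Binomial(2, MAF) under
  Hardy–Weinberg. TF expression is standard Gaussian.
* **Latents:** `G = σ(X_c (W₁⊙M_a)) + σ(X_tf (W₂⊙M_b))` with centered
  genotypes and known random weights, σ = ReLU by default (a tanh
  "mismatched generator" mode exists to test robustness without
  circularity). Generative weights are normalized by each input's variance
  (dosage variance is 2·MAF·(1−MAF)) before applying the side scales
  (SNP 1.0, TF 0.5), making the genotype the dominant modality — the regime
  in which single-modality prediction through the transfer retains most of
  the dual performance, which is the phenomenon of interest.
* **Labels:** class scores are `γ · standardize(G[:, causal] @ V) + ε`,
  ε ~ N(0, noise_sd²) with noise_sd = 0.5; the per-sample mean is removed
  and the contrast standardized so γ is a well-defined effect size
  regardless of the random effect-matrix draw. Labels are the argmax of the
  noisy scores (the noise term is the label randomness): γ = 0 yields
  feature-independent labels, large γ with zero noise yields exact
  separability. Per-class intercepts are fitted iteratively so realized
  class frequencies match the configured balance.
* **Default sizes:** 1000 samples, 200 SNPs, 30 TFs, 50 genes, 2 causal
  genes, 10 causal SNPs, γ = 3 — chosen so a full train/evaluate cycle runs
  in seconds on one CPU while leaving the learning problem non-trivial.

What the generator does **not** emulate: linkage disequilibrium and
population structure, expression covariance beyond the planted mechanism,
batch effects, and covariates. Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted structure, not
performance on real cohorts.

## Study protocols

The prediction benchmark (`planted_signal_study`) runs the complete
pipeline per replicate seed — cohort, stratified 80/20 split, selection
(α = 0.05), prior intersection, standard scaling, five-fold grid search
over λ scored on both prediction modes, final fit, held-out evaluation —
and averages metrics over 8 replicate seeds derived from one master seed;
held-out balanced accuracy on 200 samples has a standard error near 0.035,
so replication is what makes the reported means stable. The permuted-label
null retrains the selected configuration on 10 label permutations of the
first replicate with preprocessing held fixed, calibrating the pipeline
against chance (expected BACC 0.5).

The prioritization benchmark (`causal_recovery_study`, 5 replicate seeds)
trains on the full masked feature set *without* the univariate filter:
attribution must rank the complete candidate set, and a feature discarded
by a filter could never receive a score. Causal-SNP recovery is summarized
as the rank-AUC of planted causal SNPs in the node-importance ranking (any
SNP absent from a model scores 0, consistent with a disconnected feature's
attribution).

## Numerical choices and edge cases

* Cross-entropy clamps probabilities at 1e-12; softmax is max-shifted.
* Finite-difference verification uses tanh encoders (central differences
  are unreliable at ReLU kinks; the analytic backprop is activation-
  agnostic).
* Constant features: dropped before univariate testing; mapped to 0 under
  minmax; centered but unscaled under standard scaling.
* Duplicate edges collapse; edges with endpoints outside the identifier
  universes are dropped with a logged count; an empty post-filter edge set
  is an error distinguishing ID mismatch from empty input.
* Checkpoints are single `.npz` files holding all parameter arrays, both
  masks with identifier orderings, the class-label encoding, and a format
  version; save→load→save is byte-stable.
* Run manifests identify a run by a digest of command, config, seed, and
  input digests; wall-clock timestamps are recorded only on request so
  identical runs produce byte-identical manifests.

## Limitations

Two modalities only; the transfer is linear (a nonlinear transfer is a
natural extension); scalar α, β cannot express per-gene imputation
coefficients unless the vector variant is enabled; training is
single-threaded CPU NumPy, appropriate for the masked-layer sizes the
prior networks induce (hundreds to thousands of effective weights) but not
for dense genome-scale inputs; and the synthetic benchmark, by design,
cannot speak to confounding structure present in real cohorts.
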