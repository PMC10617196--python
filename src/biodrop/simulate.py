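"""Synthetic multimodal cohorts with planted masks, signal, and transfer truth.

The generator emulates the structure the model consumes: dosage-valued
genotypes under Hardy-Weinberg equilibrium, Gaussian TF expression, two
Bernoulli bipartite prior networks, latent gene activity produced through
the masked layers, and class labels assigned by the noisy argmax of class
scores driven by a small causal subset of latent genes.  Ground truth (masks, causal sets, effect vectors,
latents) is exposed so recovery can be scored.

Signal design: a designated set of causal SNPs is wired (round-robin)
exclusively into the causal genes' eQTL columns, so causal genes receive
genotype signal only through those SNPs; the TF-side generative weights are
scaled down relative to the SNP side, making the genotype the dominant
modality (the regime in which single-modality prediction through the
learned transfer retains most of the dual-modality performance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import ModalityMatrix, write_edges, write_labels, write_matrix
from .masks import BipartiteMask
from .nn import relu


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 1000
    n_snps: int = 200
    n_tfs: int = 30
    n_genes: int = 50
    density_eqtl: float = 0.05
    density_grn: float = 0.2
    maf_range: tuple = (0.05, 0.5)
    gamma: float = 3.0              # effect size of the causal latent score
    noise_sd: float = 0.5           # sd of the logit noise
    n_causal_genes: int = 2
    n_causal_snps: int = 10
    class_balance: tuple = (0.5, 0.5)
    transfer_alpha: float = 2.0     # truth for the linear-transfer regime
    transfer_beta: float = 0.5
    snp_weight_scale: float = 1.0
    tf_weight_scale: float = 0.5
    latent_activation: str = "relu"  # 'tanh' = mismatched-generator mode
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.density_eqtl <= 1.0 and 0.0 < self.density_grn <= 1.0):
            raise ValueError("edge densities must be in (0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie in (0, 0.5]")
        if self.n_samples < 4 * len(self.class_balance):
            raise ValueError("need at least 4 samples per class")
        if abs(sum(self.class_balance) - 1.0) > 1e-9:
            raise ValueError("class_balance must sum to 1")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("more causal genes than genes")
        if self.n_causal_snps > self.n_snps:
            raise ValueError("more causal SNPs than SNPs")
        if self.latent_activation not in ("relu", "tanh"):
            raise ValueError("latent_activation must be 'relu' or 'tanh'")
        self.class_balance = tuple(float(b) for b in self.class_balance)
        self.maf_range = (float(lo), float(hi))

    @property
    def n_classes(self) -> int:
        return len(self.class_balance)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Planted ground truth for scoring recovery."""

    mask_a: BipartiteMask
    mask_b: BipartiteMask
    causal_genes: list
    causal_snps: list
    effect_matrix: np.ndarray        # causal-gene x class effect vectors
    latent: np.ndarray               # generative latent gene activity G
    latent_a: np.ndarray             # SNP-side contribution
    latent_b: np.ndarray             # TF-side contribution
    labels: np.ndarray
    maf: np.ndarray
    class_probs: np.ndarray = field(default=None)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,)))


def _ids(prefix: str, n: int) -> list:
    width = len(str(max(n - 1, 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _causal_sets(cfg: SimConfig) -> tuple:
    rng = _rng(cfg, 3)
    genes = np.sort(rng.choice(cfg.n_genes, cfg.n_causal_genes, replace=False))
    snps = np.sort(rng.choice(cfg.n_snps, cfg.n_causal_snps, replace=False))
    return genes, snps


def simulate_masks(cfg: SimConfig) -> tuple:
    """Bernoulli bipartite masks with planted causal wiring.

    Every latent gene is guaranteed at least one incoming edge in at least
    one mask (deficient columns are redrawn, up to 1000 attempts).  Causal
    genes receive eQTL edges exclusively from the designated causal SNPs.
    """
    rng = _rng(cfg, 0)
    l, n, p = cfg.n_snps, cfg.n_tfs, cfg.n_genes
    ma = (rng.random((l, p)) < cfg.density_eqtl).astype(float)
    mb = (rng.random((n, p)) < cfg.density_grn).astype(float)
    causal_genes, causal_snps = _causal_sets(cfg)
    ma[:, causal_genes] = 0.0
    for k, snp in enumerate(causal_snps):
        ma[snp, causal_genes[k % len(causal_genes)]] = 1.0
    deficient = np.where((ma.sum(axis=0) + mb.sum(axis=0)) == 0)[0]
    for j in deficient:
        for attempt in range(1000):
            col_a = (rng.random(l) < cfg.density_eqtl).astype(float)
            col_b = (rng.random(n) < cfg.density_grn).astype(float)
            if col_a.sum() + col_b.sum() > 0:
                ma[:, j], mb[:, j] = col_a, col_b
                break
        else:
            raise RuntimeError(
                f"could not wire latent gene column {j} after 1000 attempts; "
                "edge densities are too low")
    snp_ids, tf_ids, gene_ids = _ids("rs", l), _ids("TF", n), _ids("G", p)
    return (BipartiteMask(ma, snp_ids, gene_ids),
            BipartiteMask(mb, tf_ids, gene_ids))


def simulate_genotypes(cfg: SimConfig) -> ModalityMatrix:
    """Dosage matrix: per-SNP MAF ~ Uniform(range), dosage ~ Binomial(2, MAF)."""
    rng = _rng(cfg, 1)
    maf = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    X = rng.binomial(2, maf, size=(cfg.n_samples, cfg.n_snps)).astype(float)
    return ModalityMatrix(X, _ids("S", cfg.n_samples), _ids("rs", cfg.n_snps), "A")


def _genotype_maf(cfg: SimConfig) -> np.ndarray:
    return _rng(cfg, 1).uniform(*cfg.maf_range, size=cfg.n_snps)


def _generative_weights(cfg: SimConfig, mask_a, mask_b, maf, rng) -> tuple:
    ma, mb = mask_a.matrix, mask_b.matrix
    w1 = rng.normal(size=ma.shape) * cfg.snp_weight_scale
    w2 = rng.normal(size=mb.shape) * cfg.tf_weight_scale
    # normalize each input's variance contribution (dosage variance is
    # 2*maf*(1-maf), TF expression is unit variance) so the side scales set
    # the modality variance shares as stated, then keep latent scale
    # comparable across in-degrees
    dosage_sd = np.sqrt(2.0 * maf * (1.0 - maf))
    w1 /= np.maximum(dosage_sd, 1e-6)[:, None]
    w1 /= np.sqrt(np.maximum(ma.sum(axis=0), 1.0))
    w2 /= np.sqrt(np.maximum(mb.sum(axis=0), 1.0))
    return w1, w2


def _fit_intercepts(logits: np.ndarray, balance: np.ndarray,
                    n_iter: int = 400, step: float = 0.5) -> np.ndarray:
    """Per-class intercepts making argmax class frequencies hit the balance."""
    K, C = logits.shape
    c = np.zeros(C)
    for _ in range(n_iter):
        idx = np.argmax(logits + c, axis=1)
        freq = np.bincount(idx, minlength=C) / K
        c += step * (balance - freq)
        c -= c.mean()
    return c


def simulate_expression_and_labels(cfg: SimConfig, masks: tuple,
                                   genotypes: ModalityMatrix) -> tuple:
    """TF expression, labels, and ground truth.

    Latent activity is G = act(Xc (W1 .* M_a)) + act(Xtf (W2 .* M_b)) with
    centered genotypes Xc and known random weights; class scores are
    gamma * standardized(G[:, causal] @ V) + Gaussian noise, with intercepts
    fitted so class frequencies match the configured balance, and each label
    is the argmax of its noisy scores (the noise term is the label
    randomness).  The softmax of the scores is exposed as a soft truth.
    """
    mask_a, mask_b = masks
    rng = _rng(cfg, 2)
    K = cfg.n_samples
    maf = _genotype_maf(cfg)
    Xsnp = genotypes.values
    Xc = Xsnp - 2.0 * maf  # center at the Hardy-Weinberg mean
    Xtf = rng.normal(size=(K, cfg.n_tfs))
    w1, w2 = _generative_weights(cfg, mask_a, mask_b, maf, rng)
    act = np.tanh if cfg.latent_activation == "tanh" else relu
    Ga = act(Xc @ (w1 * mask_a.matrix))
    Gb = act(Xtf @ (w2 * mask_b.matrix))
    G = Ga + Gb

    causal_genes, causal_snps = _causal_sets(cfg)
    V = rng.normal(size=(cfg.n_causal_genes, cfg.n_classes))
    S = G[:, causal_genes] @ V
    # softmax only sees between-class contrasts; remove the per-sample mean
    # and standardize the contrast so gamma is the effect size regardless of
    # the random effect-matrix draw
    S = S - S.mean(axis=1, keepdims=True)
    S = (S - S.mean(axis=0)) / np.maximum(S.std(), 1e-12)
    noise = rng.normal(0.0, cfg.noise_sd, size=(K, cfg.n_classes))
    logits = cfg.gamma * S + noise
    balance = np.asarray(cfg.class_balance)
    logits = logits + _fit_intercepts(logits, balance)

    z = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)
    class_names = np.array([f"C{i}" for i in range(cfg.n_classes)])
    # noisy-argmax assignment: the Gaussian noise inside the class scores is
    # the label randomness (gamma=0 makes labels feature-independent; large
    # gamma with zero noise makes them exactly separable)
    labels_idx = np.argmax(logits, axis=1)
    for attempt in range(100):
        if len(np.unique(labels_idx)) == cfg.n_classes:
            break
        extra = rng.normal(0.0, max(cfg.noise_sd, 1e-3), size=(K, cfg.n_classes))
        labels_idx = np.argmax(logits + extra, axis=1)
    else:
        raise RuntimeError("could not assign labels covering every class in 100 attempts")
    labels = class_names[labels_idx]

    expression = ModalityMatrix(Xtf, list(genotypes.sample_ids),
                                list(mask_b.input_ids), "B")
    truth = SimTruth(
        mask_a=mask_a, mask_b=mask_b,
        causal_genes=[mask_a.latent_ids[j] for j in causal_genes],
        causal_snps=[mask_a.input_ids[i] for i in causal_snps],
        effect_matrix=V, latent=G, latent_a=Ga, latent_b=Gb,
        labels=labels, maf=maf, class_probs=probs)
    return expression, labels, truth


def simulate_cohort(cfg: SimConfig) -> dict:
    """Full in-memory cohort: masks, genotypes, expression, labels, truth."""
    masks = simulate_masks(cfg)
    genotypes = simulate_genotypes(cfg)
    expression, labels, truth = simulate_expression_and_labels(cfg, masks, genotypes)
    return {"mask_a": masks[0], "mask_b": masks[1], "genotypes": genotypes,
            "expression": expression, "labels": labels, "truth": truth}


def simulate_linear_transfer_latents(cfg: SimConfig) -> tuple:
    """Latent pair (C_a, C_b) with C_b = alpha* C_a + beta* exactly.

    The A-side latent comes from genotypes through the true masked encoder;
    the B-side latent is its exact linear image, the regime in which
    minimizing the imputation MSE recovers the transfer truth.
    """
    masks = simulate_masks(cfg)
    genotypes = simulate_genotypes(cfg)
    rng = _rng(cfg, 2)
    maf = _genotype_maf(cfg)
    Xc = genotypes.values - 2.0 * maf
    w1, _ = _generative_weights(cfg, masks[0], masks[1], maf, rng)
    Ca = relu(Xc @ (w1 * masks[0].matrix))
    Cb = cfg.transfer_alpha * Ca + cfg.transfer_beta
    return Ca, Cb, {"alpha": cfg.transfer_alpha, "beta": cfg.transfer_beta}


def fixture_bundle(cfg: SimConfig, outdir, overwrite: bool = False) -> dict:
    """Write a complete on-disk cohort (6 files) in the package's dialects.

    Files: genotypes.csv, expression.csv, labels.csv, eqtl_edges.csv,
    grn_edges.csv, truth.json.  Byte-identical across reruns with the same
    config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = ["genotypes.csv", "expression.csv", "labels.csv",
             "eqtl_edges.csv", "grn_edges.csv", "truth.json"]
    paths = {n: outdir / n for n in names}
    if not overwrite:
        existing = [str(p) for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite existing files: {existing}; "
                "pass overwrite=True")
    cohort = simulate_cohort(cfg)
    write_matrix(cohort["genotypes"], paths["genotypes.csv"])
    write_matrix(cohort["expression"], paths["expression.csv"])
    write_labels(pd.Series(cohort["labels"],
                           index=cohort["genotypes"].sample_ids),
                 paths["labels.csv"])
    write_edges(cohort["mask_a"].edges(), paths["eqtl_edges.csv"])
    write_edges(cohort["mask_b"].edges(), paths["grn_edges.csv"])
    truth = cohort["truth"]
    truth_doc = {
        "config": cfg.to_dict(),
        "causal_genes": truth.causal_genes,
        "causal_snps": truth.causal_snps,
        "effect_matrix": truth.effect_matrix.tolist(),
        "class_names": sorted(set(map(str, truth.labels))),
    }
    paths["truth.json"].write_text(json.dumps(truth_doc, indent=2, sort_keys=True) + "\n")
    return {n: str(p) for n, p in paths.items()}
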