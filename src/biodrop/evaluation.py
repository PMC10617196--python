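"""End-to-end study protocols on synthetic cohorts.

Two protocols are exposed:

* ``planted_signal_study`` — the prediction benchmark.  Per replicate seed it
  generates a cohort, splits 80/20, runs the full pipeline on the training
  portion (Welch t-test feature selection, prior-network intersection,
  standard scaling, five-fold-CV grid search over the auxiliary-loss weight
  scored on both prediction modes), fits the final model, and evaluates
  held-out dual- and single-modality balanced accuracy and AUC.  A
  permuted-label null (labels permuted, same preprocessing and selected
  configuration) calibrates the pipeline against chance.

* ``causal_recovery_study`` — the prioritization benchmark.  Attribution
  must rank the complete candidate feature set, so these models train on
  all masked features (no univariate filter: a feature discarded by a
  filter could never be scored).  Integrated-gradients node importance on
  the held-out samples is compared against the planted causal SNPs by
  rank-AUC.

Replicate seeds are derived deterministically from one master seed and kept
below 2^31.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

from .attribution import node_importance
from .masks import build_mask
from .model import BioDropClassifier
from .preprocessing import (apply_scaler, fit_scaler, intersect_with_priors,
                            select_features)
from .simulate import SimConfig, simulate_cohort
from .training import (TrainConfig, auc_score, balanced_accuracy, grid_search,
                       split_train_test, train_model)

DEFAULT_GRID = {"lambda_aux": [0.1, 1.0, 10.0]}


def child_seeds(master_seed: int, n: int) -> list:
    """n deterministic child seeds < 2^31 derived from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


def prepare_replicate(seed: int, select: bool = True, alpha: float = 0.05,
                      ratio: float = 0.8, sim_config: Optional[SimConfig] = None) -> dict:
    """Simulate a cohort and run the training-fitted preprocessing pipeline."""
    cfg = sim_config if sim_config is not None else SimConfig(seed=seed)
    cohort = simulate_cohort(cfg)
    y = cohort["labels"]
    ids = cohort["genotypes"].sample_ids
    train_ids, _ = split_train_test(ids, y, ratio=ratio, seed=seed)
    tr = np.isin(ids, train_ids)
    A, B = cohort["genotypes"], cohort["expression"]
    if select:
        # if selection empties a modality (possible on weak-signal draws),
        # fall back to the unfiltered feature set for that modality
        def _kept(mat):
            try:
                return select_features(mat.values[tr], mat.feature_ids,
                                       y[tr], alpha=alpha).kept
            except ValueError:
                return list(mat.feature_ids)

        kept_a, kept_b = _kept(A), _kept(B)
    else:
        kept_a, kept_b = list(A.feature_ids), list(B.feature_ids)
    fa, fb, latent, ea, eb = intersect_with_priors(
        kept_a, kept_b, cohort["mask_a"].edges(), cohort["mask_b"].edges())
    A2, B2 = A.subset_features(fa), B.subset_features(fb)
    mask_a = build_mask(ea, fa, latent)
    mask_b = build_mask(eb, fb, latent)
    sa = fit_scaler(A2.values[tr], "standard")
    sb = fit_scaler(B2.values[tr], "standard")
    return {"cohort": cohort, "y": y, "train_mask": tr,
            "Xa": apply_scaler(A2.values, sa), "Xb": apply_scaler(B2.values, sb),
            "mask_a": mask_a, "mask_b": mask_b,
            "features_a": fa, "features_b": fb, "latent": latent}


def fit_replicate(rep: dict, seed: int, grid: Optional[dict] = None,
                  k: int = 5, base_config: Optional[TrainConfig] = None) -> tuple:
    """Grid-search (scored on both prediction modes) and final fit."""
    tr = rep["train_mask"]
    base = base_config or TrainConfig(seed=seed)
    grid = DEFAULT_GRID if grid is None else grid
    best, table = grid_search(grid, rep["Xa"][tr], rep["Xb"][tr], rep["y"][tr],
                              (rep["mask_a"], rep["mask_b"]), base_config=base,
                              k=k, selection_metric="dual+single")
    est, _ = train_model(rep["Xa"][tr], rep["Xb"][tr], rep["y"][tr],
                         (rep["mask_a"], rep["mask_b"]), best)
    return est, best, table


def _heldout_metrics(est: BioDropClassifier, rep: dict) -> dict:
    te = ~rep["train_mask"]
    Xte = np.concatenate([rep["Xa"][te], rep["Xb"][te]], axis=1)
    y_te = rep["y"][te]
    out = {}
    for mode, X in (("dual", Xte), ("single", rep["Xa"][te])):
        prob = est.predict_proba(X, mode=mode)
        pred = est.classes_[np.argmax(prob, axis=1)]
        out[f"{mode}_bacc"] = balanced_accuracy(y_te, pred)
        out[f"{mode}_auc"] = auc_score(y_te, prob)
    return out


def planted_signal_study(master_seed: int, n_replicates: int = 8,
                         n_permutations: int = 10,
                         grid: Optional[dict] = None) -> dict:
    """Replicated held-out benchmark plus a permuted-label null.

    Returns per-replicate and mean dual/single BACC and AUC, the fitted
    estimators (reusable for attribution), and the mean permuted-label
    held-out BACC over ``n_permutations`` label permutations.
    """
    seeds = child_seeds(master_seed, n_replicates)
    replicates = []
    for seed in seeds:
        rep = prepare_replicate(seed, select=True)
        est, best, _ = fit_replicate(rep, seed, grid=grid)
        metrics = _heldout_metrics(est, rep)
        replicates.append({"seed": seed, "estimator": est, "config": best,
                           "replicate": rep, **metrics})

    # permuted-label null: first replicate's preprocessed data, selected
    # config, fresh label permutation per null seed
    null_rep = replicates[0]["replicate"]
    null_cfg = replicates[0]["config"]
    tr, te = null_rep["train_mask"], ~null_rep["train_mask"]
    Xte = np.concatenate([null_rep["Xa"][te], null_rep["Xb"][te]], axis=1)
    perm_baccs = []
    for pseed in child_seeds(master_seed + 1, n_permutations):
        rng = np.random.default_rng(pseed)
        y_perm = rng.permutation(null_rep["y"])
        cfg = TrainConfig(**{**null_cfg.to_dict(), "seed": pseed})
        est_p, _ = train_model(null_rep["Xa"][tr], null_rep["Xb"][tr],
                               y_perm[tr], (null_rep["mask_a"], null_rep["mask_b"]),
                               cfg)
        perm_baccs.append(balanced_accuracy(y_perm[te], est_p.predict(Xte)))

    out = {"replicates": replicates,
           "permuted_baccs": perm_baccs,
           "permuted_bacc_mean": float(np.mean(perm_baccs))}
    for key in ("dual_bacc", "single_bacc", "dual_auc", "single_auc"):
        out[f"{key}_mean"] = float(np.mean([r[key] for r in replicates]))
    return out


def causal_rank_auc(est: BioDropClassifier, rep: dict, n_steps: int = 50) -> float:
    """Rank-AUC of planted causal SNPs in held-out node importance.

    SNPs absent from the fitted model (possible when a filter preceded
    training) score 0, consistent with a disconnected feature's attribution.
    """
    te = ~rep["train_mask"]
    target = est.classes_[-1]
    nodes = node_importance(est, rep["Xa"][te], rep["Xb"][te], target,
                            n_steps=n_steps)
    scores = nodes[nodes["layer"] == "input_a"].set_index("feature_id")["score"]
    truth = rep["cohort"]["truth"]
    all_snps = rep["cohort"]["genotypes"].feature_ids
    causal = set(truth.causal_snps)
    y = np.array([1 if f in causal else 0 for f in all_snps])
    s = np.array([float(scores.get(f, 0.0)) for f in all_snps])
    return float(roc_auc_score(y, s))


def causal_recovery_study(master_seed: int, n_replicates: int = 5,
                          n_steps: int = 50,
                          config: Optional[TrainConfig] = None) -> dict:
    """Prioritization benchmark on full-feature models (no univariate filter)."""
    seeds = child_seeds(master_seed, n_replicates)
    aucs = []
    for seed in seeds:
        rep = prepare_replicate(seed, select=False)
        cfg = config or TrainConfig(seed=seed, lambda_aux=10.0, dropout_rate=0.3)
        cfg = TrainConfig(**{**cfg.to_dict(), "seed": seed})
        est, _ = train_model(rep["Xa"][rep["train_mask"]],
                             rep["Xb"][rep["train_mask"]],
                             rep["y"][rep["train_mask"]],
                             (rep["mask_a"], rep["mask_b"]), cfg)
        aucs.append(causal_rank_auc(est, rep, n_steps=n_steps))
    return {"rank_aucs": aucs, "rank_auc_mean": float(np.mean(aucs))}
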