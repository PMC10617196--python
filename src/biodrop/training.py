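"""Training protocol: losses, splits, metrics, cross-validation, grid search.

The objective is  L = L_pri + lambda * L_aux  where L_pri is the mean
cross-entropy of the softmax classifier and L_aux the mean squared error of
the cross-modal latent imputation.  Model quality is reported as balanced
accuracy (mean of sensitivity and specificity for two classes, unweighted
mean per-class recall beyond that) and ROC AUC (macro one-vs-rest for more
than two classes), both robust to class imbalance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import balanced_accuracy_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .model import BioDropClassifier
from .nn import EPS_LOG, Adam, cross_entropy, mse


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    latent_dim is only used in the mask-free fallback; with prior networks
    the latent width is the number of shared target genes.
    """

    latent_dim: int = 50
    hidden_sizes: tuple = (64,)
    dropout_rate: float = 0.1
    lambda_aux: float = 1.0
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 10
    batch_size: Optional[int] = 32
    val_fraction: float = 0.15
    seed: int = 0
    normalization: str = "standard"
    activation: str = "relu"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    vector_transfer: bool = False

    def __post_init__(self):
        if self.lambda_aux < 0:
            raise ValueError("lambda_aux must be >= 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.normalization not in ("standard", "minmax", "log"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.hidden_sizes = tuple(self.hidden_sizes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d


@dataclass
class EvalReport:
    """Per-fold (or held-out) evaluation summary."""

    bacc: float
    auc: float
    sensitivity: dict
    specificity: dict
    confusion: np.ndarray
    fold: int = -1
    classes: list = field(default_factory=list)


# ------------------------------------------------------------------- losses
def primary_loss(y_true: np.ndarray, y_prob: np.ndarray,
                 classes: Optional[Sequence] = None, eps: float = EPS_LOG) -> float:
    """Mean cross-entropy of one-hot labels against predicted probabilities."""
    y_true = np.asarray(y_true)
    classes = np.unique(y_true) if classes is None else np.asarray(classes)
    if y_prob.shape[1] != len(classes):
        raise ValueError("probability columns do not match the class set")
    idx = np.searchsorted(classes, y_true)
    if np.any(idx >= len(classes)) or not np.array_equal(classes[np.minimum(idx, len(classes) - 1)], y_true):
        bad = set(np.asarray(y_true).tolist()) - set(classes.tolist())
        raise ValueError(f"labels outside the class set: {sorted(map(str, bad))}")
    Y = np.eye(len(classes))[idx]
    return cross_entropy(Y, y_prob, eps=eps)


def aux_loss(c_target: np.ndarray, c_imputed: np.ndarray) -> float:
    """MSE between a latent space and its cross-modal estimate (entrywise mean)."""
    return mse(np.asarray(c_target, float), np.asarray(c_imputed, float))


def total_loss(lp: float, la: float, lam: float) -> float:
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return lp + lam * la


# -------------------------------------------------------------------- splits
def split_train_test(sample_ids: Sequence, labels: Sequence, ratio: float = 0.8,
                     seed: int = 0) -> tuple:
    """Stratified train/test partition of sample identifiers."""
    sample_ids = np.asarray(sample_ids)
    labels = np.asarray(labels)
    if len(sample_ids) < 10:
        raise ValueError("need at least 10 samples to split")
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be strictly between 0 and 1")
    classes, counts = np.unique(labels, return_counts=True)
    for c, n in zip(classes, counts):
        if n < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    tr, te = train_test_split(sample_ids, train_size=ratio, stratify=labels,
                              random_state=int(seed) % (2 ** 31))
    return list(tr), list(te)


# ------------------------------------------------------------------- metrics
def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recall: (sensitivity + specificity) / 2 for 2 classes."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    return float(balanced_accuracy_score(y_true, y_pred))


def auc_score(y_true, y_prob) -> float:
    """ROC AUC; binary from the positive-class column, macro one-vs-rest otherwise."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined with a single class in y_true")
    if y_prob.ndim == 2 and y_prob.shape[1] == 2:
        y_prob = y_prob[:, 1]
    if y_prob.ndim == 1:
        return float(roc_auc_score(y_true, y_prob))
    return float(roc_auc_score(y_true, y_prob, multi_class="ovr", average="macro"))


def evaluate(y_true, y_pred, y_prob, classes: Sequence, fold: int = -1) -> EvalReport:
    """Confusion-matrix summary with per-class sensitivity and specificity."""
    classes = list(classes)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    sens, spec = {}, {}
    total = cm.sum()
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = tp / (tp + fn) if (tp + fn) else np.nan
        spec[c] = tn / (tn + fp) if (tn + fp) else np.nan
    return EvalReport(bacc=balanced_accuracy(y_true, y_pred),
                      auc=auc_score(y_true, y_prob),
                      sensitivity=sens, specificity=spec, confusion=cm,
                      fold=fold, classes=classes)


# ------------------------------------------------------------- train wrapper
def _make_estimator(masks, config: TrainConfig, n_features_a=None) -> BioDropClassifier:
    mask_a, mask_b = (masks if masks is not None else (None, None))
    return BioDropClassifier(
        mask_a=mask_a, mask_b=mask_b, latent_dim=config.latent_dim,
        n_features_a=n_features_a, hidden_sizes=config.hidden_sizes,
        dropout=config.dropout_rate, activation=config.activation,
        lam=config.lambda_aux, lr=config.learning_rate,
        max_epochs=config.max_epochs, patience=config.patience,
        batch_size=config.batch_size, val_fraction=config.val_fraction,
        vector_transfer=config.vector_transfer, random_state=config.seed)


def train_model(Xa: np.ndarray, Xb: np.ndarray, labels, masks,
                config: TrainConfig):
    """Fit the classifier on aligned, preprocessed modality matrices.

    Returns (fitted estimator, per-epoch training log DataFrame).
    """
    Xa, Xb = np.asarray(Xa, float), np.asarray(Xb, float)
    est = _make_estimator(masks, config, n_features_a=Xa.shape[1])
    est.fit(np.concatenate([Xa, Xb], axis=1), np.asarray(labels))
    return est, est.history_


def fit_transfer(c_source: np.ndarray, c_target: np.ndarray,
                 method: str = "adam", lr: float = 0.05, n_steps: int = 3000,
                 tol: float = 1e-10) -> tuple:
    """Estimate the scalar transfer (alpha, beta) minimizing the imputation MSE.

    method='adam' runs the same optimizer used in full training on the
    isolated auxiliary objective; method='lstsq' solves the normal equations
    exactly and serves as an independent cross-check.
    """
    Cs = np.asarray(c_source, float).ravel()
    Ct = np.asarray(c_target, float).ravel()
    if Cs.shape != Ct.shape:
        raise ValueError("latent matrices must have identical shapes")
    if method == "lstsq":
        A = np.column_stack([Cs, np.ones_like(Cs)])
        (alpha, beta), *_ = np.linalg.lstsq(A, Ct, rcond=None)
        return float(alpha), float(beta)
    if method != "adam":
        raise ValueError("method must be 'adam' or 'lstsq'")
    params = {"alpha": np.array(1.0), "beta": np.array(0.0)}
    opt = Adam(params, lr=lr)
    n = Cs.size
    prev = np.inf
    for _ in range(n_steps):
        r = params["alpha"] * Cs + params["beta"] - Ct
        loss = float((r * r).mean())
        grads = {"alpha": np.asarray(2.0 * (r * Cs).sum() / n),
                 "beta": np.asarray(2.0 * r.sum() / n)}
        opt.step(grads)
        if abs(prev - loss) < tol:
            break
        prev = loss
    return float(params["alpha"]), float(params["beta"])


# ----------------------------------------------------------- cross-validation
def cross_validate(Xa: np.ndarray, Xb: np.ndarray, labels, masks,
                   config: TrainConfig, k: int = 5,
                   single_modality_eval: bool = False) -> list:
    """Stratified k-fold cross-validation on the training partition.

    Per-fold scaling statistics are fitted on the fold's training portion
    only (no leakage into the evaluation fold).  Returns a list of
    EvalReport, one per fold.
    """
    Xa, Xb = np.asarray(Xa, float), np.asarray(Xb, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count ({counts.min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(config.seed) % (2 ** 31))
    reports = []
    for fold, (tr, te) in enumerate(skf.split(Xa, labels)):
        sa, sb = StandardScaler(), StandardScaler()
        Xa_tr = sa.fit_transform(Xa[tr])
        Xb_tr = sb.fit_transform(Xb[tr])
        Xa_te, Xb_te = sa.transform(Xa[te]), sb.transform(Xb[te])
        est, _ = train_model(Xa_tr, Xb_tr, labels[tr], masks, config)
        Xte = Xa_te if single_modality_eval else np.concatenate([Xa_te, Xb_te], axis=1)
        prob = est.predict_proba(Xte)
        pred = est.classes_[np.argmax(prob, axis=1)]
        reports.append(evaluate(labels[te], pred, prob, list(est.classes_), fold=fold))
    return reports


def summarize_cv(reports: list) -> dict:
    baccs = np.array([r.bacc for r in reports])
    aucs = np.array([r.auc for r in reports])
    return {"bacc_mean": float(baccs.mean()), "bacc_sd": float(baccs.std(ddof=1)) if len(baccs) > 1 else 0.0,
            "auc_mean": float(aucs.mean()), "auc_sd": float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
            "k": len(reports)}


def grid_search(grid: dict, Xa, Xb, labels, masks,
                base_config: Optional[TrainConfig] = None, k: int = 5,
                selection_metric: str = "dual") -> tuple:
    """Exhaustive grid search by k-fold CV mean balanced accuracy.

    ``selection_metric='dual'`` scores candidates on dual-modality CV BACC;
    ``'dual+single'`` scores the mean of the dual and single-modality CV
    BACCs, selecting hyperparameters for a model meant to predict from
    either input.  Ties are broken deterministically by higher mean AUC,
    then lower lambda_aux, then smaller latent_dim, then the lexicographic
    order of the candidate's parameter assignment.
    """
    if not grid:
        raise ValueError("empty grid")
    if selection_metric not in ("dual", "dual+single"):
        raise ValueError("selection_metric must be 'dual' or 'dual+single'")
    base = base_config or TrainConfig()
    keys = sorted(grid)
    candidates = [dict(zip(keys, values))
                  for values in itertools.product(*(grid[key] for key in keys))]
    # lexicographic candidate order is the final tie-break (first wins)
    candidates.sort(key=lambda ov: tuple(repr(ov[key]) for key in keys))
    table = []
    best = None
    for overrides in candidates:
        cfg = TrainConfig(**{**base.to_dict(), **overrides})
        summary = summarize_cv(cross_validate(Xa, Xb, labels, masks, cfg, k=k))
        score = summary["bacc_mean"]
        if selection_metric == "dual+single":
            single = summarize_cv(cross_validate(
                Xa, Xb, labels, masks, cfg, k=k, single_modality_eval=True))
            summary["single_bacc_mean"] = single["bacc_mean"]
            score = 0.5 * (summary["bacc_mean"] + single["bacc_mean"])
        table.append({**overrides, **summary})
        key = (score, summary["auc_mean"], -cfg.lambda_aux, -cfg.latent_dim)
        if best is None or key > best[0]:
            best = (key, cfg)
    return best[1], table
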