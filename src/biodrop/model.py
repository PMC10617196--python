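"""Scikit-learn style estimator around the masked dual-modality network.

``BioDropClassifier`` follows the sklearn estimator contract (``fit`` /
``predict`` / ``predict_proba`` / ``get_params`` / ``set_params``, fitted
attributes with a trailing underscore) so it composes with pipelines and
model selection.  The two modalities are passed as a single horizontally
concatenated matrix ``X = [X_a | X_b]``; the split point is taken from the
masks (or from ``n_features_a`` when running mask-free).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .masks import BipartiteMask
from .nn import Adam, MaskedDualNet


class BioDropClassifier(BaseEstimator, ClassifierMixin):
    """Biologically guided DropConnect classifier with cross-modal imputation.

    Parameters
    ----------
    mask_a, mask_b : BipartiteMask or ndarray or None
        Prior-network masks for the two encoders (SNP->gene eQTL edges and
        TF->gene regulatory edges in the genotype/expression application).
        When both are None, all-ones masks of width ``latent_dim`` are used
        (full connectivity; for datasets with no usable prior network) and
        ``n_features_a`` must be given.
    latent_dim : int
        Latent width p for the mask-free fallback; ignored when masks are
        supplied (p is then the number of shared latent genes).
    n_features_a : int or None
        Number of columns of X belonging to modality A; required only when
        masks are absent.
    hidden_sizes : tuple of int
        Classifier hidden-layer widths.
    dropout : float
        Dropout rate inside the classifier stack.
    activation : str
        Encoder activation ('relu', 'tanh', 'sigmoid', 'identity').
    lam : float
        Weight of the auxiliary cross-modal imputation loss (lambda >= 0).
    lr : float
        Adam learning rate (beta1=0.9, beta2=0.999).
    max_epochs, patience : int
        Epoch cap and early-stopping patience on the validation total loss;
        the best-epoch parameters are restored.
    batch_size : int or None
        None trains full-batch.
    val_fraction : float
        Stratified fraction of the training data held out for early stopping.
        0 disables early stopping.
    vector_transfer : bool
        Per-latent-dimension transfer parameters instead of scalars.
    random_state : int
        Seed for initialization, shuffling, dropout, and the validation split.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels; probability columns follow this order.
    net_ : MaskedDualNet
        The fitted numerical network.
    history_ : DataFrame
        Per-epoch train/validation primary, auxiliary, and total losses.
    best_epoch_ : int
    """

    def __init__(self, mask_a=None, mask_b=None, latent_dim: int = 50,
                 n_features_a: Optional[int] = None,
                 hidden_sizes: Sequence[int] = (64,), dropout: float = 0.1,
                 activation: str = "relu", lam: float = 1.0, lr: float = 1e-3,
                 max_epochs: int = 100, patience: int = 10,
                 batch_size: Optional[int] = 32, val_fraction: float = 0.15,
                 vector_transfer: bool = False, random_state: int = 0):
        self.mask_a = mask_a
        self.mask_b = mask_b
        self.latent_dim = latent_dim
        self.n_features_a = n_features_a
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.activation = activation
        self.lam = lam
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.vector_transfer = vector_transfer
        self.random_state = random_state

    # ----------------------------------------------------------------- masks
    def _resolve_masks(self, n_features: int):
        def as_matrix(m):
            return m.matrix if isinstance(m, BipartiteMask) else np.asarray(m, dtype=float)

        if self.mask_a is not None and self.mask_b is not None:
            ma, mb = as_matrix(self.mask_a), as_matrix(self.mask_b)
        elif self.mask_a is None and self.mask_b is None:
            if self.n_features_a is None:
                raise ValueError("n_features_a is required when no masks are supplied")
            na = int(self.n_features_a)
            nb = n_features - na
            if nb <= 0:
                raise ValueError("n_features_a leaves no columns for modality B")
            ma = np.ones((na, self.latent_dim))
            mb = np.ones((nb, self.latent_dim))
        else:
            raise ValueError("supply both masks or neither")
        if ma.shape[0] + mb.shape[0] != n_features:
            raise ValueError(
                f"X has {n_features} columns but masks expect "
                f"{ma.shape[0]} + {mb.shape[0]}")
        return ma, mb

    def _split_X(self, X: np.ndarray):
        na = self.net_.mask_a.shape[0]
        return X[:, :na], X[:, na:]

    # ------------------------------------------------------------------- fit
    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.patience >= self.max_epochs and self.val_fraction > 0:
            raise ValueError("patience must be smaller than max_epochs")

        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.n_features_in_ = X.shape[1]
        Y = np.eye(len(self.classes_))[y_idx]

        ma, mb = self._resolve_masks(X.shape[1])
        ss = np.random.SeedSequence(self.random_state)
        s_init, s_split, s_train = [np.random.default_rng(c) for c in ss.spawn(3)]
        split_seed = int(np.random.SeedSequence(self.random_state).generate_state(1)[0] % (2 ** 31))

        self.net_ = MaskedDualNet(
            ma, mb, hidden_sizes=self.hidden_sizes,
            n_classes=len(self.classes_), dropout_rate=self.dropout,
            activation=self.activation, vector_transfer=self.vector_transfer,
            rng=s_init)
        na = ma.shape[0]

        if self.val_fraction > 0:
            idx_tr, idx_val = train_test_split(
                np.arange(X.shape[0]), test_size=self.val_fraction,
                stratify=y_idx, random_state=split_seed)
        else:
            idx_tr, idx_val = np.arange(X.shape[0]), None
        Xtr, Ytr = X[idx_tr], Y[idx_tr]
        Xval = X[idx_val] if idx_val is not None else None
        Yval = Y[idx_val] if idx_val is not None else None

        opt = Adam(self.net_.params, lr=self.lr)
        history = []
        best_val = np.inf
        best_params = self.net_.copy_params()
        best_epoch = 0
        wait = 0
        K = Xtr.shape[0]
        bs = K if self.batch_size is None else min(self.batch_size, K)

        for epoch in range(1, self.max_epochs + 1):
            order = s_train.permutation(K)
            for start in range(0, K, bs):
                b = order[start:start + bs]
                lpri, laux, total, grads = self.net_.loss_and_grads(
                    Xtr[b, :na], Xtr[b, na:], Ytr[b], self.lam,
                    training=True, rng=s_train)
                if not np.isfinite(total):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                opt.step(grads)

            cache = self.net_.forward(Xtr[:, :na], Xtr[:, na:], training=False)
            tr_pri, tr_aux, tr_tot = self.net_.losses(cache, Ytr, self.lam)
            if Xval is not None:
                vc = self.net_.forward(Xval[:, :na], Xval[:, na:], training=False)
                _, _, val_tot = self.net_.losses(vc, Yval, self.lam)
            else:
                val_tot = np.nan
            history.append({"epoch": epoch, "train_primary": tr_pri,
                            "train_aux": tr_aux, "train_total": tr_tot,
                            "val_total": val_tot})
            if Xval is not None:
                if val_tot < best_val - 1e-12:
                    best_val = val_tot
                    best_params = self.net_.copy_params()
                    best_epoch = epoch
                    wait = 0
                else:
                    wait += 1
                    if wait >= self.patience:
                        break
            else:
                best_params = self.net_.copy_params()
                best_epoch = epoch

        self.net_.set_params_arrays(best_params)
        self.best_epoch_ = best_epoch
        self.history_ = pd.DataFrame(history)
        return self

    # --------------------------------------------------------------- predict
    def _infer_mode(self, X: np.ndarray, mode: Optional[str]) -> str:
        na = self.net_.mask_a.shape[0]
        nb = self.net_.mask_b.shape[0]
        if mode is None:
            if X.shape[1] == na + nb:
                return "dual"
            if X.shape[1] == na:
                return "single"
            raise ValueError(
                f"X width {X.shape[1]} matches neither dual ({na + nb}) nor "
                f"single-modality ({na}) input")
        if mode not in ("dual", "single"):
            raise ValueError("mode must be 'dual' or 'single'")
        expected = na + nb if mode == "dual" else na
        if X.shape[1] != expected:
            raise ValueError(f"mode {mode!r} expects width {expected}, got {X.shape[1]}")
        return mode

    def predict_proba(self, X, mode: Optional[str] = None) -> np.ndarray:
        """Class probabilities; ``mode='single'`` imputes the B-side latent."""
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=np.float64)
        mode = self._infer_mode(X, mode)
        na = self.net_.mask_a.shape[0]
        if mode == "dual":
            cache = self.net_.forward(X[:, :na], X[:, na:], training=False)
        else:
            cache = self.net_.forward(X, None, training=False)
        return cache["probs"]

    def predict(self, X, mode: Optional[str] = None):
        return self.classes_[np.argmax(self.predict_proba(X, mode=mode), axis=1)]

    def score(self, X, y, sample_weight=None):
        """Balanced accuracy (the model's headline metric), not plain accuracy."""
        return balanced_accuracy_score(y, self.predict(X))

    # ------------------------------------------------------------ inspection
    @property
    def transfer_params_(self) -> tuple:
        """Fitted (alpha, beta) of the cross-modal transfer function."""
        check_is_fitted(self, "net_")
        a, b = self.net_.params["alpha"], self.net_.params["beta"]
        if a.ndim == 0:
            return float(a), float(b)
        return np.array(a), np.array(b)


def predict_dual(Xa: np.ndarray, Xb: np.ndarray, model: BioDropClassifier) -> np.ndarray:
    """Class probabilities from both modalities."""
    return model.predict_proba(np.concatenate([Xa, Xb], axis=1), mode="dual")


def predict_single(Xa: np.ndarray, model: BioDropClassifier) -> np.ndarray:
    """Class probabilities from modality A alone, imputing the B latent."""
    return model.predict_proba(np.asarray(Xa), mode="single")
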