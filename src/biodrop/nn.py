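"""Numerical core: masked dual-encoder network, backprop, and Adam.

The architecture has four stages:

1. Two *biological DropConnect* encoders, one per modality.  Each is a dense
   layer whose weight matrix is elementwise-multiplied by a fixed binary
   mask from a prior network (eQTL SNP->gene, GRN TF->gene), so only
   biologically supported connections carry signal:

       C_a = sigma(X_a (W1 .* M_a) + b1),   C_b = sigma(X_b (W2 .* M_b) + b2)

2. A scalar linear *transfer* that imputes modality B's latent space from
   modality A's:  C_b_hat = alpha * C_a + beta.  At prediction time with
   modality B missing, C_b_hat stands in for C_b.

3. Concatenation [C_a | C_b] feeding a fully connected classifier stack with
   ReLU hidden units and (training-only) inverted dropout.

4. Softmax over class logits.

Training minimizes  L = L_pri + lambda * L_aux,  where L_pri is mean
cross-entropy of the softmax output and L_aux is the mean squared error
between C_b and its transfer-imputed estimate, averaged over every
sample x latent entry.

All gradients below are exact analytic backprop; the masked positions of W1
and W2 receive exactly zero gradient because the chain rule factor is the
mask itself.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

EPS_LOG = 1e-12


def relu(z):
    return np.maximum(z, 0.0)


def _relu_grad(z):
    return (z > 0).astype(np.float64)


ACTIVATIONS = {
    "relu": (relu, _relu_grad),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "sigmoid": (expit, lambda z: expit(z) * (1.0 - expit(z))),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shifted for numerical stability."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(y_onehot: np.ndarray, probs: np.ndarray, eps: float = EPS_LOG) -> float:
    """Mean negative log-likelihood with the log argument clamped at eps."""
    p = np.clip(probs, eps, 1.0)
    return float(-(y_onehot * np.log(p)).sum() / y_onehot.shape[0])


def mse(target: np.ndarray, estimate: np.ndarray) -> float:
    """Mean squared error over every sample x latent entry."""
    if target.shape != estimate.shape:
        raise ValueError(f"shape mismatch {target.shape} vs {estimate.shape}")
    d = target - estimate
    return float((d * d).mean())


def dropconnect_forward(X: np.ndarray, weights: np.ndarray, bias: np.ndarray,
                        mask: np.ndarray, activation: str = "relu") -> np.ndarray:
    """One biologically masked layer:  sigma(X (W .* M) + b).

    Entries of ``weights`` at mask-zero positions contribute exactly nothing
    regardless of their stored value.
    """
    X = np.asarray(X, float)
    weights = np.asarray(weights, float)
    mask = np.asarray(mask, float)
    if weights.shape != mask.shape:
        raise ValueError(f"weights {weights.shape} and mask {mask.shape} differ")
    if X.shape[1] != mask.shape[0]:
        raise ValueError(f"X width {X.shape[1]} != mask rows {mask.shape[0]}")
    act, _ = ACTIVATIONS[activation]
    return act(X @ (weights * mask) + np.asarray(bias, float))


def transfer_impute(c_source: np.ndarray, alpha, beta) -> np.ndarray:
    """Linear cross-modal latent imputation  alpha * C + beta  (elementwise)."""
    c_source = np.asarray(c_source, float)
    if not np.all(np.isfinite(c_source)):
        raise ValueError("latent matrix contains non-finite values")
    return alpha * c_source + beta


class Adam:
    """Adam optimizer over a dict of named parameter arrays (in-place updates)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MaskedDualNet:
    """The full parameter set and differentiable forward/backward passes.

    Parameters
    ----------
    mask_a, mask_b : ndarray
        Binary (n_features, n_latents) masks; both must share the latent
        dimension p.
    hidden_sizes : sequence of int
        Widths of the classifier's hidden layers (input width is 2p).
    n_classes : int
    dropout_rate : float in [0, 1)
        Applied inside the classifier stack only; the encoders are already
        sparsified by the masks.
    activation : str
        Encoder activation sigma; the classifier always uses ReLU.
    vector_transfer : bool
        If True, alpha and beta are per-latent-dimension vectors instead of
        scalars.
    """

    def __init__(self, mask_a: np.ndarray, mask_b: np.ndarray,
                 hidden_sizes: Sequence[int] = (64,), n_classes: int = 2,
                 dropout_rate: float = 0.1, activation: str = "relu",
                 vector_transfer: bool = False,
                 rng: Optional[np.random.Generator] = None):
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        if not (0.0 <= dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        mask_a = np.asarray(mask_a, dtype=np.float64)
        mask_b = np.asarray(mask_b, dtype=np.float64)
        if mask_a.shape[1] != mask_b.shape[1]:
            raise ValueError(
                f"masks disagree on latent dimension: {mask_a.shape[1]} vs {mask_b.shape[1]}")
        self.mask_a = mask_a
        self.mask_b = mask_b
        self.p = mask_a.shape[1]
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.n_classes = int(n_classes)
        self.dropout_rate = float(dropout_rate)
        self.activation = activation
        self.vector_transfer = bool(vector_transfer)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.params = self._init_params(rng)

    # ------------------------------------------------------------------ init
    def _init_params(self, rng: np.random.Generator) -> dict:
        la, p = self.mask_a.shape
        nb = self.mask_b.shape[0]
        params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / la), size=(la, p)),
            "b1": np.zeros(p),
            "W2": rng.normal(0.0, np.sqrt(2.0 / nb), size=(nb, p)),
            "b2": np.zeros(p),
        }
        if self.vector_transfer:
            params["alpha"] = np.ones(p)
            params["beta"] = np.zeros(p)
        else:
            params["alpha"] = np.array(1.0)
            params["beta"] = np.array(0.0)
        dims = [2 * p, *self.hidden_sizes, self.n_classes]
        for i in range(len(dims) - 1):
            params[f"V{i}"] = rng.normal(0.0, np.sqrt(2.0 / dims[i]),
                                         size=(dims[i], dims[i + 1]))
            params[f"c{i}"] = np.zeros(dims[i + 1])
        return params

    @property
    def n_classifier_layers(self) -> int:
        return len(self.hidden_sizes) + 1

    # --------------------------------------------------------------- forward
    def encode_a(self, Xa: np.ndarray) -> tuple:
        if Xa.shape[1] != self.mask_a.shape[0]:
            raise ValueError(
                f"modality A width {Xa.shape[1]} != mask rows {self.mask_a.shape[0]}")
        act, _ = ACTIVATIONS[self.activation]
        Za = Xa @ (self.params["W1"] * self.mask_a) + self.params["b1"]
        return Za, act(Za)

    def encode_b(self, Xb: np.ndarray) -> tuple:
        if Xb.shape[1] != self.mask_b.shape[0]:
            raise ValueError(
                f"modality B width {Xb.shape[1]} != mask rows {self.mask_b.shape[0]}")
        act, _ = ACTIVATIONS[self.activation]
        Zb = Xb @ (self.params["W2"] * self.mask_b) + self.params["b2"]
        return Zb, act(Zb)

    def transfer(self, Ca: np.ndarray) -> np.ndarray:
        """Linear cross-modal imputation  alpha * C_a + beta."""
        return self.params["alpha"] * Ca + self.params["beta"]

    def classifier_forward(self, H: np.ndarray, training: bool = False,
                           rng: Optional[np.random.Generator] = None) -> dict:
        """Run the fully connected stack on a (samples x 2p) latent block."""
        if H.shape[1] != 2 * self.p:
            raise ValueError(f"classifier expects width {2 * self.p}, got {H.shape[1]}")
        Zs, As, drops = [], [H], []
        A = H
        n_layers = self.n_classifier_layers
        for i in range(n_layers - 1):
            Z = A @ self.params[f"V{i}"] + self.params[f"c{i}"]
            A = relu(Z)
            if training and self.dropout_rate > 0.0:
                if rng is None:
                    raise ValueError("training-mode dropout requires an rng")
                keep = 1.0 - self.dropout_rate
                d = (rng.random(A.shape) < keep) / keep
                A = A * d
                drops.append(d)
            else:
                drops.append(None)
            Zs.append(Z)
            As.append(A)
        i = n_layers - 1
        logits = A @ self.params[f"V{i}"] + self.params[f"c{i}"]
        probs = softmax(logits)
        return {"Zs": Zs, "As": As, "drops": drops, "logits": logits, "probs": probs}

    def forward(self, Xa: np.ndarray, Xb: Optional[np.ndarray] = None,
                training: bool = False,
                rng: Optional[np.random.Generator] = None) -> dict:
        """Full forward pass.

        With both modalities the classifier sees the true latents of each;
        with only modality A (``Xb=None``) the B-side latent is imputed by
        the transfer function.
        """
        Za, Ca = self.encode_a(Xa)
        Cb_hat = self.transfer(Ca)
        if Xb is None:
            Zb, Cb = None, Cb_hat
            single = True
        else:
            Zb, Cb = self.encode_b(Xb)
            single = False
        H = np.concatenate([Ca, Cb], axis=1)
        cls = self.classifier_forward(H, training=training, rng=rng)
        cls.update({"Za": Za, "Ca": Ca, "Zb": Zb, "Cb": Cb, "Cb_hat": Cb_hat,
                    "H": H, "single": single})
        return cls

    # ---------------------------------------------------------------- losses
    def losses(self, cache: dict, y_onehot: np.ndarray, lam: float) -> tuple:
        lpri = cross_entropy(y_onehot, cache["probs"])
        if cache["single"]:
            laux = 0.0
        else:
            laux = mse(cache["Cb"], cache["Cb_hat"])
        return lpri, laux, lpri + lam * laux

    # -------------------------------------------------------------- backward
    def _classifier_backward(self, cache: dict, dlogits: np.ndarray,
                             grads: dict) -> np.ndarray:
        """Backprop dlogits through the stack; returns gradient w.r.t. H."""
        n_layers = self.n_classifier_layers
        delta = dlogits
        for i in range(n_layers - 1, -1, -1):
            A_prev = cache["As"][i]
            grads[f"V{i}"] = grads.get(f"V{i}", 0) + A_prev.T @ delta
            grads[f"c{i}"] = grads.get(f"c{i}", 0) + delta.sum(axis=0)
            dA = delta @ self.params[f"V{i}"].T
            if i > 0:
                d = cache["drops"][i - 1]
                if d is not None:
                    dA = dA * d
                delta = dA * _relu_grad(cache["Zs"][i - 1])
            else:
                delta = dA
        return delta  # dL/dH

    def loss_and_grads(self, Xa: np.ndarray, Xb: np.ndarray, y_onehot: np.ndarray,
                       lam: float, training: bool = True,
                       rng: Optional[np.random.Generator] = None) -> tuple:
        """Joint objective and exact gradients for every parameter.

        Returns (lpri, laux, total, grads).
        """
        cache = self.forward(Xa, Xb, training=training, rng=rng)
        lpri, laux, total = self.losses(cache, y_onehot, lam)
        K = Xa.shape[0]
        _, dact = ACTIVATIONS[self.activation]
        grads: dict = {}

        dlogits = (cache["probs"] - y_onehot) / K
        dH = self._classifier_backward(cache, dlogits, grads)
        dCa = dH[:, : self.p].copy()
        dCb = dH[:, self.p:].copy()

        Ca, Cb, Cb_hat = cache["Ca"], cache["Cb"], cache["Cb_hat"]
        # auxiliary MSE term: R = Cb_hat - Cb, L_aux = mean(R^2)
        R = Cb_hat - Cb
        g = 2.0 * R / R.size
        if self.vector_transfer:
            grads["alpha"] = lam * (g * Ca).sum(axis=0)
            grads["beta"] = lam * g.sum(axis=0)
        else:
            grads["alpha"] = np.asarray(lam * (g * Ca).sum())
            grads["beta"] = np.asarray(lam * g.sum())
        dCa += lam * g * self.params["alpha"]
        dCb += -lam * g

        dZb = dCb * dact(cache["Zb"])
        grads["W2"] = (Xb.T @ dZb) * self.mask_b
        grads["b2"] = dZb.sum(axis=0)
        dZa = dCa * dact(cache["Za"])
        grads["W1"] = (Xa.T @ dZa) * self.mask_a
        grads["b1"] = dZa.sum(axis=0)
        return lpri, laux, total, grads

    # ----------------------------------------------------- attribution hooks
    def logit_input_gradients(self, Xa: np.ndarray, Xb: Optional[np.ndarray],
                              target_class: int) -> tuple:
        """Gradient of the target-class logit w.r.t. the raw inputs.

        Returns (F, dXa, dXb) where F is the per-sample logit value and dXb
        is None in single-modality mode (the B latent is then a function of
        Xa and its gradient is folded into dXa through the transfer).
        """
        cache = self.forward(Xa, Xb, training=False)
        K = Xa.shape[0]
        _, dact = ACTIVATIONS[self.activation]
        dlogits = np.zeros_like(cache["logits"])
        dlogits[:, target_class] = 1.0
        grads: dict = {}
        dH = self._classifier_backward(cache, dlogits, grads)
        dCa = dH[:, : self.p].copy()
        dCb = dH[:, self.p:]
        dXb = None
        if cache["single"]:
            dCa += dCb * self.params["alpha"]
        else:
            dZb = dCb * dact(cache["Zb"])
            dXb = dZb @ (self.params["W2"] * self.mask_b).T
        dZa = dCa * dact(cache["Za"])
        dXa = dZa @ (self.params["W1"] * self.mask_a).T
        F = cache["logits"][:, target_class]
        return F, dXa, dXb

    def logit_latent_gradients(self, H: np.ndarray, target_class: int) -> tuple:
        """Gradient of the target-class logit w.r.t. the concatenated latent layer."""
        cache = self.classifier_forward(H, training=False)
        cache["As"][0] = H
        dlogits = np.zeros_like(cache["logits"])
        dlogits[:, target_class] = 1.0
        grads: dict = {}
        dH = self._classifier_backward(cache, dlogits, grads)
        return cache["logits"][:, target_class], dH

    def logit_gate_gradients(self, Xa: np.ndarray, Xb: np.ndarray,
                             target_class: int, gate: float) -> tuple:
        """Per-sample gradient of the target logit w.r.t. per-edge gate variables.

        Every permitted edge (i, j) of either mask is multiplied by a shared
        gate value ``gate`` (an interpolation point between 0 = edge absent
        and 1 = edge present).  Returns (F, Ga, Gb) with Ga of shape
        (samples, n_a, p) and Gb of shape (samples, n_b, p); entries at
        mask-zero positions are exactly zero.
        """
        act, dact = ACTIVATIONS[self.activation]
        Wa = self.params["W1"] * self.mask_a
        Wb = self.params["W2"] * self.mask_b
        Za = Xa @ (Wa * gate) + self.params["b1"]
        Zb = Xb @ (Wb * gate) + self.params["b2"]
        Ca, Cb = act(Za), act(Zb)
        H = np.concatenate([Ca, Cb], axis=1)
        cache = self.classifier_forward(H, training=False)
        dlogits = np.zeros_like(cache["logits"])
        dlogits[:, target_class] = 1.0
        grads: dict = {}
        dH = self._classifier_backward(cache, dlogits, grads)
        dZa = dH[:, : self.p] * dact(Za)
        dZb = dH[:, self.p:] * dact(Zb)
        # dF/dgate_{i,j} per sample k:  X[k,i] * W_eff[i,j] * dF/dZ[k,j]
        Ga = Xa[:, :, None] * Wa[None, :, :] * dZa[:, None, :]
        Gb = Xb[:, :, None] * Wb[None, :, :] * dZb[:, None, :]
        F = cache["logits"][:, target_class]
        return F, Ga, Gb

    # ------------------------------------------------------------- utilities
    def copy_params(self) -> dict:
        return {k: np.array(v, copy=True) for k, v in self.params.items()}

    def set_params_arrays(self, params: dict) -> None:
        for k in self.params:
            self.params[k] = np.array(params[k], copy=True)
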