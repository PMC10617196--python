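"""Integrated-gradients attribution for inputs, latent genes, and prior edges.

Integrated gradients assign feature i the share

    IG_i(x) = (x_i - x'_i) * integral_0^1  dF/dx_i (x' + t (x - x'))  dt

of the change in model output between a baseline x' and the input x.  The
integral is approximated by a midpoint Riemann sum, which satisfies the
completeness identity  sum_i IG_i ~= F(x) - F(x')  with error vanishing as
the number of steps grows.

Edge (link) importance is obtained by gate augmentation: every permitted
edge of a prior mask is multiplied by a gate variable fixed at 1, and IG is
computed with respect to the gate vector against a baseline of 0 (edge
absent).  This converts the presence of an edge into an input that the
attribution integral applies to.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .masks import BipartiteMask
from .model import BioDropClassifier


def integrated_gradients(grad_fn: Callable, x: np.ndarray,
                         baseline: Optional[np.ndarray] = None,
                         n_steps: int = 50) -> np.ndarray:
    """Midpoint-rule integrated gradients for a batch of inputs.

    Parameters
    ----------
    grad_fn : callable
        Maps a batch (samples x features) to ``(F, dF/dx)`` with F of shape
        (samples,) and the gradient of the batch's shape.
    x : ndarray (samples x features)
    baseline : ndarray or None
        Per-feature baseline x'; defaults to the zero vector (the cohort
        mean in standardized space).
    n_steps : int

    Returns per-sample attributions with the shape of ``x``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    x = np.asarray(x, float)
    baseline = np.zeros_like(x) if baseline is None else np.broadcast_to(
        np.asarray(baseline, float), x.shape)
    diff = x - baseline
    total = np.zeros_like(x)
    for i in range(n_steps):
        t = (i + 0.5) / n_steps
        _, g = grad_fn(baseline + t * diff)
        total += g
    return diff * (total / n_steps)


def completeness_gap(grad_fn: Callable, x: np.ndarray,
                     baseline: Optional[np.ndarray] = None,
                     n_steps: int = 200) -> tuple:
    """Return (sum of attributions, F(x) - F(x')) per sample."""
    x = np.asarray(x, float)
    baseline = np.zeros_like(x) if baseline is None else np.broadcast_to(
        np.asarray(baseline, float), x.shape)
    attr = integrated_gradients(grad_fn, x, baseline, n_steps)
    Fx, _ = grad_fn(x)
    F0, _ = grad_fn(baseline)
    return attr.sum(axis=1), Fx - F0


def _ids_from_mask(mask, prefix: str, n: int, which: str) -> list:
    if isinstance(mask, BipartiteMask):
        return list(mask.input_ids if which == "input" else mask.latent_ids)
    return [f"{prefix}{i}" for i in range(n)]


def node_importance(model: BioDropClassifier, Xa: np.ndarray, Xb: np.ndarray,
                    target_class, n_steps: int = 50,
                    baseline_a: Optional[np.ndarray] = None,
                    baseline_b: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Mean absolute IG score per input feature and per latent gene.

    Input-node attributions target the class's pre-softmax logit with
    respect to the raw inputs; latent-node attributions apply IG to the
    classifier sub-network at the concatenated latent layer.  Scores are
    mean absolute per-sample attributions over the supplied (evaluation)
    samples.  Returns a rank table with columns feature_id, layer, class,
    score, rank (rank 1 = most important, per layer).
    """
    net = model.net_
    Xa, Xb = np.asarray(Xa, float), np.asarray(Xb, float)
    ci = list(model.classes_).index(target_class)

    X = np.concatenate([Xa, Xb], axis=1)
    na = Xa.shape[1]
    base = None
    if baseline_a is not None or baseline_b is not None:
        base = np.concatenate([
            np.zeros(na) if baseline_a is None else np.asarray(baseline_a, float),
            np.zeros(Xb.shape[1]) if baseline_b is None else np.asarray(baseline_b, float)])

    def grad_inputs(batch):
        F, dXa, dXb = net.logit_input_gradients(batch[:, :na], batch[:, na:], ci)
        return F, np.concatenate([dXa, dXb], axis=1)

    attr_inputs = integrated_gradients(grad_inputs, X, base, n_steps)
    input_scores = np.abs(attr_inputs).mean(axis=0)

    cache = net.forward(Xa, Xb, training=False)
    H = cache["H"]

    def grad_latent(batch):
        return net.logit_latent_gradients(batch, ci)

    attr_latent = integrated_gradients(grad_latent, H, None, n_steps)
    # a latent gene appears once per encoder; sum the two blocks per gene
    latent_scores = (np.abs(attr_latent[:, :net.p]) +
                     np.abs(attr_latent[:, net.p:])).mean(axis=0)

    ids_a = _ids_from_mask(model.mask_a, "a", na, "input")
    ids_b = _ids_from_mask(model.mask_b, "b", Xb.shape[1], "input")
    ids_g = _ids_from_mask(model.mask_a, "g", net.p, "latent")

    rows = []
    for layer, ids, scores in (("input_a", ids_a, input_scores[:na]),
                               ("input_b", ids_b, input_scores[na:]),
                               ("latent", ids_g, latent_scores)):
        order = np.argsort(-scores, kind="stable")
        rank = np.empty(len(ids), dtype=int)
        rank[order] = np.arange(1, len(ids) + 1)
        for i, fid in enumerate(ids):
            rows.append({"feature_id": fid, "layer": layer,
                         "class": target_class, "score": float(scores[i]),
                         "rank": int(rank[i])})
    df = pd.DataFrame(rows)
    return df.sort_values(["layer", "rank"]).reset_index(drop=True)


def link_importance(model: BioDropClassifier, Xa: np.ndarray, Xb: np.ndarray,
                    target_class, n_steps: int = 50,
                    network_names: Sequence[str] = ("A", "B")) -> pd.DataFrame:
    """Mean absolute IG score per permitted prior-network edge.

    IG runs over per-edge gate variables (baseline 0 = edge absent,
    input 1 = edge present) against the class's pre-softmax logit, then
    averages absolute per-sample attributions.  Only mask-one edges are
    scored.  Returns columns source, target, network, class, score, rank.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    net = model.net_
    Xa, Xb = np.asarray(Xa, float), np.asarray(Xb, float)
    ci = list(model.classes_).index(target_class)

    acc_a = np.zeros((Xa.shape[0],) + net.mask_a.shape)
    acc_b = np.zeros((Xb.shape[0],) + net.mask_b.shape)
    for i in range(n_steps):
        t = (i + 0.5) / n_steps
        _, Ga, Gb = net.logit_gate_gradients(Xa, Xb, ci, gate=t)
        acc_a += Ga
        acc_b += Gb
    # gate path length is 1 - 0, so IG = mean gradient over steps
    score_a = np.abs(acc_a / n_steps).mean(axis=0)
    score_b = np.abs(acc_b / n_steps).mean(axis=0)

    ids = {
        "A": (_ids_from_mask(model.mask_a, "a", net.mask_a.shape[0], "input"),
              _ids_from_mask(model.mask_a, "g", net.p, "latent")),
        "B": (_ids_from_mask(model.mask_b, "b", net.mask_b.shape[0], "input"),
              _ids_from_mask(model.mask_b, "g", net.p, "latent")),
    }
    rows = []
    for name, mask, scores, key in ((network_names[0], net.mask_a, score_a, "A"),
                                    (network_names[1], net.mask_b, score_b, "B")):
        src_ids, tgt_ids = ids[key]
        for i, j in zip(*np.nonzero(mask)):
            rows.append({"source": src_ids[i], "target": tgt_ids[j],
                         "network": name, "class": target_class,
                         "score": float(scores[i, j])})
    df = pd.DataFrame(rows)
    df = df.sort_values(["score", "source", "target"],
                        ascending=[False, True, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def edge_score(model: BioDropClassifier, Xa, Xb, target_class, source, target,
               network: str = "A", n_steps: int = 50) -> float:
    """Score of one permitted edge; rejects mask-zero positions."""
    df = link_importance(model, Xa, Xb, target_class, n_steps=n_steps)
    hit = df[(df["source"] == source) & (df["target"] == target)]
    if hit.empty:
        raise ValueError(
            f"edge ({source!r} -> {target!r}) is not a permitted (mask-one) edge")
    return float(hit["score"].iloc[0])


def top_link_genes(link_scores: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Genes touched by the top fraction of edges ranked by importance.

    Takes ceil(fraction * n_edges) edges from the top of the ranking (score
    descending, ties broken by (source, target) lexicographic order) and
    returns the distinct latent genes they reach with the count of
    prioritized incident links per gene.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if link_scores.empty:
        raise ValueError("empty link-score table")
    df = link_scores.sort_values(["score", "source", "target"],
                                 ascending=[False, True, True], kind="stable")
    n_top = math.ceil(fraction * len(df))
    top = df.head(n_top)
    counts = top.groupby("target").size().rename("n_prioritized_links")
    out = counts.reset_index().rename(columns={"target": "gene"})
    return out.sort_values(["n_prioritized_links", "gene"],
                           ascending=[False, True]).reset_index(drop=True)
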