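"""Input pipeline: univariate selection, prior intersection, scaling, SMOTE.

All statistics (selection p-values, scaler moments, SMOTE neighborhoods) are
fitted on training samples only; the fitted objects record what they were
fitted on so a pipeline audit can verify the absence of test-set leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.neighbors import NearestNeighbors


@dataclass
class SelectionResult:
    """Outcome of univariate feature selection on one modality."""

    kept: list
    p_values: dict
    alpha: float
    test_name: str
    n_fit_samples: int
    dropped_constant: list = field(default_factory=list)


def select_features(X: np.ndarray, feature_ids: Sequence[str], labels,
                    test: str = "auto", alpha: float = 0.05,
                    bh_correct: bool = False) -> SelectionResult:
    """Keep features whose mean differs between classes at level alpha.

    Two classes use Welch's two-sample t-test; three or more use a one-way
    ANOVA F-test.  Constant features are dropped before testing.  An
    optional Benjamini-Hochberg correction is off by default.
    Must be fitted on training samples only.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    feature_ids = list(feature_ids)
    classes = np.unique(labels)
    if test == "auto":
        test = "t" if len(classes) == 2 else "anova"
    if test == "t" and len(classes) != 2:
        raise ValueError("t-test requires exactly 2 classes")
    groups_idx = [labels == c for c in classes]

    const = X.std(axis=0) == 0
    dropped_constant = [f for f, c in zip(feature_ids, const) if c]
    pvals = {}
    for j, fid in enumerate(feature_ids):
        if const[j]:
            continue
        groups = [X[g, j] for g in groups_idx]
        if test == "t":
            _, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        else:
            _, p = stats.f_oneway(*groups)
        pvals[fid] = float(p) if np.isfinite(p) else 1.0

    ids = list(pvals)
    ps = np.array([pvals[f] for f in ids])
    if bh_correct and len(ps):
        order = np.argsort(ps)
        ranked = ps[order] * len(ps) / (np.arange(len(ps)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        qs = np.empty_like(ps)
        qs[order] = np.minimum(adj, 1.0)
        keep_mask = qs < alpha
    else:
        keep_mask = ps < alpha
    kept = [f for f, k in zip(ids, keep_mask) if k]
    if not kept:
        raise ValueError(
            f"feature selection removed every feature at alpha={alpha}; "
            "consider a larger alpha")
    return SelectionResult(kept=kept, p_values=pvals, alpha=alpha,
                           test_name="t-test" if test == "t" else "ANOVA",
                           n_fit_samples=X.shape[0],
                           dropped_constant=dropped_constant)


def intersect_with_priors(selected_a: Iterable[str], selected_b: Iterable[str],
                          edges_a: Iterable[tuple], edges_b: Iterable[tuple]) -> tuple:
    """Restrict features and edges to the gene set shared by both networks.

    The latent gene layer is the intersection of the two networks' target
    sets; input features survive only if selected and wired into that shared
    set.  All identifier lists come back lexicographically sorted, and edge
    lists sorted, so downstream orderings are deterministic.

    Returns (features_a, features_b, latent_genes, edges_a, edges_b).
    """
    edges_a, edges_b = list(edges_a), list(edges_b)
    targets_a = {t for _, t in edges_a}
    targets_b = {t for _, t in edges_b}
    shared = targets_a & targets_b
    if not shared:
        raise ValueError(
            f"the two prior networks share no target genes "
            f"(network A has {len(targets_a)} targets, network B {len(targets_b)})")
    sel_a, sel_b = set(selected_a), set(selected_b)
    ea = sorted({(s, t) for s, t in edges_a if s in sel_a and t in shared})
    eb = sorted({(s, t) for s, t in edges_b if s in sel_b and t in shared})
    feats_a = sorted({s for s, _ in ea})
    feats_b = sorted({s for s, _ in eb})
    latent = sorted({t for _, t in ea} | {t for _, t in eb})
    return feats_a, feats_b, latent, ea, eb


@dataclass
class ScalerState:
    """Fitted per-feature scaling statistics.

    kind='standard' stores mean/sd (population sd, ddof=0); 'minmax' stores
    min/max; 'log' is the stateless log1p transform.  Constant features
    under minmax map to 0 (flagged); under standard they are centered and
    left unscaled.
    """

    kind: str
    mean: Optional[np.ndarray] = None
    scale: Optional[np.ndarray] = None
    min: Optional[np.ndarray] = None
    max: Optional[np.ndarray] = None
    constant: Optional[np.ndarray] = None
    n_fit_samples: int = 0
    fitted: bool = False


def fit_scaler(X: np.ndarray, kind: str = "standard") -> ScalerState:
    """Fit scaling statistics on the training partition only."""
    X = np.asarray(X, float)
    if kind == "standard":
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        const = sd == 0
        sd = np.where(const, 1.0, sd)
        return ScalerState("standard", mean=mu, scale=sd, constant=const,
                           n_fit_samples=X.shape[0], fitted=True)
    if kind == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        const = hi == lo
        return ScalerState("minmax", min=lo, max=hi, constant=const,
                           n_fit_samples=X.shape[0], fitted=True)
    if kind == "log":
        if (X < 0).any():
            raise ValueError("log scaling requires non-negative values")
        return ScalerState("log", n_fit_samples=X.shape[0], fitted=True)
    raise ValueError(f"unknown scaler kind {kind!r}")


def apply_scaler(X: np.ndarray, state: ScalerState) -> np.ndarray:
    if not state.fitted:
        raise ValueError("scaler must be fitted before transform")
    X = np.asarray(X, float)
    if state.kind == "standard":
        return (X - state.mean) / state.scale
    if state.kind == "minmax":
        span = np.where(state.constant, 1.0, state.max - state.min)
        out = (X - state.min) / span
        return np.where(state.constant, 0.0, out)
    if (X < 0).any():
        raise ValueError("log scaling requires non-negative values")
    return np.log1p(X)


def invert_scaler(Z: np.ndarray, state: ScalerState) -> np.ndarray:
    """Inverse transform (standard and minmax only)."""
    if not state.fitted:
        raise ValueError("scaler must be fitted before inverse transform")
    Z = np.asarray(Z, float)
    if state.kind == "standard":
        return Z * state.scale + state.mean
    if state.kind == "minmax":
        span = np.where(state.constant, 1.0, state.max - state.min)
        return Z * span + state.min
    return np.expm1(Z)


def smote_oversample(X: np.ndarray, labels, k_neighbors: int = 5,
                     seed: int = 0) -> tuple:
    """Synthetic minority oversampling to the majority-class count.

    Each synthetic sample is  x_i + u * (x_nn - x_i)  with u ~ Uniform(0, 1)
    and x_nn drawn among the k nearest same-class neighbors of x_i.  Apply
    to the training partition only, on the concatenated per-sample feature
    vector, so paired modalities stay consistent; re-split by modality
    afterwards.  Already balanced input comes back unchanged.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    if np.all(counts == target):
        return X.copy(), labels.copy()
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [labels]
    for c, n in zip(classes, counts):
        deficit = target - n
        if deficit == 0:
            continue
        if n <= k_neighbors:
            raise ValueError(
                f"class {c!r} has {n} samples, not enough for "
                f"k_neighbors={k_neighbors}")
        Xc = X[labels == c]
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # column 0 is the point itself
        base = rng.integers(0, n, size=deficit)
        pick = rng.integers(1, k_neighbors + 1, size=deficit)
        u = rng.random(deficit)
        parents = Xc[base]
        neighbors = Xc[idx[base, pick]]
        synth = parents + u[:, None] * (neighbors - parents)
        new_X.append(synth)
        new_y.append(np.full(deficit, c, dtype=labels.dtype))
    return np.concatenate(new_X, axis=0), np.concatenate(new_y)
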