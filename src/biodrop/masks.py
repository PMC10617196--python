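"""Bipartite prior-network masks.

A mask encodes which input features (SNPs or transcription factors) are
allowed to feed which latent genes in the first, biologically sparsified
layer of the network.  An eQTL network gives SNP -> gene edges; a gene
regulatory network gives TF -> target-gene edges.  The mask entries are the
fixed zero pattern of a DropConnect layer: a weight at a zero position never
contributes to the forward pass and never receives gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class MaskError(ValueError):
    """Raised when an edge list cannot produce a usable mask."""


@dataclass
class BipartiteMask:
    """Binary input-feature x latent-feature connectivity matrix.

    Parameters
    ----------
    matrix : ndarray of shape (n_inputs, n_latents)
        Entries in {0, 1}.
    input_ids : list of str
        Ordered input-feature identifiers (SNPs or TFs), one per row.
    latent_ids : list of str
        Ordered latent-feature identifiers (target genes), one per column.
    """

    matrix: np.ndarray
    input_ids: list = field(default_factory=list)
    latent_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise MaskError("mask matrix must be 2-dimensional")
        if self.matrix.shape != (len(self.input_ids), len(self.latent_ids)):
            raise MaskError(
                f"mask shape {self.matrix.shape} does not match id lists "
                f"({len(self.input_ids)} x {len(self.latent_ids)})"
            )
        vals = np.unique(self.matrix)
        if not np.all(np.isin(vals, (0, 1))):
            raise MaskError("mask entries must be 0 or 1")
        if len(set(self.input_ids)) != len(self.input_ids):
            raise MaskError("duplicate input_ids in mask")
        if len(set(self.latent_ids)) != len(self.latent_ids):
            raise MaskError("duplicate latent_ids in mask")
        self.matrix = self.matrix.astype(np.float64)
        # no self-loops: an id present on both sides may not connect to itself
        common = set(self.input_ids) & set(self.latent_ids)
        for ident in common:
            i = self.input_ids.index(ident)
            j = self.latent_ids.index(ident)
            if self.matrix[i, j] != 0:
                raise MaskError(f"self-loop on identifier {ident!r}")

    @property
    def shape(self) -> tuple:
        return self.matrix.shape

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum())

    def edges(self) -> list:
        """Return the (input_id, latent_id) pairs present in the mask."""
        rows, cols = np.nonzero(self.matrix)
        return [(self.input_ids[i], self.latent_ids[j]) for i, j in zip(rows, cols)]

    @classmethod
    def full(cls, input_ids: Sequence[str], latent_ids: Sequence[str]) -> "BipartiteMask":
        """All-ones fallback mask for datasets with no usable prior network.

        Identifiers shared between the two sides keep a zero at their own
        position (no self-loop).
        """
        input_ids = list(input_ids)
        latent_ids = list(latent_ids)
        m = np.ones((len(input_ids), len(latent_ids)))
        lat_index = {g: j for j, g in enumerate(latent_ids)}
        for i, ident in enumerate(input_ids):
            j = lat_index.get(ident)
            if j is not None:
                m[i, j] = 0.0
        return cls(m, input_ids, latent_ids)


def build_mask(
    edges: Iterable[tuple],
    input_ids: Sequence[str],
    latent_ids: Sequence[str],
) -> BipartiteMask:
    """Tabulate an edge list into a binary mask over given identifier universes.

    Duplicate edges collapse to a single 1.  Edges with an endpoint outside
    the supplied universes are dropped (a count is logged).  An edge whose two
    endpoints are the same identifier would be a self-loop and is dropped:
    multi-level chains such as S1 -> S2 -> T1 are represented as the two
    separate edges (S1, S2) and (S2, T1), with S2 appearing both as an input
    and as a latent feature.

    Raises
    ------
    MaskError
        If no edge survives filtering.  The message distinguishes an empty
        input list from an identifier mismatch.
    """
    input_ids = list(input_ids)
    latent_ids = list(latent_ids)
    edges = list(edges)
    row = {s: i for i, s in enumerate(input_ids)}
    col = {t: j for j, t in enumerate(latent_ids)}
    matrix = np.zeros((len(input_ids), len(latent_ids)))
    n_dropped = 0
    n_self = 0
    for s, t in edges:
        if s == t:
            n_self += 1
            continue
        i = row.get(s)
        j = col.get(t)
        if i is None or j is None:
            n_dropped += 1
            continue
        matrix[i, j] = 1.0
    if n_dropped:
        logger.info("build_mask: dropped %d edges with endpoints outside the universes", n_dropped)
    if n_self:
        logger.info("build_mask: dropped %d self-loop edges", n_self)
    if matrix.sum() == 0:
        if not edges:
            raise MaskError("no edges retained: input edge list is empty")
        raise MaskError(
            f"no edges retained: all {len(edges)} edges were dropped "
            "(endpoints absent from the identifier universes or self-loops); "
            "check that edge-list identifiers match the feature/gene lists"
        )
    return BipartiteMask(matrix, input_ids, latent_ids)
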