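"""File formats, containers, model checkpoints, and run manifests.

Matrices travel as delimited text: first column sample ID, header row of
feature IDs, comma or tab separated (auto-detected).  Edge lists are
two-column files with a ``source,target`` header (extra columns ignored).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .masks import BipartiteMask

FORMAT_VERSION = 1


@dataclass
class ModalityMatrix:
    """Samples x features numeric matrix with identifiers and a modality tag."""

    values: np.ndarray
    sample_ids: list
    feature_ids: list
    modality_tag: str = "A"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("values shape does not match id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)

    def subset_features(self, keep: Sequence[str]) -> "ModalityMatrix":
        keep = list(keep)
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in keep]
        return ModalityMatrix(self.values[:, idx], list(self.sample_ids),
                              keep, self.modality_tag)

    def reorder_samples(self, order: Sequence[str]) -> "ModalityMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in order]
        return ModalityMatrix(self.values[idx], list(order),
                              list(self.feature_ids), self.modality_tag)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_matrix(path, modality_tag: str = "A") -> ModalityMatrix:
    """Read a sample x feature matrix; comma and tab dialects parse identically."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID {dup!r} in {path}")
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                i = int(np.where(coerced.isna())[0][0])
                raise ValueError(
                    f"non-numeric cell at row {df.index[i]!r}, column {col!r} in {path}"
                ) from exc
        raise
    return ModalityMatrix(values, [str(s) for s in df.index],
                          [str(f) for f in df.columns], modality_tag)


def write_matrix(mat: ModalityMatrix, path, sep: str = ",") -> None:
    df = mat.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format="%.10g")


def read_edges(path) -> list:
    """Read an edge list with a source,target header; blank lines skipped."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, skip_blank_lines=True)
    cols = [c.strip().lower() for c in df.columns]
    if "source" not in cols or "target" not in cols:
        raise ValueError(
            f"edge list {path} must have a header with columns source,target")
    s = df.columns[cols.index("source")]
    t = df.columns[cols.index("target")]
    return [(str(a), str(b)) for a, b in zip(df[s], df[t])]


def write_edges(edges: Sequence[tuple], path, sep: str = ",") -> None:
    df = pd.DataFrame(edges, columns=["source", "target"])
    df.to_csv(path, sep=sep, index=False)


def read_labels(path) -> pd.Series:
    """Read a (sample ID, label) file; returns labels indexed by sample ID."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"label file {path} must have exactly one label column")
    ser = df.iloc[:, 0].astype(str)
    ser.index = ser.index.astype(str)
    if ser.index.has_duplicates:
        raise ValueError(f"duplicate sample IDs in label file {path}")
    return ser


def write_labels(labels: pd.Series, path, sep: str = ",") -> None:
    df = labels.rename("label").to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


# ----------------------------------------------------------------- checkpoint
def save_model(model, path) -> None:
    """Serialize a fitted BioDropClassifier to one .npz checkpoint file."""
    from .model import BioDropClassifier  # deferred to avoid a cycle

    if not isinstance(model, BioDropClassifier):
        raise TypeError("save_model expects a BioDropClassifier")
    net = model.net_
    meta = {
        "format_version": FORMAT_VERSION,
        "classes": [str(c) for c in model.classes_],
        "hidden_sizes": list(net.hidden_sizes),
        "n_classes": net.n_classes,
        "dropout_rate": net.dropout_rate,
        "activation": net.activation,
        "vector_transfer": net.vector_transfer,
        "estimator_params": {
            k: v for k, v in model.get_params().items()
            if k not in ("mask_a", "mask_b") and _jsonable(v)
        },
        "mask_a_ids": _mask_ids(model.mask_a),
        "mask_b_ids": _mask_ids(model.mask_b),
    }
    arrays = {f"param_{k}": v for k, v in net.params.items()}
    arrays["mask_a"] = net.mask_a
    arrays["mask_b"] = net.mask_b
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _jsonable(v):
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _mask_ids(mask) -> Optional[dict]:
    if isinstance(mask, BipartiteMask):
        return {"input_ids": list(mask.input_ids), "latent_ids": list(mask.latent_ids)}
    return None


def load_model(path):
    """Load a checkpoint back into a fitted BioDropClassifier."""
    from .model import BioDropClassifier
    from .nn import MaskedDualNet

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        if meta["format_version"] != FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        mask_a_arr, mask_b_arr = z["mask_a"], z["mask_b"]
        params = {k[len("param_"):]: z[k] for k in z.files if k.startswith("param_")}

    def rebuild(arr, ids):
        if ids is None:
            return arr
        return BipartiteMask(arr, ids["input_ids"], ids["latent_ids"])

    mask_a = rebuild(mask_a_arr, meta["mask_a_ids"])
    mask_b = rebuild(mask_b_arr, meta["mask_b_ids"])
    est = BioDropClassifier(mask_a=mask_a, mask_b=mask_b,
                            **meta["estimator_params"])
    net = MaskedDualNet(
        mask_a_arr, mask_b_arr, hidden_sizes=meta["hidden_sizes"],
        n_classes=meta["n_classes"], dropout_rate=meta["dropout_rate"],
        activation=meta["activation"], vector_transfer=meta["vector_transfer"])
    net.set_params_arrays(params)
    est.net_ = net
    est.classes_ = np.array(meta["classes"])
    est.n_features_in_ = mask_a_arr.shape[0] + mask_b_arr.shape[0]
    est.best_epoch_ = -1
    return est


# ------------------------------------------------------------------- manifest
def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one CLI run.

    The run id is a deterministic digest of the command, config, seed, and
    input digests, so two identical runs produce byte-identical manifests;
    a wall-clock timestamp is recorded only on request.
    """

    command: str
    seed: int
    config: dict
    inputs: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    package_version: str = "0.1.0"
    timestamp: Optional[str] = None

    def run_id(self) -> str:
        payload = json.dumps({"command": self.command, "seed": self.seed,
                              "config": self.config, "inputs": self.inputs},
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, path) -> None:
        doc = {"run_id": self.run_id(), "command": self.command,
               "seed": self.seed, "package_version": self.package_version,
               "config": self.config, "inputs": self.inputs,
               "outputs": sorted(self.outputs)}
        if self.timestamp is not None:
            doc["timestamp"] = self.timestamp
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        tmp.replace(path)
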