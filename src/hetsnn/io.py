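"""File formats: spike containers with JSON sidecars, tabular traces,
sparse expression matrices, and checkpoints."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .params import PARAM_FIELDS, NeuronParams, SpikeTrain
from .network import NetworkParams


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating, np.bool_)):
        return x.item()
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def save_spike_dataset(path, spikes: np.ndarray, sidecar: dict, labels: Optional[np.ndarray] = None) -> Path:
    """Write a binary spike container (.npz) with a JSON sidecar.

    The sidecar records shape, dt_label, seed and any ground truth; the
    container holds the (compressed) arrays.
    """
    path = Path(path)
    arrays = {"spikes": np.asarray(spikes)}
    if labels is not None:
        arrays["labels"] = np.asarray(labels)
    np.savez_compressed(path, **arrays)
    npz = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    side = {"shape": list(np.asarray(spikes).shape), **_jsonable(sidecar)}
    npz.with_suffix(".json").write_text(json.dumps(side, indent=1, sort_keys=True))
    return npz


def load_spike_dataset(path) -> Tuple[np.ndarray, Optional[np.ndarray], dict]:
    path = Path(path)
    with np.load(path) as z:
        spikes = z["spikes"]
        labels = z["labels"] if "labels" in z.files else None
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return spikes, labels, sidecar


def save_trace_table(path, current: np.ndarray, spikes: Optional[np.ndarray] = None) -> Path:
    """Wide tabular text: one row per time step, one column per trial."""
    path = Path(path)
    cur = np.atleast_2d(current)
    cols = {f"current_{i}": cur[i] for i in range(cur.shape[0])}
    if spikes is not None:
        sp = np.atleast_2d(spikes)
        cols.update({f"spikes_{i}": sp[i].astype(int) for i in range(sp.shape[0])})
    df = pd.DataFrame(cols)
    df.insert(0, "step", np.arange(cur.shape[1]))
    df.to_csv(path, sep="\t", index=False)
    return path


def load_trace_table(path) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    df = pd.read_csv(path, sep="\t")
    cur = df[[c for c in df.columns if c.startswith("current_")]].to_numpy().T
    sp_cols = [c for c in df.columns if c.startswith("spikes_")]
    spikes = df[sp_cols].to_numpy().T if sp_cols else None
    return cur, spikes


def save_expression_mtx(out_prefix, counts: np.ndarray, labels: np.ndarray, type_names=None) -> Path:
    """MatrixMarket counts (cells x genes) plus labels and index CSVs."""
    out_prefix = Path(out_prefix)
    mtx = out_prefix.with_suffix(".mtx")
    spio.mmwrite(str(mtx), sparse.csr_matrix(counts))
    names = type_names or [f"type_{c}" for c in np.unique(labels)]
    pd.DataFrame({"cell": np.arange(len(labels)), "cell_type": [names[c] for c in labels]}).to_csv(
        out_prefix.parent / (out_prefix.name + "_labels.csv"), index=False
    )
    pd.DataFrame({"gene": [f"g{j}" for j in range(counts.shape[1])]}).to_csv(
        out_prefix.parent / (out_prefix.name + "_genes.csv"), index=False
    )
    return mtx


def load_expression_mtx(out_prefix) -> Tuple[np.ndarray, np.ndarray]:
    out_prefix = Path(out_prefix)
    counts = np.asarray(spio.mmread(str(out_prefix.with_suffix(".mtx"))).todense())
    lab = pd.read_csv(out_prefix.parent / (out_prefix.name + "_labels.csv"))
    codes = pd.Categorical(lab["cell_type"]).codes
    return counts, np.asarray(codes)


def save_checkpoint(path, params: NetworkParams, config: dict, history: Optional[pd.DataFrame] = None) -> Path:
    """Single-file archive of weights + biophysics + resolved config."""
    path = Path(path)
    arrays = {}
    for l, w in enumerate(params.W):
        arrays[f"W_{l}"] = w
    for l, a in enumerate(params.alphas):
        for f in PARAM_FIELDS:
            arrays[f"alpha_{l}_{f}"] = getattr(a, f)
    np.savez_compressed(path, **arrays)
    npz = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    manifest = {"config": _jsonable(config), "n_layers": len(params.W)}
    if history is not None:
        manifest["history"] = json.loads(history.to_json(orient="split"))
    npz.with_suffix(".json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return npz


def load_checkpoint(path) -> Tuple[NetworkParams, dict]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        n = manifest["n_layers"]
        W = [z[f"W_{l}"] for l in range(n)]
        alphas = [NeuronParams(**{f: z[f"alpha_{l}_{f}"] for f in PARAM_FIELDS}) for l in range(n)]
    return NetworkParams(W, alphas), manifest


def digest(obj) -> str:
    """Stable sha256 digest of an array, file path, or JSON-able object."""
    h = hashlib.sha256()
    if isinstance(obj, (str, Path)) and Path(obj).is_file():
        h.update(Path(obj).read_bytes())
    elif isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
        h.update(str(obj.shape).encode())
    else:
        h.update(json.dumps(_jsonable(obj), sort_keys=True).encode())
    return h.hexdigest()
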