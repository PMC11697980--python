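"""High-level run recipes with reproducible manifests.

These functions are the package's end-to-end entry points (generate
fixtures, train, fit a neuron to traces, evaluate a checkpoint).  Every run
writes a RunManifest — the resolved configuration, the run seed, input
digests and output paths — from which :func:`reproduce` re-executes the run
and must obtain bit-identical histories and reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .params import NeuronParams, SurrogateSpec
from .network import NetworkSpec, encode_static, forward, spike_histograms
from .bilevel import BilevelConfig, FitConfig, fit_single_neuron, hifi_train
from .metrics import classification_report, dense_mac_count, energy_estimate, generation_mse, similarity_report
from .synthetic import FixtureSpec, generate
from .io import digest, load_checkpoint, save_checkpoint, save_spike_dataset, _jsonable


def _write_manifest(out_dir: Path, kind: str, config: dict, inputs: dict, outputs: dict) -> dict:
    manifest = {
        "kind": kind,
        "package_version": __version__,
        "config": _jsonable(config),
        "input_digests": {k: digest(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_fixtures(spec: FixtureSpec, out_dir) -> dict:
    """Generate a fixture to disk (container + sidecar) with a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = generate(spec)
    if spec.kind == "neuron-trace":
        currents, spikes, sidecar = result
        path = save_spike_dataset(out_dir / "trace.npz", spikes.spikes, sidecar)
        np.savetxt(out_dir / "currents.tsv", currents.T, delimiter="\t")
        outputs = {"container": path, "currents": out_dir / "currents.tsv"}
    elif spec.kind == "temporal-classes":
        X, y, sidecar = result
        sidecar = {k: v for k, v in sidecar.items() if k != "templates"}
        path = save_spike_dataset(out_dir / "temporal.npz", X, sidecar, labels=y)
        outputs = {"container": path}
    elif spec.kind == "expression-matrix":
        from .io import save_expression_mtx

        counts, log1p, y, sidecar = result
        path = save_expression_mtx(out_dir / "expr", counts, y)
        np.savetxt(out_dir / "expr_log1p.tsv", log1p, delimiter="\t")
        outputs = {"mtx": path, "log1p": out_dir / "expr_log1p.tsv"}
    else:
        inputs, templates, sidecar = result
        sidecar = {k: v for k, v in sidecar.items() if k not in ("rates", "latent", "mixing")}
        path = save_spike_dataset(out_dir / "generation.npz", templates, sidecar)
        np.savez_compressed(out_dir / "generation_inputs.npz", inputs=inputs)
        outputs = {"templates": path, "inputs": out_dir / "generation_inputs.npz"}
    cfg = {"kind": spec.kind, "seed": spec.seed, "sizes": spec.sizes, "noise": spec.noise}
    return _write_manifest(out_dir, "fixtures", cfg, {}, outputs)


def run_train(
    spec: NetworkSpec,
    data,
    config: BilevelConfig,
    out_dir,
    homogeneous: bool = False,
    encode: Optional[str] = None,
    train_kwargs: Optional[dict] = None,
) -> dict:
    """Train a network on (features-or-sequences, labels); write checkpoint,
    history and manifest.  ``homogeneous=True`` forces xi2 = 0 (weights-only
    learning, the ablation baseline)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    x, y = data
    x = np.asarray(x, dtype=float)
    if encode:
        x = encode_static(x, spec.time_steps, encode, seed=config.seed)
    cfg = asdict(config)
    if homogeneous:
        cfg["xi2"] = 0.0
        config = BilevelConfig(**{**cfg, "class_weight": config.class_weight})
    train_kwargs = dict(train_kwargs or {})
    result = hifi_train(spec, (x, y), config, **train_kwargs)
    ckpt = save_checkpoint(out_dir / "checkpoint.npz", result.params, cfg, result.history)
    result.history.to_csv(out_dir / "history.csv", index=False)
    run_cfg = {
        "network": {
            "layer_sizes": spec.layer_sizes, "time_steps": spec.time_steps,
            "encoding": spec.encoding, "readout": spec.readout,
            "delayed_interlayer": spec.delayed_interlayer, "leak_slope": spec.leak_slope,
        },
        "bilevel": {k: v for k, v in cfg.items() if k != "class_weight"},
        "homogeneous": homogeneous,
        "encode": encode,
        "train_kwargs": _jsonable({k: v for k, v in train_kwargs.items() if k != "graphs"}),
        "events": result.events,
    }
    manifest = _write_manifest(
        out_dir, "train", run_cfg,
        {"x": np.asarray(data[0], dtype=float), "y": np.asarray(y)},
        {"checkpoint": ckpt, "history": out_dir / "history.csv"},
    )
    return manifest


def reproduce_train(manifest: dict, data) -> pd.DataFrame:
    """Re-execute a training run from its manifest; returns the new history
    (bit-identical to the recorded one for the same inputs)."""
    net = manifest["config"]["network"]
    spec = NetworkSpec(**net)
    bl = dict(manifest["config"]["bilevel"])
    config = BilevelConfig(**bl)
    x, y = data
    x = np.asarray(x, dtype=float)
    if manifest["config"].get("encode"):
        x = encode_static(x, spec.time_steps, manifest["config"]["encode"], seed=config.seed)
    kwargs = manifest["config"].get("train_kwargs") or {}
    result = hifi_train(spec, (x, np.asarray(y)), config, **kwargs)
    return result.history


def run_fit_neuron(
    currents,
    target_spikes,
    init: NeuronParams,
    config: FitConfig,
    out_dir,
    md_windows=(10.0, 20.0),
    dt_label: float = 1.0,
) -> dict:
    """Fit one neuron to (current, spikes) trials and score the reproduction.

    Writes the fitted parameters, the per-window similarity report between
    reproduced and target spike trains, and a manifest.
    """
    from .neuron import simulate_neuron

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = fit_single_neuron(currents, target_spikes, init, config)
    reproduced = [simulate_neuron(np.asarray(c, float).ravel(), result.params).spikes[0] for c in currents]
    targets = [np.asarray(t, float).ravel() for t in target_spikes]
    if len(targets) >= 2:
        rep = similarity_report(reproduced, targets, windows=md_windows, dt_label=dt_label)
        md = {str(k): (None if np.isnan(v) else v) for k, v in rep.md_star.items()}
    else:
        md = {}
    fitted = {f: result.params.as_dict()[f].tolist() for f in result.params.as_dict()}
    report = {
        "fitted_params": fitted,
        "final_loss": result.loss,
        "restart_losses": result.restart_losses.tolist(),
        "silent_fit": result.silent,
        "md_star": md,
    }
    (out_dir / "fit_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    cfg = {k: _jsonable(v) for k, v in asdict(config).items() if k != "surrogate"}
    cfg["init"] = {f: v.tolist() for f, v in init.as_dict().items()}
    manifest = _write_manifest(
        out_dir, "fit-neuron", cfg,
        {"currents": np.stack([np.asarray(c, float).ravel() for c in currents]),
         "targets": np.stack(targets)},
        {"report": out_dir / "fit_report.json"},
    )
    return manifest


def run_evaluate(checkpoint_path, spec: NetworkSpec, data, out_dir, encode: Optional[str] = None, seed: int = 0) -> dict:
    """Evaluate a checkpoint: classification report, energy estimate and
    biophysics histograms; all written as CSV/JSON plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params, _ = load_checkpoint(checkpoint_path)
    x, y = data
    x = np.asarray(x, dtype=float)
    if encode:
        x = encode_static(x, spec.time_steps, encode, seed=seed)
    record = forward(spec, params, x)
    y_pred = np.argmax(record.logits, axis=1)
    report = classification_report(np.asarray(y), y_pred)
    energy = energy_estimate(record, dense_mac_count(spec.layer_sizes))
    hist = spike_histograms(params)
    report["per_class"].to_csv(out_dir / "per_class.csv", index=False)
    report["flow"].to_csv(out_dir / "flow.csv", index=False)
    hist.to_csv(out_dir / "biophysics.csv", index=False)
    summary = {
        "accuracy": report["accuracy"],
        "macro_f1": report["macro_f1"],
        "energy": _jsonable(asdict(energy)),
        "total_spikes": record.total_spikes,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest = _write_manifest(
        out_dir, "evaluate",
        {"checkpoint": str(checkpoint_path), "encode": encode, "seed": seed},
        {"x": x, "y": np.asarray(y), "checkpoint": checkpoint_path},
        {"summary": out_dir / "summary.json", "per_class": out_dir / "per_class.csv"},
    )
    return manifest
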