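"""Evaluation metrics: spike-train similarity, classification reports,
generation error, manifold projection and energy accounting."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix, f1_score

from .params import ContractError, SpikeTrain
from .network import ForwardRecord


# ---------------------------------------------------------------------------
# Bias-corrected spike-train set similarity


@dataclass
class SimilarityReport:
    """M_d* per time-window resolution (windows in nominal ms)."""

    md_star: Dict[float, float]
    dt_label: float
    flags: List[str] = field(default_factory=list)


def _smoothed(trains: Sequence[np.ndarray], window_bins: int) -> np.ndarray:
    arr = np.stack([np.asarray(t, dtype=float).ravel() for t in trains])
    if window_bins > 1:
        arr = uniform_filter1d(arr, size=window_bins, axis=1, mode="constant")
    return arr


def _as_train_list(s) -> List[np.ndarray]:
    if isinstance(s, SpikeTrain):
        return [s.spikes[i] for i in range(s.n_neurons)]
    return [t.spikes.ravel() if isinstance(t, SpikeTrain) else np.asarray(t) for t in s]


def md_star(
    setA,
    setB,
    window: float = 10.0,
    dt_label: float = 1.0,
    flags: Optional[List[str]] = None,
) -> float:
    """Normalized, bias-corrected similarity between two sets of spike trains.

    Each train is boxcar-smoothed over ``window`` (nominal ms, converted to
    bins via ``dt_label``); pairwise similarity is the cosine of smoothed
    trains.  The statistic is the mean cross-set similarity divided by the
    geometric mean of the within-set similarities, with self-pairs excluded
    from the within-set means (bias correction).  When the two sets have the
    same size, index-matched cross pairs are treated as trial-paired and
    excluded as well, so a set compared with an identical copy of itself
    scores exactly 1.  Symmetric in its arguments.  A set whose trains are
    all silent makes the statistic undefined: NaN is returned and a flag
    recorded.
    """
    A = _as_train_list(setA)
    B = _as_train_list(setB)
    if len(A) < 2 or len(B) < 2:
        raise ContractError("bias correction needs >= 2 trains per set")
    bins = max(1, int(round(window / dt_label)))
    ra, rb = _smoothed(A, bins), _smoothed(B, bins)
    flags = flags if flags is not None else []
    na = np.linalg.norm(ra, axis=1)
    nb = np.linalg.norm(rb, axis=1)
    if np.all(na == 0) or np.all(nb == 0):
        flags.append("all-silent set: M_d* undefined")
        return float("nan")
    if np.any(na == 0) or np.any(nb == 0):
        flags.append("silent trains dropped from M_d*")
        ra, na = ra[na > 0], na[na > 0]
        rb, nb = rb[nb > 0], nb[nb > 0]
        if len(ra) < 2 or len(rb) < 2:
            flags.append("too few active trains after dropping: M_d* undefined")
            return float("nan")
    ca = ra / na[:, None]
    cb = rb / nb[:, None]

    cross = ca @ cb.T
    if cross.shape[0] == cross.shape[1]:
        m = ~np.eye(cross.shape[0], dtype=bool)
        cross_mean = cross[m].mean()
    else:
        cross_mean = cross.mean()
    wa = ca @ ca.T
    wb = cb @ cb.T
    wa_mean = wa[~np.eye(len(ca), dtype=bool)].mean()
    wb_mean = wb[~np.eye(len(cb), dtype=bool)].mean()
    if wa_mean <= 0 or wb_mean <= 0:
        flags.append("nonpositive within-set similarity: M_d* undefined")
        return float("nan")
    return float(cross_mean / np.sqrt(wa_mean * wb_mean))


def similarity_report(setA, setB, windows: Sequence[float] = (10.0, 20.0), dt_label: float = 1.0) -> SimilarityReport:
    flags: List[str] = []
    vals = {float(w): md_star(setA, setB, w, dt_label, flags) for w in windows}
    return SimilarityReport(md_star=vals, dt_label=dt_label, flags=flags)


# ---------------------------------------------------------------------------
# Classification


def classification_report(
    y_true,
    y_pred,
    class_names: Optional[Sequence[str]] = None,
    rare_threshold: float = 0.05,
) -> dict:
    """Accuracy, per-class F1, macro-F1, a rare-class panel and a flow table.

    The rare-class panel lists classes whose prevalence in ``y_true`` falls
    below ``rare_threshold`` together with their F1 — the regime where a
    majority-vote classifier silently fails.  The flow table gives
    true-class -> predicted-class counts for Sankey-style plots.  A class
    absent from both vectors gets F1 = NA.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ContractError("y_true and y_pred lengths differ")
    if class_names is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
        class_names = [str(c) for c in labels]
    else:
        labels = np.arange(len(class_names))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    support = cm.sum(axis=1)
    f1 = f1_score(y_true, y_pred, labels=labels, average=None, zero_division=0.0)
    present = (support > 0) | (cm.sum(axis=0) > 0)
    per_class = pd.DataFrame(
        {
            "class": class_names,
            "support": support,
            "prevalence": support / max(1, len(y_true)),
            "f1": [f1[i] if present[i] else np.nan for i in range(len(labels))],
        }
    )
    flow = pd.DataFrame(
        [
            {"true": class_names[i], "predicted": class_names[j], "count": int(cm[i, j])}
            for i in range(len(labels))
            for j in range(len(labels))
            if cm[i, j] > 0
        ]
    )
    rare = per_class[(per_class.prevalence < rare_threshold) & (per_class.support > 0)]
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "macro_f1": float(np.nanmean(per_class.f1.to_numpy(dtype=float))),
        "per_class": per_class,
        "rare_classes": rare.reset_index(drop=True),
        "confusion": cm,
        "flow": flow,
    }


def generation_mse(generated, template) -> float:
    """Elementwise mean squared error over neurons x time (x trials)."""
    g = np.asarray(generated.spikes if isinstance(generated, SpikeTrain) else generated, dtype=float)
    t = np.asarray(template.spikes if isinstance(template, SpikeTrain) else template, dtype=float)
    if g.shape != t.shape:
        raise ContractError(f"shape mismatch {g.shape} vs {t.shape}")
    return float(np.mean((g - t) ** 2))


# ---------------------------------------------------------------------------
# Neural-manifold projection


def manifold_project(
    trains,
    n_components: int = 3,
    smoothing_window: int = 5,
):
    """Project population activity onto its leading principal axes.

    ``trains`` is one SpikeTrain / array ``(neurons, T)`` or a list of such
    trials.  Firing rates are boxcar-smoothed along time, all time points
    (pooled across trials) are mean-centered, and PCA returns per-trial
    trajectories of shape ``(T, n_components)`` plus explained-variance
    ratios.  Degenerate constant input yields a zero-variance warning flag.
    """
    if isinstance(trains, (SpikeTrain, np.ndarray)):
        trains = [trains]
    mats = [np.asarray(t.spikes if isinstance(t, SpikeTrain) else t, dtype=float) for t in trains]
    n_neurons = mats[0].shape[0]
    if n_neurons < n_components:
        raise ContractError("need at least n_components neurons")
    sm = [uniform_filter1d(m, size=max(1, smoothing_window), axis=1, mode="constant") for m in mats]
    X = np.concatenate([m.T for m in sm], axis=0)  # (trials*T, neurons)
    flags = []
    if np.allclose(X.var(axis=0), 0):
        flags.append("zero-variance input: projection is degenerate")
    pca = PCA(n_components=n_components)
    Z = pca.fit_transform(X)
    T = mats[0].shape[1]
    trajs = [Z[i * T : (i + 1) * T] for i in range(len(mats))]
    return {
        "trajectories": trajs,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "components": pca.components_,
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# Energy accounting


@dataclass
class EnergyReport:
    """Event-driven (accumulate) vs dense (multiply-accumulate) energy.

    Counts are per sample; energies in pJ using per-operation constants for
    45 nm CMOS floating point (e_mac = 4.6 pJ, e_ac = 0.9 pJ by default).
    ``fold_reduction`` is ANN energy / SNN energy.
    """

    ann_ops: float
    snn_ac_ops: float
    snn_mac_ops: float
    e_mac: float
    e_ac: float
    ann_energy_pj: float
    snn_energy_pj: float
    fold_reduction: Optional[float]
    time_steps: int
    flags: List[str] = field(default_factory=list)


def dense_mac_count(layer_sizes: Sequence[int]) -> int:
    """MACs of one dense analog pass through the same architecture."""
    return int(sum(layer_sizes[i] * layer_sizes[i + 1] for i in range(len(layer_sizes) - 1)))


def energy_estimate(
    record: ForwardRecord,
    ann_ops_reference: float,
    e_mac: float = 4.6,
    e_ac: float = 0.9,
) -> EnergyReport:
    """Estimate event-driven energy of a forward pass against a dense ANN.

    SNN energy = e_ac x (spike-driven accumulates) + e_mac x (real-valued
    first-layer MACs, repeated over T steps); the ANN reference evaluates
    the same architecture once with dense MACs.  Counts in the record are
    batch totals and are normalized per sample.
    """
    B = max(1, record.batch_size)
    ac = record.ac_ops / B
    mac = record.mac_ops / B
    snn_energy = e_ac * ac + e_mac * mac
    ann_energy = e_mac * ann_ops_reference
    flags: List[str] = []
    fold: Optional[float]
    if snn_energy == 0:
        flags.append("zero SNN energy: fold reduction undefined")
        fold = None
    else:
        fold = float(ann_energy / snn_energy)
    return EnergyReport(
        ann_ops=float(ann_ops_reference),
        snn_ac_ops=float(ac),
        snn_mac_ops=float(mac),
        e_mac=e_mac,
        e_ac=e_ac,
        ann_energy_pj=float(ann_energy),
        snn_energy_pj=float(snn_energy),
        fold_reduction=fold,
        time_steps=record.time_steps,
        flags=flags,
    )
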