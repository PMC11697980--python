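"""Identifying a rare cell type from a synthetic expression matrix.

Generates negative-binomial counts for four cell types (one at 1%
prevalence) with type-specific marker blocks, certifies separability with a
nearest-centroid oracle, then trains a spiking classifier on log1p
features encoded as direct current.  Balanced class weights keep the rare
type from being swallowed by the majority classes.
"""

import numpy as np
from sklearn.metrics import f1_score
from sklearn.neighbors import NearestCentroid

from hetsnn import BilevelConfig, NetworkSpec, forward, hifi_train, split_orthogonal
from hetsnn.metrics import classification_report, dense_mac_count, energy_estimate
from hetsnn.network import encode_static
from hetsnn.synthetic import gen_expression_matrix

_, log1p, y, side = gen_expression_matrix(
    n_cells=1000, n_genes=100, type_proportions=(0.5, 0.3, 0.19, 0.01),
    marker_strength=4.0, seed=3,
)
print("cells per type:", side["counts_per_type"], "(type 3 is the 1% rare class)")

it, iv = split_orthogonal(y, 0.8, seed=0)
oracle = NearestCentroid().fit(log1p[it], y[it])
print(f"centroid-oracle macro-F1 (separability certificate): "
      f"{f1_score(y[iv], oracle.predict(log1p[iv]), average='macro'):.3f}")

scale = log1p[it].max()
spec = NetworkSpec([100, 32, 4], time_steps=4, encoding="direct-current")
cw = len(it) / (4 * np.bincount(y[it]))
cfg = BilevelConfig(xi1=0.5, xi2=0.02, epochs=15, batch_size=32, seed=0, class_weight=cw)
res = hifi_train(spec, (encode_static(log1p[it] / scale, 4, "direct-current"), y[it]), cfg,
                 alpha_jitter_sd=0.02)

rec = forward(spec, res.params, encode_static(log1p[iv] / scale, 4, "direct-current"))
rep = classification_report(y[iv], rec.logits.argmax(1), rare_threshold=0.05)
print(f"spiking classifier: accuracy {rep['accuracy']:.3f}, macro-F1 {rep['macro_f1']:.3f}")
print("rare-class panel:\n", rep["rare_classes"].to_string(index=False))

energy = energy_estimate(rec, dense_mac_count(spec.layer_sizes))
print(f"\nevent-driven energy: {energy.snn_energy_pj:.0f} pJ/sample vs "
      f"{energy.ann_energy_pj:.0f} pJ dense ({energy.fold_reduction:.2f}x ratio)")
print("Here the direct-current front end (dense MACs repeated over T steps)")
print("dominates, so the ratio is below 1; event-driven savings appear when")
print("spiking layers carry most of the fan-out, as the accounting shows.")
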