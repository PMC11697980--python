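"""Bi-level heterogeneous learning on a spike-timing classification task.

The fixture's three classes share identical per-neuron firing rates and
differ only in spike timing, so any rate-based readout is at chance (1/3).
Training alternates SGD steps on the synaptic weights (inner loop, on the
sub-training split) with hypergradient steps on every neuron's five
biophysical parameters (outer loop, on the disjoint sub-validation split).
"""

from hetsnn import BilevelConfig, NetworkSpec, hifi_train
from hetsnn.synthetic import gen_temporal_classes

X, y, _ = gen_temporal_classes(n_classes=3, neurons=2, T=5, jitter=0.1, n_per_class=40, seed=7)
spec = NetworkSpec([2, 16, 3], time_steps=5, encoding="native-spikes")
cfg = BilevelConfig(xi1=1.0, xi2=0.02, lam=0.01, epochs=100, batch_size=16, seed=0,
                    alpha_every_epoch=False, alternation=1)
res = hifi_train(spec, (X, y), cfg, w_gain=2.0, alpha_jitter_sd=0.02)

h = res.history
print(f"epoch   0: train loss {h.L_t.values[0]:.3f}, val acc {h.val_acc.values[0]:.2f}")
print(f"epoch {h.epoch.values[-1]:3d}: train loss {h.L_t.values[-1]:.3f}, val acc {h.val_acc.values[-1]:.2f}")
print(f"penalty Omega: {h.omega.values[0]:.4f} -> {h.omega.values[-1]:.4f}")
print(f"input-gain spread across neurons:  {h.C_std.values[0]:.4f} -> {h.C_std.values[-1]:.4f}")
print(f"threshold spread across neurons:   {h.u_th_std.values[0]:.4f} -> {h.u_th_std.values[-1]:.4f}")
print("\nChance is 0.33 (classes share identical rates); accuracy above it is")
print("evidence the network reads spike timing.  The growing per-neuron spreads")
print("show neurons specializing: heterogeneous learning in action.")
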