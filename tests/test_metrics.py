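"""Tests for the evaluation metrics: spike-train similarity, classification
reporting, generation error, manifold projection and energy accounting."""

import numpy as np
import pytest
from scipy.ndimage import uniform_filter1d

from hetsnn import (
    ContractError,
    ForwardRecord,
    NetworkSpec,
    classification_report,
    dense_mac_count,
    energy_estimate,
    forward,
    generation_mse,
    init_network_params,
    manifold_project,
    md_star,
    similarity_report,
)


def _brute_md(A, B, bins):
    """Independent double-loop oracle for the set-similarity statistic."""
    ra = [uniform_filter1d(np.asarray(a, float), bins, mode="constant") for a in A]
    rb = [uniform_filter1d(np.asarray(b, float), bins, mode="constant") for b in B]

    def cos(x, y):
        return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))

    cross = [cos(ra[i], rb[j]) for i in range(len(A)) for j in range(len(B))
             if not (len(A) == len(B) and i == j)]
    wa = [cos(ra[i], ra[j]) for i in range(len(A)) for j in range(len(A)) if i != j]
    wb = [cos(rb[i], rb[j]) for i in range(len(B)) for j in range(len(B)) if i != j]
    return np.mean(cross) / np.sqrt(np.mean(wa) * np.mean(wb))


class TestMdStar:
    def _sets(self, rng, n=8, T=500, p=0.05):
        return (
            [(rng.random(T) < p).astype(float) for _ in range(n)],
            [(rng.random(T) < p).astype(float) for _ in range(n)],
        )

    def test_identical_copy_scores_one(self, rng):
        A, _ = self._sets(rng)
        assert md_star(A, [a.copy() for a in A], 10.0) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        A, B = self._sets(rng)
        assert md_star(A, B, 10.0) == pytest.approx(md_star(B, A, 10.0), abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        A, B = self._sets(rng)
        assert md_star(A, B, 10.0) == pytest.approx(_brute_md(A, B, 10), rel=1e-10)
        A2 = A[:5]  # unequal sizes exercise the all-pairs branch
        assert md_star(A2, B, 10.0) == pytest.approx(_brute_md(A2, B, 10), rel=1e-10)

    def test_population_mean_near_one_for_iid_sets(self):
        """For two independent sets with identical Bernoulli statistics the
        estimator's expectation is ~1 (cross pairs are exchangeable with
        within pairs); the Monte Carlo mean must sit within 3 sigma of it."""
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(100):
            A, B = self._sets(rng, n=6)
            vals.append(md_star(A, B, 50.0))
        sem = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 3 * sem + 0.01

    def test_bounded_on_tested_inputs(self, rng):
        for _ in range(20):
            A, B = self._sets(rng, n=6)
            v = md_star(A, B, 20.0)
            assert 0.0 <= v <= 1.15  # tol covers estimator variance at n=6

    def test_all_silent_set_is_flagged_nan(self, rng):
        A, _ = self._sets(rng)
        flags = []
        v = md_star([np.zeros(500), np.zeros(500)], A, 10.0, flags=flags)
        assert np.isnan(v) and flags

    def test_needs_two_trains_per_set(self, rng):
        A, B = self._sets(rng)
        with pytest.raises(ContractError):
            md_star(A[:1], B)

    def test_report_over_windows(self, rng):
        A, B = self._sets(rng)
        rep = similarity_report(A, B, windows=(10.0, 20.0))
        assert set(rep.md_star) == {10.0, 20.0}


class TestClassificationReport:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = classification_report(y, y.copy())
        assert rep["accuracy"] == 1.0
        assert np.allclose(rep["per_class"].f1.dropna(), 1.0)
        assert rep["macro_f1"] == 1.0

    def test_majority_vote_gives_zero_minority_f1(self):
        y = np.array([0] * 90 + [1] * 10)
        pred = np.zeros(100, dtype=int)
        rep = classification_report(y, pred, rare_threshold=0.2)
        assert rep["per_class"].f1.values[1] == 0.0
        assert "1" in rep["rare_classes"]["class"].values

    def test_matches_hand_confusion_oracle(self, rng):
        y = rng.integers(0, 3, 60)
        pred = rng.integers(0, 3, 60)
        rep = classification_report(y, pred)
        cm = np.zeros((3, 3), int)
        for a, b in zip(y, pred):
            cm[a, b] += 1
        np.testing.assert_array_equal(rep["confusion"], cm)
        # row sums equal class supports
        np.testing.assert_array_equal(rep["confusion"].sum(axis=1), rep["per_class"].support)
        # per-class F1 from the hand confusion matrix
        for k in range(3):
            tp = cm[k, k]
            prec = tp / max(1, cm[:, k].sum())
            rec = tp / max(1, cm[k].sum())
            f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
            assert rep["per_class"].f1.values[k] == pytest.approx(f1)

    def test_flow_table_totals(self, rng):
        y = rng.integers(0, 3, 40)
        pred = rng.integers(0, 3, 40)
        rep = classification_report(y, pred)
        assert rep["flow"]["count"].sum() == 40


class TestGenerationMSE:
    def test_identical_is_zero(self, rng):
        s = (rng.random((3, 4, 20)) < 0.2).astype(float)
        assert generation_mse(s, s.copy()) == 0.0

    def test_ones_vs_zeros_is_one(self):
        assert generation_mse(np.ones((2, 5)), np.zeros((2, 5))) == 1.0

    def test_matches_mean_oracle(self, rng):
        a, b = rng.random((2, 3, 7)), rng.random((2, 3, 7))
        acc = sum((a[i, j, k] - b[i, j, k]) ** 2 for i in range(2) for j in range(3) for k in range(7))
        assert generation_mse(a, b) == pytest.approx(acc / 42)

    def test_shape_mismatch(self):
        with pytest.raises(ContractError):
            generation_mse(np.ones((2, 3)), np.ones((3, 2)))


class TestManifold:
    def test_planar_data_has_negligible_third_component(self):
        t = np.linspace(0, 2 * np.pi, 300)
        basis = np.random.default_rng(1).standard_normal((5, 2))
        X = basis @ np.stack([np.sin(t), np.cos(t)])  # exactly rank 2
        out = manifold_project(X, 3, smoothing_window=1)
        assert out["explained_variance_ratio"][2] < 1e-10

    def test_projection_orthonormality(self, rng):
        X = rng.random((6, 200))
        out = manifold_project(X, 3, smoothing_window=3)
        np.testing.assert_allclose(out["components"] @ out["components"].T, np.eye(3), atol=1e-10)

    def test_reconstruction_matches_eigendecomposition_oracle(self, rng):
        X = rng.random((5, 60))
        out = manifold_project(X, 2, smoothing_window=1)
        Xc = X.T - X.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (Xc.shape[0] - 1))
        expected_evr = evals[::-1][:2] / evals.sum()
        np.testing.assert_allclose(out["explained_variance_ratio"], expected_evr, rtol=1e-8)

    def test_degenerate_input_flagged(self):
        out = manifold_project(np.ones((4, 50)), 3, smoothing_window=1)
        assert out["flags"]


class TestEnergy:
    def _record(self, ac, mac, B=1, T=3):
        return ForwardRecord(np.zeros((B, 2)), [], 0, ac, mac, B, T)

    def test_zero_spikes_no_front_end_is_sentinel(self):
        rep = energy_estimate(self._record(0, 0), ann_ops_reference=8)
        assert rep.fold_reduction is None and rep.flags

    def test_hand_counted_2_2_2_case(self):
        # 3 hidden spikes with fan-out 2 -> 6 ACs; dense ANN has 2*2+2*2 = 8 MACs
        rep = energy_estimate(self._record(ac=6, mac=0), ann_ops_reference=dense_mac_count([2, 2, 2]))
        assert rep.snn_energy_pj == pytest.approx(0.9 * 6)
        assert rep.ann_energy_pj == pytest.approx(4.6 * 8)
        assert rep.fold_reduction == pytest.approx(4.6 * 8 / (0.9 * 6))

    def test_counts_come_from_the_forward_record(self, rng):
        spec = NetworkSpec([4, 6, 3], 5, encoding="native-spikes")
        params = init_network_params(spec, 2, w_gain=2.0)
        x = (rng.random((2, 4, 5)) < 0.4).astype(float)
        rec = forward(spec, params, x)
        oracle = 0
        for t in range(5):
            oracle += int(x[:, :, t].sum()) * 6 + int(rec.layer_spikes[0][:, :, t].sum()) * 3
        rep = energy_estimate(rec, dense_mac_count([4, 6, 3]))
        assert rep.snn_ac_ops == pytest.approx(oracle / 2)  # per-sample

    def test_fold_reduction_scales_inversely_with_spikes(self):
        r1 = energy_estimate(self._record(ac=10, mac=0), 100)
        r2 = energy_estimate(self._record(ac=20, mac=0), 100)
        assert r1.fold_reduction == pytest.approx(2 * r2.fold_reduction)
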