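import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

import qsmiles as q


class TestTargetFunctions:
    def test_tf1_zero_penalty_at_equal_correlations(self):
        assert q.tf1(0.9, 0.9) == pytest.approx(1.8)

    def test_tf1_penalizes_imbalance(self):
        assert q.tf1(1.0, 0.0, 0.1) == pytest.approx(0.9)
        assert q.tf1(1.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_tf2_ideality_terms(self):
        assert q.tf2(1.5, 1.0, 1.0, 0.3) == pytest.approx(2.1)
        assert q.tf2(1.5, 0.4, -0.4, 0.3) == pytest.approx(1.5)
        assert q.tf2(1.5, 0.8, 0.6, 0.0) == pytest.approx(1.5)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [dict(tf_kind="TF9"), dict(N=0), dict(T=0), dict(step=0.0),
         dict(init="ones"), dict(persistence=0)],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            q.OptimizationConfig(**kw)


@pytest.fixture(scope="module")
def small_labeled():
    spec = q.GeneratorSpec.default(n=80, noise_sd=0.2, seed=1)
    ds = q.generate(spec)
    return ds.with_labels(q.random_split(ds, seed=2))


@pytest.fixture(scope="module")
def small_result(small_labeled):
    return q.optimize(small_labeled, q.OptimizationConfig(tf_kind="TF2", seed=3))


class TestOptimize:
    def test_trace_is_monotone_nondecreasing(self, small_result):
        tf_values = [e.tf_value for e in small_result.trace]
        assert len(tf_values) > 0
        assert all(b >= a for a, b in zip(tf_values, tf_values[1:]))

    def test_blocked_codes_stay_exactly_zero(self, small_labeled):
        degraded = q.degrade(small_labeled, 0.25, seed=9)
        res = q.optimize(degraded, q.OptimizationConfig(tf_kind="TF1", seed=4))
        assert res.weights.blocked  # degradation created rare codes
        assert all(res.weights.weight(c) == 0.0 for c in res.weights.blocked)

    def test_deterministic_given_seed(self, small_labeled):
        cfg = q.OptimizationConfig(tf_kind="TF1", seed=11)
        a = q.optimize(small_labeled, cfg)
        b = q.optimize(small_labeled, cfg)
        assert a.weights == b.weights
        assert a.params == b.params

    def test_validation_set_never_touched(self, small_labeled):
        """Dropping the validation records must not change the fit at all."""
        cfg = q.OptimizationConfig(tf_kind="TF2", seed=5)
        full = q.optimize(small_labeled, cfg)
        trimmed = q.Dataset([r for r in small_labeled if r.set_label != "V"])
        held_out = q.optimize(trimmed, cfg)
        assert held_out.weights == full.weights
        assert held_out.params == full.params

    def test_slope_gauge_is_nonnegative(self, small_result):
        assert small_result.params.C1 >= 0

    def test_target_state_consistent_with_tf_formula(self, small_result):
        s = small_result.state
        expected = q.tf2(q.tf1(s.r_at, s.r_pt), s.iic_c, s.cii_c)
        assert s.tf_value == pytest.approx(expected)

    def test_empty_subset_rejected(self, small_labeled):
        no_cal = q.Dataset([r for r in small_labeled if r.set_label != "C"])
        with pytest.raises(ValueError, match="empty C"):
            q.optimize(no_cal, q.OptimizationConfig())


class TestRecovery:
    def test_noise_free_additive_data_fit_almost_exactly(self):
        spec = q.GeneratorSpec.default(n=300, noise_sd=0.0, seed=3)
        ds = q.generate(spec)
        labeled = ds.with_labels(q.random_split(ds, seed=11))
        # identifiability check, so let the hill-climb run to convergence
        res = q.optimize(labeled, q.OptimizationConfig(tf_kind="TF1", seed=2, N=40))
        obs = [r.endpoint for r in labeled]
        pred = [q.predict(res.params, res.weights, r.qs).value for r in labeled]
        assert q.r2(obs, pred) > 0.999

    def test_validation_r2_high_on_low_noise_data(self):
        spec = q.GeneratorSpec.default(n=500, noise_sd=0.1, seed=5)
        ds = q.generate(spec)
        labeled = ds.with_labels(q.random_split(ds, seed=5))
        res = q.optimize(labeled, q.OptimizationConfig(tf_kind="TF2", seed=1))
        V = labeled.subset("V")
        pred = [q.predict(res.params, res.weights, r.qs).value for r in V]
        assert q.r2([r.endpoint for r in V], pred) > 0.9

    def test_true_weights_recovered_up_to_gauge(self):
        """Rank correlation between learned and generating weights, after
        removing the per-slot gauge freedom, averaged over 5 seeds."""
        corrs = []
        for seed in range(5):
            spec = q.GeneratorSpec.default(n=200, noise_sd=0.1, seed=seed)
            ds = q.generate(spec)
            labeled = ds.with_labels(q.random_split(ds, seed=seed + 50))
            res = q.optimize(labeled, q.OptimizationConfig(tf_kind="TF1", seed=seed + 1))
            true_c, learned_c = [], []
            for slot in spec.slots:
                present = [c for c in slot
                           if c in res.weights.weights and c not in res.weights.blocked]
                t = np.array([spec.true_weights[c] for c in present])
                l = np.array([res.weights.weights[c] for c in present])
                true_c.extend(t - t.mean())
                learned_c.extend(l - l.mean())
            corrs.append(spearmanr(true_c, learned_c).statistic)
        assert np.mean(corrs) > 0.8


class TestIdealityAdvantage:
    def test_tf2_raises_calibration_iic_over_tf1(self, small_labeled):
        """Adding the ideality terms steers the fit toward balanced
        calibration-set residuals (paired over 10 seeds)."""
        C = small_labeled.subset("C")
        obs = [r.endpoint for r in C]
        means = {}
        for tf in ("TF1", "TF2"):
            vals = []
            for seed in range(10):
                cfg = q.OptimizationConfig(tf_kind=tf, seed=seed)
                res = q.optimize(small_labeled, cfg)
                pred = [q.predict(res.params, res.weights, r.qs).value for r in C]
                vals.append(q.iic(obs, pred))
            means[tf] = np.mean(vals)
        assert means["TF2"] >= means["TF1"]


class TestEnsemble:
    def test_distinct_seeds_distinct_weights(self, small_labeled):
        runs = q.run_ensemble(small_labeled, q.OptimizationConfig(seed=1), 3)
        assert len(runs) == 3
        assert runs[0].weights != runs[1].weights != runs[2].weights

    def test_single_run_rejected(self, small_labeled):
        with pytest.raises(ValueError):
            q.run_ensemble(small_labeled, q.OptimizationConfig(), 1)

    def test_ensemble_is_reproducible(self, small_labeled):
        cfg = q.OptimizationConfig(tf_kind="TF1", seed=6)
        a = q.run_ensemble(small_labeled, cfg, 2)
        b = q.run_ensemble(small_labeled, cfg, 2)
        assert [r.weights for r in a] == [r.weights for r in b]
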