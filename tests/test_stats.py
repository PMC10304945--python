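import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import qsmiles as q
from qsmiles.stats import UndefinedCorrelationError, cii, q2_loo


def _series(n=8, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    return x, x + noise * rng.normal(size=n)


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        assert q.pearson_r(x, x) == pytest.approx(1.0)
        assert q.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(UndefinedCorrelationError):
            q.pearson_r([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestCCC:
    def test_identity_is_perfectly_concordant(self):
        x, _ = _series()
        assert q.ccc(x, x) == pytest.approx(1.0)

    def test_shift_penalized_while_r_is_not(self):
        x, _ = _series()
        shifted = x + 1.5
        assert q.pearson_r(x, shifted) == pytest.approx(1.0)
        assert q.ccc(x, shifted) < 1.0

    def test_population_moment_convention(self):
        obs, pred = _series(n=6, seed=3)
        e_obs, e_pred = obs - obs.mean(), pred - pred.mean()
        manual = (2 * (e_obs * e_pred).mean()
                  / (e_obs.var() + e_pred.var() + (obs.mean() - pred.mean()) ** 2))
        assert q.ccc(obs, pred) == pytest.approx(manual)

    def test_ccc_never_exceeds_abs_r(self):
        for seed in range(10):
            obs, pred = _series(n=10, seed=seed, noise=0.5)
            assert q.ccc(obs, pred) <= abs(q.pearson_r(obs, pred)) + 1e-12


class TestIIC:
    def test_balanced_residuals_equal_r(self):
        obs = np.array([0.0, 1.0, 2.0, 3.0])
        pred = obs + np.array([0.5, -0.5, 0.5, -0.5])
        assert q.iic(obs, pred) == pytest.approx(q.pearson_r(obs, pred))

    def test_one_sided_residuals_give_zero(self):
        obs = np.array([0.0, 1.0, 2.0, 3.0])
        assert q.iic(obs, obs - 1.0) == 0.0

    @given(hnp.arrays(np.float64, 8, elements=st.floats(-5, 5)),
           hnp.arrays(np.float64, 8, elements=st.floats(-5, 5)))
    @settings(max_examples=100, derandomize=True)
    def test_magnitude_bounded_by_r(self, obs, pred):
        if obs.std() == 0 or pred.std() == 0:
            return
        assert abs(q.iic(obs, pred)) <= abs(q.pearson_r(obs, pred)) + 1e-12


class TestCII:
    def test_collinear_data_give_one(self):
        x = np.linspace(0, 1, 6)
        assert q.cii(x, 2 * x + 1) == pytest.approx(1.0)

    def test_gross_outlier_is_an_oppositionist(self):
        x = np.linspace(0, 1, 9)
        y = 2 * x.copy()
        y[4] += 5.0  # off the otherwise tight line
        res = q.cii(x, y, detail=True)
        assert res.value < 1.0
        assert res.labels[4] == "oppositionist"

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_removal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        obs = rng.normal(size=n)
        pred = obs + 0.5 * rng.normal(size=n)
        base = q.r2(obs, pred)
        removed = []
        for k in range(n):
            mask = np.arange(n) != k
            removed.append(q.r2(obs[mask], pred[mask]))
        oracle = 1.0 - sum(max(0.0, rk - base) for rk in removed)
        assert q.cii(obs, pred) == pytest.approx(oracle, abs=1e-10)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            q.cii([0.0, 1.0], [0.0, 1.0])


class TestQ2:
    def test_exact_linear_data_give_one(self):
        x = np.linspace(0, 1, 7)
        assert q.q2_loo(np.column_stack([x, 3 * x - 1])) == pytest.approx(1.0)

    def test_matches_explicit_refits_at_n3(self):
        pairs = np.array([(0.0, 0.1), (1.0, 0.8), (2.0, 2.3)])
        press = 0.0
        for k in range(3):
            rest = np.delete(pairs, k, axis=0)
            c1, c0 = np.polyfit(rest[:, 0], rest[:, 1], 1)
            press += (pairs[k, 1] - (c0 + c1 * pairs[k, 0])) ** 2
        expected = 1 - press / ((pairs[:, 1] - pairs[:, 1].mean()) ** 2).sum()
        assert q.q2_loo(pairs) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(6))
    def test_never_exceeds_full_fit_r2(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = 0.8 * x + 0.4 * rng.normal(size=12)
        m = q.fit_linear(np.column_stack([x, y]))
        assert q.q2_loo(np.column_stack([x, y])) <= q.r2(y, m.C0 + m.C1 * x) + 1e-12


class TestErrorsAndF:
    def test_zero_residuals(self):
        x = np.array([0.0, 1.0, 2.0])
        assert q.rmse(x, x) == 0.0
        assert q.mae(x, x) == 0.0

    def test_rmse_dominates_mae_and_scales_linearly(self):
        obs, pred = _series(n=9, seed=5)
        assert q.rmse(obs, pred) >= q.mae(obs, pred)
        scaled = obs + 3 * (pred - obs)
        assert q.rmse(obs, scaled) == pytest.approx(3 * q.rmse(obs, pred))
        assert q.mae(obs, scaled) == pytest.approx(3 * q.mae(obs, pred))

    def test_bessel_corrected_variant(self):
        obs, pred = _series(n=5, seed=1)
        assert q.rmse(obs, pred, ddof=1) == pytest.approx(
            q.rmse(obs, pred) * np.sqrt(5 / 4)
        )

    def test_f_ratio_formula_and_infinity(self):
        obs, pred = _series(n=26, seed=2, noise=0.05)
        rsq = q.r2(obs, pred)
        assert q.f_ratio(obs, pred) == pytest.approx(rsq * 24 / (1 - rsq))
        x = np.linspace(0, 1, 5)
        assert q.f_ratio(x, 2 * x) == np.inf


class TestReferenceReproduction:
    """The printed per-set statistics table is recomputed from the bundled
    observed/calculated columns; agreement validates every formula choice."""

    PRINTED = {
        "A": dict(n=26, r2=0.9029, ccc=0.9490, iic=0.6968, cii=0.9203, q2=0.8850, rmse=0.282),
        "P": dict(n=25, r2=0.7780, ccc=0.8048, iic=0.8727, cii=0.8391, q2=0.7534, rmse=0.477),
        "C": dict(n=25, r2=0.5926, ccc=0.7273, iic=0.7696, cii=0.7677, q2=0.5227, rmse=0.468),
        "V": dict(n=26, r2=0.6895, rmse=0.325),
    }

    @pytest.mark.parametrize("label", ["A", "P", "C", "V"])
    def test_set_statistics_match_printed_values(self, ref_frame, label):
        sub = ref_frame[ref_frame["set"] == label]
        stats = q.set_statistics(sub["endpoint"], sub["calc"], dcw=sub["dcw"])
        printed = self.PRINTED[label]
        assert stats.n == printed["n"]
        for key, value in printed.items():
            if key == "n":
                continue
            tol = 5e-4 if key != "rmse" else 5e-3
            assert getattr(stats, key) == pytest.approx(value, abs=tol), key

    def test_f_ratio_printed_for_active_set(self, ref_frame):
        sub = ref_frame[ref_frame["set"] == "A"]
        assert q.f_ratio(sub["endpoint"], sub["calc"]) == pytest.approx(223, abs=1)
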