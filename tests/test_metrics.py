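"""Validation statistics against hand arithmetic and one-line formula oracles."""

import numpy as np
import pytest

from mkqsar.metrics import (
    PairedSeries,
    ccc,
    kfold_r2cv,
    mae,
    metrics_report,
    mse,
    q2_external,
    r_squared,
    rmse,
    split_4_to_1,
)


class TestHandArithmetic:
    """Frozen expected values computed by direct formula evaluation."""

    y = np.array([1.0, 2.0, 3.0])
    yhat = np.array([1.0, 2.0, 4.0])

    def test_r_squared(self):
        # SSres = 1, SStot = 2
        assert r_squared(self.y, self.yhat) == pytest.approx(0.5, abs=1e-15)

    def test_rmse(self):
        assert rmse(self.y, self.yhat) == pytest.approx(np.sqrt(1 / 3), abs=1e-15)

    def test_mae(self):
        assert mae(self.y, self.yhat) == pytest.approx(1 / 3, abs=1e-15)

    def test_ccc_shifted_series(self):
        # y=(1,2,3), yhat=(2,3,4): cov=2/3, vars=2/3, mean gap 1 -> (4/3)/(7/3)
        assert ccc(self.y, np.array([2.0, 3.0, 4.0])) == pytest.approx(4 / 7, abs=1e-15)


class TestDegenerateAndIdentity:
    def test_perfect_prediction(self):
        y = np.array([0.3, 1.2, 2.2, 0.9])
        assert r_squared(y, y) == 1.0
        assert rmse(y, y) == 0.0
        assert mae(y, y) == 0.0
        assert ccc(y, y) == 1.0
        assert q2_external(y, 0.5, "F1", predicted=y) == 1.0
        assert q2_external(y, 0.5, "F2", predicted=y) == 1.0

    def test_mean_predictor_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.full(4, y.mean())
        assert r_squared(y, yhat) == pytest.approx(0.0, abs=1e-15)

    def test_constant_observed_convention(self):
        assert r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]) == 0.0
        assert ccc([2.0, 2.0], [2.0, 2.0]) == 1.0
        assert ccc([2.0, 2.0], [1.0, 3.0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            PairedSeries(np.ones(3), np.ones(4))


class TestFormulaOracles:
    """Agreement with direct one-line formula evaluation on random series."""

    def test_all_metrics_match_oracles(self):
        rng = np.random.default_rng(20240901)
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            y = rng.normal(size=n)
            yhat = y + rng.normal(scale=rng.uniform(0.01, 2.0), size=n)
            tm = float(rng.normal())
            assert r_squared(y, yhat) == pytest.approx(
                1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2), abs=1e-12)
            assert rmse(y, yhat) == pytest.approx(
                np.sqrt(np.mean((y - yhat) ** 2)), abs=1e-12)
            assert mse(y, yhat) == pytest.approx(np.mean((y - yhat) ** 2), abs=1e-12)
            assert mae(y, yhat) == pytest.approx(np.mean(np.abs(y - yhat)), abs=1e-12)
            sxy = np.mean((y - y.mean()) * (yhat - yhat.mean()))
            expected_ccc = 2 * sxy / (y.var() + yhat.var() + (y.mean() - yhat.mean()) ** 2)
            assert ccc(y, yhat) == pytest.approx(expected_ccc, abs=1e-12)
            assert q2_external(y, tm, "F1", predicted=yhat) == pytest.approx(
                1 - np.sum((y - yhat) ** 2) / np.sum((y - tm) ** 2), abs=1e-12)
            assert q2_external(y, tm, "F2", predicted=yhat) == pytest.approx(
                1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2), abs=1e-12)

    def test_q2f2_equals_r_squared(self):
        rng = np.random.default_rng(3)
        y, yhat = rng.normal(size=12), rng.normal(size=12)
        assert q2_external(y, 99.0, "F2", predicted=yhat) == pytest.approx(
            r_squared(y, yhat), abs=1e-14)

    def test_q2f1_at_least_q2f2_when_means_differ(self):
        rng = np.random.default_rng(4)
        y, yhat = rng.normal(size=15), rng.normal(size=15)
        assert q2_external(y, y.mean() + 1.0, "F1", predicted=yhat) >= q2_external(
            y, 0.0, "F2", predicted=yhat)


class TestInvariances:
    def test_r_squared_affine_invariance(self):
        rng = np.random.default_rng(5)
        y, yhat = rng.normal(size=20), rng.normal(size=20)
        base = r_squared(y, yhat)
        for c, d in [(2.0, 1.0), (0.5, -3.0), (10.0, 0.0)]:
            assert r_squared(c * y + d, c * yhat + d) == pytest.approx(base, abs=1e-10)

    def test_rmse_scale_equivariance(self):
        rng = np.random.default_rng(6)
        y, yhat = rng.normal(size=10), rng.normal(size=10)
        assert rmse(-2.5 * y, -2.5 * yhat) == pytest.approx(2.5 * rmse(y, yhat), abs=1e-12)

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            y, yhat = rng.normal(size=8), rng.normal(size=8)
            assert mae(y, yhat) <= rmse(y, yhat) + 1e-15

    def test_abs_ccc_bounded_by_abs_pearson(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            y, yhat = rng.normal(size=10), rng.normal(size=10)
            assert abs(ccc(y, yhat)) <= abs(np.corrcoef(y, yhat)[0, 1]) + 1e-12


class TestSplit:
    def test_57_splits_45_12(self):
        train, test = split_4_to_1(list(range(1, 58)), seed=11)
        assert (len(train), len(test)) == (45, 12)

    def test_minimum_size(self):
        train, test = split_4_to_1([1, 2, 3, 4, 5], seed=0)
        assert len(test) == 1
        with pytest.raises(ValueError):
            split_4_to_1([1, 2, 3, 4], seed=0)

    @pytest.mark.parametrize("n", [5, 13, 57, 100])
    def test_partition_properties(self, n):
        ids = [f"c{i}" for i in range(n)]
        train, test = split_4_to_1(ids, seed=n)
        assert set(train) | set(test) == set(ids)
        assert set(train) & set(test) == set()
        assert split_4_to_1(ids, seed=n) == (train, test)  # deterministic


class TestKfoldR2cv:
    @staticmethod
    def _ols_fitter(X, y):
        Xi = np.column_stack([X, np.ones(len(y))])
        coef, *_ = np.linalg.lstsq(Xi, y, rcond=None)
        return lambda Xv: np.column_stack([Xv, np.ones(len(Xv))]) @ coef

    def test_even_fold_sizes(self):
        rng = np.random.default_rng(1)
        sizes = []

        def spy_fitter(X, y):
            sizes.append(len(y))
            return self._ols_fitter(X, y)

        X = rng.normal(size=(45, 2))
        y = X @ [1.0, -1.0]
        kfold_r2cv(X, y, 5, spy_fitter, seed=0)
        assert sizes == [36] * 5  # each training fold leaves out exactly 9

    def test_interpolating_fitter_scores_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        y = X @ [2.0, 0.5, -1.0] + 0.3
        assert kfold_r2cv(X, y, 5, self._ols_fitter, seed=1) == pytest.approx(1.0, abs=1e-10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(24, 2))
        y = X[:, 0] + rng.normal(size=24)
        a = kfold_r2cv(X, y, 4, self._ols_fitter, seed=9)
        assert a == kfold_r2cv(X, y, 4, self._ols_fitter, seed=9)

    def test_mean_predictor_not_positive_on_noise(self):
        rng = np.random.default_rng(4)
        vals = []
        for s in range(10):
            y = rng.normal(size=40)
            X = np.zeros((40, 1))
            fit = lambda Xt, yt: (lambda Xv: np.full(len(Xv), yt.mean()))
            vals.append(kfold_r2cv(X, y, 5, fit, seed=s))
        assert np.mean(vals) <= 0.0


def test_metrics_report_bundles_consistently():
    rng = np.random.default_rng(10)
    y, yhat = rng.normal(size=12), rng.normal(size=12)
    rep = metrics_report(y, 0.25, yhat)
    assert rep.r2 == pytest.approx(r_squared(y, yhat))
    assert rep.q2_f1 == pytest.approx(q2_external(y, 0.25, "F1", predicted=yhat))
    assert rep.n == 12
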