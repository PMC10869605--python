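"""Heuristic preprocessing and forward model expansion."""

import itertools

import numpy as np
import pytest

from mkqsar.descriptors import DescriptorMatrix
from mkqsar.selection import (
    SelectionConfig,
    SelectionResult,
    choose_model_size,
    fit_mlr,
    forward_select,
    preprocess_descriptors,
)
from mkqsar.synthetic import SyntheticSpec, generate


def _matrix(values, names=None):
    values = np.asarray(values, dtype=float)
    return DescriptorMatrix(values, col_names=names or [])


class TestPreprocess:
    def test_zero_variance_column_removed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        X[:, 1] = 4.2
        m = _matrix(X, ["a", "b", "c"])
        clean, removed = preprocess_descriptors(m, rng.normal(size=10))
        assert ("b", "low-variance") in removed
        assert clean.col_names == ["a", "c"]

    def test_missing_column_removed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        X[3, 0] = np.nan
        clean, removed = preprocess_descriptors(_matrix(X, ["a", "b"]), rng.normal(size=8))
        assert removed == [("a", "missing")]
        assert clean.col_names == ["b"]

    def test_exact_duplicate_drops_exactly_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        X = np.column_stack([x, x, rng.normal(size=12)])
        clean, removed = preprocess_descriptors(_matrix(X, ["a", "a2", "c"]), x)
        collinear = [nm for nm, r in removed if r == "collinear"]
        assert len(collinear) == 1
        assert len(clean.col_names) == 2

    def test_weaker_member_of_correlated_pair_removed(self):
        # shared latent + small noise -> |r| ~ 0.95; 'strong' drives y
        rng = np.random.default_rng(3)
        latent = rng.normal(size=200)
        strong = latent + 0.2 * rng.normal(size=200)
        weak = latent + 0.2 * rng.normal(size=200)
        y = strong + 0.05 * rng.normal(size=200)
        assert abs(np.corrcoef(strong, weak)[0, 1]) > 0.9  # sanity of the setup
        m = _matrix(np.column_stack([weak, strong]), ["weak", "strong"])
        clean, removed = preprocess_descriptors(m, y)
        assert ("weak", "collinear") in removed
        assert clean.col_names == ["strong"]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        spec = SyntheticSpec(n_compounds=40, n_descriptors=12, n_signal=2, beta=(1.0, -1.0),
                             collinear_blocks=((3, 0.95),), noise_sd=0.1, seed=4)
        m, y, _ = generate(spec)
        once, _ = preprocess_descriptors(m, y)
        twice, removed2 = preprocess_descriptors(once, y)
        assert twice.col_names == once.col_names
        assert removed2 == []

    def test_everything_removed_is_an_error(self):
        m = _matrix(np.ones((5, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="relax"):
            preprocess_descriptors(m, np.arange(5.0))

    def test_response_length_mismatch(self):
        with pytest.raises(ValueError):
            preprocess_descriptors(_matrix(np.ones((5, 1))), np.arange(4.0))


class TestFitMlr:
    def test_exact_identity_fit(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        m = _matrix(x[:, None], ["d"])
        model = fit_mlr(m, x)
        assert model.r2 == pytest.approx(1.0, abs=1e-12)
        assert model.coefficients[0] == pytest.approx(1.0, abs=1e-10)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)

    def test_constant_response_convention(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(size=(10, 2)))
        model = fit_mlr(m, np.full(10, 3.3))
        assert model.r2 == 0.0
        assert model.f_stat == 0.0
        assert np.allclose(model.coefficients, 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = fit_mlr(_matrix(X), y)
        Xi = np.column_stack([X, np.ones(20)])
        coef_o = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        assert model.coefficients == pytest.approx(coef_o[:3], abs=1e-8)
        assert model.intercept == pytest.approx(coef_o[3], abs=1e-8)
        resid = y - Xi @ coef_o
        r2_o = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert model.r2 == pytest.approx(r2_o, abs=1e-10)
        # F statistic from its definition
        k, n = 3, 20
        f_o = (r2_o / k) / ((1 - r2_o) / (n - k - 1))
        assert model.f_stat == pytest.approx(f_o, abs=1e-8)
        # t values from standard errors
        s2 = resid @ resid / (n - 4)
        se = np.sqrt(np.diag(np.linalg.inv(Xi.T @ Xi)) * s2)
        assert model.t_values == pytest.approx(coef_o[:3] / se[:3], abs=1e-8)

    def test_rank_deficiency_detected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=15)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_mlr(_matrix(X), rng.normal(size=15))

    def test_underdetermined_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            fit_mlr(_matrix(rng.normal(size=(4, 4))), rng.normal(size=4))


class TestForwardSelect:
    def test_exact_single_descriptor_signal(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 8))
        y = X[:, 3].copy()
        res = forward_select(_matrix(X), y, SelectionConfig(max_size=3))
        assert res.models_by_size[1].descriptor_names == ["d3"]
        assert res.models_by_size[1].r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_size2_equals_exhaustive_best_subset(self, seed):
        rng = np.random.default_rng(200 + seed)
        X = rng.normal(size=(40, 8))
        y = 2 * X[:, 0] - X[:, 3] + rng.normal(0, 0.01, size=40)
        m = _matrix(X)
        res = forward_select(m, y, SelectionConfig(max_size=2))
        best = sorted(res.models_by_size[2].descriptor_names)
        brute = max(
            itertools.combinations(m.col_names, 2),
            key=lambda pair: fit_mlr(m.subset(list(pair)), y).r2,
        )
        assert best == sorted(brute) == ["d0", "d3"]

    def test_r2_non_decreasing_with_size(self):
        spec = SyntheticSpec(n_compounds=60, n_descriptors=15, n_signal=3,
                             beta=(1.5, -1.0, 0.8), noise_sd=0.3, seed=10)
        m, y, _ = generate(spec)
        res = forward_select(m, y, SelectionConfig(max_size=6))
        sizes = sorted(res.models_by_size)
        r2s = [res.models_by_size[s].r2 for s in sizes]
        assert all(a <= b + 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_gate_failure_reported(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)  # pure noise: t-gate should reject everything
        with pytest.raises(ValueError, match="gates"):
            forward_select(_matrix(X), y, SelectionConfig(t_min=50.0))

    def test_planted_signal_recovery(self):
        """Independent descriptors, sparse linear signal: the planted set is
        found at its true size in >= 90% of 20 seeds."""
        hits = 0
        for seed in range(20):
            spec = SyntheticSpec(n_compounds=60, n_descriptors=20, n_signal=3,
                                 beta=(2.0, -1.0, 1.5), noise_sd=0.05, seed=seed)
            m, y, truth = generate(spec)
            res = forward_select(m, y, SelectionConfig(max_size=5))
            if res.chosen_size == 3 and sorted(
                    res.models_by_size[3].descriptor_names) == sorted(truth.signal_names):
                hits += 1
        assert hits >= 18


class TestChooseSize:
    @staticmethod
    def _result(r2s):
        class M:
            def __init__(self, r2):
                self.r2 = r2

        return SelectionResult(models_by_size={i: M(r) for i, r in enumerate(r2s, 1)})

    def test_stops_at_small_gain(self):
        res = self._result([0.5, 0.9, 0.905, 0.91])
        assert choose_model_size(res, SelectionConfig(delta_r2_stop=0.02)) == 2

    def test_large_gains_run_to_max(self):
        res = self._result([0.2, 0.4, 0.6, 0.8])
        assert choose_model_size(res, SelectionConfig(delta_r2_stop=0.02, max_size=4)) == 4

    def test_single_size(self):
        res = self._result([0.7])
        assert choose_model_size(res, SelectionConfig()) == 1
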