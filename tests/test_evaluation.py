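"""Metrics, folds, dimension selection, frontier rule, forecasting baseline."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from priodyn import (
    contiguous_kfold,
    mean_cc,
    multiclass_auc,
    naive_forecast_baseline,
    paired_signed_rank,
    performance_frontier,
    select_dimension,
    standardize_2d_latents,
)


class TestContiguousKfold:
    def test_even_partition(self):
        folds = contiguous_kfold(100, 5)
        assert all(len(te) == 20 for _, te in folds)

    def test_remainder_to_earliest_folds(self):
        folds = contiguous_kfold(103, 5)
        lengths = [len(te) for _, te in folds]
        assert lengths == [21, 21, 21, 20, 20]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(5, 200), st.integers(2, 5))
    def test_partition_properties(self, T, K):
        folds = contiguous_kfold(T, K)
        all_test = np.concatenate([te for _, te in folds])
        assert np.array_equal(np.sort(all_test), np.arange(T))  # exhaustive, disjoint
        for tr, te in folds:
            assert np.intersect1d(tr, te).size == 0
            assert np.array_equal(te, np.arange(te[0], te[-1] + 1))  # contiguous

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            contiguous_kfold(3, 5)


class TestMeanCC:
    def test_perfect_and_anti_correlation(self, rng):
        x = rng.standard_normal((50, 3))
        assert np.isclose(mean_cc(x, x), 1.0)
        assert np.isclose(mean_cc(x, -x), -1.0)

    def test_derived_pearson_example(self):
        actual = np.array([1.0, 2, 3, 4])
        predicted = np.array([1.0, 1, 2, 2])
        expected = scipy.stats.pearsonr(actual, predicted).statistic
        assert np.isclose(mean_cc(actual, predicted), expected)
        assert np.isclose(expected, 0.8944, atol=1e-4)

    def test_affine_invariance_positive_slope(self, rng):
        a = rng.standard_normal((40, 2))
        p = rng.standard_normal((40, 2))
        assert np.isclose(mean_cc(a, p), mean_cc(a, 2.5 * p + 3.0))

    def test_constant_actual_excluded_with_warning(self, rng):
        a = np.column_stack([np.ones(20), rng.standard_normal(20)])
        p = rng.standard_normal((20, 2))
        with pytest.warns(UserWarning, match="constant"):
            out = mean_cc(a, p)
        assert -1 <= out <= 1

    def test_constant_prediction_scores_zero(self, rng):
        a = rng.standard_normal(30)
        assert mean_cc(a, np.ones(30)) == 0.0


class TestMulticlassAUC:
    def test_chance_level_for_uniform_probabilities(self, rng):
        labels = rng.integers(0, 4, size=200)
        probs = np.full((200, 4), 0.25)
        assert np.isclose(multiclass_auc(labels, probs), 0.5)

    def test_perfect_for_one_hot_correct(self, rng):
        labels = rng.integers(0, 4, size=200)
        probs = np.eye(4)[labels]
        assert np.isclose(multiclass_auc(labels, probs), 1.0)

    def test_matches_rank_statistic_oracle(self):
        """Macro one-vs-rest AUC equals the Mann-Whitney U statistic per class."""
        labels = np.array([0, 1, 2, 1, 0, 2])
        rng = np.random.default_rng(5)
        probs = rng.random((6, 3))
        probs /= probs.sum(1, keepdims=True)
        expected = []
        for c in range(3):
            pos = probs[labels == c, c]
            neg = probs[labels != c, c]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            expected.append(wins / (len(pos) * len(neg)))
        assert np.isclose(multiclass_auc(labels, probs), np.mean(expected))

    def test_absent_class_excluded_with_warning(self, rng):
        labels = np.array([0, 1, 0, 1])
        probs = np.full((4, 3), 1 / 3)
        with pytest.warns(UserWarning, match="absent"):
            multiclass_auc(labels, probs)


class TestSelectDimension:
    @staticmethod
    def _report(curves):
        rows = []
        for metric, curve in curves.items():
            for dim, val in curve.items():
                rows.append(dict(fold=0, dim=dim, split="train", metric=metric, value=val))
        return pd.DataFrame(rows)

    def test_smallest_at_peak(self):
        rep = self._report({"decoding": {1: 0.2, 2: 0.5, 4: 0.5}, "selfpred": {1: 0, 2: 0, 4: 0}})
        assert select_dimension(rep, "decoding_peak") == {0: 2}

    def test_joint_rule_takes_larger(self):
        rep = self._report(
            {"decoding": {4: 0.9, 64: 0.9}, "selfpred": {4: 0.1, 64: 0.8}}
        )
        assert select_dimension(rep, "joint_peak") == {0: 64}

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_scan(self, seed):
        r = np.random.default_rng(seed)
        dims = [1, 2, 4, 8]
        dec = {d: r.random() for d in dims}
        sp = {d: r.random() for d in dims}
        rep = self._report({"decoding": dec, "selfpred": sp})
        best_dec = min(d for d in dims if dec[d] == max(dec.values()))
        best_sp = min(d for d in dims if sp[d] == max(sp.values()))
        assert select_dimension(rep, "decoding_peak") == {0: best_dec}
        assert select_dimension(rep, "joint_peak") == {0: max(best_dec, best_sp)}

    def test_empty_curve(self):
        with pytest.raises(ValueError):
            select_dimension(pd.DataFrame(columns=["fold", "dim", "split", "metric", "value"]))


class TestSignedRank:
    def test_equal_samples_not_significant(self):
        a = np.arange(10.0)
        assert paired_signed_rank(a, a) == 1.0

    def test_ten_positive_differences(self):
        """10 strictly positive differences: exact one-sided p = 1/1024."""
        rng = np.random.default_rng(0)
        b = rng.standard_normal(10)
        a = b + rng.random(10) + 0.1
        assert np.isclose(paired_signed_rank(a, b), 1 / 1024)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(6, 11))
    def test_matches_exact_enumeration(self, seed, n):
        """Exact null distribution by enumerating all sign assignments."""
        r = np.random.default_rng(seed)
        d = np.round(r.standard_normal(n), 3)
        d = d[d != 0]
        if len(d) < 5 or len(np.unique(np.abs(d))) != len(d):
            return  # ties/zeros: exact enumeration does not apply
        ranks = scipy.stats.rankdata(np.abs(d))
        W = ranks[d > 0].sum()
        count = 0
        total = 2 ** len(d)
        for m in range(total):
            w = sum(ranks[i] for i in range(len(d)) if m >> i & 1)
            if w >= W:
                count += 1
        assert np.isclose(paired_signed_rank(d, np.zeros_like(d)), count / total)


class TestPerformanceFrontier:
    @staticmethod
    def _samples(mean, n=8, jitter=0.001):
        rng = np.random.default_rng(0)
        return mean + jitter * rng.standard_normal(n)

    def test_dominating_model_only(self):
        ms = {
            "good": (self._samples(0.8), self._samples(0.8)),
            "bad": (self._samples(0.5), self._samples(0.5)),
        }
        out = performance_frontier(ms)
        assert out == {"good": True, "bad": False}

    def test_each_better_in_one_metric(self):
        ms = {
            "decoder": (self._samples(0.9), self._samples(0.4)),
            "predictor": (self._samples(0.4), self._samples(0.9)),
        }
        out = performance_frontier(ms)
        assert out == {"decoder": True, "predictor": True}

    def test_identical_samples_both_on_frontier(self):
        a = self._samples(0.7)
        ms = {"m1": (a, a), "m2": (a.copy(), a.copy())}
        assert performance_frontier(ms) == {"m1": True, "m2": True}

    def test_reduces_to_pareto_dominance_when_all_significant(self):
        """With clearly separated metrics, frontier = Pareto-nondominated set."""
        means = {"a": (0.9, 0.9), "b": (0.8, 0.95), "c": (0.7, 0.7), "d": (0.95, 0.6)}
        ms = {k: (self._samples(v[0]), self._samples(v[1])) for k, v in means.items()}
        out = performance_frontier(ms)
        pareto = {
            k: not any(
                means[o][0] > means[k][0] and means[o][1] > means[k][1] for o in means
            )
            for k in means
        }
        assert out == pareto

    def test_small_mean_difference_not_significant(self):
        """Consistent but < 1% relative differences do not exclude a model."""
        base = self._samples(0.800, jitter=0.0)
        ms = {"m1": (base + 0.004, base), "m2": (base, base)}
        out = performance_frontier(ms)
        assert out == {"m1": True, "m2": True}

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            performance_frontier({"a": (np.ones(5), np.ones(5)), "b": (np.ones(4), np.ones(4))})


class TestDimensionSweep:
    def test_sweep_produces_train_and_test_metrics(self, small_linear_data):
        from priodyn import dimension_sweep
        from priodyn.model import ModelSpec
        from priodyn.training import FitConfig

        cfg = FitConfig(max_epochs=15, patience=10**9, batch_size=8, seed=0)
        spec = ModelSpec(n_y=2, n_z=1, n_x=1, n_1=1)
        rep = dimension_sweep(small_linear_data, spec, cfg, dims=[1, 2], n_folds=2)
        assert set(rep["dim"]) == {1, 2}
        assert set(rep["split"]) == {"train", "test"}
        assert set(rep["metric"]) == {"decoding", "selfpred"}
        assert len(rep) == 2 * 2 * 2 * 2  # folds x dims x splits x metrics
        assert rep["value"].between(-1, 1).all()

    def test_default_dims_are_powers_of_two(self):
        from priodyn.evaluation import DEFAULT_DIMS

        assert list(DEFAULT_DIMS) == [1, 2, 4, 8, 16, 32, 64, 128]


class TestNaiveForecast:
    def test_constant_series_zero_error(self):
        Y = np.ones((30, 2)) * 3.3
        for m in (1, 3, 7):
            assert np.allclose(naive_forecast_baseline(Y, m).y_hat, Y)

    def test_m1_is_one_step_shift(self, rng):
        Y = rng.standard_normal((20, 2))
        out = naive_forecast_baseline(Y, 1).y_hat
        assert np.array_equal(out[1:], Y[:-1])

    def test_ramp_error_grows_linearly_with_horizon(self):
        Y = np.arange(50.0)[:, None]
        errs = [np.abs(Y[10:] - naive_forecast_baseline(Y, m).y_hat[10:]).mean() for m in (1, 2, 4)]
        assert np.allclose(errs, [1.0, 2.0, 4.0])


class TestStandardize2D:
    @staticmethod
    def _trajs(rng, ccw=True):
        t = np.linspace(0, 1.5 * np.pi, 40)
        sgn = 1.0 if ccw else -1.0
        first = np.column_stack([3 * np.cos(sgn * t + 0.7) + 1, 2 * np.sin(sgn * t + 0.7) - 0.5])
        second = rng.standard_normal((25, 2))
        return [first, second]

    def test_zero_mean_unit_variance(self, rng):
        """Pooled states are z-scored before the rotation; the rotation keeps
        the mean at zero and the total variance at 2 (unit per dimension on
        average)."""
        out = standardize_2d_latents(self._trajs(rng))
        pooled = np.concatenate(out)
        assert np.allclose(pooled.mean(0), 0, atol=1e-9)
        assert np.isclose(pooled.var(0).sum(), 2.0, atol=1e-9)

    @pytest.mark.parametrize("ccw", [True, False])
    def test_first_condition_starts_at_angle_zero_counterclockwise(self, rng, ccw):
        out = standardize_2d_latents(self._trajs(rng, ccw))
        p0 = out[0][0]
        assert abs(np.arctan2(p0[1], p0[0])) < 1e-6
        t0 = out[0]
        area = 0.5 * np.sum(t0[:-1, 0] * t0[1:, 1] - t0[1:, 0] * t0[:-1, 1])
        assert area > 0  # counterclockwise after optional reflection

    def test_non_2d_rejected(self, rng):
        with pytest.raises(ValueError):
            standardize_2d_latents([rng.standard_normal((10, 3))])
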