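"""Allocation regressions: family fits, LOOCV selection, holdout sweep,
sequential grouping."""

import numpy as np
import pandas as pd
import pytest

from crossmodulon.allocation import (
    AllocationModel,
    adjusted_r2,
    fit_family,
    holdout_sweep,
    module_mass_fraction,
    normalized_cv_error,
    predict_family,
    select_model_loocv,
    summarize_allocation,
)
from crossmodulon.synth import generate_allocation_data


class TestFitFamily:
    def test_exact_line(self):
        x = np.linspace(-3, 3, 20)
        params, r2 = fit_family(x, 2 * x + 1, "linear")
        assert params["slope"] == pytest.approx(2, abs=1e-10)
        assert params["intercept"] == pytest.approx(1, abs=1e-10)
        assert r2 == pytest.approx(1)

    def test_exact_broken_line(self):
        x = np.linspace(-3, 3, 25)
        y = np.where(x < 0, 0.0, 1.0 * x) + 0.5
        params, r2 = fit_family(x, y, "broken_line")
        # breakpoint lands on an observed x within one grid step of 0
        step = x[1] - x[0]
        assert abs(params["breakpoint"]) <= step + 1e-9
        assert params["left_slope"] == pytest.approx(0, abs=1e-6)
        assert params["right_slope"] == pytest.approx(1, abs=1e-6)

    def test_exact_exponential_rate(self):
        x = np.linspace(-3, 3, 57)
        params, r2 = fit_family(x, 0.1 * np.exp(0.5 * x), "exponential")
        assert params["rate"] == pytest.approx(0.5, abs=1e-4)
        assert r2 == pytest.approx(1, abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            fit_family(np.arange(7.0), np.arange(7.0), "broken_line")


def brute_force_broken_line_sse(x, y):
    """Oracle: exhaustive breakpoint grid with normal-equation segment
    fits (independent of the implementation path)."""
    best = np.inf
    for t in np.unique(x):
        if (x < t).sum() < 2 or (x > t).sum() < 2:
            continue
        basis = np.column_stack([np.ones_like(x), x, np.maximum(x - t, 0.0)])
        G = basis.T @ basis
        rhs = basis.T @ y
        try:
            coef = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            continue
        sse = float(((basis @ coef - y) ** 2).sum())
        best = min(best, sse)
    return best


class TestOracles:
    @pytest.mark.parametrize("seed", range(5))
    def test_broken_line_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 30))
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        params, _ = fit_family(x, y, "broken_line")
        pred = predict_family(params, x, "broken_line")
        sse = float(((pred - y) ** 2).sum())
        assert sse == pytest.approx(brute_force_broken_line_sse(x, y), abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_loocv_equals_explicit_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        x = rng.normal(0, 1, n)
        y = 0.05 + 0.01 * x + rng.normal(0, 0.003, n)
        fit = select_model_loocv(x, y)
        # oracle: plain python leave-one-out loop per family
        for family, mae in fit.family_maes.items():
            preds = []
            for i in range(n):
                mask = [j for j in range(n) if j != i]
                params, _ = fit_family(x[mask], y[mask], family)
                preds.append(predict_family(params, np.array([x[i]]), family)[0])
            oracle_mae = float(np.mean(np.abs(np.array(preds) - y)))
            assert mae == pytest.approx(oracle_mae, abs=1e-12)


class TestSelection:
    def test_noiseless_linear_selected_strong(self):
        x = np.linspace(-2, 2, 20)
        fit = select_model_loocv(x, 0.02 * x + 0.1)
        assert fit.family == "linear"
        assert fit.adjusted_r2 == pytest.approx(1.0)
        assert fit.strength == "strong"

    def test_pure_noise_is_weak(self):
        weak = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 57)
            y = rng.normal(0.05, 0.01, 57)
            fit = select_model_loocv(x, y)
            weak += fit.strength == "weak"
        assert weak / n_seeds >= 0.95

    @pytest.mark.parametrize("family", ["linear", "exponential", "broken_line"])
    def test_generating_family_recovered(self, family):
        hits = 0
        for seed in range(10):
            x, y, _ = generate_allocation_data(family, 57, 0.05, seed=seed)
            fit = select_model_loocv(x, y)
            hits += fit.family == family
        assert hits >= 8

    def test_broken_line_breakpoint_recovered(self):
        x, y, params = generate_allocation_data("broken_line", 57, 0.02, seed=3)
        fit = select_model_loocv(x, y)
        assert fit.family == "broken_line"
        assert abs(fit.parameters["breakpoint"] - params["breakpoint"]) <= 0.1 * np.ptp(x)

    def test_summary_is_printable(self):
        x, y, _ = generate_allocation_data("linear", 20, 0.02, seed=0)
        text = select_model_loocv(x, y).summary()
        assert "family" in text and "LOOCV" in text


class TestNormalizedError:
    def test_perfect_predictions_zero(self):
        assert normalized_cv_error([1, 2], [1, 2], 1.5).tolist() == [0, 0]

    def test_single_value_arithmetic(self):
        assert normalized_cv_error([0.02], [0.01], 0.01)[0] == pytest.approx(1.0)

    def test_five_point_example_matches_explicit_loop(self, rng):
        pred = rng.random(5)
        test = rng.random(5)
        avg = 0.37
        out = normalized_cv_error(pred, test, avg)
        for i in range(5):
            assert out[i] == pytest.approx(abs(pred[i] - test[i]) / avg)

    def test_zero_average_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            normalized_cv_error([1.0], [1.0], 0.0)


class TestHoldoutSweep:
    def test_test_size_rounds_half_up(self):
        x, y, _ = generate_allocation_data("linear", 57, 0.02, seed=0)
        df = holdout_sweep(x, y, fractions=(0.10,), n_repeats=2, seed=0)
        # 57 * 0.10 = 5.7 -> 6 held out
        assert (df["fraction"] == 0.10).all()
        fit_n = 57 - 6
        assert df.shape[0] == 2

    def test_noiseless_linear_every_repeat(self):
        x = np.linspace(-2, 2, 40)
        y = 0.01 * x + 0.05
        df = holdout_sweep(x, y, fractions=(0.2,), n_repeats=3, seed=1)
        assert (df["family"] == "linear").all()
        assert df["test_mae"].max() < 1e-12

    def test_strong_module_stays_strong_across_fractions(self):
        x, y, _ = generate_allocation_data("linear", 57, 0.03, seed=5)
        df = holdout_sweep(x, y, n_repeats=5, seed=2)
        med = df.groupby("fraction")["train_adjusted_r2"].median()
        assert (med >= 0.3).all()

    def test_deterministic_under_seed(self):
        x, y, _ = generate_allocation_data("linear", 30, 0.05, seed=0)
        df1 = holdout_sweep(x, y, fractions=(0.2,), n_repeats=3, seed=9)
        df2 = holdout_sweep(x, y, fractions=(0.2,), n_repeats=3, seed=9)
        pd.testing.assert_frame_equal(df1, df2)


class TestModuleMassFraction:
    def test_whole_proteome_sums_to_one(self, rng):
        frac = pd.DataFrame(
            rng.dirichlet(np.ones(20), size=5).T,
            index=[f"g{i}" for i in range(20)],
            columns=[f"c{j}" for j in range(5)],
        )
        series = module_mass_fraction(list(frac.index), frac)
        assert np.allclose(series, 1.0)

    def test_two_gene_sum(self):
        frac = pd.DataFrame({"c0": [0.01, 0.02, 0.97]}, index=["a", "b", "c"])
        assert module_mass_fraction(["a", "b"], frac)["c0"] == pytest.approx(0.03)

    def test_uncovered_module_rejected(self):
        frac = pd.DataFrame({"c0": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="covered"):
            module_mass_fraction(["z"], frac)


class _FakeFit:
    def __init__(self, ti, adj, strength):
        self.ti_index = ti
        self.adjusted_r2 = adj
        self.strength = strength


class TestSummarizeAllocation:
    def _fractions(self, rng, genes, conds=6):
        return pd.DataFrame(
            rng.dirichlet(np.ones(len(genes)), size=conds).T,
            index=genes,
            columns=[f"c{j}" for j in range(conds)],
        )

    def test_shared_gene_counted_once_in_higher_ranked(self, rng):
        genes = [f"g{i}" for i in range(10)]
        frac = self._fractions(rng, genes)
        fits = {
            "t_hi": _FakeFit("t_hi", 0.9, "strong"),
            "t_lo": _FakeFit("t_lo", 0.5, "strong"),
        }
        members = {"t_hi": {"g0", "g1"}, "t_lo": {"g1", "g2"}}
        summary = {s.group: s for s in summarize_allocation(fits, members, frac)}
        assert summary["strong"].gene_count == 3
        strong_genes = summary["strong"].genes
        assert {"g0", "g1", "g2"} == set(strong_genes)

    def test_single_module_covering_everything(self, rng):
        genes = [f"g{i}" for i in range(8)]
        frac = self._fractions(rng, genes)
        fits = {"t0": _FakeFit("t0", 0.8, "strong")}
        summary = {
            s.group: s
            for s in summarize_allocation(fits, {"t0": set(genes)}, frac)
        }
        assert summary["strong"].gene_count == 8
        assert summary["strong"].mean_mass_share == pytest.approx(1.0)
        assert summary["weak"].gene_count == 0

    def test_group_shares_partition_the_proteome(self, rng):
        genes = [f"g{i}" for i in range(30)]
        frac = self._fractions(rng, genes, conds=10)
        fits = {
            "t0": _FakeFit("t0", 0.7, "strong"),
            "t1": _FakeFit("t1", 0.1, "weak"),
        }
        members = {"t0": set(genes[:5]), "t1": set(genes[5:12])}
        groups = summarize_allocation(fits, members, frac)
        total_share = sum(s.mean_mass_share for s in groups)
        total_genes = sum(s.gene_count for s in groups)
        assert total_share == pytest.approx(1.0, abs=1e-9)
        assert total_genes == 30
        # no gene in two groups
        all_genes = [g for s in groups for g in s.genes]
        assert len(all_genes) == len(set(all_genes))

    def test_invariant_versus_other_split_by_cv(self, rng):
        genes = ["stable", "noisy"]
        frac = pd.DataFrame(
            {
                "c0": [0.5, 0.001],
                "c1": [0.5, 0.9],
                "c2": [0.5, 0.002],
                "c3": [0.5, 0.8],
            },
            index=genes,
        )
        groups = {s.group: s for s in summarize_allocation({}, {}, frac)}
        assert "stable" in groups["invariant"].genes
        assert "noisy" in groups["other"].genes


def test_adjusted_r2_parameter_penalty():
    # same R^2, more parameters -> lower adjusted value
    assert adjusted_r2(0.5, 57, 4) < adjusted_r2(0.5, 57, 2)
    assert adjusted_r2(1.0, 57, 4) == pytest.approx(1.0)


def test_noise_conditions_do_not_flip_strong_linear_module():
    x = np.linspace(-2, 2, 40)
    y = 0.02 * x + 0.1
    rng = np.random.default_rng(0)
    y_noisy = y + rng.normal(0, 1e-6, 40)
    fit = select_model_loocv(x, y_noisy)
    assert fit.strength == "strong"
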