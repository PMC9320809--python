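"""Standardization, fitness, median regression, binomial fit, reduction, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from courtship_select.errors import DegenerateStatisticsError, ValidationError
from courtship_select.selection import (
    _l1_fit_enumerate,
    _l1_fit_lp,
    binomial_success_regression,
    build_trait_table,
    median_regression,
    pca_traits,
    relative_fitness,
    standardize,
    variable_select,
)


class TestStandardize:
    def test_sample_sd_convention(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_constant_column_error(self):
        with pytest.raises(DegenerateStatisticsError):
            standardize([2.0, 2.0, 2.0], name="cVA")

    def test_idempotent(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        np.testing.assert_allclose(standardize(standardize(x)), standardize(x), atol=1e-12)


class TestRelativeFitness:
    def test_latency_convention(self):
        np.testing.assert_allclose(
            relative_fitness([100, 200, 300], "latency"), [0.5, 1.0, 1.5]
        )

    def test_inverse_latency_convention(self):
        np.testing.assert_allclose(
            relative_fitness([100, 200], "inverse_latency"), [4 / 3, 2 / 3]
        )

    def test_equal_latencies_all_one(self):
        for conv in ("latency", "inverse_latency"):
            np.testing.assert_allclose(relative_fitness([50, 50, 50], conv), 1.0)

    def test_mean_is_one(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(20, 900, 13)
        for conv in ("latency", "inverse_latency"):
            assert relative_fitness(t, conv).mean() == pytest.approx(1.0)

    def test_mating_index_convention_handles_infinite(self):
        w = relative_fitness([100.0, 200.0, np.inf], "mating_index")
        assert w[2] == 0.0
        assert w.mean() == pytest.approx(1.0)

    def test_nonpositive_latency_rejected(self):
        with pytest.raises(ValidationError):
            relative_fitness([100, 0], "latency")


class TestMedianRegression:
    def test_collinear_points_exact(self):
        z = np.array([-1.0, 0.0, 1.0])
        w = 1 + 0.5 * z
        res = median_regression(z, w, n_boot=200, seed=1)
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.ci_low == pytest.approx(0.5, abs=1e-9)
        assert res.ci_high == pytest.approx(0.5, abs=1e-9)

    def test_outlier_does_not_drag_median_fit(self):
        # three collinear points plus one outlier: the six-candidate-line
        # enumeration and the LP agree, and the flat majority line attains
        # the optimal loss (the outlier costs 4 whichever optimum is picked)
        z = np.array([-1.0, 0.0, 1.0, 2.0])
        w = np.array([1.0, 1.0, 1.0, 5.0])
        a_e, b_e, loss_e = _l1_fit_enumerate(z, w)
        a_l, b_l, loss_l = _l1_fit_lp(z, w)
        assert loss_e == pytest.approx(loss_l, abs=1e-9)
        flat_loss = np.abs(w - 1.0).sum()
        assert loss_e == pytest.approx(flat_loss, abs=1e-9)

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=60, deadline=None)
    def test_enumeration_equals_linear_program(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        z = rng.standard_normal(n)
        w = 1 + 0.3 * z + rng.standard_normal(n) * 0.2
        a_e, b_e, loss_e = _l1_fit_enumerate(z, w)
        a_l, b_l, loss_l = _l1_fit_lp(z, w)
        assert loss_l == pytest.approx(loss_e, abs=1e-8)

    def test_slope_recovery_under_laplace_noise(self):
        """w = 1 + 0.4 z + Laplace(0, 0.1), n = 200: slope lands within
        0.05 of truth in ≥95% of replicates (LP path)."""
        rng = np.random.default_rng(7)
        hits = 0
        reps = 60
        for _ in range(reps):
            z = standardize(rng.standard_normal(200))
            w = 1 + 0.4 * z + rng.laplace(0, 0.1, 200)
            _, b, _ = _l1_fit_lp(z, w)
            hits += abs(b - 0.4) < 0.05
        assert hits / reps >= 0.95

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            median_regression([1, 2], [1, 1], n_boot=100)
        with pytest.raises(DegenerateStatisticsError):
            median_regression([1.0, 1.0, 1.0], [1, 2, 3], n_boot=100)


class TestBinomialRegression:
    def test_flat_success_gives_zero_slope(self):
        z = np.array([-1.0, 0.0, 1.0])
        res = binomial_success_regression(z, [5, 5, 5], [10, 10, 10])
        assert res.coef == pytest.approx(0.0, abs=1e-8)
        assert res.intercept == pytest.approx(0.0, abs=1e-8)

    def test_two_point_closed_form(self):
        # logit(0.2) = a − b, logit(0.8) = a + b → a = 0, b = ln 4
        z = np.array([-1.0, 1.0, 0.0])
        res = binomial_success_regression(z, [2, 8, 5], [10, 10, 10])
        assert res.intercept == pytest.approx(0.0, abs=1e-6)
        assert res.coef == pytest.approx(np.log(4.0), abs=1e-6)

    def test_complete_separation_flagged(self):
        z = np.array([-2.0, -1.0, 1.0, 2.0])
        res = binomial_success_regression(z, [0, 0, 10, 10], [10, 10, 10, 10])
        assert res.separated
        assert not res.excludes_zero

    def test_zero_trials_rejected(self):
        with pytest.raises(ValidationError):
            binomial_success_regression([0.0, 1.0, 2.0], [0, 1, 1], [0, 2, 2])


class TestVariableSelect:
    @staticmethod
    def signal_data(seed, n=60, p=10):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.standard_normal((n, p)), columns=[f"t{i}" for i in range(p)]
        )
        y = X["t0"].to_numpy() + 0.3 * rng.standard_normal(n)
        return X, y

    def test_deterministic_given_seed(self):
        X, y = self.signal_data(0)
        a = variable_select(X, y, seed=42, n_fits=10, n_trees=40, refit_fits=5)
        b = variable_select(X, y, seed=42, n_fits=10, n_trees=40, refit_fits=5)
        assert a == b

    def test_recovers_signal_trait_with_few_false_positives(self):
        ok = 0
        runs = 8
        for seed in range(runs):
            X, y = self.signal_data(seed)
            sel = variable_select(X, y, seed=seed, n_fits=12, n_trees=50, refit_fits=5)
            ok += ("t0" in sel) and (len(sel) <= 2)
        assert ok >= runs - 1

    def test_all_noise_selects_at_most_one(self):
        ok = 0
        runs = 8
        for seed in range(runs):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(
                rng.standard_normal((60, 8)), columns=[f"t{i}" for i in range(8)]
            )
            y = rng.standard_normal(60)
            sel = variable_select(X, y, seed=seed, n_fits=12, n_trees=50, refit_fits=5)
            ok += len(sel) <= 1
        assert ok >= runs - 1

    def test_constant_response_error(self):
        X, _ = self.signal_data(1)
        with pytest.raises(DegenerateStatisticsError):
            variable_select(X, np.ones(len(X)), seed=0, n_fits=4)


class TestPcaTraits:
    def test_perfectly_correlated_pair_loads_on_pc1(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({"a": x, "b": 3 * x})
        out = pca_traits(df)
        assert out["explained"]["PC1"] == pytest.approx(1.0)

    def test_block_structure_matches_eigensolve_oracle(self):
        # two independent blocks of unequal size (3 vs 2 traits) so the two
        # leading eigenvalues are well separated and block-pure
        rng = np.random.default_rng(5)
        block1 = rng.standard_normal(30)
        block2 = rng.standard_normal(30)
        noise = lambda: 0.01 * rng.standard_normal(30)
        df = pd.DataFrame(
            {"a1": block1, "a2": block1 + noise(), "a3": block1 + noise(),
             "b1": block2, "b2": block2 + noise()}
        )
        out = pca_traits(df)
        Z = np.column_stack([standardize(df[c]) for c in df.columns])
        evals = np.sort(np.linalg.eigvalsh((Z.T @ Z) / (len(df) - 1)))[::-1]
        np.testing.assert_allclose(
            out["explained"].to_numpy(), evals / evals.sum(), atol=1e-10
        )
        load = out["loadings"].abs()
        assert set(load["PC1"].nlargest(3).index) == {"a1", "a2", "a3"}
        assert set(load["PC2"].nlargest(2).index) == {"b1", "b2"}

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.standard_normal((6, 4)), columns=list("abcd"))
        a = pca_traits(df)
        b = pca_traits(df)
        pd.testing.assert_frame_equal(a["loadings"], b["loadings"])
        for comp in a["loadings"].columns:
            col = a["loadings"][comp]
            assert col[col.abs().idxmax()] > 0

    def test_too_few_strains_error(self):
        with pytest.raises(ValidationError):
            pca_traits(pd.DataFrame({"a": [1, 2.0], "b": [2, 1.0]}))


class TestTraitTable:
    def test_standardization_and_fitness_invariants(self, small_panel):
        from courtship_select.behavior import summarize_panel
        from courtship_select.io import chc_profiles_to_frame

        summaries = summarize_panel(small_panel.trials)
        frame = chc_profiles_to_frame(small_panel.chc_profiles)
        chc_means = frame.drop(columns=["individual", "sex", "treatment"]).groupby("strain").mean()
        table = build_trait_table(summaries, "Mlike", chc_means)
        zcols = [c for c in table.columns if c.startswith("z_")]
        for c in zcols:
            assert table[c].mean() == pytest.approx(0.0, abs=1e-9)
            assert table[c].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert table["w"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_success_strains_dropped_for_gradient(self, small_panel):
        from courtship_select.behavior import summarize_panel

        summaries = summarize_panel(small_panel.trials)
        never = small_panel.config.never_mate  # e.g. S02 never mates with Mlike
        male = [m for m, f in never.items() if f == "Mlike"][0]
        table = build_trait_table(summaries, "Mlike")
        assert male not in table.index
        btable = build_trait_table(summaries, "Mlike", drop_zero_success=False)
        assert male in btable.index

    def test_mating_index_fitness_retains_never_mating_strains(self, small_panel):
        from courtship_select.behavior import summarize_panel

        summaries = summarize_panel(small_panel.trials)
        never = [m for m, f in small_panel.config.never_mate.items() if f == "Mlike"][0]
        table = build_trait_table(summaries, "Mlike", fitness="mating_index")
        assert never in table.index
        assert table.loc[never, "w"] == 0.0  # infinite index → zero fitness
        assert table["w"].mean() == pytest.approx(1.0, abs=1e-9)
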