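"""Stability percentiles, group tests, winsorized regression, stratified bootstrap."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from pulserate.stats import (
    CELLS,
    bootstrap_model,
    composition_enrichment,
    correlation_r2,
    fit_linear_model,
    group_mean_changes,
    group_stability_test,
    odds_ratio_ci,
    stability_percentile,
    winsorize_log,
)


def make_flags(index, tf, me3, cts):
    return pd.DataFrame({"tf": tf, "me3": me3, "cts": cts}, index=index)


def eight_group_data(n_per_cell=30, means=None, sd=0.1, seed=0):
    """Balanced 8-cell dataset with configurable cell means."""
    rng = np.random.default_rng(seed)
    if means is None:
        means = {cell: rng.normal(0, 1) for cell in CELLS}
    rows, ys = [], []
    for cell in CELLS:
        for _ in range(n_per_cell):
            rows.append(cell)
            ys.append(means[cell] + sd * rng.standard_normal())
    index = pd.Index([f"g{i}" for i in range(len(ys))])
    flags = make_flags(index, *(np.array(rows).T.astype(bool)))
    return pd.Series(ys, index=index), flags, means


class TestPercentiles:
    def test_four_distinct_rates(self):
        decay = pd.Series([0.4, 0.3, 0.2, 0.1], index=list("abcd"))
        pct = stability_percentile(decay)
        assert pct.to_dict() == {"a": 25.0, "b": 50.0, "c": 75.0, "d": 100.0}

    def test_ties_share_percentile(self):
        pct = stability_percentile(pd.Series([0.1, 0.1, 0.5], index=list("abc")))
        assert pct["a"] == pct["b"]

    def test_least_stable_gene_has_lowest_percentile(self):
        rng = np.random.default_rng(1)
        decay = pd.Series(rng.lognormal(size=100))
        pct = stability_percentile(decay)
        assert pct.idxmin() == decay.idxmax()
        assert pct.mean() == pytest.approx(50.0, abs=1.0)


class TestGroupTest:
    def test_identical_distributions_give_central_u(self):
        decay = pd.Series(np.r_[np.arange(1, 21), np.arange(1, 21)] + 0.0,
                          index=[f"g{i}" for i in range(40)])
        pct = stability_percentile(decay)
        out = group_stability_test(decay, pct, {f"g{i}" for i in range(20)})
        assert out["U"] == pytest.approx(20 * 20 / 2)

    def test_planted_shift_is_detected_with_stars(self):
        rng = np.random.default_rng(2)
        n = 2000
        decay = pd.Series(rng.normal(0, 1, n), index=[f"g{i}" for i in range(n)])
        group = {f"g{i}" for i in range(200)}
        decay.loc[sorted(group)] += 3.0
        pct = stability_percentile(decay)
        out = group_stability_test(decay, pct, group)
        assert out["p"] < 1e-10
        assert out["stars"] in ("**", "***")
        assert out["median_percentile"] < 20

    def test_singleton_group_is_testable(self):
        decay = pd.Series(np.arange(1.0, 31.0), index=[f"g{i}" for i in range(30)])
        pct = stability_percentile(decay)
        out = group_stability_test(decay, pct, {"g0"})
        assert 0 < out["p"] <= 1

    def test_empty_or_universal_group_rejected(self):
        decay = pd.Series([1.0, 2.0], index=["a", "b"])
        pct = stability_percentile(decay)
        with pytest.raises(ValueError):
            group_stability_test(decay, pct, set())
        with pytest.raises(ValueError):
            group_stability_test(decay, pct, {"a", "b"})


class TestEnrichment:
    def test_fraction_arithmetic(self):
        universe = pd.Index([f"g{i}" for i in range(200)])
        feature = pd.Series(universe.isin([f"g{i}" for i in range(13)] + ["g150"]), index=universe)
        frac, _ = composition_enrichment({f"g{i}" for i in range(100)}, feature)
        assert frac == pytest.approx(0.13)

    def test_background_rate_is_not_significant(self):
        universe = pd.Index([f"g{i}" for i in range(100)])
        feature = pd.Series([i % 2 == 0 for i in range(100)], index=universe)
        frac, p = composition_enrichment({f"g{i}" for i in range(0, 40)}, feature)
        assert p > 0.5

    def test_nested_rare_feature_matches_hypergeometric_tail(self):
        universe = pd.Index([f"g{i}" for i in range(1000)])
        feature = pd.Series(universe.isin([f"g{i}" for i in range(20)]), index=universe)
        group = {f"g{i}" for i in range(15)}
        frac, p = composition_enrichment(group, feature)
        assert frac == 1.0
        # one-sided hypergeometric upper tail bounds the two-sided Fisher p
        tail = sps.hypergeom.sf(14, 1000, 20, 15)
        assert p < 1e-4
        assert p >= tail

    def test_odds_ratio_values_and_woolf_ci(self):
        assert odds_ratio_ci([[10, 10], [10, 10]])["odds_ratio"] == pytest.approx(1.0)
        out = odds_ratio_ci([[20, 5], [5, 20]])
        assert out["odds_ratio"] == pytest.approx(16.0)
        se = np.sqrt(1 / 20 + 1 / 5 + 1 / 5 + 1 / 20)
        assert out["ci_low"] == pytest.approx(np.exp(np.log(16) - 1.959964 * se), rel=1e-6)
        assert out["ci_high"] == pytest.approx(np.exp(np.log(16) + 1.959964 * se), rel=1e-6)

    def test_zero_cell_uses_haldane_and_empty_margin_errors(self):
        out = odds_ratio_ci([[10, 0], [5, 20]])
        assert np.isfinite(out["odds_ratio"])
        with pytest.raises(ValueError):
            odds_ratio_ci([[0, 0], [5, 20]])


class TestWinsorize:
    def test_all_equal_unchanged(self):
        y = winsorize_log(pd.Series([0.5] * 10))
        assert np.allclose(y, np.log10(0.5))

    def test_exactly_two_per_tail_replaced_in_200(self):
        rng = np.random.default_rng(5)
        decay = pd.Series(rng.lognormal(0, 1, 200))
        y = winsorize_log(decay, tail=0.01)
        raw = np.log10(decay.to_numpy())
        lo, hi = np.quantile(raw, [0.01, 0.99])
        order = np.sort(raw)
        assert (order[:2] < lo).all() and (order[2] > lo)
        assert (order[-2:] > hi).all() and (order[-3] < hi)
        assert (y.to_numpy() != raw).sum() == 4
        assert y.min() == pytest.approx(lo)
        assert y.max() == pytest.approx(hi)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            winsorize_log(pd.Series([0.1, 0.0]))

    def test_downstream_fit_insensitive_to_outlier_inflation(self):
        y, flags, _ = eight_group_data(seed=3)
        decay = pd.Series(10 ** y.to_numpy(), index=y.index)
        inflated = decay.copy()
        inflated.loc[inflated.idxmax()] *= 1e6
        fit_a = fit_linear_model(winsorize_log(decay), flags, interactions=True)
        fit_b = fit_linear_model(winsorize_log(inflated), flags, interactions=True)
        np.testing.assert_allclose(fit_a.params, fit_b.params, atol=0.05)


class TestLinearModel:
    def test_saturated_model_reproduces_cell_means(self):
        y, flags, means = eight_group_data(seed=7)
        fit = fit_linear_model(y, flags, interactions=True)
        observed = y.groupby(
            [flags["tf"].astype(int), flags["me3"].astype(int), flags["cts"].astype(int)]
        ).mean()
        p = fit.params
        assert p["beta0"] == pytest.approx(observed[(0, 0, 0)], abs=1e-10)
        assert p["beta0"] + p["beta1"] == pytest.approx(observed[(1, 0, 0)], abs=1e-10)
        assert p["beta0"] + p["beta1"] + p["beta2"] + p["beta4"] == pytest.approx(
            observed[(1, 1, 0)], abs=1e-10
        )
        fitted = fit.fitted_cell_means()
        for cell in CELLS:
            assert fitted[str(cell)] == pytest.approx(observed[cell], abs=1e-10)

    def test_additive_fit_matches_normal_equations(self):
        y, flags, _ = eight_group_data(seed=9)
        fit = fit_linear_model(y, flags, interactions=False)
        X = np.column_stack(
            [
                np.ones(len(y)),
                flags["tf"].to_numpy(float),
                flags["me3"].to_numpy(float),
                flags["cts"].to_numpy(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-10)

    def test_empty_cell_with_interactions_names_cell(self):
        y, flags, _ = eight_group_data(seed=11)
        keep = ~((flags["tf"]) & (flags["me3"]) & (flags["cts"]))
        with pytest.raises(ValueError, match=r"\(1, 1, 1\)"):
            fit_linear_model(y[keep], flags[keep], interactions=True)

    def test_all_flags_zero_gives_grand_mean_intercept(self):
        index = pd.Index([f"g{i}" for i in range(50)])
        y = pd.Series(np.random.default_rng(1).normal(2.0, 0.1, 50), index=index)
        flags = make_flags(index, False, False, False)
        fit = fit_linear_model(y, flags, interactions=False)
        assert fit.params["beta0"] == pytest.approx(y.mean())
        assert fit.params[["beta1", "beta2", "beta3"]].abs().max() < 1e-10


class TestBootstrap:
    def test_fixed_seed_reproduces_draws(self):
        y, flags, _ = eight_group_data(seed=13)
        a = bootstrap_model(y, flags, n_iter=50, seed=123)
        b = bootstrap_model(y, flags, n_iter=50, seed=123)
        pd.testing.assert_frame_equal(a.draws_interaction, b.draws_interaction)
        pd.testing.assert_frame_equal(a.draws_additive, b.draws_additive)

    def test_vectorized_reduction_matches_literal_refit(self):
        """One resample drawn the same way, refit with statsmodels OLS."""
        y, flags, _ = eight_group_data(n_per_cell=12, seed=17)
        n_iter, seed = 3, 99
        boot = bootstrap_model(y, flags, n_iter=n_iter, seed=seed)
        n = boot.per_group_n

        X3 = flags[["tf", "me3", "cts"]].to_numpy().astype(int)
        yv = y.to_numpy()
        rng = np.random.default_rng(seed)
        picks = {}
        for cell in CELLS:
            members = np.flatnonzero((X3 == np.array(cell)).all(axis=1))
            picks[cell] = members[rng.integers(0, members.size, size=(n_iter, n))]
        for it in range(n_iter):
            rows = np.concatenate([picks[cell][it] for cell in CELLS])
            yy = yv[rows]
            xx = X3[rows].astype(float)
            design = np.column_stack(
                [np.ones(len(yy)), xx,
                 xx[:, 0] * xx[:, 1], xx[:, 0] * xx[:, 2], xx[:, 1] * xx[:, 2],
                 xx[:, 0] * xx[:, 1] * xx[:, 2]]
            )
            ref = sm.OLS(yy, design).fit().params
            np.testing.assert_allclose(
                boot.draws_interaction.iloc[it].to_numpy(), ref, rtol=1e-8, atol=1e-10
            )
            ref4 = sm.OLS(yy, design[:, :4]).fit().params
            np.testing.assert_allclose(
                boot.draws_additive.iloc[it].to_numpy(), ref4, rtol=1e-8, atol=1e-10
            )

    def test_min_group_rule_sets_resample_size(self):
        y, flags, _ = eight_group_data(n_per_cell=20, seed=19)
        smallest = y.index[
            (flags["tf"]) & (flags["me3"]) & (flags["cts"])
        ][:5]
        keep = ~flags.index.isin(y.index[(flags["tf"]) & (flags["me3"]) & (flags["cts"])][5:])
        boot = bootstrap_model(y[keep], flags[keep], n_iter=10, seed=1)
        assert boot.per_group_n == 5

    def test_additive_means_give_null_centered_interactions(self):
        means = {cell: 1.0 + 0.5 * cell[0] + 0.3 * cell[1] - 0.2 * cell[2] for cell in CELLS}
        y, flags, _ = eight_group_data(n_per_cell=200, means=means, sd=0.05, seed=23)
        boot = bootstrap_model(y, flags, n_iter=2000, seed=7)
        for name in ("beta4", "beta5", "beta6", "beta7"):
            draws = boot.draws_interaction[name]
            mc_se = draws.std(ddof=1)
            assert abs(draws.median()) < 2 * mc_se

    def test_bootstrap_mean_converges_to_balanced_fit_not_raw_fit(self):
        # unbalanced data in which equal-weight and raw OLS differ
        means = {cell: float(sum(cell)) for cell in CELLS}
        rng = np.random.default_rng(29)
        rows, ys = [], []
        sizes = {cell: 10 if sum(cell) >= 2 else 300 for cell in CELLS}
        for cell, size in sizes.items():
            for _ in range(size):
                rows.append(cell)
                ys.append(means[cell] + 0.4 * rng.standard_normal())
        index = pd.Index([f"g{i}" for i in range(len(ys))])
        flags = make_flags(index, *(np.array(rows).T.astype(bool)))
        y = pd.Series(ys, index=index)

        boot = bootstrap_model(y, flags, n_iter=4000, seed=31)
        cell_means = np.array(
            [y[(flags[["tf", "me3", "cts"]].astype(int) == np.array(c)).all(axis=1)].mean() for c in CELLS]
        )
        D4 = np.array([[1, *c] for c in CELLS], dtype=float)
        balanced = np.linalg.pinv(D4) @ cell_means
        raw = fit_linear_model(y, flags, interactions=False).params.to_numpy()
        boot_mean = boot.draws_additive.mean().to_numpy()
        np.testing.assert_allclose(boot_mean, balanced, atol=0.02)
        assert np.abs(raw - balanced).max() > 0.05  # the two targets genuinely differ

    def test_empty_group_rejected(self):
        y, flags, _ = eight_group_data(seed=37)
        keep = ~((flags["tf"]) & (flags["me3"]) & (flags["cts"]))
        with pytest.raises(ValueError, match=r"\(1, 1, 1\)"):
            bootstrap_model(y[keep], flags[keep], n_iter=10, seed=0)


class TestMeanChanges:
    def test_constant_planted_effect_recovered_in_all_contexts(self):
        means = {cell: 1.0 + 0.3 * cell[1] + 0.1 * cell[0] for cell in CELLS}
        y, flags, _ = eight_group_data(n_per_cell=50, means=means, sd=0.0, seed=41)
        table = group_mean_changes(y, flags)
        me3_rows = table[table["feature"] == "me3"]
        np.testing.assert_allclose(me3_rows["delta"], 0.3, atol=1e-12)
        cts_rows = table[table["feature"] == "CTS"]
        np.testing.assert_allclose(cts_rows["delta"], 0.0, atol=1e-12)

    def test_empty_cell_reported_missing_not_zero(self):
        y, flags, _ = eight_group_data(n_per_cell=5, seed=43)
        drop = (flags["tf"]) & (flags["me3"]) & (flags["cts"])
        table = group_mean_changes(y[~drop], flags[~drop])
        row = table[(table["feature"] == "TF") & (table["context"] == "me3=1,CTS=1")]
        assert np.isnan(row["delta"].iloc[0])
        assert row["n_with"].iloc[0] == 0


class TestCorrelation:
    def test_identity_and_independence(self):
        rng = np.random.default_rng(47)
        x = pd.Series(rng.lognormal(0, 1, 10000))
        assert correlation_r2(x, x) == pytest.approx(1.0)
        y = pd.Series(rng.lognormal(0, 1, 10000))
        assert correlation_r2(x, y) < 0.01

    def test_constant_input_rejected(self):
        x = pd.Series([1.0, 1.0, 1.0])
        y = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlation_r2(x, y)
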