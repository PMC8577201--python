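"""Regression, ANOVA and protected-LSD layer against brute-force algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st_h
from scipy import stats as sps

from rhizosim.stats import (
    analyze_trial,
    fit_linear,
    fit_quadratic,
    percent_change_from_fit,
    protected_lsd,
    treatment_percent_difference,
    two_way_block_anova,
)


def normal_equations(x, y, degree):
    X = np.vander(x, degree + 1, increasing=True)
    return np.linalg.solve(X.T @ X, X.T @ y)


def balanced_table(rng, n_g=4, n_t=2, n_b=3, effects=None):
    rows = []
    g_eff = effects["g"] if effects else rng.normal(0, 1, n_g)
    t_eff = effects["t"] if effects else rng.normal(0, 1, n_t)
    b_eff = effects["b"] if effects else rng.normal(0, 1, n_b)
    for gi in range(n_g):
        for ti in range(n_t):
            for bi in range(n_b):
                y = 10 + g_eff[gi] + t_eff[ti] + b_eff[bi] + rng.normal(0, 0.5)
                rows.append({"ril": f"G{gi}", "treatment": f"T{ti}",
                             "block": bi + 1, "y": y})
    return pd.DataFrame(rows)


def anova_brute_force(df):
    """Direct sums-of-squares decomposition for the balanced layout."""
    y = df["y"].to_numpy()
    gm = y.mean()
    out = {}
    for eff, col in (("genotype", "ril"), ("treatment", "treatment"), ("block", "block")):
        means = df.groupby(col)["y"].mean()
        n = len(df) / len(means)
        out[eff] = float(n * ((means - gm) ** 2).sum())
    cell = df.groupby(["ril", "treatment"])["y"].mean()
    gmean = df.groupby("ril")["y"].mean()
    tmean = df.groupby("treatment")["y"].mean()
    nb = df["block"].nunique()
    out["interaction"] = float(nb * sum(
        (cell[(g, t)] - gmean[g] - tmean[t] + gm) ** 2 for g, t in cell.index))
    sst = float(((y - gm) ** 2).sum())
    out["residual"] = sst - sum(out.values())
    out["total"] = sst
    return out


class TestFitLinear:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        f = fit_linear(x, 2 * x + 1)
        assert (f.intercept, f.slope, f.r_squared) == pytest.approx((1.0, 2.0, 1.0))

    def test_constant_response(self):
        f = fit_linear([0, 1, 2, 3], [5, 5, 5, 5])
        assert f.slope == pytest.approx(0.0)
        assert f.r_squared == 0.0

    def test_matches_normal_equations(self, rng):
        for _ in range(20):
            x = rng.normal(0, 2, 10)
            y = rng.normal(0, 3, 10)
            f = fit_linear(x, y)
            a, b = normal_equations(x, y, 1)
            assert f.intercept == pytest.approx(a, abs=1e-10)
            assert f.slope == pytest.approx(b, abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_linear([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_linear([1, 2], [1, 2])


class TestFitQuadratic:
    def test_exact_parabola(self):
        x = np.linspace(-2, 2, 7)
        f = fit_quadratic(x, x ** 2)
        assert f.quadratic == pytest.approx(1.0, abs=1e-10)
        assert f.r_squared == pytest.approx(1.0)

    def test_linear_data_nests(self, rng):
        x = np.linspace(0, 1, 9)
        y = 3 * x + rng.normal(0, 0.01, 9)
        fq = fit_quadratic(x, y)
        fl = fit_linear(x, y)
        assert abs(fq.quadratic) < 0.2
        assert fq.r_squared >= fl.r_squared

    def test_matches_polynomial_normal_equations(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        f = fit_quadratic(x, y)
        a, b, c = normal_equations(x, y, 2)
        assert (f.intercept, f.slope, f.quadratic) == pytest.approx((a, b, c), abs=1e-9)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic([1, 1, 2, 2], [1, 2, 3, 4])

    @given(st_h.integers(0, 10 ** 6))
    def test_quadratic_r2_never_below_linear(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 8)
        if np.ptp(x) == 0 or len(np.unique(x)) < 3:
            return
        y = rng.normal(0, 1, 8)
        assert fit_quadratic(x, y).r_squared >= fit_linear(x, y).r_squared - 1e-12


class TestPercentChange:
    def test_flat_fit_zero_change(self):
        f = fit_linear([0, 1, 2], [4, 4, 4])
        assert percent_change_from_fit(f, 0, 2).value == pytest.approx(0.0)

    def test_hand_evaluated_line(self):
        f = fit_linear([0.0, 0.5, 1.0], [1.0, 2.0, 3.0])  # y = 1 + 2x
        assert percent_change_from_fit(f, 0.0, 1.0).value == pytest.approx(200.0)

    def test_scale_invariance(self):
        f1 = fit_linear([0.0, 0.5, 1.0], [1.0, 2.0, 3.0])
        f2 = fit_linear([0.0, 0.5, 1.0], [2.0, 4.0, 6.0])
        assert percent_change_from_fit(f1, 0, 1).value == pytest.approx(
            percent_change_from_fit(f2, 0, 1).value)

    def test_nonpositive_baseline_raises_with_value(self):
        f = fit_linear([0.0, 0.5, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="-1"):
            percent_change_from_fit(f, -1.0, 1.0)


class TestAnova:
    def test_matches_direct_ss_decomposition(self, rng):
        df = balanced_table(rng)
        tab = two_way_block_anova(df, "y").table
        brute = anova_brute_force(df)
        for eff in ("genotype", "treatment", "interaction", "block", "residual"):
            assert tab.loc[eff, "sum_sq"] == pytest.approx(brute[eff], abs=1e-8)
        assert tab["df"].sum() == len(df) - 1
        assert tab["sum_sq"].sum() == pytest.approx(brute["total"], abs=1e-8)

    def test_additive_known_effects_no_noise(self):
        g_eff = np.array([0.0, 1.0, 2.0])
        t_eff = np.array([0.0, 4.0])
        b_eff = np.array([0.0, -1.0])
        rows = []
        for gi in range(3):
            for ti in range(2):
                for bi in range(2):
                    rows.append({"ril": f"G{gi}", "treatment": f"T{ti}",
                                 "block": bi, "y": 5 + g_eff[gi] + t_eff[ti] + b_eff[bi]})
        df = pd.DataFrame(rows)
        tab = two_way_block_anova(df, "y").table
        # hand-computed effect sums of squares for the additive layout:
        # genotype deviations (-1, 0, 1) with 4 obs per level; treatment
        # deviations (-2, +2) with 6 obs per level
        assert tab.loc["genotype", "sum_sq"] == pytest.approx(4 * 2.0, abs=1e-8)
        assert tab.loc["treatment", "sum_sq"] == pytest.approx(6 * 8.0, abs=1e-8)
        assert tab.loc["interaction", "sum_sq"] == pytest.approx(0.0, abs=1e-8)
        assert tab.loc["residual", "sum_sq"] == pytest.approx(0.0, abs=1e-8)

    def test_row_order_invariance(self, rng):
        df = balanced_table(rng)
        tab1 = two_way_block_anova(df, "y").table
        tab2 = two_way_block_anova(df.sample(frac=1, random_state=1), "y").table
        pd.testing.assert_frame_equal(tab1, tab2)

    def test_constant_trait_flagged(self, rng):
        df = balanced_table(rng)
        df["y"] = 3.0
        out = two_way_block_anova(df, "y")
        assert out.zero_variance
        assert (out.table["sum_sq"] == 0).all()

    def test_unbalanced_rejected(self, rng):
        df = balanced_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced|incomplete"):
            two_way_block_anova(df, "y")

    def test_splitplot_uses_whole_plot_error_for_treatment(self, rng):
        df = balanced_table(rng, n_g=5, n_t=2, n_b=3)
        rcbd = two_way_block_anova(df, "y", design="rcbd")
        sp = two_way_block_anova(df, "y", design="splitplot")
        assert "whole_plot_error" in sp.table.index
        assert sp.table["df"].sum() == len(df) - 1
        # treatment F re-tested against MS(block x treatment)
        ms_wp = sp.table.loc["whole_plot_error", "mean_sq"]
        expect_f = sp.table.loc["treatment", "mean_sq"] / ms_wp
        assert sp.table.loc["treatment", "F"] == pytest.approx(expect_f)
        assert rcbd.table.loc["genotype", "F"] == pytest.approx(
            sp.table.loc["genotype", "mean_sq"] / sp.table.loc["residual", "mean_sq"],
            rel=0.2)


class TestProtectedLsd:
    def anova_with(self, p_genotype, ms_res=2.0, df_res=12):
        tab = pd.DataFrame(
            {"df": [3, 1, 3, 2, df_res], "sum_sq": [1, 1, 1, 1, ms_res * df_res]},
            index=["genotype", "treatment", "interaction", "block", "residual"])
        tab["mean_sq"] = tab["sum_sq"] / tab["df"]
        tab["F"] = np.nan
        tab["p"] = [p_genotype, 0.5, 0.5, 0.5, np.nan]
        from rhizosim.stats import AnovaTable
        return AnovaTable(table=tab)

    def test_protection_failure_gives_no_letters(self):
        means = pd.Series({"a": 5.0, "b": 4.0}, name="y")
        out = protected_lsd(self.anova_with(0.5), means, 4)
        assert not out.protected and out.letters == {} and out.lsd is None

    def test_huge_separation_distinct_letters(self):
        means = pd.Series({"hi": 100.0, "lo": 1.0})
        out = protected_lsd(self.anova_with(0.001), means, 4)
        assert out.letters["hi"] != out.letters["lo"]

    def test_lsd_value_matches_hand_formula_and_pairwise_oracle(self, rng):
        ms_res, df_res, n = 2.0, 12, 4
        anova = self.anova_with(0.001, ms_res, df_res)
        means = pd.Series(rng.normal(10, 2, 5), index=list("abcde"))
        out = protected_lsd(anova, means, n)
        expect = sps.t.ppf(0.975, df_res) * np.sqrt(2 * ms_res / n)
        assert out.lsd == pytest.approx(expect, rel=1e-12)
        # exhaustive pairwise oracle: shared letter <=> |diff| <= LSD
        for a in means.index:
            for b in means.index:
                share = bool(set(out.letters[a]) & set(out.letters[b]))
                close = abs(means[a] - means[b]) <= out.lsd
                assert share == close, (a, b)

    def test_mismatched_inputs_rejected(self):
        means = pd.Series([1.0, 1.0], index=["x", "x"])
        with pytest.raises(ValueError):
            protected_lsd(self.anova_with(0.001), means, 4)


class TestTreatmentPercentDifference:
    def test_identical_means_zero(self):
        df = pd.DataFrame({"treatment": ["A", "B"], "y": [3.0, 3.0]})
        assert treatment_percent_difference(df, "y", "A", "B").value == 0.0

    def test_hand_arithmetic(self):
        df = pd.DataFrame({"treatment": ["A", "A", "B", "B"], "y": [99, 101, 54, 56]})
        assert treatment_percent_difference(df, "y", "A", "B").value == pytest.approx(-45.0)

    def test_numerator_antisymmetry(self):
        df = pd.DataFrame({"treatment": ["A", "B"], "y": [10.0, 8.0]})
        fwd = treatment_percent_difference(df, "y", "A", "B").value
        rev = treatment_percent_difference(df, "y", "B", "A").value
        assert fwd * 10 == pytest.approx(-rev * 8)

    def test_missing_level_rejected(self):
        df = pd.DataFrame({"treatment": ["A"], "y": [1.0]})
        with pytest.raises(ValueError):
            treatment_percent_difference(df, "y", "A", "Z")


def test_analyze_trial_report_structure(rng):
    from rhizosim import synthetic as syn
    t = syn.generate("ghII", seed=5)
    rep = analyze_trial(t.table, design="rcbd",
                        endpoints={trt: t.rhl_endpoints(trt) for trt in ("HN", "LN")})
    assert set(rep["traits"]) == set(t.scenario.traits())
    shoot = rep["traits"]["shoot_g"]
    assert {"anova", "lsd", "regression", "treatment_pct"} <= set(shoot)
    assert shoot["regression"]["LN"]["percent_change"] > 0
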