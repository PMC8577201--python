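"""Trial statistics: OLS regressions, blocked ANOVA, protected LSD.

The chain mirrors standard agronomic practice for blocked RIL trials:

* per-treatment ordinary least squares of a shoot trait on root hair
  length, with the effect summarised as the percent change between the
  fitted values at the two ends of the observed RHL range;
* two-way ANOVA (genotype, treatment, their interaction) with block as an
  additive factor, on balanced complete designs only — for which the
  fixed-block F-tests coincide with the random-block mixed-model tests the
  field reports;
* Fisher's protected LSD at alpha = 0.05: pairwise letters are assigned
  only when the omnibus F-test is itself significant;
* quadratic regression with R^2 for simulation sweep output.

OLS and ANOVA computations are delegated to statsmodels; this module owns
the protection logic, the letter display and the percent-change readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

__all__ = [
    "RegressionFit",
    "AnovaTable",
    "LsdGrouping",
    "PercentChange",
    "fit_linear",
    "fit_quadratic",
    "percent_change_from_fit",
    "two_way_block_anova",
    "protected_lsd",
    "treatment_percent_difference",
]


@dataclass
class RegressionFit:
    intercept: float
    slope: float
    quadratic: float | None
    r_squared: float
    df_resid: int
    slope_se: float
    p_value: float  # slope t-test (linear) or model F (quadratic)
    x_range: tuple[float, float]

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        y = self.intercept + self.slope * x
        if self.quadratic is not None:
            y = y + self.quadratic * x ** 2
        return y


@dataclass
class AnovaTable:
    table: pd.DataFrame  # rows: genotype, treatment, interaction, block, residual
    zero_variance: bool = False

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def ms_residual(self) -> float:
        return float(self.table.loc["residual", "mean_sq"])

    def df_residual(self) -> int:
        return int(self.table.loc["residual", "df"])


@dataclass
class LsdGrouping:
    means: pd.Series  # per-level means, descending
    lsd: float | None
    letters: dict[str, str]
    protected: bool
    alpha: float = 0.05


@dataclass
class PercentChange:
    trait: str
    subset: str
    value: float  # percent
    x_min: float
    x_max: float
    fit: RegressionFit | None = None


def _check_xy(x, y, min_n):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    return x, y


def fit_linear(x, y) -> RegressionFit:
    """OLS of ``y`` on ``x`` with R^2, slope SE and two-sided slope t-test."""
    x, y = _check_xy(x, y, 3)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = float(res.rsquared) if sst > 0 else 0.0
    return RegressionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        quadratic=None,
        r_squared=r2,
        df_resid=int(res.df_resid),
        slope_se=float(res.bse[1]),
        p_value=float(res.pvalues[1]) if sst > 0 else 1.0,
        x_range=(float(x.min()), float(x.max())),
    )


def fit_quadratic(x, y) -> RegressionFit:
    """Least squares on (1, x, x^2); p-value is the model F-test."""
    x, y = _check_xy(x, y, 4)
    design = np.column_stack([np.ones_like(x), x, x ** 2])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient quadratic design (too few distinct x)")
    res = sm.OLS(y, design).fit()
    sst = float(((y - y.mean()) ** 2).sum())
    return RegressionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        quadratic=float(res.params[2]),
        r_squared=float(res.rsquared) if sst > 0 else 0.0,
        df_resid=int(res.df_resid),
        slope_se=float(res.bse[1]),
        p_value=float(res.f_pvalue) if sst > 0 else 1.0,
        x_range=(float(x.min()), float(x.max())),
    )


def percent_change_from_fit(fit: RegressionFit, x_min: float | None = None,
                            x_max: float | None = None, trait: str = "",
                            subset: str = "") -> PercentChange:
    """Percent change between fitted values at the range endpoints.

    ``100 * (yhat(x_max) - yhat(x_min)) / yhat(x_min)``; endpoints default
    to the fitted x range.
    """
    if x_min is None:
        x_min = fit.x_range[0]
    if x_max is None:
        x_max = fit.x_range[1]
    y0, y1 = (float(v) for v in fit.predict([x_min, x_max]))
    if y0 <= 0:
        raise ValueError(
            f"baseline fitted value at x_min={x_min} is non-positive ({y0:.6g}); "
            "percent change undefined")
    return PercentChange(trait=trait, subset=subset,
                         value=100.0 * (y1 - y0) / y0,
                         x_min=float(x_min), x_max=float(x_max), fit=fit)


_ROW_ORDER = ["genotype", "treatment", "interaction", "block", "residual"]


def _assert_balanced(df, genotype, treatment, block):
    counts = df.groupby([genotype, treatment, block], observed=True).size()
    full = df[genotype].nunique() * df[treatment].nunique() * df[block].nunique()
    if len(counts) != full or counts.nunique() != 1:
        raise ValueError(
            "design is unbalanced or incomplete; this analysis requires a "
            "complete balanced layout")


def two_way_block_anova(df: pd.DataFrame, trait: str, genotype: str = "ril",
                        treatment: str = "treatment", block: str = "block",
                        design: str = "rcbd") -> AnovaTable:
    """Blocked two-way ANOVA with interaction on a balanced complete design.

    ``design='rcbd'`` tests every effect against the residual mean square.
    ``design='splitplot'`` (N level on whole plots, genotype on subplots)
    re-tests the treatment main effect against the block x treatment
    whole-plot error, which is the correct split-plot denominator.
    """
    for col in (trait, genotype, treatment, block):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from trial table")
    _assert_balanced(df, genotype, treatment, block)
    y = df[trait].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        tab = pd.DataFrame(0.0, index=_ROW_ORDER, columns=["df", "sum_sq", "mean_sq", "F", "p"])
        tab["p"] = 1.0
        return AnovaTable(table=tab, zero_variance=True)
    d = df[[trait, genotype, treatment, block]].copy()
    d.columns = ["y", "g", "t", "b"]
    model = smf.ols("y ~ C(b) + C(g) + C(t) + C(g):C(t)", data=d).fit()
    a = anova_lm(model, typ=2)
    rows = {
        "genotype": a.loc["C(g)"],
        "treatment": a.loc["C(t)"],
        "interaction": a.loc["C(g):C(t)"],
        "block": a.loc["C(b)"],
        "residual": a.loc["Residual"],
    }
    tab = pd.DataFrame(
        {
            "df": [rows[r]["df"] for r in _ROW_ORDER],
            "sum_sq": [rows[r]["sum_sq"] for r in _ROW_ORDER],
        },
        index=_ROW_ORDER,
    )
    tab["mean_sq"] = tab["sum_sq"] / tab["df"]
    ms_res = tab.loc["residual", "mean_sq"]
    tab["F"] = tab["mean_sq"] / ms_res
    tab.loc["residual", "F"] = np.nan
    tab["p"] = sps.f.sf(tab["F"], tab["df"], tab.loc["residual", "df"])
    if design == "splitplot":
        # whole-plot error: block x treatment interaction
        cell = d.groupby(["b", "t"], observed=True)["y"].mean()
        gm = d["y"].mean()
        bm = d.groupby("b", observed=True)["y"].mean()
        tm = d.groupby("t", observed=True)["y"].mean()
        n_sub = len(d) / len(cell)
        ss_wp = n_sub * sum(
            (cell[(b, t)] - bm[b] - tm[t] + gm) ** 2 for b, t in cell.index)
        df_wp = (d["b"].nunique() - 1) * (d["t"].nunique() - 1)
        ms_wp = ss_wp / df_wp
        f_t = tab.loc["treatment", "mean_sq"] / ms_wp if ms_wp > 0 else np.inf
        tab.loc["treatment", "F"] = f_t
        tab.loc["treatment", "p"] = sps.f.sf(f_t, tab.loc["treatment", "df"], df_wp)
        wp = pd.DataFrame(
            {"df": [df_wp], "sum_sq": [ss_wp], "mean_sq": [ms_wp],
             "F": [np.nan], "p": [np.nan]}, index=["whole_plot_error"])
        # keep residual free of the whole-plot component
        tab.loc["residual", "sum_sq"] -= ss_wp
        tab.loc["residual", "df"] -= df_wp
        tab.loc["residual", "mean_sq"] = (
            tab.loc["residual", "sum_sq"] / tab.loc["residual", "df"])
        tab = pd.concat([tab.loc[_ROW_ORDER[:4]], wp, tab.loc[["residual"]]])
    elif design != "rcbd":
        raise ValueError(f"unknown design {design!r}")
    return AnovaTable(table=tab)


def _letters_from_groups(levels: list, groups: list[tuple[int, int]]) -> dict:
    letters = {lv: "" for lv in levels}
    for li, (a, b) in enumerate(groups):
        ch = chr(ord("a") + li)
        for i in range(a, b + 1):
            letters[levels[i]] += ch
    return letters


def protected_lsd(anova: AnovaTable, means: pd.Series, n_per_level: int,
                  alpha: float = 0.05, effect: str = "genotype") -> LsdGrouping:
    """Fisher's protected LSD with letter display.

    If the omnibus F for ``effect`` is not significant at ``alpha``,
    protection fails: no LSD threshold and no letters.  Otherwise
    ``LSD = t(1 - alpha/2, df_res) * sqrt(2 MS_res / n)`` and letters come
    from an insert-and-absorb sweep over the means sorted descending;
    differences of exactly the LSD are treated as not significant.
    """
    if n_per_level <= 0:
        raise ValueError("n_per_level must be positive")
    if len(means) != means.index.nunique():
        raise ValueError("duplicate levels in means")
    means = means.sort_values(ascending=False)
    if anova.zero_variance or anova.p_value(effect) >= alpha:
        return LsdGrouping(means=means, lsd=None, letters={}, protected=False,
                           alpha=alpha)
    ms_res = anova.ms_residual()
    df_res = anova.df_residual()
    lsd = float(sps.t.ppf(1 - alpha / 2.0, df_res) * np.sqrt(2.0 * ms_res / n_per_level))
    vals = means.to_numpy()
    levels = list(means.index)
    # maximal runs of mutually non-significant levels
    groups = []
    for i in range(len(vals)):
        j = i
        while j + 1 < len(vals) and vals[i] - vals[j + 1] <= lsd:
            j += 1
        groups.append((i, j))
    # absorb runs contained in an earlier run
    maximal = []
    for g in groups:
        if not any(o[0] <= g[0] and g[1] <= o[1] for o in maximal):
            maximal.append(g)
    return LsdGrouping(means=means, lsd=lsd,
                       letters=_letters_from_groups(levels, maximal),
                       protected=True, alpha=alpha)


def treatment_percent_difference(df: pd.DataFrame, trait: str, ref_level: str,
                                 alt_level: str, treatment: str = "treatment") -> PercentChange:
    """Percent difference of trait means: 100 (mean_alt - mean_ref)/mean_ref."""
    levels = set(df[treatment].unique())
    for lv in (ref_level, alt_level):
        if lv not in levels:
            raise ValueError(f"treatment level {lv!r} not present")
    m_ref = float(df.loc[df[treatment] == ref_level, trait].mean())
    m_alt = float(df.loc[df[treatment] == alt_level, trait].mean())
    if m_ref == 0:
        raise ValueError("reference mean is zero; percent difference undefined")
    return PercentChange(trait=trait, subset=f"{alt_level} vs {ref_level}",
                         value=100.0 * (m_alt - m_ref) / m_ref,
                         x_min=np.nan, x_max=np.nan)


def analyze_trial(df: pd.DataFrame, design: str = "rcbd", traits=None,
                  ref_level: str = "HN", rhl_col: str = "rhl_mm",
                  endpoints: dict | None = None, alpha: float = 0.05) -> dict:
    """Run the full analysis chain on one trial table; returns a JSON-ready
    report.

    Per trait: blocked ANOVA with protected LSD over genotypes, a linear
    RHL regression with endpoint percent change inside each treatment, and
    the treatment percent difference against ``ref_level``.  ``endpoints``
    optionally fixes the per-treatment RHL endpoints used for the percent
    change (defaults to the observed range in the subset).
    """
    block = "block" if "block" in df.columns else "rep"
    if traits is None:
        traits = [c for c in df.columns
                  if c not in ("ril", block, "treatment", rhl_col)]
    treatments = list(df["treatment"].unique())
    report: dict = {"design": design, "traits": {}}
    # RHL itself responds to treatment
    rhl_anova = two_way_block_anova(df, rhl_col, block=block, design=design)
    report["rhl"] = {
        "anova": _anova_dict(rhl_anova),
        "treatment_pct": {
            t: treatment_percent_difference(df, rhl_col, ref_level, t).value
            for t in treatments if t != ref_level},
    }
    for trait in traits:
        entry: dict = {}
        anova = two_way_block_anova(df, trait, block=block, design=design)
        entry["anova"] = _anova_dict(anova)
        means = df.groupby("ril", observed=True)[trait].mean()
        n_per = len(df) // df["ril"].nunique()
        lsd = protected_lsd(anova, means, n_per, alpha=alpha)
        entry["lsd"] = {"protected": lsd.protected, "lsd": lsd.lsd,
                        "letters": lsd.letters}
        entry["regression"] = {}
        for trt in treatments:
            sub = df[df["treatment"] == trt]
            fit = fit_linear(sub[rhl_col], sub[trait])
            ep = (endpoints or {}).get(trt)
            pc = percent_change_from_fit(
                fit, *(ep if ep else (None, None)), trait=trait, subset=trt)
            entry["regression"][trt] = {
                "intercept": fit.intercept, "slope": fit.slope,
                "r_squared": fit.r_squared, "p_slope": fit.p_value,
                "percent_change": pc.value,
                "x_min": pc.x_min, "x_max": pc.x_max,
            }
        entry["treatment_pct"] = {
            t: treatment_percent_difference(df, trait, ref_level, t).value
            for t in treatments if t != ref_level}
        report["traits"][trait] = entry
    return report


def _anova_dict(anova: AnovaTable) -> dict:
    tab = anova.table.replace({np.nan: None})
    return {"zero_variance": anova.zero_variance,
            "rows": {idx: {k: row[k] for k in ("df", "sum_sq", "mean_sq", "F", "p")}
                     for idx, row in tab.iterrows()}}
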