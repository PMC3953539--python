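"""General linear model of ranking accuracy on the design factors.

A factorial sweep yields one Kendall's W per run together with the build
flags and resource levels of that run. The headline analysis is an ordinary
least-squares fit of W on food availability and the three binary build
factors (items needed, sequential assessment, real-time-only observation),
with per-factor effect sizes reported as partial eta squared,
``SS_factor / (SS_factor + SS_error)``.

Food availability enters as a fraction of the largest food level swept
(``food_level / max(food_levels)``), keeping the predictor on a unit scale
commensurate with W; raw-count coding is available via ``food_coding``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

FACTOR_ORDER = ("food", "items_needed", "sequential_assessment", "realtime_only")


@dataclass
class GLMFit:
    """OLS fit summary, one row per model term in design order.

    ``table`` has columns coefficient, std error, t-value, p-value and
    partial eta squared (the intercept carries no effect size).
    """

    table: pd.DataFrame
    df_resid: float
    ss_error: float
    model: object  # fitted statsmodels results, for diagnostics

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "coef"])

    def partial_eta_sq(self, term: str) -> float:
        return float(self.table.loc[term, "partial_eta_sq"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def partial_eta_squared(ss_factor: float, ss_error: float) -> float:
    """Effect size ``SS_factor / (SS_factor + SS_error)``."""
    if ss_factor < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    denom = ss_factor + ss_error
    return float(ss_factor / denom) if denom > 0 else 0.0


def fit_glm(
    table: pd.DataFrame,
    response: str = "W",
    food_coding: str = "fraction",
    ss_type: int = 1,
) -> GLMFit:
    """OLS of per-run W on food level and the three binary build factors.

    ``table`` is a tidy sweep table with columns ``food_level``,
    ``items_needed``, ``sequential_assessment``, ``realtime_only`` and the
    response. Effect sizes use each factor's sum of squares in the fixed
    design order (sequential/Type-I by default; ``ss_type=3`` gives
    partial/Type-III sums of squares instead).
    """
    df = table.copy()
    for col in ("food_level", "items_needed", "sequential_assessment", "realtime_only"):
        if col not in df.columns:
            raise ValueError(f"sweep table lacks required column {col!r}")
    if food_coding == "fraction":
        df["food"] = df["food_level"] / float(df["food_level"].max())
    elif food_coding == "raw":
        df["food"] = df["food_level"].astype(float)
    else:
        raise ValueError("food_coding must be 'fraction' or 'raw'")
    for col in FACTOR_ORDER:
        if df[col].nunique() < 2:
            raise ValueError(
                f"predictor {col!r} is constant in this table; the design is rank-deficient"
            )
    df[list(FACTOR_ORDER[1:])] = df[list(FACTOR_ORDER[1:])].astype(float)

    formula = f"{response} ~ " + " + ".join(FACTOR_ORDER)
    fit = ols(formula, data=df).fit()
    anova = anova_lm(fit, typ=1 if ss_type == 1 else 3)
    ss_error = float(anova.loc["Residual", "sum_sq"])

    rows = []
    for term in ("Intercept",) + FACTOR_ORDER:
        eta = (
            np.nan
            if term == "Intercept"
            else partial_eta_squared(float(anova.loc[term, "sum_sq"]), ss_error)
        )
        rows.append(
            {
                "term": term,
                "coef": float(fit.params[term]),
                "std_err": float(fit.bse[term]),
                "t_value": float(fit.tvalues[term]),
                "partial_eta_sq": eta,
                "p_value": float(fit.pvalues[term]),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    return GLMFit(table=out, df_resid=float(fit.df_resid), ss_error=ss_error, model=fit)


def condition_summaries(table: pd.DataFrame, response: str = "W") -> dict[str, pd.DataFrame]:
    """Figure-ready mean +/- s.e.m. tables of W against food availability.

    One table per binary factor (mean response by ``food_level`` split by
    the factor) plus, within item-needed runs, a split by display-item
    level. Cells with a single replicate report a zero-width s.e.m.
    """
    if table.empty:
        raise ValueError("sweep table is empty")

    def agg(df: pd.DataFrame, split: str) -> pd.DataFrame:
        g = df.groupby(["food_level", split])[response]
        out = g.agg(mean="mean", sem=lambda v: v.sem(ddof=1) if len(v) > 1 else 0.0, n="count")
        return out.reset_index()

    out = {
        "items_needed": agg(table, "items_needed"),
        "sequential_assessment": agg(table, "sequential_assessment"),
        "realtime_only": agg(table, "realtime_only"),
    }
    items = table[table["items_needed"] == 1]
    if not items.empty and "display_level" in items.columns:
        out["display_level"] = agg(items, "display_level")
    return out


def plot_condition_summary(summary: pd.DataFrame, split: str, ax=None):
    """Plot a condition-summary table: mean W vs food level, one line per level."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for val, sub in summary.groupby(split):
        ax.errorbar(
            sub["food_level"], sub["mean"], yerr=sub["sem"], marker="o",
            capsize=3, label=f"{split}={val}",
        )
    ax.set_xscale("log")
    ax.set_xlabel("food items initialized")
    ax.set_ylabel("Kendall's W")
    ax.legend()
    return ax
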