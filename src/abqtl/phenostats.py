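"""Phenotype adjustment, heritability and ANOVA for multi-environment trials.

Line values observed over environments and nitrogen (N) levels are condensed
to adjusted (least-squares) line means with environment treated as an
additive nuisance effect; variance components of the random-genotype model

    Y = G + E + N + GxE + GxN + eps        (traits, across N levels)
    Y = G + E + eps                        (ratio traits / within N level)

are estimated by the ANOVA (expected-mean-squares) method, and entry-mean
broad-sense heritability is evaluated as

    h2 = V_G / (V_G + V_GxE/e + V_GxN/n + V_R/(e*n))   across N levels
    h2 = V_G / (V_G + V_R/e)                           within an N level

with e environments and n N levels.  Negative component estimates are
truncated at zero, so traits without genetic variance report h2 = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "VarianceComponents",
    "adjusted_line_means",
    "trait_ratio",
    "descriptive_stats",
    "pearson_correlations",
    "variance_components",
    "heritability",
    "anova",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Truncated-at-zero variance components and the design sizes they refer to."""

    v_g: float
    v_r: float
    v_gxe: float = 0.0
    v_gxn: float = 0.0
    e: int = 1
    n: int = 1

    def __post_init__(self) -> None:
        if min(self.v_g, self.v_r, self.v_gxe, self.v_gxn) < 0:
            raise ValueError("variance components must be >= 0")
        if self.e < 1 or self.n < 1:
            raise ValueError("e and n must be >= 1")


def _pivot_trait(table: pd.DataFrame, trait: str, n_level: str | None) -> pd.DataFrame:
    sub = table[table["trait"] == trait]
    if n_level is not None:
        sub = sub[sub["n_level"] == n_level]
    else:
        sub = sub.copy()
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r} in scope")
    # across-N scope: each environment x N combination is one trial cell
    sub["cell"] = sub["environment"].astype(str) + ":" + sub["n_level"].astype(str)
    return sub


def adjusted_line_means(
    table: pd.DataFrame,
    scope: str | None = None,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Least-squares line means from the additive line + environment model.

    ``scope`` is ``None`` (across N levels, each environment x N combination
    forming one trial cell) or an N-level label.  For every trait the two-way
    fixed-effects model value = line + cell is solved by least squares and the
    line mean is the fitted value averaged over all cells; with complete
    balanced data this reduces to the arithmetic mean.  Lines without any
    observation in scope are absent from the output.

    Returns a line x trait DataFrame.
    """
    if traits is None:
        traits = list(pd.unique(table["trait"]))
    out = {}
    for trait in traits:
        sub = _pivot_trait(table, trait, scope).dropna(subset=["value"])
        lines = pd.unique(sub["line_id"])
        cells = pd.unique(sub["cell"])
        li = np.asarray(pd.Categorical(sub["line_id"], categories=lines).codes, dtype=int)
        ci = np.asarray(pd.Categorical(sub["cell"], categories=cells).codes, dtype=int)
        y = sub["value"].to_numpy(dtype=float)
        nl, nc = len(lines), len(cells)
        # design: intercept-free line dummies + cell dummies (first cell as baseline)
        X = np.zeros((len(y), nl + nc - 1))
        X[np.arange(len(y)), li] = 1.0
        nonbase = ci > 0
        X[np.flatnonzero(nonbase), nl + ci[nonbase] - 1] = 1.0
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        cell_eff = np.concatenate([[0.0], beta[nl:]])
        means = beta[:nl] + cell_eff.mean()
        out[trait] = pd.Series(means, index=pd.Index(lines, name="line_id"))
    return pd.DataFrame(out)


def trait_ratio(means_n0: pd.Series, means_n1: pd.Series) -> pd.Series:
    """Per-line ratio of the low-N to the high-N adjusted mean (N0 / N1).

    Lines missing either mean, or with a zero N1 mean, are dropped (a warning
    is raised for zero denominators).
    """
    common = means_n0.index.intersection(means_n1.index)
    n0 = means_n0.loc[common]
    n1 = means_n1.loc[common]
    zero = n1 == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} line(s) dropped from ratio: N1 mean is zero",
            stacklevel=2,
        )
    keep = ~zero & n0.notna() & n1.notna()
    return (n0[keep] / n1[keep]).rename("ratio")


def descriptive_stats(line_means: pd.Series) -> dict[str, float]:
    """Mean, min, max, sample SD and coefficient of variation of line means.

    CV = 100 * SD / mean (percent); SD uses the n-1 denominator.
    """
    x = pd.Series(line_means).dropna()
    if len(x) < 2:
        raise ValueError("need at least two lines")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return {
        "n": int(len(x)),
        "mean": mean,
        "min": float(x.min()),
        "max": float(x.max()),
        "sd": sd,
        "cv_percent": 100.0 * sd / mean if mean != 0 else np.nan,
    }


def pearson_correlations(line_means: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between trait line-mean columns.

    Missing lines are handled pairwise-complete; a zero-variance column
    raises.
    """
    for col in line_means.columns:
        x = line_means[col].dropna()
        if len(x) >= 2 and float(x.std(ddof=1)) == 0.0:
            raise ValueError(f"trait {col!r} has zero variance")
    return line_means.corr(method="pearson", min_periods=3)


def _balanced_mean_squares(wide: pd.DataFrame, e: int, n: int) -> tuple[float, float, float, float]:
    """Mean squares of the crossed G/E/N design from a complete balanced table.

    ``wide`` is line x (environment, n_level) with no missing cells; returns
    (MS_G, MS_GxE, MS_GxN, MS_residual) identical to Type-I/III ANOVA under
    balance, computed from cell means.
    """
    g = wide.shape[0]
    y = wide.to_numpy(dtype=float).reshape(g, e, n)
    grand = y.mean()
    m_g = y.mean(axis=(1, 2))
    m_e = y.mean(axis=(0, 2))
    m_n = y.mean(axis=(0, 1))
    m_ge = y.mean(axis=2)
    m_gn = y.mean(axis=1)
    ss_g = e * n * np.sum((m_g - grand) ** 2)
    ss_ge = n * np.sum((m_ge - m_g[:, None] - m_e[None, :] + grand) ** 2)
    ss_gn = e * np.sum((m_gn - m_g[:, None] - m_n[None, :] + grand) ** 2)
    ss_e = g * n * np.sum((m_e - grand) ** 2)
    ss_n = g * e * np.sum((m_n - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_res = ss_tot - ss_g - ss_e - ss_n - ss_ge - ss_gn
    df_res = g * e * n - 1 - (g - 1) - (e - 1) - (n - 1) - (g - 1) * (e - 1) - (g - 1) * (n - 1)
    return (
        ss_g / (g - 1),
        ss_ge / ((g - 1) * (e - 1)),
        ss_gn / ((g - 1) * (n - 1)),
        ss_res / df_res,
    )


def _type1_mean_squares(sub: pd.DataFrame, formula: str) -> pd.DataFrame:
    model = smf.ols(formula, data=sub).fit()
    return sm.stats.anova_lm(model, typ=1)


def variance_components(
    table: pd.DataFrame,
    trait: str,
    model: str = "across",
    n_level: str | None = None,
) -> VarianceComponents:
    """ANOVA-method variance components for one trait.

    ``model='across'`` fits Y = G + E + N + GxE + GxN + eps over all
    environments and N levels and solves the balanced expected-mean-squares
    equations

        MS_G   = V_R + n V_GxE + e V_GxN + e n V_G
        MS_GxE = V_R + n V_GxE
        MS_GxN = V_R + e V_GxN
        MS_res = V_R

    ``model='within'`` fits Y = G + E + eps (within one N level when
    ``n_level`` is given, or pooling cells otherwise) with MS_G = V_R + e V_G.
    Negative estimates are truncated at zero.  Mildly unbalanced data use the
    same equations with Type-I mean squares and average cell counts.
    """
    sub = table[table["trait"] == trait].dropna(subset=["value"]).copy()
    if n_level is not None:
        sub = sub[sub["n_level"] == n_level]
    if sub.empty:
        raise ValueError(f"no data for trait {trait!r}")
    if sub["value"].nunique() <= 1:
        e = int(sub["environment"].nunique())
        n = int(sub["n_level"].nunique())
        return VarianceComponents(0.0, 0.0, 0.0, 0.0, e=e, n=max(n, 1))
    e = int(sub["environment"].nunique())
    if model == "across":
        n = int(sub["n_level"].nunique())
        if e < 2 or n < 2:
            raise ValueError("across-N model needs >= 2 environments and >= 2 N levels")
        wide = sub.pivot_table(
            index="line_id", columns=["environment", "n_level"], values="value"
        )
        if not wide.isna().any().any() and wide.shape[1] == e * n:
            ms_g, ms_ge, ms_gn, ms_res = _balanced_mean_squares(wide, e, n)
        else:
            aov = _type1_mean_squares(
                sub,
                "value ~ C(line_id) + C(environment) + C(n_level)"
                " + C(line_id):C(environment) + C(line_id):C(n_level)",
            )
            ms = aov["sum_sq"] / aov["df"]
            ms_g = float(ms["C(line_id)"])
            ms_ge = float(ms["C(line_id):C(environment)"])
            ms_gn = float(ms["C(line_id):C(n_level)"])
            ms_res = float(ms["Residual"])
        v_r = ms_res
        v_gxe = (ms_ge - v_r) / n
        v_gxn = (ms_gn - v_r) / e
        v_g = (ms_g - ms_ge - ms_gn + v_r) / (e * n)
        return VarianceComponents(
            max(v_g, 0.0), max(v_r, 0.0), max(v_gxe, 0.0), max(v_gxn, 0.0), e=e, n=n
        )
    elif model == "within":
        sub["cell"] = sub["environment"].astype(str) + ":" + sub["n_level"].astype(str)
        n_cells = int(sub["cell"].nunique())
        if n_cells < 2:
            raise ValueError("within model needs >= 2 environment cells")
        aov = _type1_mean_squares(sub, "value ~ C(line_id) + C(cell)")
        ms = aov["sum_sq"] / aov["df"]
        v_r = float(ms["Residual"])
        v_g = (float(ms["C(line_id)"]) - v_r) / n_cells
        return VarianceComponents(max(v_g, 0.0), max(v_r, 0.0), e=n_cells, n=1)
    raise ValueError(f"unknown model {model!r}")


def heritability(vc: VarianceComponents, scope: str = "across") -> float:
    """Entry-mean broad-sense heritability on the [0, 1] scale.

    across: h2 = V_G / (V_G + V_GxE/e + V_GxN/n + V_R/(e n));
    within: h2 = V_G / (V_G + V_R/e).  All-zero components define h2 = 0.
    """
    if scope == "across":
        denom = vc.v_g + vc.v_gxe / vc.e + vc.v_gxn / vc.n + vc.v_r / (vc.e * vc.n)
    elif scope == "within":
        denom = vc.v_g + vc.v_r / vc.e
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if denom == 0:
        return 0.0
    return vc.v_g / denom


def anova(table: pd.DataFrame, trait: str, model: str = "across") -> pd.DataFrame:
    """Fixed-effects general-linear-model ANOVA table (effect, df, SS, F, p).

    Uses Y = G + E + N + GxE + GxN + eps (``model='across'``) or
    Y = G + E + eps (``model='within'``, environment x N cells pooled).
    """
    sub = table[table["trait"] == trait].dropna(subset=["value"]).copy()
    if sub.empty:
        raise ValueError(f"no data for trait {trait!r}")
    if model == "across":
        formula = (
            "value ~ C(line_id) + C(environment) + C(n_level)"
            " + C(line_id):C(environment) + C(line_id):C(n_level)"
        )
    elif model == "within":
        sub["cell"] = sub["environment"].astype(str) + ":" + sub["n_level"].astype(str)
        formula = "value ~ C(line_id) + C(cell)"
    else:
        raise ValueError(f"unknown model {model!r}")
    fit = smf.ols(formula, data=sub).fit()
    aov = sm.stats.anova_lm(fit, typ=1)
    return aov.rename(columns={"sum_sq": "SS", "df": "df", "F": "F", "PR(>F)": "p"})
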