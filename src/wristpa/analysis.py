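"""Cohort statistics: group descriptives, rank tests, Spearman matrix and
the activity-energy regression with its sex-specific contrasts.

The regression puts AEE (kJ day^-1 kg^-1) on dummy-coded InCHIANTI level
(reference = lowest observed level), age, sex and BMI; the fully adjusted
variant adds MMSE and GDS with complete-case deletion. Confidence intervals
use a configurable normal quantile (default 1.96).

Two contrast conventions are exposed side by side: the "reported" style in
which the male contrast to a level is that level's dummy coefficient and the
female contrast adds the female term, and the textbook additive contrast
(difference of dummy coefficients, sex-free). Neither is silently preferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

ALPHA = 0.05
CI_QUANTILE = 1.96


# ---------------------------------------------------------------- descriptives

@dataclass
class GroupComparison:
    variable: str
    groups: dict  # group -> {"median","min","max","n"} or counts
    statistic: float
    p_value: float
    test_name: str


def describe_by_group(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = "inchianti",
    categorical: bool = False,
) -> GroupComparison:
    """Per-group median/range plus Kruskal-Wallis, or counts plus Fisher exact."""
    if variable not in cohort.columns:
        raise ValueError(f"unknown variable {variable!r}")
    df = cohort[[group_col, variable]].dropna()
    levels = sorted(df[group_col].unique())
    if len(levels) < 2:
        raise ValueError("need at least two non-empty groups")
    if categorical:
        table = pd.crosstab(df[variable], df[group_col])
        p = fisher_exact_2xc(table.to_numpy()) if table.shape[0] == 2 else float("nan")
        groups = {lvl: table[lvl].to_dict() for lvl in levels}
        return GroupComparison(variable, groups, float("nan"), p, "fisher_exact")
    samples = [df.loc[df[group_col] == lvl, variable].to_numpy() for lvl in levels]
    if df[variable].nunique() < 2:  # constant variable: test undefined, not a crash
        stat, p = float("nan"), float("nan")
    else:
        stat, p = stats.kruskal(*samples)
    groups = {
        lvl: {"median": float(np.median(s)), "min": float(s.min()), "max": float(s.max()), "n": len(s)}
        for lvl, s in zip(levels, samples)
    }
    return GroupComparison(variable, groups, float(stat), float(p), "kruskal_wallis")


def kruskal_test(*samples) -> tuple[float, float]:
    stat, p = stats.kruskal(*samples)
    return float(stat), float(p)


def fisher_exact_2xc(table: np.ndarray) -> float:
    """Exact Freeman-Halton p-value for a 2 x C contingency table.

    Enumerates every table with the observed margins; the p-value is the
    total conditional (multivariate hypergeometric) probability of tables no
    more probable than the observed one.
    """
    table = np.asarray(table, dtype=int)
    if table.shape[0] != 2:
        raise ValueError("expected a 2 x C table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    cols = table.sum(axis=0)
    row0 = int(table[0].sum())
    n = int(table.sum())
    lg = math.lgamma

    def log_prob(top: tuple[int, ...]) -> float:
        # P(table | margins) via log-gamma
        out = lg(row0 + 1) + lg(n - row0 + 1) - lg(n + 1)
        for c, t in zip(cols, top):
            out += lg(c + 1) - lg(t + 1) - lg(c - t + 1)
        return out

    obs = log_prob(tuple(int(v) for v in table[0]))
    total = 0.0
    c0 = len(cols)

    def recurse(col: int, remaining: int, top: list[int]) -> None:
        nonlocal total
        if col == c0 - 1:
            if remaining <= cols[col]:
                lp = log_prob(tuple(top + [remaining]))
                if lp <= obs + 1e-10:
                    total += math.exp(lp)
            return
        tail_capacity = int(cols[col + 1 :].sum())
        lo = max(0, remaining - tail_capacity)
        hi = min(cols[col], remaining)
        for t in range(lo, hi + 1):
            recurse(col + 1, remaining - t, top + [t])

    recurse(0, row0, [])
    return min(1.0, float(total))


# ---------------------------------------------------------------- correlation

def spearman_matrix(cohort: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Tie-corrected pairwise Spearman correlations; constant columns give NaN."""
    out = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if j <= i:
                continue
            pair = cohort[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                rho = float("nan")
            else:
                rho = float(stats.spearmanr(pair[a], pair[b]).statistic)
            out.iloc[i, j] = out.iloc[j, i] = rho
    return out


# ---------------------------------------------------------------- regression

@dataclass
class RegressionResult:
    model_tag: str  # "partial" | "full"
    terms: pd.DataFrame  # index=term, columns beta, se, ci_low, ci_high, p
    reference_level: int
    n_obs: int
    n_dropped: int = 0
    ci_quantile: float = CI_QUANTILE
    levels: list = field(default_factory=list)

    def beta(self, term: str) -> float:
        return float(self.terms.loc[term, "beta"])


def _design(cohort: pd.DataFrame, full: bool) -> tuple[pd.DataFrame, pd.Series, int, list]:
    cols = ["aee_kj_day_kg", "inchianti", "age", "sex", "bmi"]
    if full:
        cols += ["mmse", "gds"]
    df = cohort[cols].dropna()
    levels = sorted(df["inchianti"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two distinct InCHIANTI levels")
    ref = levels[0]
    X = pd.DataFrame(index=df.index)
    for lvl in levels[1:]:
        X[f"inchianti{lvl}"] = (df["inchianti"] == lvl).astype(float)
    X["age"] = df["age"]
    X["female"] = (df["sex"] == "female").astype(float)
    X["bmi"] = df["bmi"]
    if full:
        X["mmse"] = df["mmse"]
        X["gds"] = df["gds"]
    X = sm.add_constant(X, prepend=True)
    return X, df["aee_kj_day_kg"], ref, levels


def fit_aee_model(
    cohort: pd.DataFrame,
    adjustment: str = "partial",
    ci_quantile: float = CI_QUANTILE,
) -> RegressionResult:
    """OLS of AEE on InCHIANTI dummies + covariates.

    ``adjustment='partial'`` adjusts for age, sex and BMI; ``'full'`` adds
    MMSE and GDS (complete cases only). Raises on an aliased (collinear)
    design, naming the offending term.
    """
    if adjustment not in ("partial", "full"):
        raise ValueError("adjustment must be 'partial' or 'full'")
    X, y, ref, levels = _design(cohort, full=adjustment == "full")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the first column whose removal restores full column rank
        for col in X.columns:
            sub = X.drop(columns=col)
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                raise ValueError(f"collinear design: term {col!r} is aliased")
        raise ValueError("collinear design")
    fit = sm.OLS(y, X).fit()
    terms = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "ci_low": fit.params - ci_quantile * fit.bse,
            "ci_high": fit.params + ci_quantile * fit.bse,
            "p": fit.pvalues,
        }
    )
    return RegressionResult(
        model_tag=adjustment,
        terms=terms,
        reference_level=int(ref),
        n_obs=int(fit.nobs),
        n_dropped=len(cohort) - int(fit.nobs),
        ci_quantile=ci_quantile,
        levels=[int(l) for l in levels],
    )


def reported_style_contrast(
    result: RegressionResult,
    from_level: int,
    to_level: int,
    sex: str,
) -> float:
    """Sex-specific AEE contrast in the reported convention.

    Male contrast = the destination level's dummy coefficient; female
    contrast additionally adds the female coefficient. See
    :func:`standard_contrast` for the sex-free additive-model difference.
    """
    if to_level not in result.levels or from_level not in result.levels:
        raise ValueError(f"levels {from_level}->{to_level} not in fitted model {result.levels}")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    beta = result.beta(f"inchianti{to_level}") if to_level != result.reference_level else 0.0
    if sex == "female":
        beta += result.beta("female")
    return float(beta)


def standard_contrast(result: RegressionResult, from_level: int, to_level: int) -> float:
    """Textbook additive contrast: beta(to) - beta(from), sex-independent."""
    def b(lvl):
        return 0.0 if lvl == result.reference_level else result.beta(f"inchianti{lvl}")

    if to_level not in result.levels or from_level not in result.levels:
        raise ValueError(f"levels {from_level}->{to_level} not in fitted model {result.levels}")
    return float(b(to_level) - b(from_level))


def regression_from_coefficients(
    coefficients: dict,
    ses: dict | None = None,
    model_tag: str = "reported",
    reference_level: int = 1,
    ci_quantile: float = CI_QUANTILE,
) -> RegressionResult:
    """Wrap externally printed coefficients so contrast/CI arithmetic can run
    on them exactly as on a fresh fit (used to check worked examples)."""
    ses = ses or {}
    terms = pd.DataFrame(
        {
            "beta": pd.Series(coefficients, dtype=float),
            "se": pd.Series({k: ses.get(k, float("nan")) for k in coefficients}, dtype=float),
        }
    )
    terms["ci_low"] = terms["beta"] - ci_quantile * terms["se"]
    terms["ci_high"] = terms["beta"] + ci_quantile * terms["se"]
    terms["p"] = float("nan")
    levels = sorted(
        {reference_level}
        | {int(k.replace("inchianti", "")) for k in coefficients if k.startswith("inchianti")}
    )
    return RegressionResult(
        model_tag=model_tag,
        terms=terms,
        reference_level=reference_level,
        n_obs=0,
        ci_quantile=ci_quantile,
        levels=levels,
    )
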