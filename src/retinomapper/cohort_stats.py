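"""One-way and two-way ANOVA with Bonferroni post hoc tests.

One-way ANOVA is the classical between/within sum-of-squares
decomposition computed directly.  Two-way ANOVA is fit by OLS with
sum-to-zero contrasts; balanced designs get the classical decomposition
and unbalanced designs default to Type-III sums of squares (the
convention of common commercial statistics software — the sum-of-squares
type for unbalanced designs is otherwise a free choice), with Type II
available.  Post hoc pairwise comparisons use the pooled ANOVA residual
variance and a Bonferroni correction ``p_adj = min(1, m * p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .isoi_sim import CohortDesign, simulate_cohort_responses

__all__ = ["EffectResult", "PosthocResult", "AnovaResult", "one_way_anova",
           "two_way_anova", "bonferroni_posthoc", "rejection_rate"]


@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df: tuple[int, int]   # (numerator, denominator)
    p: float


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple[str, str]
    t: float
    p_raw: float
    p_adjusted: float


@dataclass
class AnovaResult:
    effects: list[EffectResult]
    residual_df: int
    residual_ms: float
    posthoc: list[PosthocResult] = field(default_factory=list)

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(f"no effect named {name!r}; have "
                       f"{[e.name for e in self.effects]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"effect": e.name, "F": e.F, "df_num": e.df[0], "df_den": e.df[1],
              "p": e.p} for e in self.effects]
        )


def _as_groups(values: Sequence[float], groups: Sequence[str]):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and groups must have equal length")
    level_names = list(pd.unique(groups))
    return values, groups, level_names


def one_way_anova(values: Sequence[float], groups: Sequence[str]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    ``F = MS_between / MS_within`` with df ``(k - 1, N - k)``; p from the
    F distribution.  Requires >= 2 groups of >= 2 observations and a
    nonzero residual variance.
    """
    values, groups, levels = _as_groups(values, groups)
    k = len(levels)
    n = len(values)
    if k < 2:
        raise ValueError(f"need >= 2 groups, got {k}")
    for lvl in levels:
        if (groups == lvl).sum() < 2:
            raise ValueError(f"group {lvl!r} has fewer than 2 observations")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for lvl in levels:
        v = values[groups == lvl]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df_between = k - 1
    df_within = n - k
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise ValueError("zero residual variance; F statistic undefined")
    f_stat = (ss_between / df_between) / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within))
    effect = EffectResult(name="group", F=float(f_stat),
                          df=(df_between, df_within), p=p)
    return AnovaResult(effects=[effect], residual_df=df_within,
                       residual_ms=float(ms_within))


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    include_interaction: bool = True,
    ss_type: int = 3,
    names: tuple[str, str] = ("A", "B"),
) -> AnovaResult:
    """Two-factor fixed-effects ANOVA via OLS with sum-to-zero contrasts.

    Every cell must be non-empty.  For balanced designs Types I/II/III
    coincide with the classical decomposition; for unbalanced designs
    ``ss_type`` selects Type III (default) or Type II.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    values = np.asarray(values, dtype=float)
    df = pd.DataFrame({"y": values,
                       "A": np.asarray(factor_a),
                       "B": np.asarray(factor_b)})
    for col in ("A", "B"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col} needs >= 2 levels")
    counts = df.groupby(["A", "B"], sort=False).size().unstack()
    if counts.isna().any().any() or (counts == 0).any().any():
        raise ValueError(f"empty cell(s) in the design:\n{counts}")
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")
    formula = ("y ~ C(A, Sum) * C(B, Sum)" if include_interaction
               else "y ~ C(A, Sum) + C(B, Sum)")
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    residual_df = int(table.loc["Residual", "df"])
    residual_ms = float(table.loc["Residual", "sum_sq"] / residual_df)
    rename = {"C(A, Sum)": names[0], "C(B, Sum)": names[1],
              "C(A, Sum):C(B, Sum)": f"{names[0]}:{names[1]}"}
    effects = []
    for row_name, row in table.iterrows():
        if row_name in ("Residual", "Intercept"):
            continue
        effects.append(EffectResult(
            name=rename.get(row_name, str(row_name)),
            F=float(row["F"]),
            df=(int(row["df"]), residual_df),
            p=float(row["PR(>F)"]),
        ))
    return AnovaResult(effects=effects, residual_df=residual_df,
                       residual_ms=residual_ms)


def bonferroni_posthoc(
    values: Sequence[float],
    groups: Sequence[str],
    comparisons: Sequence[tuple[str, str]] | None = None,
    anova: AnovaResult | None = None,
) -> list[PosthocResult]:
    """Pairwise t-tests on the pooled ANOVA residual variance.

    ``t = (m1 - m2) / sqrt(MS_resid * (1/n1 + 1/n2))`` with the ANOVA
    residual df; adjusted ``p = min(1, m * p_raw)`` for m comparisons.
    Defaults to all pairwise comparisons among the present groups.
    """
    values, groups, levels = _as_groups(values, groups)
    if anova is None:
        anova = one_way_anova(values, groups)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(levels)
                       for b in levels[i + 1:]]
    for a, b in comparisons:
        for g in (a, b):
            if g not in levels:
                raise ValueError(f"unknown group {g!r}; have {levels}")
    m = len(comparisons)
    results = []
    for a, b in comparisons:
        va, vb = values[groups == a], values[groups == b]
        se = np.sqrt(anova.residual_ms * (1.0 / len(va) + 1.0 / len(vb)))
        t = float((va.mean() - vb.mean()) / se)
        p_raw = float(2.0 * stats.t.sf(abs(t), anova.residual_df))
        results.append(PosthocResult(pair=(a, b), t=t, p_raw=p_raw,
                                     p_adjusted=min(1.0, m * p_raw)))
    return results


def rejection_rate(
    design: CohortDesign,
    effect: str = "genotype",
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    area: str | None = None,
) -> float:
    """Fraction of simulated cohorts where the named effect has p < alpha.

    The calibration harness: each rep draws a fresh cohort from ``design``
    and runs the configured ANOVA (one-way for single-factor designs,
    two-way otherwise).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a stable rate estimate")
    if area is None:
        first_cell = next(iter(design.cell_means.values()))
        area = next(iter(first_cell))
    col = f"norm_{area}"
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(reps):
        table = simulate_cohort_responses(design, seed=int(child.generate_state(1)[0]))
        if len(design.factors) == 1:
            res = one_way_anova(table[col], table[design.factors[0]])
            p = res.effects[0].p
        else:
            res = two_way_anova(table[col], table[design.factors[0]],
                                table[design.factors[1]],
                                names=(design.factors[0], design.factors[1]))
            p = res.effect(effect).p
        if p < alpha:
            rejections += 1
    return rejections / reps
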