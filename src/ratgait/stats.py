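"""Inference procedures for the gait and behavior metrics.

The statistical toolkit mirrors what is conventional in preclinical gait
work:

* a Gaussian linear model with a common velocity slope (ANCOVA) for
  metrics that correlate with the animal's self-selected walking speed,
  with group means adjusted to the grand-mean velocity;
* Student-Newman-Keuls (SNK) step-down post-hoc comparisons based on the
  studentized-range distribution, with the containment rule and a
  harmonic-mean n for unequal group sizes;
* a repeated-measures (one-sample, animal-level) t-test of each group
  against the theoretical value for balanced symmetric gait (imbalance 0,
  symmetry 0.5, weight distribution 50%), Bonferroni-corrected;
* one-way and two-factor (group x limb, Type II) ANOVA.

The experimental unit is the animal by default: trials are averaged
within animal before any group test, avoiding pseudo-replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "VelocityAdjustedModel",
    "PosthocResult",
    "DeviationTest",
    "fit_velocity_adjusted",
    "oneway_anova",
    "snk_posthoc",
    "deviation_test",
    "two_factor_anova",
]

ALPHA = 0.05


@dataclass
class VelocityAdjustedModel:
    """ANCOVA fit: metric ~ group + velocity (common slope)."""

    response: str
    groups: list[str]
    adjusted_means: dict[str, float]
    slope: float
    slope_se: float
    grand_mean_velocity: float
    mse: float
    df_resid: int
    group_sizes: dict[str, int]
    anova_F: float
    anova_p: float


@dataclass
class PosthocResult:
    """SNK pairwise decisions over a set of (adjusted) means."""

    means: dict[str, float]
    comparisons: pd.DataFrame  # group_a, group_b, diff, span, q, q_crit, p, significant
    alpha: float = ALPHA

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.comparisons[self.comparisons["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))


@dataclass
class DeviationTest:
    """One-sample t of animal means against a theoretical value."""

    theoretical: float
    mean: float
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    family_size: int
    below_machine_floor: bool = False

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA


def _check_groups(groups: Sequence[str]) -> list[str]:
    order: list[str] = []
    for g in groups:
        if g not in order:
            order.append(g)
    if len(order) < 2:
        raise ValueError("need >=2 groups")
    return order


def fit_velocity_adjusted(
    values: Sequence[float],
    groups: Sequence[str],
    velocities: Sequence[float],
    response: str = "metric",
    include_velocity: bool = True,
) -> VelocityAdjustedModel:
    """Fit metric ~ group + velocity and adjust group means to v̄.

    With ``include_velocity=False`` the slope is constrained to zero and
    the fit reduces exactly to a one-way ANOVA.  Raises if the velocities
    carry no within-group variation (the covariate would be collinear
    with the group factor).
    """
    y = np.asarray(values, float)
    v = np.asarray(velocities, float)
    g = np.asarray(groups)
    order = _check_groups(g)
    df = pd.DataFrame({"y": y, "velocity": v, "group": g})
    if include_velocity:
        within = df.groupby("group")["velocity"].std(ddof=0)
        if (within < 1e-12).all():
            raise ValueError(
                "velocity is constant within every group; the covariate is "
                "collinear with the group factor — fit with include_velocity=False"
            )
        formula = "y ~ C(group) + velocity"
    else:
        formula = "y ~ C(group)"
    fit = smf.ols(formula, data=df).fit()
    vbar = float(v.mean())
    pred = pd.DataFrame({"group": order, "velocity": vbar})
    adj = dict(zip(order, fit.predict(pred)))
    slope = float(fit.params.get("velocity", 0.0))
    slope_se = float(fit.bse.get("velocity", 0.0))
    table = anova_lm(fit, typ=2)
    ss_group = float(table.loc["C(group)", "sum_sq"])
    if ss_group < 1e-12 and fit.mse_resid < 1e-24:
        F, p = 0.0, 1.0
    else:
        F = float(table.loc["C(group)", "F"])
        p = float(table.loc["C(group)", "PR(>F)"])
        if not np.isfinite(F):
            F, p = 0.0, 1.0
    return VelocityAdjustedModel(
        response=response,
        groups=order,
        adjusted_means={k: float(x) for k, x in adj.items()},
        slope=slope,
        slope_se=slope_se,
        grand_mean_velocity=vbar,
        mse=float(fit.mse_resid),
        df_resid=int(fit.df_resid),
        group_sizes={k: int((g == k).sum()) for k in order},
        anova_F=F,
        anova_p=p,
    )


def oneway_anova(
    values: Sequence[float], groups: Sequence[str]
) -> tuple[float, float, float, int]:
    """One-way ANOVA: returns (F, p, residual MSE, residual df)."""
    y = np.asarray(values, float)
    g = np.asarray(groups)
    order = _check_groups(g)
    groups_y = [y[g == k] for k in order]
    n = len(y)
    grand = y.mean()
    ss_between = sum(len(gy) * (gy.mean() - grand) ** 2 for gy in groups_y)
    ss_within = sum(((gy - gy.mean()) ** 2).sum() for gy in groups_y)
    df_b, df_w = len(order) - 1, n - len(order)
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = ss_within / df_w
    if ss_between < 1e-12 and mse < 1e-24:
        return 0.0, 1.0, mse, df_w
    if mse == 0:
        return float("inf"), 0.0, mse, df_w
    F = (ss_between / df_b) / mse
    return float(F), float(sps.f.sf(F, df_b, df_w)), float(mse), int(df_w)


def snk_posthoc(
    means: Mapping[str, float],
    mse: float,
    df: int,
    sizes: Mapping[str, int],
    alpha: float = ALPHA,
) -> PosthocResult:
    """Student-Newman-Keuls step-down comparisons.

    Means are sorted; a pair spanning p ordered means is tested against
    the studentized-range critical value q(alpha, p, df) with standard
    error sqrt(MSE / n_h), n_h the harmonic mean of the two group sizes.
    The containment rule applies: every pair inside a non-significant
    range is declared non-significant without testing.
    """
    if df <= 0:
        raise ValueError("residual df must be positive")
    if mse < 0:
        raise ValueError("MSE must be >= 0")
    names = sorted(means, key=means.__getitem__)
    k = len(names)
    if k < 2:
        raise ValueError("need >=2 groups")
    rows: list[dict] = []
    blocked = np.zeros((k, k), bool)  # inside a non-significant span
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            a, b = names[i], names[j]
            diff = means[b] - means[a]
            if blocked[i, j]:
                q = q_crit = p = np.nan
                sig = False
            else:
                n_h = 2.0 / (1.0 / sizes[a] + 1.0 / sizes[b])
                se = np.sqrt(mse / n_h)
                if se == 0:
                    q = 0.0 if diff == 0 else float("inf")
                    p = 1.0 if diff == 0 else 0.0
                else:
                    q = diff / se
                    p = float(sps.studentized_range.sf(q, span, df))
                q_crit = float(sps.studentized_range.ppf(1 - alpha, span, df))
                sig = p < alpha
                if not sig:  # containment: block all enclosed pairs
                    blocked[i : j + 1, i : j + 1] = True
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "diff": diff,
                    "span": span,
                    "q": q,
                    "q_crit": q_crit,
                    "p": min(p, 1.0) if np.isfinite(p) else p,
                    "significant": sig,
                }
            )
    return PosthocResult(
        means=dict(means), comparisons=pd.DataFrame(rows), alpha=alpha
    )


def deviation_test(
    animal_means: Sequence[float],
    theoretical: float,
    family_size: int = 1,
) -> DeviationTest:
    """Repeated-measures t of animal-level means vs a theoretical value.

    The Bonferroni-adjusted p is ``min(1, p_raw * family_size)``.  With
    zero variance the test degenerates: p = 1 at the theoretical value,
    otherwise p is reported as 0 with the below-machine-floor flag set.
    """
    x = np.asarray(animal_means, float)
    if len(x) < 2:
        raise ValueError("need >=2 animals")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    df = len(x) - 1
    floor = False
    if sd == 0:
        if mean == theoretical:
            t, p = 0.0, 1.0
        else:
            t = float("inf") if mean > theoretical else float("-inf")
            p, floor = 0.0, True
    else:
        t = (mean - theoretical) / (sd / np.sqrt(len(x)))
        p = float(2 * sps.t.sf(abs(t), df))
    return DeviationTest(
        theoretical=theoretical,
        mean=mean,
        t=float(t),
        df=df,
        p_raw=p,
        p_adjusted=min(1.0, p * family_size),
        family_size=family_size,
        below_machine_floor=floor,
    )


def two_factor_anova(
    values: Sequence[float],
    groups: Sequence[str],
    limbs: Sequence[str],
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, PosthocResult]:
    """Two-factor (group x limb) ANOVA with SNK over the cells.

    Type II sums of squares accommodate unbalanced designs.  Every
    group x limb cell must be populated.  Returns the ANOVA table and the
    SNK post-hoc over all cell means (cells labelled ``group:limb``).
    """
    y = np.asarray(values, float)
    g = np.asarray(groups)
    l = np.asarray(limbs)
    df = pd.DataFrame({"y": y, "group": g, "limb": l})
    counts = df.groupby(["group", "limb"], sort=False).size().unstack()
    if counts.isna().any().any() or (counts == 0).any().any():
        empty = counts.stack(future_stack=True)
        empty = list(empty[empty.isna() | (empty == 0)].index)
        raise ValueError(f"empty group x limb cells: {empty}")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need >=2 levels for each factor")
    fit = smf.ols("y ~ C(group) * C(limb)", data=df).fit()
    table = anova_lm(fit, typ=2)
    # degenerate cases: zero effect and/or zero residual variance
    mse = fit.mse_resid
    for row in table.index[:-1]:
        ss = table.loc[row, "sum_sq"]
        if ss < 1e-12:
            table.loc[row, ["F", "PR(>F)"]] = [0.0, 1.0]
        elif mse < 1e-24:
            table.loc[row, ["F", "PR(>F)"]] = [np.inf, 0.0]
    cells = df.groupby(["group", "limb"], sort=False)["y"]
    cell_means = {f"{a}:{b}": float(m) for (a, b), m in cells.mean().items()}
    cell_sizes = {f"{a}:{b}": int(n) for (a, b), n in cells.size().items()}
    posthoc = snk_posthoc(
        cell_means, float(mse), int(fit.df_resid), cell_sizes, alpha=alpha
    )
    return table, posthoc
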