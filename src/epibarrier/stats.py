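"""Group-comparison statistics for barrier-model readouts.

Two classical workflows, both at alpha = 0.05 by default:

* one-way ANOVA followed by Dunnett's many-to-one comparisons against a
  control group, and
* two-way ANOVA (genotype x treatment style designs) with
  Bonferroni-adjusted post-hoc cell contrasts.

Homogeneous variances are assumed throughout (pooled error), as in the
classical forms of these tests.  Dunnett's adjusted p-values and critical
values come from a seeded Monte-Carlo sample of the null distribution of
the maximum absolute Dunnett statistic (correlated multivariate t), which
keeps the procedure dimension-agnostic and directly testable against
published tables or independent implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "TestResult",
    "one_way_anova",
    "dunnett_many_to_one",
    "dunnett_critical_value",
    "two_way_anova",
    "bonferroni_contrasts",
    "significance_stars",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """One effect or contrast with raw and adjusted p-values."""

    effect: str
    statistic: float
    df: tuple[float, float]
    p_value: float
    p_adjusted: float
    alpha: float = ALPHA
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_adjusted < self.alpha

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


def significance_stars(p: float) -> str:
    """Reporting tiers: * p<0.05, ** p<0.01, *** p<0.001, ns otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in out):
        raise ValueError("empty group")
    return out


def one_way_anova(groups, alpha: float = ALPHA) -> TestResult:
    """One-way fixed-effects ANOVA from between/within sums of squares.

    ``F = MS_between / MS_within``.  If the within-group variance is zero
    and all group means coincide the statistic is degenerate (0/0) and
    flagged; zero within-variance with distinct means yields ``inf``.
    """
    gs = _as_groups(groups)
    n = sum(g.size for g in gs)
    k = len(gs)
    if n - k < 1:
        raise ValueError("no residual degrees of freedom")
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df = (k - 1.0, float(n - k))
    if ss_within == 0 and ss_between == 0:
        return TestResult("group", 0.0, df, 1.0, 1.0, alpha, degenerate=True)
    ms_between = ss_between / df[0]
    ms_within = ss_within / df[1]
    if ms_within == 0:
        return TestResult("group", np.inf, df, 0.0, 0.0, alpha, degenerate=True)
    f = ms_between / ms_within
    p = float(sps.f.sf(f, *df))
    return TestResult("group", float(f), df, p, p, alpha)


def _dunnett_null_max_t(
    n_sizes: np.ndarray, df_resid: int, mc_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo sample of max_i |T_i| under the complete null.

    T_i = (Zbar_i - Zbar_0) / (s * sqrt(1/n_i + 1/n_0)) with shared
    control mean and shared pooled-variance draw, which induces the
    characteristic positive correlation between the comparisons.
    """
    n0 = n_sizes[0]
    trt = n_sizes[1:]
    z0 = rng.standard_normal(mc_samples) / np.sqrt(n0)
    zt = rng.standard_normal((mc_samples, trt.size)) / np.sqrt(trt)
    s = np.sqrt(rng.chisquare(df_resid, mc_samples) / df_resid)
    t = (zt - z0[:, None]) / (s[:, None] * np.sqrt(1.0 / trt + 1.0 / n0))
    return np.abs(t).max(axis=1)


def dunnett_critical_value(
    group_sizes,
    alpha: float = ALPHA,
    mc_samples: int = 200_000,
    seed: int = 0,
) -> float:
    """Two-sided Dunnett critical value |t| for a given design.

    ``group_sizes[0]`` is the control group.  Obtained as the (1 - alpha)
    quantile of the Monte-Carlo max-|t| null sample.
    """
    sizes = np.asarray(group_sizes, dtype=float)
    df_resid = int(sizes.sum()) - sizes.size
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for the pooled variance")
    rng = np.random.default_rng(seed)
    max_t = _dunnett_null_max_t(sizes, df_resid, mc_samples, rng)
    return float(np.quantile(max_t, 1.0 - alpha))


def dunnett_many_to_one(
    groups,
    labels=None,
    control: int | str = 0,
    alpha: float = ALPHA,
    mc_samples: int = 200_000,
    seed: int = 0,
) -> list[TestResult]:
    """Dunnett's test of each treatment group against one control.

    Pooled-variance t statistics per comparison; adjusted p-values are the
    Monte-Carlo probabilities that the null max-|t| exceeds each observed
    |t| (family-wise, two-sided).  With a single treatment group this
    reduces to a two-sample pooled t test up to Monte-Carlo error.
    """
    gs = _as_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    labels = list(labels)
    ctrl_idx = labels.index(control) if isinstance(control, str) else control
    ctrl = gs[ctrl_idx]
    others = [(lab, g) for i, (lab, g) in enumerate(zip(labels, gs)) if i != ctrl_idx]
    n = sum(g.size for g in gs)
    k = len(gs)
    df_resid = n - k
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for the pooled variance")
    pooled_var = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_resid

    sizes = np.array([ctrl.size] + [g.size for _, g in others], dtype=float)
    rng = np.random.default_rng(seed)
    null_max_t = _dunnett_null_max_t(sizes, df_resid, mc_samples, rng)

    results = []
    for lab, g in others:
        se = np.sqrt(pooled_var * (1.0 / g.size + 1.0 / ctrl.size))
        if se == 0:
            t = 0.0 if g.mean() == ctrl.mean() else np.inf
        else:
            t = (g.mean() - ctrl.mean()) / se
        p_raw = float(2.0 * sps.t.sf(abs(t), df_resid)) if np.isfinite(t) else 0.0
        p_adj = float((null_max_t >= abs(t)).mean()) if np.isfinite(t) else 0.0
        p_adj = max(p_adj, p_raw) if np.isfinite(t) else 0.0
        results.append(
            TestResult(
                effect=f"{lab} vs {labels[ctrl_idx]}",
                statistic=float(t),
                df=(1.0, float(df_resid)),
                p_value=min(p_raw, 1.0),
                p_adjusted=min(p_adj, 1.0),
                alpha=alpha,
            )
        )
    return results


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
    alpha: float = ALPHA,
) -> list[TestResult]:
    """Two-way fixed-effects ANOVA: main effects and interaction.

    Balanced designs give the classical decomposition; unbalanced designs
    use Type-II sums of squares.  Every factor-A x factor-B cell must be
    non-empty.
    """
    counts = data.groupby([factor_a, factor_b], observed=True)[value].count()
    n_a = data[factor_a].nunique()
    n_b = data[factor_b].nunique()
    if len(counts) < n_a * n_b:
        raise ValueError("two-way layout has empty cells")
    df = data.rename(columns={value: "y", factor_a: "A", factor_b: "B"})
    model = ols("y ~ C(A) * C(B)", data=df).fit()
    table = anova_lm(model, typ=2)
    name_map = {"C(A)": factor_a, "C(B)": factor_b, "C(A):C(B)": f"{factor_a}:{factor_b}"}
    df_resid = float(table.loc["Residual", "df"])
    results = []
    for row_name, effect in name_map.items():
        f = float(table.loc[row_name, "F"])
        p = float(table.loc[row_name, "PR(>F)"])
        results.append(
            TestResult(effect, f, (float(table.loc[row_name, "df"]), df_resid), p, p, alpha)
        )
    return results


def bonferroni_contrasts(
    data: pd.DataFrame,
    contrasts: list[tuple],
    value: str = "value",
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
    alpha: float = ALPHA,
) -> list[TestResult]:
    """Bonferroni-adjusted pairwise cell contrasts after a two-way ANOVA.

    Each contrast is a pair of cells ``((a1, b1), (a2, b2))``.  The t
    statistic uses the pooled within-cell error from the full layout;
    adjusted p = min(1, m * p) for m contrasts (identity when m = 1).
    """
    cells = {
        key: np.asarray(sub[value], dtype=float)
        for key, sub in data.groupby([factor_a, factor_b], observed=True)
    }
    n = sum(v.size for v in cells.values())
    df_resid = n - len(cells)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    pooled_var = sum(((v - v.mean()) ** 2).sum() for v in cells.values()) / df_resid
    m = len(contrasts)
    results = []
    for cell1, cell2 in contrasts:
        if cell1 not in cells or cell2 not in cells:
            raise ValueError(f"contrast references an empty or unknown cell: {cell1} vs {cell2}")
        g1, g2 = cells[cell1], cells[cell2]
        se = np.sqrt(pooled_var * (1.0 / g1.size + 1.0 / g2.size))
        t = (g1.mean() - g2.mean()) / se if se > 0 else 0.0
        p = float(2.0 * sps.t.sf(abs(t), df_resid))
        results.append(
            TestResult(
                effect=f"{cell1} vs {cell2}",
                statistic=float(t),
                df=(1.0, float(df_resid)),
                p_value=p,
                p_adjusted=min(1.0, m * p),
                alpha=alpha,
            )
        )
    return results
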