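"""Two-way fixed-effects ANOVA and Tukey-Kramer post hoc comparisons.

Classification errors from the evaluation protocols are compared with a
balanced two-way ANOVA using the classifier and the time level (days or
sessions) as factors; subjects enter as replicates within cells.  With one
replicate per cell the interaction cannot be separated from error and the
additive model is fitted instead.  Post hoc pairwise comparisons of the
classifier factor use the Tukey-Kramer honestly-significant-difference
criterion on the residual mean square, with simultaneous confidence
intervals from the studentized-range distribution.  Effects with p < 0.05
(default alpha) are called significant.  CE values enter untransformed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import ValidationError


@dataclass
class AnovaResult:
    """Balanced two-way decomposition; terms: A (classifier), B (time),
    AB (interaction, absent when replicates == 1), residual."""

    table: pd.DataFrame  # index: term; columns: ss, df, ms, F, p
    factor_a: str
    factor_b: str
    alpha: float = 0.05
    degenerate: bool = False  # zero residual variance: F undefined
    cell_means: pd.DataFrame | None = None
    n_replicates: int = 1

    def significant(self, term: str) -> bool:
        if self.degenerate:
            return False
        return bool(self.table.loc[term, "p"] < self.alpha)


@dataclass
class PosthocResult:
    """Tukey-Kramer pairwise comparisons on one factor."""

    comparisons: pd.DataFrame  # a, b, diff, ci_low, ci_high, p_adj, significant
    factor: str
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.comparisons[self.comparisons["significant"]]
        return [tuple(x) for x in sig[["a", "b"]].itertuples(index=False)]


def _check_balanced(df: pd.DataFrame, a: str, b: str) -> int:
    counts = df.groupby([a, b], observed=True).size()
    full = df[a].nunique() * df[b].nunique()
    if len(counts) != full or counts.nunique() != 1:
        raise ValidationError(
            "unbalanced design: every (factor_a, factor_b) cell needs the "
            "same number of replicates; build a balanced table (the study "
            "design is balanced) or drop incomplete cells"
        )
    return int(counts.iloc[0])


def anova_two_way(
    df: pd.DataFrame,
    value: str = "ce",
    factor_a: str = "classifier",
    factor_b: str = "time",
    alpha: float = 0.05,
) -> AnovaResult:
    """Balanced fixed-effects two-way ANOVA.

    With r replicates per cell the model is y = mu + A + B + AB + e; with
    r = 1 the additive model y = mu + A + B + e.  Closed-form sums of
    squares for the balanced case; p-values from the F distribution.
    """
    for col in (value, factor_a, factor_b):
        if col not in df.columns:
            raise ValidationError(f"column {col!r} missing from table")
    if df[factor_a].nunique() < 2 or df[factor_b].nunique() < 2:
        raise ValidationError("each factor needs at least 2 levels")
    r = _check_balanced(df, factor_a, factor_b)

    y = df[value].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    a_levels = sorted(df[factor_a].unique())
    b_levels = sorted(df[factor_b].unique())
    na, nb = len(a_levels), len(b_levels)

    a_means = df.groupby(factor_a, observed=True)[value].mean()
    b_means = df.groupby(factor_b, observed=True)[value].mean()
    cell_means = df.groupby([factor_a, factor_b], observed=True)[value].mean()

    ss_total = float(np.sum((y - grand) ** 2))
    ss_a = r * nb * float(np.sum((a_means.to_numpy() - grand) ** 2))
    ss_b = r * na * float(np.sum((b_means.to_numpy() - grand) ** 2))
    # interaction from cell means
    inter = 0.0
    for (la, lb), m in cell_means.items():
        inter += (m - a_means[la] - b_means[lb] + grand) ** 2
    ss_ab = r * float(inter)
    ss_resid = ss_total - ss_a - ss_b - ss_ab

    rows = {}
    if r > 1:
        df_resid = na * nb * (r - 1)
        rows["A"] = (ss_a, na - 1)
        rows["B"] = (ss_b, nb - 1)
        rows["AB"] = (ss_ab, (na - 1) * (nb - 1))
        rows["residual"] = (max(ss_resid, 0.0), df_resid)
    else:
        # replicates == 1: interaction is the error stratum
        df_resid = (na - 1) * (nb - 1)
        rows["A"] = (ss_a, na - 1)
        rows["B"] = (ss_b, nb - 1)
        rows["residual"] = (ss_ab, df_resid)

    ms_resid = rows["residual"][0] / rows["residual"][1] if rows["residual"][1] else 0.0
    degenerate = ms_resid <= 0
    out = []
    for term, (ss, dof) in rows.items():
        ms = ss / dof if dof else np.nan
        if term == "residual" or degenerate:
            f_stat, p = np.nan, np.nan
        else:
            f_stat = ms / ms_resid
            p = float(sps.f.sf(f_stat, dof, rows["residual"][1]))
        out.append(
            {"term": term, "ss": ss, "df": dof, "ms": ms, "F": f_stat, "p": p}
        )
    table = pd.DataFrame(out).set_index("term")
    return AnovaResult(
        table=table,
        factor_a=factor_a,
        factor_b=factor_b,
        alpha=alpha,
        degenerate=degenerate,
        cell_means=cell_means.reset_index(),
        n_replicates=r,
    )


def posthoc_pairwise(
    anova: AnovaResult,
    df: pd.DataFrame,
    value: str = "ce",
    factor: str | None = None,
) -> PosthocResult:
    """Tukey-Kramer HSD comparisons of the classifier-factor levels.

    Uses the ANOVA residual mean square; the adjusted p-value for a pair is
    the studentized-range tail probability of the observed q, and the
    simultaneous CI half-width is q_crit * sqrt(MSE/2 * (1/n_i + 1/n_j)).
    """
    factor = factor or anova.factor_a
    levels = sorted(df[factor].unique())
    if len(levels) < 2:
        raise ValidationError("post hoc needs at least 2 levels to compare")
    ms_resid = float(anova.table.loc["residual", "ms"])
    df_resid = int(anova.table.loc["residual", "df"])
    k = len(levels)
    means = df.groupby(factor, observed=True)[value].mean()
    counts = df.groupby(factor, observed=True)[value].count()

    rows = []
    for la, lb in itertools.combinations(levels, 2):
        diff = float(means[la] - means[lb])
        if anova.degenerate:
            rows.append(
                {
                    "a": la,
                    "b": lb,
                    "diff": diff,
                    "ci_low": diff,
                    "ci_high": diff,
                    "p_adj": np.nan,
                    "significant": False,
                }
            )
            continue
        se = np.sqrt(0.5 * ms_resid * (1.0 / counts[la] + 1.0 / counts[lb]))
        q_obs = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q_obs, k, df_resid))
        q_crit = float(sps.studentized_range.ppf(1.0 - anova.alpha, k, df_resid))
        half = q_crit * se
        rows.append(
            {
                "a": la,
                "b": lb,
                "diff": diff,
                "ci_low": diff - half,
                "ci_high": diff + half,
                "p_adj": p_adj,
                "significant": p_adj < anova.alpha,
            }
        )
    return PosthocResult(
        comparisons=pd.DataFrame(rows), factor=factor, alpha=anova.alpha
    )


def describe(anova: AnovaResult, posthoc: PosthocResult | None = None) -> str:
    """Human-readable summary naming significant terms and pairs."""
    lines = []
    if anova.degenerate:
        lines.append(
            "degenerate table (zero residual variance): F undefined, no "
            "effect called significant"
        )
    else:
        for term in anova.table.index:
            if term == "residual":
                continue
            p = anova.table.loc[term, "p"]
            label = {"A": anova.factor_a, "B": anova.factor_b, "AB": "interaction"}[
                term
            ]
            verdict = "significant" if p < anova.alpha else "not significant"
            lines.append(f"{label}: F = {anova.table.loc[term, 'F']:.3f}, "
                         f"p = {p:.3g} ({verdict})")
    if posthoc is not None:
        for _, row in posthoc.comparisons.iterrows():
            verdict = "significant" if row["significant"] else "n.s."
            lines.append(
                f"{row['a']} vs {row['b']}: diff = {row['diff']:+.4f}, "
                f"p = {row['p_adj']:.3g} ({verdict})"
            )
    return "\n".join(lines)
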