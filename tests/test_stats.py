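"""ANOVA decomposition oracles, invariances, and post hoc behavior."""

import itertools

import numpy as np
import pandas as pd
import pytest

from emgdays.dataset import ValidationError
from emgdays.stats import anova_two_way, describe, posthoc_pairwise


def make_table(values_by_cell, reps=1):
    """values_by_cell: {(a_level, b_level): [replicates...]}"""
    rows = []
    for (a, b), vals in values_by_cell.items():
        for v in np.atleast_1d(vals):
            rows.append({"classifier": a, "time": b, "ce": float(v)})
    return pd.DataFrame(rows)


def brute_force_ss(df):
    """Explicit sums-of-squares computation, independent of the module."""
    y = df["ce"].to_numpy()
    grand = y.mean()
    a_levels = sorted(df["classifier"].unique())
    b_levels = sorted(df["time"].unique())
    r = len(df) // (len(a_levels) * len(b_levels))
    ss_a = ss_b = ss_ab = ss_e = 0.0
    for a in a_levels:
        m = df[df["classifier"] == a]["ce"].mean()
        ss_a += r * len(b_levels) * (m - grand) ** 2
    for b in b_levels:
        m = df[df["time"] == b]["ce"].mean()
        ss_b += r * len(a_levels) * (m - grand) ** 2
    for a in a_levels:
        for b in b_levels:
            cell = df[(df["classifier"] == a) & (df["time"] == b)]["ce"]
            ma = df[df["classifier"] == a]["ce"].mean()
            mb = df[df["time"] == b]["ce"].mean()
            ss_ab += r * (cell.mean() - ma - mb + grand) ** 2
            ss_e += ((cell - cell.mean()) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_e


def test_two_by_two_hand_oracle():
    """2x2 balanced, 2 replicates, base values {10,12;20,22}, replicate
    offsets {0,1}: SS terms equal the explicit computation."""
    cells = {
        ("A1", "B1"): [10, 11],
        ("A1", "B2"): [12, 13],
        ("A2", "B1"): [20, 21],
        ("A2", "B2"): [22, 23],
    }
    df = make_table(cells)
    res = anova_two_way(df)
    ss_a, ss_b, ss_ab, ss_e = brute_force_ss(df)
    assert res.table.loc["A", "ss"] == pytest.approx(ss_a)
    assert res.table.loc["B", "ss"] == pytest.approx(ss_b)
    assert res.table.loc["AB", "ss"] == pytest.approx(ss_ab)
    assert res.table.loc["residual", "ss"] == pytest.approx(ss_e)
    assert res.table["df"].sum() == len(df) - 1


def test_ss_decomposition_sums_to_total_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(10):
        df = make_table(
            {
                (f"A{i}", f"B{j}"): rng.normal(size=3)
                for i in range(3)
                for j in range(4)
            }
        )
        res = anova_two_way(df)
        total = float(((df["ce"] - df["ce"].mean()) ** 2).sum())
        assert res.table["ss"].sum() == pytest.approx(total, rel=1e-8)


def test_factor_relabeling_leaves_f_unchanged():
    rng = np.random.default_rng(1)
    cells = {
        (f"A{i}", f"B{j}"): rng.normal(size=2) for i in range(3) for j in range(3)
    }
    df = make_table(cells)
    res1 = anova_two_way(df)
    relabel = {"A0": "Az", "A1": "Ay", "A2": "Ax"}
    df2 = df.assign(classifier=df["classifier"].map(relabel))
    res2 = anova_two_way(df2)
    np.testing.assert_allclose(
        res1.table["F"].dropna(), res2.table["F"].dropna()
    )


def test_degenerate_all_equal_flagged_not_significant():
    df = make_table({(a, b): [5.0, 5.0] for a in "AB" for b in "CD"})
    res = anova_two_way(df)
    assert res.degenerate
    assert not res.significant("A")
    post = posthoc_pairwise(res, df)
    assert not post.comparisons["significant"].any()
    assert "degenerate" in describe(res)


def test_single_replicate_uses_additive_model():
    rng = np.random.default_rng(2)
    df = make_table(
        {(f"A{i}", f"B{j}"): rng.normal() for i in range(4) for j in range(5)}
    )
    res = anova_two_way(df)
    assert "AB" not in res.table.index
    assert res.table.loc["residual", "df"] == 3 * 4
    assert res.table["df"].sum() == len(df) - 1


def test_unbalanced_rejected():
    df = make_table({("A", "B1"): [1, 2], ("A", "B2"): [1], ("C", "B1"): [1],
                     ("C", "B2"): [2]})
    with pytest.raises(ValidationError, match="balanced"):
        anova_two_way(df)


def test_posthoc_pair_count_and_duplicate_classifiers():
    rng = np.random.default_rng(3)
    base = {f"B{j}": rng.normal(size=3) for j in range(5)}
    cells = {}
    for a in ("c1", "c2", "c3", "c4"):
        for b, v in base.items():
            # c1 and c2 duplicated; c4 strongly offset
            off = 3.0 if a == "c4" else 0.0
            jitter = rng.normal(scale=0.05, size=3) if a == "c3" else 0.0
            cells[(a, b)] = v + off + jitter
    df = make_table(cells)
    res = anova_two_way(df)
    post = posthoc_pairwise(res, df)
    assert len(post.comparisons) == 6  # C(4,2)
    dup = post.comparisons.query("a == 'c1' and b == 'c2'").iloc[0]
    assert dup["diff"] == pytest.approx(0.0, abs=1e-12)
    assert not dup["significant"]
    # the offset classifier differs significantly from all others
    sig = post.significant_pairs()
    assert all(("c4" in p) == (p in sig or (p[1], p[0]) in sig)
               for p in itertools.combinations(("c1", "c2", "c3", "c4"), 2))
    # CI consistency: significant iff CI excludes 0
    for _, row in post.comparisons.iterrows():
        excludes = row["ci_low"] > 0 or row["ci_high"] < 0
        assert excludes == row["significant"]


def test_strong_effect_detected_by_monte_carlo():
    """A classifier offset by 10x the noise SD is flagged significant."""
    rng = np.random.default_rng(4)
    cells = {}
    for a in ("c1", "c2", "c3"):
        for j in range(6):
            off = 1.0 if a == "c3" else 0.0
            cells[(a, f"B{j}")] = rng.normal(scale=0.1, size=4) + off
    df = make_table(cells)
    res = anova_two_way(df)
    assert res.significant("A")
    post = posthoc_pairwise(res, df)
    flags = {
        tuple(sorted((r["a"], r["b"]))): r["significant"]
        for _, r in post.comparisons.iterrows()
    }
    assert flags[("c1", "c3")] and flags[("c2", "c3")]
    assert not flags[("c1", "c2")]


def test_matches_statsmodels_reference():
    """Cross-check SS/F/p against statsmodels OLS ANOVA, and the post hoc
    against its Tukey HSD implementation."""
    smf = pytest.importorskip("statsmodels.formula.api")
    sma = pytest.importorskip("statsmodels.stats.anova")
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(5)
    cells = {
        (f"A{i}", f"B{j}"): rng.normal(loc=0.3 * i, size=4)
        for i in range(3)
        for j in range(4)
    }
    df = make_table(cells)
    ours = anova_two_way(df)
    fit = smf.ols("ce ~ C(classifier) * C(time)", data=df).fit()
    ref = sma.anova_lm(fit, typ=2)
    assert ours.table.loc["A", "ss"] == pytest.approx(
        ref.loc["C(classifier)", "sum_sq"], rel=1e-8
    )
    assert ours.table.loc["AB", "F"] == pytest.approx(
        ref.loc["C(classifier):C(time)", "F"], rel=1e-8
    )
    assert ours.table.loc["A", "p"] == pytest.approx(
        ref.loc["C(classifier)", "PR(>F)"], rel=1e-6, abs=1e-12
    )
    # Tukey: statsmodels uses one-way MSE, so compare on matching residual df
    post = posthoc_pairwise(ours, df)
    ref_tukey = pairwise_tukeyhsd(df["ce"], df["classifier"])
    ours_sorted = post.comparisons.sort_values(["a", "b"])
    np.testing.assert_allclose(
        ours_sorted["diff"].to_numpy(),
        -np.asarray(ref_tukey.meandiffs),  # sign convention differs
        rtol=1e-8,
    )
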