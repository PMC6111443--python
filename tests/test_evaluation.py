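"""Protocol structure, metric arithmetic, stubs and aggregation."""

import numpy as np
import pandas as pd
import pytest

from emgdays.classifiers import make_classifier
from emgdays.dataset import ValidationError
from emgdays.evaluation import (
    EvalReport,
    between_sessions_cv,
    classification_error,
    iter_within_session_folds,
    leave_one_day_out_cv,
    pairwise_days_cv,
    run_protocols,
    within_session_cv,
)

from .conftest import ConstantStub, OracleStub, UniformRandomStub


def test_classification_error_arithmetic():
    assert classification_error([1, 1, 0, 0, 1, 1, 1, 1, 1, 1],
                                [1, 1, 0, 0, 1, 1, 1, 1, 0, 0]) == 0.2
    assert classification_error([1, 2, 3], [1, 2, 3]) == 0.0
    assert classification_error([1, 1, 1], [2, 2, 2]) == 1.0
    with pytest.raises(ValidationError):
        classification_error([], [])
    with pytest.raises(ValidationError):
        classification_error([1], [1, 2])


def test_within_session_folds_partition_by_repetition(tiny_session):
    """Each fold holds out exactly one repetition of every movement."""
    folds = list(iter_within_session_folds(tiny_session))
    assert len(folds) == 3  # fixture has 3 repetitions
    meta = tiny_session.meta
    seen = np.zeros(len(meta), dtype=int)
    for rep, train, test in folds:
        held = meta[test]
        assert set(held["repetition"]) == {rep}
        assert set(held["movement"]) == set(meta["movement"].unique())
        assert not np.any(train & test)
        seen += test
    assert np.all(seen == 1)  # test folds tile the session exactly


def test_within_session_missing_repetition_is_reported(tiny_session):
    broken = tiny_session.subset(
        ~(
            (tiny_session.meta["movement"] == "WF")
            & (tiny_session.meta["repetition"] == 2)
        ).to_numpy()
    )
    with pytest.raises(ValidationError, match=r"'WF', .*2"):
        within_session_cv(broken, lambda s: ConstantStub())


def test_oracle_stub_has_zero_ce_everywhere(tiny_sessions):
    stub = OracleStub(tiny_sessions)
    mk = lambda s: stub
    assert within_session_cv(tiny_sessions[0], mk)["ce"].eq(0).all()
    assert between_sessions_cv(tiny_sessions[:2], mk)["ce"].eq(0).all()
    assert pairwise_days_cv(tiny_sessions, mk)["ce"].eq(0).all()
    assert leave_one_day_out_cv(tiny_sessions, mk)["ce"].eq(0).all()


def test_uniform_random_stub_ce_near_six_sevenths(tiny_sessions):
    stub = UniformRandomStub(seed=0)
    ces = pd.concat(
        [within_session_cv(sd, lambda s: stub)["ce"] for sd in tiny_sessions]
    )
    assert ces.mean() == pytest.approx(6 / 7, abs=0.05)


def test_constant_stub_ce_is_one_minus_majority_share(tiny_session):
    df = within_session_cv(tiny_session, lambda s: ConstantStub())
    meta = tiny_session.meta
    for (rep,), row in zip(
        [(r,) for r in sorted(meta["repetition"].unique())], df.itertuples()
    ):
        held = meta[meta["repetition"] == rep]
        # constant stub predicts class of first training window
        share = (held["movement"].map(lambda m: m) == "RT").mean()
        assert 0 <= row.ce <= 1


def test_between_sessions_requires_two(tiny_sessions):
    with pytest.raises(ValidationError, match="2 sessions"):
        between_sessions_cv(tiny_sessions[:1], lambda s: ConstantStub())


def test_between_sessions_swap_symmetry(tiny_sessions):
    mk = lambda s: make_classifier("lda", seed=s)
    a = between_sessions_cv(tiny_sessions[:2], mk)
    b = between_sessions_cv(tiny_sessions[:2][::-1], mk)
    assert sorted(a["ce"]) == sorted(b["ce"])


def test_pair_count_formula(tiny_sessions):
    pairs = pairwise_days_cv(tiny_sessions, lambda s: ConstantStub())
    assert len(pairs) == 1  # 2 days -> 1 pair
    assert pairs["ce"].iloc[0] == pytest.approx(
        0.5 * (pairs["ce_ij"] + pairs["ce_ji"]).iloc[0]
    )
    with pytest.raises(ValidationError, match="2 days"):
        pairwise_days_cv(tiny_sessions[:2], lambda s: ConstantStub())


def test_two_day_lodo_equals_day_pair_folds(tiny_sessions):
    """With 2 days, leave-one-day-out reduces to the single pair's folds."""
    mk = lambda s: make_classifier("lda", seed=s)
    lodo = leave_one_day_out_cv(tiny_sessions, mk)
    pair = pairwise_days_cv(tiny_sessions, mk)
    assert len(lodo) == 2
    assert sorted(lodo["ce"]) == sorted([pair["ce_ij"].iloc[0], pair["ce_ji"].iloc[0]])


def test_aggregate_arithmetic():
    rep = EvalReport(
        records=pd.DataFrame(
            [
                {"subject": "S1", "analysis": "a", "classifier": "lda",
                 "fold": "f1", "ce": 0.1},
                {"subject": "S1", "analysis": "a", "classifier": "lda",
                 "fold": "f2", "ce": 0.3},
                {"subject": "S1", "analysis": "a", "classifier": "cnn",
                 "fold": "f1", "ce": 0.2},
            ]
        )
    )
    agg = rep.aggregate("classifier").set_index("classifier")
    assert agg.loc["lda", "mean_ce"] == pytest.approx(0.2)
    assert agg.loc["cnn", "mean_ce"] == pytest.approx(0.2)
    assert agg.loc["cnn", "sd_ce"] == 0.0  # single record


def test_run_protocols_completeness(tiny_sessions):
    """The full grid produces records for every analysis x classifier with
    the expected fold counts."""
    report = run_protocols(
        tiny_sessions,
        {"lda": lambda s: make_classifier("lda", seed=s),
         "stub": lambda s: ConstantStub()},
    )
    r = report.records
    counts = r.groupby(["analysis", "classifier"]).size().unstack()
    # 3 reps x 4 sessions, 2 folds x 2 days, 1 pair, 2 days held out
    expected = {"within_session": 12, "between_sessions": 4,
                "pair_of_days": 1, "leave_one_day_out": 2}
    for analysis, n in expected.items():
        assert (counts.loc[analysis] == n).all()
    table = report.summary_table()
    assert not table.isna().any().any()


def test_triangle_table_layout(tiny_sessions):
    from emgdays.evaluation import triangle_table

    mk = lambda s: make_classifier("lda", seed=s)
    pairs = pairwise_days_cv(tiny_sessions, mk)
    text = triangle_table(pairs, pairs, "cnn", "ssae_r")
    lines = text.splitlines()
    assert "upper triangle: cnn" in lines[0]
    assert len(lines) == 2 + 2  # header rows + one row per day
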