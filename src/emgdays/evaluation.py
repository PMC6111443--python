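"""Cross-validation protocols and the classification-error metric.

Four protocols probe increasingly severe nonstationarity:

* **within_session** — 10-fold by repetition index: fold r holds out
  repetition r of every movement, so overlapping windows from one
  repetition never straddle the train/test boundary.
* **between_sessions** — 2-fold across the two same-day sessions.
* **pair_of_days** — every unordered day pair (i, j): train day i / test
  day j and the swap; the two fold CEs are averaged into the pair's cell
  (n days give n(n-1)/2 pairs, 105 for 15 days).
* **leave_one_day_out** — per day d, train on all other days (both
  sessions), test on day d.

The metric is the classification error CE = wrongly classified windows /
total windows (CA = 1 - CE).  A classifier is retrained from scratch with
a fresh fold-derived seed for every fold; no state crosses folds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Recording, ValidationError
from .features import FeatureSet, featurize
from .preprocess import (
    WindowSet,
    concat_windowsets,
    extract_windows,
    highpass,
    trim_transitions,
)

ANALYSES = (
    "within_session",
    "between_sessions",
    "pair_of_days",
    "leave_one_day_out",
)


@dataclass
class SessionData:
    """Windows plus features for one session, ready for any classifier."""

    windows: WindowSet
    features: FeatureSet

    @property
    def labels(self) -> np.ndarray:
        return self.windows.labels

    @property
    def meta(self) -> pd.DataFrame:
        return self.windows.meta

    @property
    def subject(self) -> str:
        return self.meta["subject"].iloc[0]

    @property
    def day(self) -> int:
        return int(self.meta["day"].iloc[0])

    @property
    def session(self) -> int:
        return int(self.meta["session"].iloc[0])

    def subset(self, mask: np.ndarray) -> "SessionData":
        idx = np.flatnonzero(mask)
        return SessionData(
            windows=WindowSet(
                windows=self.windows.windows[idx],
                labels=self.windows.labels[idx],
                meta=self.windows.meta.iloc[idx].reset_index(drop=True),
                fs=self.windows.fs,
            ),
            features=FeatureSet(
                features=self.features.features[idx],
                labels=self.features.labels[idx],
                meta=self.features.meta.iloc[idx].reset_index(drop=True),
                threshold=self.features.threshold,
            ),
        )


def prepare_session(
    recording: Recording,
    cutoff_hz: float = 2.0,
    order: int = 3,
    zero_phase: bool = False,
    trim_s: float = 0.5,
    window_ms: float = 150.0,
    step_ms: float = 25.0,
) -> SessionData:
    """Full preprocessing pipeline: high-pass, trim, window, featurize."""
    rec = highpass(recording, order=order, cutoff_hz=cutoff_hz, zero_phase=zero_phase)
    rec = trim_transitions(rec, trim_s=trim_s)
    ws = extract_windows(rec, window_ms=window_ms, step_ms=step_ms)
    return SessionData(windows=ws, features=featurize(ws))


def concat_sessions(sessions: list[SessionData]) -> SessionData:
    ws = concat_windowsets([s.windows for s in sessions])
    return SessionData(
        windows=ws,
        features=FeatureSet(
            features=np.concatenate([s.features.features for s in sessions]),
            labels=ws.labels,
            meta=ws.meta,
            threshold=sessions[0].features.threshold,
        ),
    )


def classification_error(pred: np.ndarray, truth: np.ndarray) -> float:
    """Wrongly classified samples divided by the total number of samples."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValidationError("pred and truth lengths differ")
    if len(pred) == 0:
        raise ValidationError("classification_error of zero samples")
    return float(np.mean(pred != truth))


def _fold_seed(base_seed: int, fold_index: int) -> int:
    return int((base_seed * 1_000_003 + fold_index) % 2**31)


def _run_fold(train_sd: SessionData, test_sd: SessionData, clf) -> float:
    clf.fit(clf.extract(train_sd), train_sd.labels)
    pred = clf.predict(clf.extract(test_sd))
    return classification_error(pred, test_sd.labels)


def iter_within_session_folds(sd: SessionData):
    """Yield (repetition, train_mask, test_mask) with folds partitioned by
    repetition index, every movement's repetition r held out together."""
    meta = sd.meta
    reps = sorted(meta["repetition"].unique())
    missing = [
        (m, r)
        for m in meta["movement"].unique()
        for r in reps
        if not ((meta["movement"] == m) & (meta["repetition"] == r)).any()
    ]
    if missing:
        raise ValidationError(
            f"missing (movement, repetition) combinations: {missing}"
        )
    rep_col = meta["repetition"].to_numpy()
    for r in reps:
        test = rep_col == r
        yield r, ~test, test


def within_session_cv(sd: SessionData, make_clf, base_seed: int = 0) -> pd.DataFrame:
    """k-fold by repetition (k = repetitions per movement, 10 in the full
    protocol): train on k-1 repetitions of every movement, test on the
    held-out one."""
    rows = []
    for i, (r, train_mask, test_mask) in enumerate(iter_within_session_folds(sd)):
        clf = make_clf(_fold_seed(base_seed, i))
        ce = _run_fold(sd.subset(train_mask), sd.subset(test_mask), clf)
        rows.append({"fold": f"rep{r}", "ce": ce})
    return pd.DataFrame(rows)


def between_sessions_cv(
    day_sessions: list[SessionData], make_clf, base_seed: int = 0
) -> pd.DataFrame:
    """2-fold across the two sessions of one day: train one, test the other,
    then swap."""
    if len(day_sessions) != 2:
        raise ValidationError(
            f"between_sessions_cv needs exactly 2 sessions, got {len(day_sessions)}"
        )
    a, b = day_sessions
    rows = []
    for i, (train_sd, test_sd) in enumerate([(a, b), (b, a)]):
        clf = make_clf(_fold_seed(base_seed, i))
        rows.append(
            {
                "fold": f"train_ses{train_sd.session}",
                "ce": _run_fold(train_sd, test_sd, clf),
            }
        )
    return pd.DataFrame(rows)


def _group_by_day(sessions: list[SessionData]) -> dict[int, SessionData]:
    days: dict[int, list[SessionData]] = {}
    for s in sessions:
        days.setdefault(s.day, []).append(s)
    return {d: concat_sessions(ss) for d, ss in sorted(days.items())}


def pairwise_days_cv(
    sessions: list[SessionData], make_clf, base_seed: int = 0
) -> pd.DataFrame:
    """Two-fold CV over every unordered pair of days.

    Returns one row per pair with the two directional fold CEs and their
    mean (``ce``), the single number a pair-of-days table cell holds.
    """
    days = _group_by_day(sessions)
    if len(days) < 2:
        raise ValidationError("pairwise_days_cv needs at least 2 days")
    rows = []
    for k, (i, j) in enumerate(itertools.combinations(sorted(days), 2)):
        ce_ij = _run_fold(days[i], days[j], make_clf(_fold_seed(base_seed, 2 * k)))
        ce_ji = _run_fold(days[j], days[i], make_clf(_fold_seed(base_seed, 2 * k + 1)))
        rows.append(
            {
                "day_i": i,
                "day_j": j,
                "ce_ij": ce_ij,
                "ce_ji": ce_ji,
                "ce": 0.5 * (ce_ij + ce_ji),
            }
        )
    return pd.DataFrame(rows)


def leave_one_day_out_cv(
    sessions: list[SessionData], make_clf, base_seed: int = 0
) -> pd.DataFrame:
    """Per day d: train on every other day (both sessions), test on day d."""
    days = _group_by_day(sessions)
    if len(days) < 2:
        raise ValidationError("leave_one_day_out_cv needs at least 2 days")
    rows = []
    for i, d in enumerate(sorted(days)):
        train = concat_sessions([days[k] for k in sorted(days) if k != d])
        clf = make_clf(_fold_seed(base_seed, i))
        rows.append({"fold": f"day{d}", "ce": _run_fold(train, days[d], clf)})
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Long-format per-fold records plus aggregation helpers.

    ``records`` columns: subject, analysis, classifier, fold, ce.
    """

    records: pd.DataFrame

    def aggregate(self, by: list[str] | str = "classifier") -> pd.DataFrame:
        """Mean and SD of CE at the requested grouping."""
        if len(self.records) == 0:
            raise ValidationError("no records to aggregate")
        if isinstance(by, str):
            by = [by]
        g = self.records.groupby(by)["ce"]
        out = g.agg(mean_ce="mean", sd_ce="std", n="count").reset_index()
        out["sd_ce"] = out["sd_ce"].fillna(0.0)
        return out

    def summary_table(self) -> pd.DataFrame:
        """Subjects x classifiers x analyses mean-CE table (the per-subject
        summary layout, one cell per combination)."""
        agg = self.aggregate(["subject", "classifier", "analysis"])
        return agg.pivot_table(
            index="subject", columns=["analysis", "classifier"], values="mean_ce"
        )

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def triangle_table(
    pairs_upper: pd.DataFrame,
    pairs_lower: pd.DataFrame,
    upper_name: str,
    lower_name: str,
    percent: bool = True,
) -> str:
    """Render two pairwise-day results as one square table: upper triangle
    holds one classifier's pair CEs, lower triangle the other's."""
    days = sorted(
        set(pairs_upper["day_i"]) | set(pairs_upper["day_j"])
    )
    n = len(days)
    cell = {}
    for _, r in pairs_upper.iterrows():
        cell[(r["day_i"], r["day_j"])] = r["ce"]
    for _, r in pairs_lower.iterrows():
        cell[(r["day_j"], r["day_i"])] = r["ce"]
    scale = 100.0 if percent else 1.0
    width = 7
    lines = [
        f"upper triangle: {upper_name}; lower triangle: {lower_name}"
        + ("; cells are mean CE in %" if percent else ""),
        " " * 5 + "".join(f"D{d:<{width - 1}}" for d in days),
    ]
    for di in days:
        row = [f"D{di:<4}"]
        for dj in days:
            if di == dj:
                row.append(f"{'-':>{width - 2}}  ")
            else:
                v = cell.get((di, dj))
                row.append(
                    f"{v * scale:>{width - 2}.2f}  " if v is not None else " " * width
                )
        lines.append("".join(row))
    return "\n".join(lines)


def run_protocols(
    sessions: list[SessionData],
    classifiers: dict[str, callable],
    analyses: tuple[str, ...] = ANALYSES,
    base_seed: int = 0,
) -> EvalReport:
    """Run the selected protocol x classifier grid over one or more
    subjects' sessions and collect long-format records.

    ``classifiers`` maps a display name to a ``factory(seed) -> classifier``.
    """
    unknown = set(analyses) - set(ANALYSES)
    if unknown:
        raise ValidationError(f"unknown analyses {sorted(unknown)}; pick from {ANALYSES}")
    subjects: dict[str, list[SessionData]] = {}
    for s in sessions:
        subjects.setdefault(s.subject, []).append(s)

    rows = []

    def add(subject, analysis, clf_name, fold, ce):
        rows.append(
            {
                "subject": subject,
                "analysis": analysis,
                "classifier": clf_name,
                "fold": fold,
                "ce": float(ce),
            }
        )

    for subject, subj_sessions in sorted(subjects.items()):
        by_day: dict[int, list[SessionData]] = {}
        for s in subj_sessions:
            by_day.setdefault(s.day, []).append(s)
        for clf_name, factory in classifiers.items():
            if "within_session" in analyses:
                for s in subj_sessions:
                    df = within_session_cv(s, factory, base_seed)
                    for _, r in df.iterrows():
                        add(
                            subject,
                            "within_session",
                            clf_name,
                            f"day{s.day}_ses{s.session}_{r['fold']}",
                            r["ce"],
                        )
            if "between_sessions" in analyses:
                for d, ss in sorted(by_day.items()):
                    df = between_sessions_cv(ss, factory, base_seed)
                    for _, r in df.iterrows():
                        add(
                            subject,
                            "between_sessions",
                            clf_name,
                            f"day{d}_{r['fold']}",
                            r["ce"],
                        )
            if "pair_of_days" in analyses:
                df = pairwise_days_cv(subj_sessions, factory, base_seed)
                for _, r in df.iterrows():
                    add(
                        subject,
                        "pair_of_days",
                        clf_name,
                        f"days{int(r['day_i'])}-{int(r['day_j'])}",
                        r["ce"],
                    )
            if "leave_one_day_out" in analyses:
                df = leave_one_day_out_cv(subj_sessions, factory, base_seed)
                for _, r in df.iterrows():
                    add(subject, "leave_one_day_out", clf_name, r["fold"], r["ce"])
    return EvalReport(records=pd.DataFrame(rows))
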