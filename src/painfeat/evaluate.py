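"""Fixed classification and evaluation stage.

Every feature set — hand-crafted or learned — is judged by the same
classifier: a 100-tree random forest evaluated in leave-one-subject-out
(LOSO) cross-validation repeated five times with different seeds.  Tasks are
binary (baseline level vs. one pain level) built either from the objective
temperature labels or the subjective CoVAS labels.  Metrics follow the
standard confusion-matrix definitions

    accuracy  = (tp + tn) / (tp + tn + fp + fn)
    precision = tp / (tp + fp)        recall = tp / (tp + fn)
    F1        = 2 * precision * recall / (precision + recall)

with zero substituted for 0/0, and the macro F1 is the unweighted mean of
the per-class (one-vs-rest) F1 scores.  Method pairs are compared with a
paired two-sided t-test on subject-aligned accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

DEFAULT_RUNS = 5
DEFAULT_TREES = 100


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(y_true, y_pred, positive=1) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(tp=int(np.sum(pos_t & pos_p)),
                           fp=int(np.sum(~pos_t & pos_p)),
                           tn=int(np.sum(~pos_t & ~pos_p)),
                           fn=int(np.sum(pos_t & ~pos_p)))


def metrics(counts: ConfusionCounts) -> dict:
    if counts.total == 0:
        raise ValueError("empty confusion table")
    acc = (counts.tp + counts.tn) / counts.total
    prec = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def macro_f1(per_class_f1) -> float:
    per_class_f1 = np.asarray(per_class_f1, dtype=float)
    if per_class_f1.size == 0:
        raise ValueError("need at least one class F1")
    return float(per_class_f1.mean())


def binary_macro_f1(y_true, y_pred) -> float:
    """Macro F1 of a two-class problem: each class one-vs-rest, averaged."""
    f1s = [metrics(confusion_from_predictions(y_true, y_pred, positive=c))["f1"]
           for c in (0, 1)]
    return macro_f1(f1s)


class EmptyTaskError(ValueError):
    pass


def make_binary_task(features: pd.DataFrame, baseline: str, pain: str,
                     label_source: str = "temperature", balance: bool = True,
                     balance_seed: int = 0):
    """Select the two named levels from a feature table.

    Returns ``(X, y, subjects)`` with baseline coded 0, pain coded 1, and
    the original row order preserved.  With ``balance`` (default) the
    majority class is deterministically undersampled per subject so both
    classes contribute equally — this puts every task on the same 50%
    chance floor (windows preceding each stimulus outnumber any single
    stimulus level five to one otherwise).
    """
    col = {"temperature": "temp_label", "covas": "covas_label"}[label_source]
    labels = features[col]
    mask = labels.isin([baseline, pain])
    for level in (baseline, pain):
        if not (labels == level).any():
            raise EmptyTaskError(f"level {level!r} absent from the data")
    sub = features.loc[mask]
    if balance:
        rng = np.random.default_rng(balance_seed)
        keep = []
        for _, grp in sub.groupby("subject_id", sort=True):
            idx_b = grp.index[grp[col] == baseline].to_numpy()
            idx_p = grp.index[grp[col] == pain].to_numpy()
            n = min(idx_b.size, idx_p.size)
            for idx in (idx_b, idx_p):
                if idx.size > n:
                    idx = rng.choice(idx, size=n, replace=False)
                keep.append(idx)
        sub = sub.loc[np.sort(np.concatenate(keep))]
    y = (sub[col] == pain).to_numpy().astype(int)
    meta = ["subject_id", "temp_label", "covas_label", "covas_sum"]
    x = sub.drop(columns=[c for c in meta if c in sub.columns]).to_numpy(float)
    return x, y, sub["subject_id"].to_numpy()


@dataclass
class CVResult:
    """Per-(run, subject) LOSO metrics plus the paper-style aggregation:
    per-run mean/SD over subjects, averaged over runs."""

    task: str
    method: str
    table: pd.DataFrame  # columns: run, subject, accuracy, macro_f1

    def aggregate(self) -> dict:
        per_run = self.table.groupby("run").agg(
            acc_mean=("accuracy", "mean"), acc_sd=("accuracy", "std"),
            f1_mean=("macro_f1", "mean"), f1_sd=("macro_f1", "std"))
        per_run = per_run.fillna(0.0)
        return {"accuracy_mean": float(per_run["acc_mean"].mean()),
                "accuracy_sd": float(per_run["acc_sd"].mean()),
                "macro_f1_mean": float(per_run["f1_mean"].mean()),
                "macro_f1_sd": float(per_run["f1_sd"].mean())}

    def per_subject_accuracy(self) -> pd.Series:
        """Subject-aligned accuracies averaged over runs (t-test input)."""
        return self.table.groupby("subject")["accuracy"].mean().sort_index()


def loso_evaluate(x, y, subjects, n_runs: int = DEFAULT_RUNS,
                  n_trees: int = DEFAULT_TREES, base_seed: int = 0,
                  extractor_factory: Optional[Callable] = None,
                  task: str = "", method: str = "") -> CVResult:
    """Repeated leave-one-subject-out evaluation with a random forest.

    ``x`` is a feature matrix, or raw (n, T, S) segments when
    ``extractor_factory`` is given — the extractor is then re-fitted inside
    every fold on training subjects only, which keeps feature learning
    subject-independent.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    rows = []
    for run in range(1, n_runs + 1):
        seed = base_seed + run - 1
        for subject in uniq:
            test = subjects == subject
            train = ~test
            assert not np.any(train & test)
            x_train, x_test = x[train], x[test]
            if extractor_factory is not None:
                feature_fn = extractor_factory(x_train, y[train], seed)
                x_train = feature_fn(x[train])
                x_test = feature_fn(x[test])
            rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
            rf.fit(x_train, y[train])
            pred = rf.predict(x_test)
            counts = confusion_from_predictions(y[test], pred)
            rows.append({"run": run, "subject": subject,
                         "accuracy": metrics(counts)["accuracy"],
                         "macro_f1": binary_macro_f1(y[test], pred)})
    return CVResult(task=task, method=method, table=pd.DataFrame(rows))


def paired_method_test(acc_a, acc_b, alpha: float = 0.05) -> dict:
    """Two-sided paired t-test on subject-aligned accuracies."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("accuracy vectors must be subject-aligned")
    if a.size < 2:
        raise ValueError("need at least 2 subjects")
    diff = a - b
    mean = diff.mean()
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.isclose(mean, 0.0):
            return {"t": 0.0, "p": 1.0, "significant": False, "direction": 0}
        return {"t": np.inf * np.sign(mean), "p": 0.0, "significant": True,
                "direction": int(np.sign(mean))}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "significant": bool(p < alpha),
            "direction": int(np.sign(mean)) if mean != 0 else 0}


def comparison_table(results: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Render a methods × tasks table of ``mean±sd`` accuracies (in %), with
    superscripts marking methods each entry significantly improves on.

    ``results`` maps ``(task, method) -> CVResult``.
    """
    tasks = sorted({t for t, _ in results})
    methods = []
    for _, m in results:
        if m not in methods:
            methods.append(m)
    out = pd.DataFrame(index=methods, columns=tasks, dtype=object)
    for task in tasks:
        accs = {m: results[(task, m)].per_subject_accuracy()
                for m in methods if (task, m) in results}
        for m in methods:
            if (task, m) not in results:
                out.loc[m, task] = ""
                continue
            agg = results[(task, m)].aggregate()
            better_than = []
            for j, other in enumerate(methods, start=1):
                if other == m or other not in accs:
                    continue
                test = paired_method_test(accs[m], accs[other], alpha)
                if test["significant"] and test["direction"] > 0:
                    better_than.append(str(j))
            sup = f" ^{','.join(better_than)}" if better_than else ""
            out.loc[m, task] = (f"{100 * agg['accuracy_mean']:.2f}"
                                f"±{100 * agg['accuracy_sd']:.2f}{sup}")
    return out
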