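"""Stratified k-fold cross-validation harness and the evaluation metrics.

Each fold rebuilds the knowledge graph and (by default) re-estimates the
edge-weight table from the training patients only, diagnoses every held-out
patient, and accumulates one-vs-rest confusion counts per syndrome. The six
reported metrics are accuracy, precision, sensitivity, specificity, F1 and
rank-based one-vs-rest AUC, summarized as mean (SD) across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .estimators import SCORE_METHODS, NeighborVoteClassifier
from .ingest import PatientRecord
from .weighting import WeightTable, compute_weight_table

METRICS = ("accuracy", "precision", "sensitivity", "specificity", "f1", "auc")


def stratified_folds(
    records: Sequence[PatientRecord], n_folds: int = 5, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Partition patient ids into ``n_folds`` stratified (train, test)
    splits: per-class test counts differ by at most 1 across folds, test
    sets are disjoint and exhaustive, and the split is deterministic per
    seed."""
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    labels = [r.syndrome for r in records]
    if any(lab is None for lab in labels):
        raise ValueError("all records must be labeled for cross-validation")
    ids = np.array([r.patient_id for r in records])
    counts = pd.Series(labels).value_counts()
    too_small = counts[counts < n_folds]
    if len(too_small):
        raise ValueError(
            f"class(es) smaller than n_folds={n_folds}: "
            + ", ".join(f"{c} (n={n})" for c, n in too_small.items())
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        (list(ids[train_idx]), list(ids[test_idx]))
        for train_idx, test_idx in skf.split(np.zeros(len(ids)), labels)
    ]


@dataclass
class ConfusionCounts:
    """One-vs-rest integer counts for a single class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """accuracy=(TP+TN)/N, precision=TP/(TP+FP), sensitivity=TP/(TP+FN),
    specificity=TN/(TN+FP), F1=2PR/(P+R). Ratios with a zero denominator are
    reported as 0 and named in the ``undefined`` set."""
    for name in ("tp", "fp", "tn", "fn"):
        if getattr(counts, name) < 0:
            raise ValueError(f"negative count {name}={getattr(counts, name)}")
    undefined: set[str] = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    sensitivity = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    if precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        undefined.add("f1")
        f1 = 0.0
    return {
        "accuracy": ratio(counts.tp + counts.tn, counts.n, "accuracy"),
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        "f1": f1,
        "undefined": undefined,
    }


def one_vs_rest_auc(
    scores: np.ndarray,
    labels: Sequence[str],
    classes: Sequence[str],
) -> dict[str, float | None]:
    """Rank-based AUC per class (probability a positive outranks a negative,
    ties counted 1/2) from an (n_patients, n_classes) score matrix. Classes
    absent from ``labels`` — or covering all of them — get ``None``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    out: dict[str, float | None] = {}
    for j, c in enumerate(classes):
        pos = labels == c
        if pos.all() or not pos.any():
            out[c] = None
        else:
            out[c] = float(roc_auc_score(pos, scores[:, j]))
    return out


@dataclass
class CVConfig:
    n_folds: int = 5
    seed: int = 0
    k: int = 20
    alpha: float = 0.0
    mode: str = "candidate-syndrome"
    methods: tuple[str, ...] = SCORE_METHODS
    leakage_safe: bool = True
    knowledge_triples: tuple = ()


@dataclass
class CVReport:
    """Per-fold, per-syndrome metrics plus summaries.

    ``per_fold`` has one row per (method, fold, syndrome); ``summary``
    aggregates mean and SD across folds; ``overall_accuracy`` is the plain
    multiclass accuracy per fold and method.
    """

    per_fold: pd.DataFrame
    summary: pd.DataFrame
    overall_accuracy: pd.DataFrame
    config: CVConfig = field(default_factory=CVConfig)

    def mean(self, method: str, metric: str) -> float:
        rows = self.summary[(self.summary["method"] == method)]
        return float(rows[f"{metric}_mean"].mean())

    def render_table(self, metric: str) -> pd.DataFrame:
        """Methods × syndromes table of fold-mean values for one metric,
        with a final mean (SD) column."""
        rows = []
        for method in self.per_fold["method"].unique():
            sub = self.summary[self.summary["method"] == method]
            row = {"method": method}
            for _, r in sub.iterrows():
                row[r["syndrome"]] = round(r[f"{metric}_mean"], 3)
            vals = sub[f"{metric}_mean"]
            row["mean (SD)"] = f"{vals.mean():.3f} ({vals.std(ddof=1):.3f})"
            rows.append(row)
        return pd.DataFrame(rows)


def run_cv(records: Sequence[PatientRecord], config: CVConfig | None = None) -> CVReport:
    """Run the full stratified CV: per fold, fit each scoring method on the
    training patients (graph + weights), diagnose every test patient, and
    score one-vs-rest confusion counts and AUC per syndrome."""
    config = config or CVConfig()
    records = list(records)
    by_id = {r.patient_id: r for r in records}
    folds = stratified_folds(records, config.n_folds, config.seed)
    classes = sorted({r.syndrome for r in records})
    shared_table: WeightTable | None = None
    if not config.leakage_safe:
        shared_table = compute_weight_table(records, alpha=config.alpha)

    rows = []
    overall = []
    for fold_idx, (train_ids, test_ids) in enumerate(folds):
        train = [by_id[i] for i in train_ids]
        test = [by_id[i] for i in test_ids]
        queries = [PatientRecord(r.patient_id, r.features) for r in test]
        truth = np.array([r.syndrome for r in test])
        for method in config.methods:
            clf = NeighborVoteClassifier(
                score_method=method,
                k=config.k,
                alpha=config.alpha,
                mode=config.mode,
                knowledge_triples=config.knowledge_triples or None,
                weight_table=shared_table,
            )
            clf.fit(train)
            pred = clf.predict(queries)
            proba = clf.predict_proba(queries)
            aucs = one_vs_rest_auc(proba, truth, list(clf.classes_))
            overall.append(
                {
                    "method": method,
                    "fold": fold_idx,
                    "accuracy": float((pred == truth).mean()),
                }
            )
            for c in classes:
                counts = ConfusionCounts(
                    tp=int(((pred == c) & (truth == c)).sum()),
                    fp=int(((pred == c) & (truth != c)).sum()),
                    tn=int(((pred != c) & (truth != c)).sum()),
                    fn=int(((pred != c) & (truth == c)).sum()),
                )
                metrics = confusion_metrics(counts)
                j = list(clf.classes_).index(c)
                rows.append(
                    {
                        "method": method,
                        "fold": fold_idx,
                        "syndrome": c,
                        "tp": counts.tp,
                        "fp": counts.fp,
                        "tn": counts.tn,
                        "fn": counts.fn,
                        "accuracy": metrics["accuracy"],
                        "precision": metrics["precision"],
                        "sensitivity": metrics["sensitivity"],
                        "specificity": metrics["specificity"],
                        "f1": metrics["f1"],
                        "auc": aucs[c],
                    }
                )

    per_fold = pd.DataFrame(rows)
    agg = per_fold.groupby(["method", "syndrome"], sort=True)[list(METRICS)]
    summary = agg.agg(["mean", "std"])
    summary.columns = [f"{m}_{stat}" for m, stat in summary.columns]
    summary = summary.reset_index()
    return CVReport(
        per_fold=per_fold,
        summary=summary,
        overall_accuracy=pd.DataFrame(overall),
        config=config,
    )
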