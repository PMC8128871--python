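"""Confusion matrices, per-class precision/recall and class-mean accuracy.

Conventions, fixed package-wide: confusion-matrix rows are the true class
and columns the predicted class; per-class recall is ``TP / (TP + FN)`` (the
diagonal over its row sum) and precision ``TP / (TP + FP)`` (the diagonal
over its column sum), both reported as percentages rounded half-up to two
decimals; "class-mean" accuracy is the unweighted arithmetic mean of the
defined per-class values.  A class never predicted has undefined precision;
undefined cells are excluded from the class mean and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import PoolingScheme

logger = logging.getLogger(__name__)


def round2(value: float) -> float:
    """Round half-up to two decimals, matching printed report tables."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; ``counts[i, j]`` = records of true class i predicted j."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{k} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.classes), columns=list(self.classes)
        )


@dataclass(frozen=True)
class MetricsReport:
    """Per-class recall/precision in percent (2 dp) plus class means.

    Undefined cells (zero denominator) hold ``None`` and are excluded from
    the class means, recorded under ``undefined_policy = "exclude"``.
    """

    classes: tuple[str, ...]
    recall: dict = field(default_factory=dict)
    precision: dict = field(default_factory=dict)
    class_mean_recall: float | None = None
    class_mean_precision: float | None = None
    undefined_policy: str = "exclude"


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionMatrix:
    """Count (true, predicted) label pairs over a fixed class order."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"{len(true_labels)} true vs {len(predicted_labels)} predicted labels"
        )
    index = {c: i for i, c in enumerate(class_order)}
    k = len(index)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(
                f"label pair ({t!r}, {p!r}) outside class order {tuple(class_order)}"
            )
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(class_order))


def _per_class(cm: ConfusionMatrix) -> tuple[dict, dict, list, list]:
    diag = np.diag(cm.counts).astype(float)
    row = cm.counts.sum(axis=1).astype(float)
    col = cm.counts.sum(axis=0).astype(float)
    recall_raw, precision_raw = [], []
    recall, precision = {}, {}
    for i, c in enumerate(cm.classes):
        if row[i] > 0:
            r = 100.0 * diag[i] / row[i]
            recall[c] = round2(r)
            recall_raw.append(r)
        else:
            logger.warning("class %s has no test records; recall undefined", c)
            recall[c] = None
        if col[i] > 0:
            p = 100.0 * diag[i] / col[i]
            precision[c] = round2(p)
            precision_raw.append(p)
        else:
            logger.warning("class %s never predicted; precision undefined", c)
            precision[c] = None
    return recall, precision, recall_raw, precision_raw


def precision_recall(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class recall/precision and their unweighted class means.

    Class means are computed from the unrounded per-class values and rounded
    once at the end.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    recall, precision, recall_raw, precision_raw = _per_class(cm)
    return MetricsReport(
        classes=cm.classes,
        recall=recall,
        precision=precision,
        class_mean_recall=round2(np.mean(recall_raw)) if recall_raw else None,
        class_mean_precision=round2(np.mean(precision_raw)) if precision_raw else None,
    )


def class_mean(report: MetricsReport, metric: str) -> float:
    """Unweighted mean of the defined per-class values of one metric."""
    if metric not in ("recall", "precision"):
        raise ValueError(f"metric must be 'recall' or 'precision', got {metric!r}")
    value = (
        report.class_mean_recall if metric == "recall" else report.class_mean_precision
    )
    if value is None:
        raise ValueError(f"all per-class {metric} values are undefined")
    return value


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Micro accuracy: trace over total, in percent (2 dp)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return round2(100.0 * np.trace(cm.counts) / cm.total)


def pool_confusion_matrix(
    cm: ConfusionMatrix, scheme: PoolingScheme
) -> ConfusionMatrix:
    """Post-hoc diagnostic: sum rows/columns of pooled classes.

    Metrics from a matrix pooled this way describe relabelled predictions of
    an *unpooled* model; they are not equivalent to training with pooling and
    are labelled ``post-hoc`` in the metadata of any rendered report.
    """
    pooled_classes: list[str] = []
    for c in cm.classes:
        p = scheme.map_label(c)
        if p not in pooled_classes:
            pooled_classes.append(p)
    index = {c: i for i, c in enumerate(pooled_classes)}
    k = len(pooled_classes)
    counts = np.zeros((k, k), dtype=int)
    for i, ti in enumerate(cm.classes):
        for j, tj in enumerate(cm.classes):
            counts[index[scheme.map_label(ti)], index[scheme.map_label(tj)]] += cm.counts[i, j]
    return ConfusionMatrix(counts=counts, classes=tuple(pooled_classes))


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def report_frame(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Tabulate a model grid: a recall block then a precision block.

    One row per (metric block, model id); columns are the per-class values
    followed by the class mean, formatted at 2 dp with undefined cells empty.
    """
    if not reports:
        raise ValueError("no reports to render")
    classes = next(iter(reports.values())).classes
    rows = []
    for metric in ("recall", "precision"):
        for model_id, rep in reports.items():
            if rep.classes != classes:
                raise ValueError("reports mix different taxonomies")
            vals = getattr(rep, metric)
            mean = (
                rep.class_mean_recall if metric == "recall" else rep.class_mean_precision
            )
            rows.append(
                {
                    "metric": metric,
                    "model_id": model_id,
                    **{c: vals[c] for c in classes},
                    "class_mean": mean,
                }
            )
    return pd.DataFrame(rows)


def render_report(reports: dict[str, MetricsReport], path=None) -> str:
    """Render a model grid as a tab-delimited table (2 dp, lossless).

    Returns the text; additionally writes it to ``path`` when given.  The
    companion :func:`parse_report` reads the text back.
    """
    frame = report_frame(reports)
    def fmt(v):
        return "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.2f}"
    out = frame.copy()
    for c in out.columns[2:]:
        out[c] = out[c].map(fmt)
    text = out.to_csv(sep="\t", index=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def parse_report(text: str) -> dict[str, MetricsReport]:
    """Parse :func:`render_report` output back into reports (at 2 dp)."""
    frame = pd.read_csv(pd.io.common.StringIO(text), sep="\t")
    classes = tuple(c for c in frame.columns if c not in ("metric", "model_id", "class_mean"))
    reports: dict[str, MetricsReport] = {}
    for model_id in frame["model_id"].unique():
        sub = frame[frame["model_id"] == model_id]
        blocks = {}
        means = {}
        for metric in ("recall", "precision"):
            row = sub[sub["metric"] == metric].iloc[0]
            blocks[metric] = {
                c: None if pd.isna(row[c]) else float(row[c]) for c in classes
            }
            means[metric] = None if pd.isna(row["class_mean"]) else float(row["class_mean"])
        reports[str(model_id)] = MetricsReport(
            classes=classes,
            recall=blocks["recall"],
            precision=blocks["precision"],
            class_mean_recall=means["recall"],
            class_mean_precision=means["precision"],
        )
    return reports
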