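"""Confusion matrices and the imbalance-aware evaluation metric suite.

Erythrocyte morphology data is heavily imbalanced (most cells are normal,
circular discs), so plain accuracy overstates performance.  This module
implements the metrics used to evaluate crowd labels against expert ground
truth:

* per-class accuracy (recall) and overall accuracy;
* the SDS-score, a sickle-cell-disease diagnosis-support measure that
  forgives elongated/other confusions (both trigger specialist review) while
  penalizing any error involving the circular/normal class;
* two Class Balance Accuracy (CBA) variants: macro-averaged recall, which
  is the variant the study's tables report, and Mosley's original
  ``diag / max(row sum, column sum)`` form;
* the Matthews correlation coefficient, binary and Gorodkin's multiclass
  generalization;
* macro / weighted / micro F-measure;
* merging of the three classes to a binary circular-vs-deformed task.

Confusion matrices use rows = ground truth, columns = predicted, in the
fixed order (circular, elongated, other), or (circular, deformed) after
merging.  When consensus output is scored, cells with no consensus occupy a
dedicated trailing no-answer column: they stay in the denominator and never
count as correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .vote_model import (
    LABEL_ORDER,
    NO_ANSWER,
    CellLabel,
    ConsensusOutcome,
    NoAnswer,
    consensus_threshold,
)

THREE_CLASS_LABELS: Tuple[str, ...] = tuple(l.value for l in LABEL_ORDER)
BINARY_LABELS: Tuple[str, ...] = ("circular", "deformed")
NO_ANSWER_COLUMN = "NA"


class MetricError(ValueError):
    """Invalid input to a metric computation."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer confusion counts with fixed label bookkeeping.

    ``counts`` has shape (L, L) or (L, L+1) when a trailing no-answer column
    is present (``has_no_answer``).  Rows are ground truth, columns are
    predictions in the same label order.
    """

    counts: np.ndarray
    labels: Tuple[str, ...]
    has_no_answer: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        n = len(self.labels)
        expected = (n, n + 1 if self.has_no_answer else n)
        if counts.shape != expected:
            raise MetricError(f"counts shape {counts.shape} != expected {expected}")
        if (counts < 0).any():
            raise MetricError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def class_columns(self) -> np.ndarray:
        """The square L x L block of class-vs-class counts."""
        return self.counts[:, : self.n_classes]

    def diagonal(self) -> np.ndarray:
        return np.diag(self.class_columns())

    def no_answer_column(self) -> np.ndarray:
        if not self.has_no_answer:
            return np.zeros(self.n_classes, dtype=np.int64)
        return self.counts[:, -1]

    def permuted(self, order: Sequence[int]) -> "ConfusionMatrix":
        """Reorder classes simultaneously on rows and columns."""
        order = list(order)
        cols = order + ([self.n_classes] if self.has_no_answer else [])
        return ConfusionMatrix(
            self.counts[np.ix_(order, cols)],
            tuple(self.labels[i] for i in order),
            self.has_no_answer,
        )


def _label_name(label: Union[CellLabel, NoAnswer, str]) -> str:
    if isinstance(label, CellLabel):
        return label.value
    if isinstance(label, NoAnswer):
        return NO_ANSWER_COLUMN
    return str(label)


def build_confusion(
    truth: Mapping[str, Union[CellLabel, str]],
    pred: Mapping[str, Union[CellLabel, NoAnswer, str]],
    labels: Sequence[str] = THREE_CLASS_LABELS,
    include_no_answer: Optional[bool] = None,
) -> ConfusionMatrix:
    """Tally predictions against ground truth.

    Every predicted cell must have a ground-truth label; a missing one is an
    error, never silently skipped.  Only cells present in ``pred`` are
    scored.  ``include_no_answer`` defaults to whether any prediction is the
    no-answer sentinel.
    """
    labels = tuple(labels)
    idx = {name: i for i, name in enumerate(labels)}
    pred_names = {cell: _label_name(p) for cell, p in pred.items()}
    if include_no_answer is None:
        include_no_answer = any(n == NO_ANSWER_COLUMN for n in pred_names.values())
    n = len(labels)
    counts = np.zeros((n, n + 1 if include_no_answer else n), dtype=np.int64)
    for cell, pred_name in pred_names.items():
        if cell not in truth:
            raise MetricError(f"cell {cell!r} has a prediction but no ground truth")
        t = _label_name(truth[cell])
        if t not in idx:
            raise MetricError(f"ground-truth label {t!r} not in {labels}")
        if pred_name == NO_ANSWER_COLUMN:
            if not include_no_answer:
                raise MetricError(
                    f"cell {cell!r} has a no-answer prediction but "
                    "include_no_answer=False"
                )
            counts[idx[t], n] += 1
        else:
            if pred_name not in idx:
                raise MetricError(f"predicted label {pred_name!r} not in {labels}")
            counts[idx[t], idx[pred_name]] += 1
    return ConfusionMatrix(counts, labels, include_no_answer)


def per_class_accuracy(cm: ConfusionMatrix) -> Dict[str, Optional[float]]:
    """Recall per ground-truth class: diagonal / row sum.

    No-answer predictions are in the row sum, so they count as incorrect.
    A class with no ground-truth cells is reported as ``None`` (missing),
    not as zero.
    """
    rows = cm.row_sums()
    diag = cm.diagonal()
    return {
        name: (int(diag[i]) / int(rows[i]) if rows[i] > 0 else None)
        for i, name in enumerate(cm.labels)
    }


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise MetricError("empty confusion matrix")
    return float(cm.diagonal().sum() / cm.total)


def sds_score(cm: ConfusionMatrix) -> Optional[float]:
    """Sickle-cell-disease diagnosis-support score, ``N / (N + Ec)``.

    ``N`` counts classifications that keep the specialist's alarm correct:
    all true positives plus elongated<->other swaps (both mean "deformed,
    review the patient").  ``Ec`` counts the dangerous errors involving the
    circular (normal) class in either direction.  On a merged binary matrix
    the same quantity is ``trace / (trace + both off-diagonals)``.

    A no-answer on a circular cell counts in ``Ec`` (the cell would wrongly
    reach review); a no-answer on a deformed cell enters neither term.
    Returns ``None`` when the denominator is zero.
    """
    if cm.n_classes not in (2, 3) or "circular" not in cm.labels:
        raise MetricError(
            "SDS-score needs a 3-class or merged 2-class matrix with a "
            "'circular' class"
        )
    c = cm.class_columns()
    na = cm.no_answer_column()
    ci = cm.labels.index("circular")
    deformed = [i for i in range(cm.n_classes) if i != ci]
    n_good = int(np.trace(c))
    if len(deformed) == 2:  # elongated<->other swaps still flag the cell
        d1, d2 = deformed
        n_good += int(c[d1, d2] + c[d2, d1])
    e_circ = int(sum(c[ci, j] + c[j, ci] for j in deformed) + na[ci])
    denom = n_good + e_circ
    if denom == 0:
        return None
    return n_good / denom


def cba_macro_recall(cm: ConfusionMatrix) -> float:
    """Class-balance accuracy as the unweighted mean of per-class recalls.

    This is the variant that reproduces the study's reported CBA values.
    """
    rows = cm.row_sums()
    if (rows == 0).any():
        raise MetricError("every class needs at least one ground-truth cell")
    return float(np.mean(cm.diagonal() / rows))


def cba_mosley(cm: ConfusionMatrix) -> float:
    """Mosley's class balance accuracy: mean of diag / max(row sum, col sum)."""
    rows = cm.row_sums()
    cols = cm.class_columns().sum(axis=0)
    denom = np.maximum(rows, cols)
    if (denom == 0).any():
        raise MetricError("a class has neither ground-truth nor predicted cells")
    return float(np.mean(cm.diagonal() / denom))


def mcc_binary(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient for a clean 2x2 matrix.

    Returns 0 when any marginal is empty (the conventional limit).
    """
    if cm.n_classes != 2 or cm.has_no_answer:
        raise MetricError("mcc_binary needs a 2x2 matrix without a no-answer column")
    (tp, fn), (fp, tn) = cm.counts
    factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(f == 0 for f in factors):
        return 0.0
    num = float(tp) * float(tn) - float(fp) * float(fn)
    return num / float(np.sqrt(np.prod([float(f) for f in factors])))


def mcc_multiclass_gorodkin(cm: ConfusionMatrix) -> float:
    """Gorodkin's multiclass MCC.

    ``(c*s - sum t_k p_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))`` with
    ``c`` the trace, ``s`` the total, ``t``/``p`` the row/column marginals.
    A no-answer column is treated as a predicted-only category (a zero
    ground-truth row is appended), which reduces to the plain formula when
    the column is absent.  Returns 0 on a zero denominator.
    """
    m = cm.counts.astype(float)
    if cm.has_no_answer:
        m = np.vstack([m, np.zeros(m.shape[1])])
    c = float(np.trace(m))
    s = float(m.sum())
    t = m.sum(axis=1)
    p = m.sum(axis=0)
    num = c * s - float(t @ p)
    den = np.sqrt(s**2 - float(p @ p)) * np.sqrt(s**2 - float(t @ t))
    if den == 0:
        return 0.0
    return num / den


def f_measure(cm: ConfusionMatrix, variant: str = "macro") -> float:
    """F1 score combined across classes.

    ``macro`` averages per-class F1 equally, ``weighted`` weights by class
    support, ``micro`` pools counts (equal to overall accuracy when every
    cell receives exactly one class prediction).  Classes where precision
    and recall are both zero contribute 0.
    """
    rows = cm.row_sums().astype(float)
    cols = cm.class_columns().sum(axis=0).astype(float)
    diag = cm.diagonal().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(rows + cols > 0, 2 * diag / (rows + cols), 0.0)
    if variant == "macro":
        return float(np.mean(f1))
    if variant == "weighted":
        if rows.sum() == 0:
            raise MetricError("empty matrix")
        return float(np.sum(f1 * rows) / rows.sum())
    if variant == "micro":
        tp = diag.sum()
        denom = rows.sum() + cols.sum()
        return float(2 * tp / denom) if denom > 0 else 0.0
    raise MetricError(f"unknown F-measure variant {variant!r}")


def merge_to_binary(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Collapse (circular, elongated, other) to (circular, deformed).

    Elongated and other rows/columns are summed; a no-answer column is
    carried through unchanged.  Totals and the circular marginals are
    preserved.
    """
    if cm.n_classes != 3 or "circular" not in cm.labels:
        raise MetricError("merge_to_binary expects a 3-class matrix with 'circular'")
    c = cm.class_columns()
    ci = cm.labels.index("circular")
    d = [i for i in range(3) if i != ci]
    merged = np.array(
        [
            [c[ci, ci], c[ci, d[0]] + c[ci, d[1]]],
            [c[d[0], ci] + c[d[1], ci], c[np.ix_(d, d)].sum()],
        ],
        dtype=np.int64,
    )
    if cm.has_no_answer:
        na = cm.no_answer_column()
        merged = np.hstack(
            [merged, np.array([[na[ci]], [na[d[0]] + na[d[1]]]], dtype=np.int64)]
        )
    return ConfusionMatrix(merged, BINARY_LABELS, cm.has_no_answer)


def round_half_up(x: float, digits: int = 2) -> float:
    """Round half away from zero to ``digits`` decimals (table convention)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricReport:
    """All metrics for one evaluation stratum."""

    stratum: str
    n_cells: int
    labels: Tuple[str, ...]
    empty: bool = False
    per_class_accuracy: Dict[str, Optional[float]] = field(default_factory=dict)
    overall_accuracy: Optional[float] = None
    sds_score: Optional[float] = None
    cba: Optional[float] = None
    mcc: Optional[float] = None
    f_measure: Optional[float] = None
    f_variant: str = "macro"

    def to_dict(self) -> Dict[str, object]:
        rec: Dict[str, object] = {
            "stratum": self.stratum,
            "n_cells": self.n_cells,
            "empty": self.empty,
            "overall_accuracy": self.overall_accuracy,
            "sds_score": self.sds_score,
            "cba": self.cba,
            "mcc": self.mcc,
            "f_measure": self.f_measure,
            "f_variant": self.f_variant,
        }
        for name in self.labels:
            rec[f"accuracy_{name}"] = self.per_class_accuracy.get(name)
        return rec


_STRATA = ("aggregated", "consensus", "5-agree", "4-agree", "3-agree")


def _select_outcomes(
    outcomes: Iterable[ConsensusOutcome], stratum: str, k: int
) -> Dict[str, Union[CellLabel, NoAnswer]]:
    threshold = consensus_threshold(k)
    preds: Dict[str, Union[CellLabel, NoAnswer]] = {}
    for out in outcomes:
        if stratum == "aggregated":
            keep = True
        elif stratum == "consensus":
            keep = out.label is not NO_ANSWER
        elif stratum.endswith("-agree"):
            level = int(stratum.split("-")[0])
            if not (threshold <= level <= k):
                raise MetricError(f"stratum {stratum!r} unattainable with k={k}")
            keep = out.agreement == level
        else:
            raise MetricError(f"unknown stratum {stratum!r}; expected one of {_STRATA}")
        if keep:
            preds[out.cell_id] = out.label
    return preds


def consensus_report(
    truth: Mapping[str, CellLabel],
    outcomes: Iterable[ConsensusOutcome],
    stratum: str = "aggregated",
    merge: bool = False,
    k: int = 5,
    f_variant: str = "macro",
) -> MetricReport:
    """Score consensus outcomes against ground truth for one stratum.

    Strata: ``"aggregated"`` keeps every cell (no-answer cells stay in the
    denominator as errors); ``"consensus"`` keeps cells that reached a
    consensus; ``"<n>-agree"`` keeps cells whose winning label got exactly
    ``n`` votes.  With ``merge=True`` the binary circular-vs-deformed task
    is scored instead.
    """
    preds = _select_outcomes(outcomes, stratum, k)
    labels = BINARY_LABELS if merge else THREE_CLASS_LABELS
    if not preds:
        return MetricReport(stratum=stratum, n_cells=0, labels=labels, empty=True)
    cm = build_confusion(truth, preds, labels=THREE_CLASS_LABELS)
    if merge:
        cm = merge_to_binary(cm)
    if cm.n_classes == 2 and not cm.has_no_answer:
        mcc = mcc_binary(cm)
    else:
        mcc = mcc_multiclass_gorodkin(cm)
    return MetricReport(
        stratum=stratum,
        n_cells=len(preds),
        labels=labels,
        per_class_accuracy=per_class_accuracy(cm),
        overall_accuracy=overall_accuracy(cm),
        sds_score=sds_score(cm),
        cba=(cba_macro_recall(cm) if (cm.row_sums() > 0).all() else None),
        mcc=mcc,
        f_measure=f_measure(cm, f_variant),
        f_variant=f_variant,
    )


@dataclass(frozen=True)
class VolumeRegression:
    """OLS fit of worker accuracy on classification volume."""

    slope: float
    intercept: float
    stderr: float
    pvalue: float
    rvalue: float


def worker_volume_regression(
    pairs: Sequence[Tuple[float, float]]
) -> VolumeRegression:
    """Regress per-worker accuracy on the number of cells each classified.

    A slope indistinguishable from zero means more prolific workers are no
    more (or less) accurate — classification quality is independent of
    volume.  Requires at least two workers with distinct volumes.
    """
    if len(pairs) < 2:
        raise MetricError("need at least two workers")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise MetricError("all workers classified the same number of cells")
    fit = stats.linregress(x, y)
    return VolumeRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr=float(fit.stderr),
        pvalue=float(fit.pvalue),
        rvalue=float(fit.rvalue),
    )
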