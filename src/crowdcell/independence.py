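"""Binomial independence model of consensus accuracy.

If the ``k`` workers voting on a cell of some class are independent and each
is correct with probability ``alpha`` (the class's average individual
accuracy), the consensus is correct whenever at least ``floor(k/2) + 1`` of
them vote correctly.  The predicted consensus accuracy is then the binomial
tail

    ``Acc_est = sum_{j=t}^{k} C(k, j) alpha^j (1 - alpha)^(k - j)``,

with ``t = floor(k/2) + 1``; for the default ``k = 5`` this is
``alpha^5 + 5 alpha^4 (1-alpha) + 10 alpha^3 (1-alpha)^2``.  The model
ignores that fewer than ``t`` correct votes could still fail to elect a
single wrong label (a 2-2-1 split), so it is an idealization, not a bound.

Comparing this estimate against the consensus accuracy actually observed
diagnoses the independence assumption: when workers share failure modes
(hard cells fool everyone), observed accuracy falls below the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping

from scipy import stats

from .metrics import ConfusionMatrix, consensus_report
from .vote_model import CellLabel, ConsensusOutcome, consensus_threshold


class IndependenceModelError(ValueError):
    pass


def estimate_consensus_accuracy(alpha: float, k: int = 5) -> float:
    """Predicted consensus accuracy for a class with individual accuracy alpha.

    ``P(X >= floor(k/2)+1)`` for ``X ~ Binomial(k, alpha)``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise IndependenceModelError(f"alpha must be in [0, 1], got {alpha}")
    if k < 3 or k % 2 == 0:
        raise IndependenceModelError(f"k must be odd and >= 3, got {k}")
    return float(stats.binom.sf(consensus_threshold(k) - 1, k, alpha))


@dataclass(frozen=True)
class IndependencePrediction:
    """Estimated vs. observed consensus accuracy for one class."""

    label: str
    alpha: float
    acc_estimated: float
    acc_observed: float
    gap: float  # estimated - observed; positive means correlated errors


def compare_estimate_vs_observed(
    cm_individual: ConfusionMatrix,
    outcomes: Iterable[ConsensusOutcome],
    truth: Mapping[str, CellLabel],
    k: int = 5,
) -> List[IndependencePrediction]:
    """Per-class independence-model prediction against observed consensus.

    ``alpha`` per class comes from the individual-vote confusion matrix
    (diagonal over row sum); the observed accuracy is the consensus accuracy
    over all cells with no-answer counted as incorrect.  The individual
    matrix must tally exactly ``k`` votes for each cell in ``truth``.
    """
    outcomes = list(outcomes)
    outcome_cells = {o.cell_id for o in outcomes}
    if outcome_cells != set(truth):
        raise IndependenceModelError(
            "outcomes and ground truth cover different cell sets"
        )
    class_cells: Dict[str, int] = {name: 0 for name in cm_individual.labels}
    for label in truth.values():
        class_cells[label.value] += 1
    rows = cm_individual.row_sums()
    for i, name in enumerate(cm_individual.labels):
        if int(rows[i]) != k * class_cells[name]:
            raise IndependenceModelError(
                f"individual matrix row {name!r} has {int(rows[i])} votes, "
                f"expected {k} x {class_cells[name]} cells"
            )
    observed = consensus_report(truth, outcomes, stratum="aggregated", k=k)
    preds = []
    diag = cm_individual.diagonal()
    for i, name in enumerate(cm_individual.labels):
        if rows[i] == 0:  # class absent from this cell set
            continue
        alpha = float(diag[i] / rows[i])
        est = estimate_consensus_accuracy(alpha, k)
        obs = observed.per_class_accuracy[name]
        if obs is None:
            raise IndependenceModelError(f"no observed accuracy for class {name!r}")
        preds.append(
            IndependencePrediction(
                label=name,
                alpha=alpha,
                acc_estimated=est,
                acc_observed=obs,
                gap=est - obs,
            )
        )
    return preds
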