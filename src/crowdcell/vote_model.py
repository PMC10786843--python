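"""Vote data model and plurality-consensus aggregation.

Each blood-smear cell image is labeled independently by ``k`` crowd workers
(``k = 5`` in the study regime this package models), each assigning one of
three morphology classes: *circular* (normal erythrocyte), *elongated*
(sickle-shaped), or *other* (any other deformation).  A cell's label is
decided by plurality: if the most-voted class reaches a strict majority
(``floor(k/2) + 1``, i.e. 3 of 5), that class is the consensus; otherwise the
cell is left unanswered.  For ``k = 5`` the only vote configuration that
fails to produce an answer is the 2-2-1 split.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Tuple, Union


class VoteModelError(ValueError):
    """Base class for vote-model validation errors."""


class LabelParseError(VoteModelError):
    """An input string is not a recognized morphology label."""


class PanelSizeError(VoteModelError):
    """A vote panel does not have the expected number of votes."""


class DuplicateCellError(VoteModelError):
    """The same cell appears more than once where cells must be distinct."""


class DuplicateVoteError(VoteModelError):
    """The same (cell, worker) pair cast more than one vote."""


class CellLabel(Enum):
    """Erythrocyte morphology class assigned by an annotator."""

    CIRCULAR = "circular"
    ELONGATED = "elongated"
    OTHER = "other"

    @classmethod
    def parse(cls, text: object) -> "CellLabel":
        """Parse a label case-insensitively; anything unrecognized is an error.

        Silent coercion of unknown strings would corrupt downstream confusion
        counts, so this never falls back to a default.
        """
        try:
            return cls(str(text).strip().lower())
        except ValueError:
            raise LabelParseError(f"unknown cell label: {text!r}") from None


#: Fixed serialization order for the three classes.
LABEL_ORDER: Tuple[CellLabel, ...] = (
    CellLabel.CIRCULAR,
    CellLabel.ELONGATED,
    CellLabel.OTHER,
)


class NoAnswer(Enum):
    """Sentinel for a panel that produced no consensus."""

    NA = "NA"


NO_ANSWER = NoAnswer.NA

ConsensusLabel = Union[CellLabel, NoAnswer]


@dataclass(frozen=True)
class Vote:
    """A single worker's label for a single cell."""

    cell_id: str
    worker_id: str
    label: CellLabel


@dataclass(frozen=True)
class VotePanel:
    """The complete set of votes cast on one cell.

    The panel size ``k`` must be odd and at least 3 so that a strict-majority
    plurality is well defined.
    """

    cell_id: str
    votes: Tuple[CellLabel, ...]

    def __post_init__(self) -> None:
        if len(self.votes) < 3 or len(self.votes) % 2 == 0:
            raise PanelSizeError(
                f"panel for cell {self.cell_id!r} has {len(self.votes)} votes; "
                "panel size must be odd and >= 3"
            )
        for v in self.votes:
            if not isinstance(v, CellLabel):
                raise LabelParseError(f"invalid vote in panel {self.cell_id!r}: {v!r}")

    @property
    def k(self) -> int:
        return len(self.votes)

    @classmethod
    def from_labels(cls, cell_id: str, labels: Iterable[object]) -> "VotePanel":
        """Build a panel from labels given as strings or :class:`CellLabel`."""
        parsed = tuple(
            v if isinstance(v, CellLabel) else CellLabel.parse(v) for v in labels
        )
        return cls(cell_id=cell_id, votes=parsed)


@dataclass(frozen=True)
class ConsensusOutcome:
    """Aggregated result for one cell.

    ``agreement`` is the vote count of the winning label (0 when no answer);
    ``configuration`` is the sorted multiset of vote counts, e.g. ``"3-1-1"``.
    """

    cell_id: str
    label: ConsensusLabel
    agreement: int
    configuration: str


def consensus_threshold(k: int) -> int:
    """Minimum plurality count required for a consensus: floor(k/2) + 1."""
    return k // 2 + 1


def classify_configuration(panel: VotePanel) -> str:
    """Signature of the panel's vote-count multiset, e.g. ``"3-2"``.

    Counts are sorted in non-increasing order and joined by dashes; zero
    counts are omitted.  For k = 5 the possible signatures are
    ``5, 4-1, 3-2, 3-1-1, 2-2-1``.
    """
    counts = sorted(Counter(panel.votes).values(), reverse=True)
    return "-".join(str(c) for c in counts)


def aggregate_votes(panel: VotePanel, k: int | None = None) -> ConsensusOutcome:
    """Aggregate one panel by strict-majority plurality.

    Returns the plurality label when its count reaches
    ``consensus_threshold(k)``; otherwise a no-answer outcome with
    agreement 0.  The winner is unique whenever the threshold is reached,
    since the threshold is a strict majority.

    Parameters
    ----------
    panel:
        The cell's votes.
    k:
        Expected panel size.  When given, a panel of any other size is
        rejected; when omitted the panel's own size is used.
    """
    if k is not None and panel.k != k:
        raise PanelSizeError(
            f"panel for cell {panel.cell_id!r} has {panel.k} votes, expected {k}"
        )
    counts = Counter(panel.votes)
    top_label, top_count = counts.most_common(1)[0]
    config = classify_configuration(panel)
    if top_count >= consensus_threshold(panel.k):
        return ConsensusOutcome(panel.cell_id, top_label, top_count, config)
    return ConsensusOutcome(panel.cell_id, NO_ANSWER, 0, config)


def panels_from_votes(votes: Iterable[Vote], k: int = 5) -> List[VotePanel]:
    """Group a flat vote table into per-cell panels of exactly ``k`` votes.

    Votes keep their input order within a panel.  Duplicate (cell, worker)
    pairs and cells with a vote count other than ``k`` are errors.
    """
    by_cell: Dict[str, List[Vote]] = {}
    seen: set = set()
    dups: List[Tuple[str, str]] = []
    for v in votes:
        key = (v.cell_id, v.worker_id)
        if key in seen:
            dups.append(key)
        seen.add(key)
        by_cell.setdefault(v.cell_id, []).append(v)
    if dups:
        raise DuplicateVoteError(f"duplicate (cell_id, worker_id) votes: {dups}")
    panels = []
    for cell_id, cell_votes in by_cell.items():
        if len(cell_votes) != k:
            raise PanelSizeError(
                f"cell {cell_id!r} has {len(cell_votes)} votes, expected {k}"
            )
        panels.append(VotePanel(cell_id, tuple(v.label for v in cell_votes)))
    return panels


def stratify_by_agreement(
    outcomes: Iterable[ConsensusOutcome], k: int = 5
) -> Dict[Union[int, NoAnswer], List[str]]:
    """Partition cell ids by agreement level.

    Keys are every attainable agreement level (``threshold .. k``) plus
    :data:`NO_ANSWER`; each cell lands in exactly one stratum, so stratum
    sizes sum to the number of cells.
    """
    strata: Dict[Union[int, NoAnswer], List[str]] = {
        level: [] for level in range(k, consensus_threshold(k) - 1, -1)
    }
    strata[NO_ANSWER] = []
    seen: set = set()
    for out in outcomes:
        if out.cell_id in seen:
            raise DuplicateCellError(f"duplicate cell_id in outcomes: {out.cell_id!r}")
        seen.add(out.cell_id)
        key: Union[int, NoAnswer]
        key = NO_ANSWER if out.label is NO_ANSWER else out.agreement
        if key not in strata:
            raise VoteModelError(
                f"agreement {out.agreement} for cell {out.cell_id!r} "
                f"is not attainable with k={k}"
            )
        strata[key].append(out.cell_id)
    return strata
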