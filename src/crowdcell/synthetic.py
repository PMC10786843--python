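"""Synthetic smear scenes and simulated crowd-worker votes.

Two generators make every stage of the pipeline testable without the
original image set or the crowdsourcing platform:

* :func:`generate_scene` renders smear-like grayscale images — dark cells
  on a light background with additive Gaussian noise — with known per-cell
  masks and morphology labels.  Circular cells are discs, elongated
  (sickle) cells are high-aspect (>= 3:1) rotated ellipses, and "other"
  deformations are irregular star-shaped blobs.
* :func:`simulate_votes` draws worker votes from per-worker 3x3 response
  matrices (row = true class, column = emitted label; the diagonal is the
  per-class accuracy alpha).  An optional shared per-cell difficulty latent
  degrades every worker's accuracy on "hard" cells, inducing the positive
  error correlation that makes observed consensus accuracy fall short of
  the independence-model estimate.

Defaults are anchored to the study regime this package models: the class
mix and the worker response rows are taken from the published individual
vote counts (:func:`reference_tables`), so the default simulation
reproduces the observed confusion structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import draw

from .metrics import THREE_CLASS_LABELS, ConfusionMatrix
from .vote_model import LABEL_ORDER, CellLabel


class SyntheticDataError(ValueError):
    pass


class PlacementError(SyntheticDataError):
    """Could not place the requested number of non-overlapping cells."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"placed only {achieved} of {requested} cells without overlap"
        )
        self.requested = requested
        self.achieved = achieved


# ---------------------------------------------------------------------------
# Published reference counts (packaged fixtures)
# ---------------------------------------------------------------------------

#: Individual-vote confusion counts: 848 cells x 5 votes, rows = ground
#: truth (circular, elongated, other), columns = emitted label.
INDIVIDUAL_COUNTS = (
    (2676, 58, 351),
    (48, 614, 243),
    (69, 28, 153),
)

#: Consensus (correct, total) pairs per class, no-answer counted in totals.
CONSENSUS_PAIRS = {
    "circular": (566, 617),
    "elongated": (128, 181),
    "other": (32, 50),
}

#: Number of cells by agreement level; "NA" = no consensus (2-2-1 splits).
STRATUM_COUNTS = {5: 463, 4: 226, 3: 135, "NA": 24}


@dataclass(frozen=True)
class ReferenceTables:
    """Packaged summary tables of the crowdsourced labeling experiment."""

    individual: ConfusionMatrix
    merged: ConfusionMatrix
    consensus_pairs: Dict[str, Tuple[int, int]]
    stratum_counts: Dict[object, int]
    n_cells: int
    k: int


def reference_tables() -> ReferenceTables:
    """The experiment's individual and consensus confusion counts.

    848 expert-labeled cells, each voted on by 5 workers.  Returned as a
    3-class individual-vote matrix, its circular-vs-deformed merge, the
    per-class consensus (correct, total) pairs, and the agreement-stratum
    sizes.  These serve as packaged inputs for metric and model checks.
    """
    individual = ConfusionMatrix(
        np.array(INDIVIDUAL_COUNTS, dtype=np.int64), THREE_CLASS_LABELS
    )
    from .metrics import merge_to_binary

    return ReferenceTables(
        individual=individual,
        merged=merge_to_binary(individual),
        consensus_pairs=dict(CONSENSUS_PAIRS),
        stratum_counts=dict(STRATUM_COUNTS),
        n_cells=sum(n for n in STRATUM_COUNTS.values()),
        k=5,
    )


#: Default class mix: the experiment's cell counts (617, 181, 50) / 848.
DEFAULT_CLASS_MIX = tuple(
    sum(row) / 5 / 848 for row in INDIVIDUAL_COUNTS
)


def reference_response_matrix() -> np.ndarray:
    """Row-normalized individual-vote counts: the average worker's profile."""
    m = np.array(INDIVIDUAL_COUNTS, dtype=float)
    return m / m.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Worker vote simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkerProfile:
    """Per-class response distribution of one (real or simulated) worker.

    ``response_matrix[i, j]`` is the probability that the worker emits label
    ``j`` on a cell whose true class is ``i``; rows must sum to 1 and the
    diagonal holds the per-class accuracies.
    """

    worker_id: str
    response_matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.response_matrix, dtype=float)
        object.__setattr__(self, "response_matrix", m)
        if m.shape != (3, 3) or (m < 0).any():
            raise SyntheticDataError("response matrix must be 3x3 and non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise SyntheticDataError("response matrix rows must sum to 1")


@dataclass(frozen=True)
class DifficultyModel:
    """Shared per-cell difficulty latent producing correlated worker errors.

    A fraction ``pi_hard`` of cells are "hard"; on those, every worker's
    diagonal accuracy is multiplied by ``hard_penalty`` and the freed
    probability mass is redistributed over the off-diagonal labels in
    proportion to the worker's usual error split.  Because the latent is
    drawn once per cell and shared by all workers, errors become positively
    correlated across workers — the mechanism that drives observed
    consensus accuracy below the independence-model estimate.
    """

    pi_hard: float = 0.3
    hard_penalty: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_hard <= 1.0 or not 0.0 <= self.hard_penalty <= 1.0:
            raise SyntheticDataError("pi_hard and hard_penalty must be in [0, 1]")


def _harden_row(row: np.ndarray, true_idx: int, penalty: float) -> np.ndarray:
    """Scale the diagonal entry by ``penalty``; rescale errors to fill row."""
    row = np.asarray(row, dtype=float)
    out = row.copy()
    diag = row[true_idx]
    out[true_idx] = diag * penalty
    err = 1.0 - diag
    if err > 0:
        out_scale = (1.0 - out[true_idx]) / err
        for j in range(len(row)):
            if j != true_idx:
                out[j] = row[j] * out_scale
    else:
        # perfectly accurate row: spread the freed mass uniformly
        spread = (1.0 - out[true_idx]) / (len(row) - 1)
        for j in range(len(row)):
            if j != true_idx:
                out[j] = spread
    return out


def make_workers(
    k: int = 5, response_matrix: Optional[np.ndarray] = None
) -> List[WorkerProfile]:
    """``k`` identical workers; default profile is the experiment's average."""
    m = (
        reference_response_matrix()
        if response_matrix is None
        else np.asarray(response_matrix, dtype=float)
    )
    return [WorkerProfile(f"w{i + 1}", m) for i in range(k)]


def simulate_votes(
    truth: Mapping[str, CellLabel],
    workers: Sequence[WorkerProfile],
    difficulty: Optional[DifficultyModel] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Draw one vote per (cell, worker) from the workers' response rows.

    Without a difficulty model votes are conditionally independent given
    the true class.  With one, a hard/easy latent is drawn once per cell
    and shared by all workers.  Deterministic given ``seed``.  Returns a
    tidy table with columns ``cell_id, worker_id, label``.
    """
    if not truth:
        raise SyntheticDataError("truth table is empty")
    if not workers:
        raise SyntheticDataError("need at least one worker profile")
    rng = np.random.default_rng(seed)
    label_values = np.array([l.value for l in LABEL_ORDER])
    label_index = {l: i for i, l in enumerate(LABEL_ORDER)}
    cell_ids = list(truth.keys())
    true_idx = np.array([label_index[truth[c]] for c in cell_ids])
    n = len(cell_ids)
    hard = (
        rng.random(n) < difficulty.pi_hard
        if difficulty is not None
        else np.zeros(n, dtype=bool)
    )
    # vectorized draws, grouped by (worker, true class, difficulty)
    emitted = np.empty((n, len(workers)), dtype=np.int64)
    for wi, w in enumerate(workers):
        for ti in range(3):
            for is_hard in (False, True):
                sel = np.nonzero((true_idx == ti) & (hard == is_hard))[0]
                if sel.size == 0:
                    continue
                row = w.response_matrix[ti]
                if is_hard:
                    row = _harden_row(row, ti, difficulty.hard_penalty)
                emitted[sel, wi] = rng.choice(3, size=sel.size, p=row)
    records = {
        "cell_id": np.repeat(cell_ids, len(workers)),
        "worker_id": np.tile([w.worker_id for w in workers], n),
        "label": label_values[emitted.ravel()],
    }
    return pd.DataFrame(records)


def sample_truth(
    n_cells: int,
    class_mix: Sequence[float] = DEFAULT_CLASS_MIX,
    seed: Optional[int] = None,
) -> Dict[str, CellLabel]:
    """Random ground-truth labels with the given class mix."""
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
        raise SyntheticDataError("class_mix must be a distribution over 3 classes")
    rng = np.random.default_rng(seed)
    draws = rng.choice(3, size=n_cells, p=mix)
    return {f"cell_{i:05d}": LABEL_ORDER[j] for i, j in enumerate(draws)}


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneCell:
    cell_id: str
    label: CellLabel
    mask: np.ndarray


@dataclass
class SyntheticScene:
    """A rendered smear-like image with per-cell ground truth."""

    image: np.ndarray
    cells: List[SceneCell]
    noise_sd: float
    seed: Optional[int]

    @property
    def truth(self) -> Dict[str, CellLabel]:
        return {c.cell_id: c.label for c in self.cells}


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = draw.disk(center, radius, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _ellipse_mask(shape, center, a, b, theta) -> np.ndarray:
    rr, cc = draw.ellipse(center[0], center[1], a, b, shape=shape, rotation=theta)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _blob_mask(shape, center, radius, rng) -> np.ndarray:
    # star-like polygon: radial profile with random low-order harmonics
    n_theta = 72
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    r = np.full(n_theta, float(radius))
    for harmonic in rng.integers(2, 7, size=3):
        r += 0.18 * radius * np.sin(harmonic * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.35 * radius, 1.55 * radius)
    rr, cc = draw.polygon(
        center[0] + r * np.sin(theta), center[1] + r * np.cos(theta), shape=shape
    )
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def generate_scene(
    n_cells: int,
    class_mix: Sequence[float] = DEFAULT_CLASS_MIX,
    image_size: Tuple[int, int] = (256, 256),
    noise_sd: float = 0.02,
    seed: Optional[int] = None,
    background: float = 0.88,
    cell_intensity: float = 0.25,
    radius_range: Tuple[float, float] = (7.0, 11.0),
    margin: float = 3.0,
    max_tries: int = 200,
) -> SyntheticScene:
    """Render a smear-like image with ``n_cells`` non-overlapping cells.

    Cells are placed by rejection sampling on their bounding radii; if a
    cell cannot be placed within ``max_tries`` attempts a
    :class:`PlacementError` reporting the achieved count is raised.
    Deterministic given ``seed``.
    """
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
        raise SyntheticDataError("class_mix must be a distribution over 3 classes")
    if n_cells < 0:
        raise SyntheticDataError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in image_size)
    labels = [LABEL_ORDER[j] for j in rng.choice(3, size=n_cells, p=mix)]

    placed: List[Tuple[float, float, float]] = []  # (row, col, bounding radius)
    cells: List[SceneCell] = []
    image = np.full(shape, background, dtype=float)
    for i, label in enumerate(labels):
        r = rng.uniform(*radius_range)
        if label is CellLabel.CIRCULAR:
            bound = r
        elif label is CellLabel.ELONGATED:
            bound = 1.8 * r  # semi-major axis of the sickle ellipse
        else:
            bound = 1.55 * r
        mask = None
        for _ in range(max_tries):
            row = rng.uniform(bound + 1, shape[0] - bound - 1)
            col = rng.uniform(bound + 1, shape[1] - bound - 1)
            if all(
                (row - pr) ** 2 + (col - pc) ** 2 >= (bound + pb + margin) ** 2
                for pr, pc, pb in placed
            ):
                if label is CellLabel.CIRCULAR:
                    mask = _disc_mask(shape, (row, col), r)
                elif label is CellLabel.ELONGATED:
                    aspect = rng.uniform(3.0, 3.8)
                    a = 1.8 * r
                    mask = _ellipse_mask(
                        shape, (row, col), a, a / aspect, rng.uniform(0, np.pi)
                    )
                else:
                    mask = _blob_mask(shape, (row, col), r, rng)
                break
        if mask is None or not mask.any():
            raise PlacementError(requested=n_cells, achieved=len(cells))
        placed.append((row, col, bound))
        image[mask] = np.clip(cell_intensity + rng.normal(0.0, 0.02), 0.05, 0.6)
        cells.append(SceneCell(cell_id=f"cell_{i:04d}", label=label, mask=mask))
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=shape)
    image = np.clip(image, 0.0, 1.0)
    return SyntheticScene(image=image, cells=cells, noise_sd=noise_sd, seed=seed)
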