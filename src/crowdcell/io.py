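"""CSV readers/writers, pipeline configuration, and the end-to-end run.

File conventions: comma-separated, UTF-8, LF line endings, header row
mandatory.  Fractions are serialized both at full precision and rounded to
4 decimals.  Every output file is written to a temporary file and renamed
into place, so a failed run leaves no partial outputs.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import metrics, synthetic, vote_model
from .metrics import (
    ConfusionMatrix,
    MetricReport,
    build_confusion,
    consensus_report,
    merge_to_binary,
)
from .vote_model import (
    NO_ANSWER,
    CellLabel,
    ConsensusOutcome,
    DuplicateCellError,
    DuplicateVoteError,
    Vote,
    aggregate_votes,
    panels_from_votes,
)

logger = logging.getLogger("crowdcell")


class IOFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Atomic writes
# ---------------------------------------------------------------------------


def _atomic_write_text(path: Union[str, Path], text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_df(path: Union[str, Path], df: pd.DataFrame) -> None:
    _atomic_write_text(path, df.to_csv(index=False, lineterminator="\n"))


# ---------------------------------------------------------------------------
# Vote / truth tables
# ---------------------------------------------------------------------------


def read_votes(path: Union[str, Path]) -> List[Vote]:
    """Read a vote table (``cell_id,worker_id,label``) with validation.

    Unknown labels are an error naming the offending row; duplicate
    (cell, worker) pairs are an error listing the offenders.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["cell_id", "worker_id", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IOFormatError(f"{path}: missing column(s) {missing}")
    votes = []
    for row in df.itertuples(index=True):
        try:
            label = CellLabel.parse(row.label)
        except vote_model.LabelParseError as exc:
            raise IOFormatError(f"{path}: row {row.Index + 2}: {exc}") from None
        votes.append(Vote(str(row.cell_id), str(row.worker_id), label))
    dup = df.duplicated(subset=["cell_id", "worker_id"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["cell_id", "worker_id"]].values.tolist()
        raise DuplicateVoteError(f"{path}: duplicate votes: {offenders}")
    return votes


def write_votes(path: Union[str, Path], votes: Sequence[Vote]) -> None:
    df = pd.DataFrame(
        [(v.cell_id, v.worker_id, v.label.value) for v in votes],
        columns=["cell_id", "worker_id", "label"],
    )
    _atomic_write_df(path, df)


def read_truth(path: Union[str, Path]) -> Dict[str, CellLabel]:
    """Read a ground-truth table (``cell_id,label``); cell ids must be unique."""
    df = pd.read_csv(path, dtype=str)
    for col in ("cell_id", "label"):
        if col not in df.columns:
            raise IOFormatError(f"{path}: missing column {col!r}")
    dup = df.duplicated(subset=["cell_id"], keep=False)
    if dup.any():
        raise DuplicateCellError(
            f"{path}: duplicate cell_id(s): {sorted(set(df.loc[dup, 'cell_id']))}"
        )
    truth = {}
    for row in df.itertuples(index=True):
        try:
            truth[str(row.cell_id)] = CellLabel.parse(row.label)
        except vote_model.LabelParseError as exc:
            raise IOFormatError(f"{path}: row {row.Index + 2}: {exc}") from None
    return truth


def write_truth(path: Union[str, Path], truth: Mapping[str, CellLabel]) -> None:
    df = pd.DataFrame(
        [(c, l.value) for c, l in truth.items()], columns=["cell_id", "label"]
    )
    _atomic_write_df(path, df)


def votes_dataframe_to_list(df: pd.DataFrame) -> List[Vote]:
    return [
        Vote(str(r.cell_id), str(r.worker_id), CellLabel.parse(r.label))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Consensus and confusion tables
# ---------------------------------------------------------------------------


def write_consensus(path: Union[str, Path], outcomes: Sequence[ConsensusOutcome]) -> None:
    rows = [
        (
            o.cell_id,
            "NA" if o.label is NO_ANSWER else o.label.value,
            o.agreement,
            o.configuration,
        )
        for o in outcomes
    ]
    df = pd.DataFrame(
        rows, columns=["cell_id", "consensus_label", "agreement", "configuration"]
    )
    _atomic_write_df(path, df)


def read_consensus(path: Union[str, Path]) -> List[ConsensusOutcome]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["cell_id", "consensus_label", "agreement", "configuration"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IOFormatError(f"{path}: missing column(s) {missing}")
    outcomes = []
    for row in df.itertuples(index=False):
        label = (
            NO_ANSWER
            if row.consensus_label == "NA"
            else CellLabel.parse(row.consensus_label)
        )
        outcomes.append(
            ConsensusOutcome(
                str(row.cell_id), label, int(row.agreement), str(row.configuration)
            )
        )
    return outcomes


def write_confusion(path: Union[str, Path], cm: ConfusionMatrix) -> None:
    """Confusion CSV: first row/column carry labels, cells are integers."""
    cols = list(cm.labels) + (["NA"] if cm.has_no_answer else [])
    df = pd.DataFrame(cm.counts, index=list(cm.labels), columns=cols)
    df.index.name = "truth"
    _atomic_write_text(path, df.to_csv(lineterminator="\n"))


def read_confusion(path: Union[str, Path]) -> ConfusionMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = tuple(str(i) for i in df.index)
    cols = tuple(str(c) for c in df.columns)
    has_na = len(cols) == len(labels) + 1 and cols[-1] == "NA"
    if not has_na and cols != labels:
        raise IOFormatError(f"{path}: row/column labels disagree: {labels} vs {cols}")
    return ConfusionMatrix(df.values.astype(np.int64), labels, has_na)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class SimulateConfig:
    """Parameters of a simulated vote-table run."""

    n_cells: int = 848
    class_mix: Tuple[float, float, float] = tuple(synthetic.DEFAULT_CLASS_MIX)
    pi_hard: Optional[float] = None
    hard_penalty: float = 0.5


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either ``votes_path`` + ``truth_path`` point at existing CSVs, or
    ``simulate`` asks for a seeded simulation whose tables are written next
    to the reports.  ``strata`` selects the report rows.
    """

    out_dir: Union[str, Path] = "crowdcell_out"
    votes_path: Optional[Union[str, Path]] = None
    truth_path: Optional[Union[str, Path]] = None
    simulate: Optional[SimulateConfig] = None
    k: int = 5
    merge: bool = True
    strata: Tuple[str, ...] = (
        "aggregated",
        "consensus",
        "5-agree",
        "4-agree",
        "3-agree",
    )
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise IOFormatError(f"k must be odd and >= 3, got {self.k}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            if "class_mix" in sim:
                sim["class_mix"] = tuple(sim["class_mix"])
            cfg.simulate = SimulateConfig(**sim)
        return cfg


def individual_report(
    truth: Mapping[str, CellLabel],
    votes: Sequence[Vote],
    merge: bool = False,
    f_variant: str = "macro",
) -> MetricReport:
    """Score every raw vote as an individual prediction (the pre-consensus row)."""
    pred = {f"{v.cell_id}::{v.worker_id}": v.label for v in votes}
    truth_expanded = {
        f"{v.cell_id}::{v.worker_id}": truth[v.cell_id] for v in votes
    }
    cm = build_confusion(truth_expanded, pred)
    if merge:
        cm = merge_to_binary(cm)
    mcc = (
        metrics.mcc_binary(cm)
        if cm.n_classes == 2 and not cm.has_no_answer
        else metrics.mcc_multiclass_gorodkin(cm)
    )
    return MetricReport(
        stratum="individual",
        n_cells=len(votes),
        labels=cm.labels,
        per_class_accuracy=metrics.per_class_accuracy(cm),
        overall_accuracy=metrics.overall_accuracy(cm),
        sds_score=metrics.sds_score(cm),
        cba=metrics.cba_macro_recall(cm),
        mcc=mcc,
        f_measure=metrics.f_measure(cm, f_variant),
        f_variant=f_variant,
    )


def _report_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        rec = rep.to_dict()
        for key, val in list(rec.items()):
            if isinstance(val, float):
                rec[key + "_4dp"] = metrics.round_half_up(val, 4)
        rows.append(rec)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Aggregate, score and report; returns the paths of the written files.

    Stages: (optional simulation) -> panel grouping -> plurality consensus
    -> stratified metric reports, 3-class and (optionally) merged binary.
    All randomness flows through ``config.seed``.  Failures propagate with
    the stage name attached and leave no partial output files.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    def stage(name):
        logger.info("stage %-12s t=%.2fs", name, time.time() - t0)

    try:
        stage("input")
        if config.simulate is not None:
            sim = config.simulate
            truth = synthetic.sample_truth(sim.n_cells, sim.class_mix, seed=config.seed)
            workers = synthetic.make_workers(config.k)
            difficulty = (
                synthetic.DifficultyModel(sim.pi_hard, sim.hard_penalty)
                if sim.pi_hard is not None
                else None
            )
            vote_df = synthetic.simulate_votes(
                truth,
                workers,
                difficulty,
                seed=None if config.seed is None else config.seed + 1,
            )
            votes = votes_dataframe_to_list(vote_df)
            write_truth(out_dir / "truth.csv", truth)
            write_votes(out_dir / "votes.csv", votes)
            written["truth"] = out_dir / "truth.csv"
            written["votes"] = out_dir / "votes.csv"
        else:
            if config.votes_path is None or config.truth_path is None:
                raise IOFormatError(
                    "config needs either votes_path+truth_path or a simulate block"
                )
            votes = read_votes(config.votes_path)
            truth = read_truth(config.truth_path)
        if not votes:
            raise IOFormatError("empty vote table")

        stage("aggregate")
        panels = panels_from_votes(votes, k=config.k)
        outcomes = [aggregate_votes(p, k=config.k) for p in panels]
        logger.info("aggregated %d cells from %d votes", len(outcomes), len(votes))

        stage("score")
        merges = [False, True] if config.merge else [False]
        reports: List[MetricReport] = []
        for merge in merges:
            rep = individual_report(truth, votes, merge=merge)
            rep.stratum = ("merged:" if merge else "") + rep.stratum
            reports.append(rep)
            for stratum in config.strata:
                rep = consensus_report(
                    truth, outcomes, stratum=stratum, merge=merge, k=config.k
                )
                rep.stratum = ("merged:" if merge else "") + rep.stratum
                reports.append(rep)

        stage("write")
        write_consensus(out_dir / "consensus.csv", outcomes)
        written["consensus"] = out_dir / "consensus.csv"
        cm3 = build_confusion(truth, {o.cell_id: o.label for o in outcomes})
        write_confusion(out_dir / "confusion_3class.csv", cm3)
        written["confusion_3class"] = out_dir / "confusion_3class.csv"
        if config.merge:
            write_confusion(out_dir / "confusion_merged.csv", merge_to_binary(cm3))
            written["confusion_merged"] = out_dir / "confusion_merged.csv"
        frame = _report_frame(reports)
        _atomic_write_df(out_dir / "report.csv", frame)
        written["report"] = out_dir / "report.csv"
        _atomic_write_text(
            out_dir / "report.json",
            json.dumps([rep.to_dict() for rep in reports], indent=2) + "\n",
        )
        written["report_json"] = out_dir / "report.json"
        logger.info("pipeline done in %.2fs", time.time() - t0)
        return written
    except Exception:
        # remove anything written so a failed run leaves no outputs behind
        for path in written.values():
            try:
                os.unlink(path)
            except OSError:
                pass
        raise
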