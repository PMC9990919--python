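"""Core data containers and CSV readers/writers.

The canonical on-disk layout is a long-format CSV with exactly four columns:
``participant_id, question_id, correct, confidence`` — one row per
participant x question cell.  ``correct`` is 1 if the participant chose the
true alternative of a two-alternative forced-choice question, 0 otherwise;
``confidence`` is a visual-analog rating on [0, 100].

In memory a dataset is held as a pair of aligned wide matrices
(participants on rows, questions on columns), which is what the resampling
simulations index into.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import IncompleteDesignError, ValidationError

LONG_COLUMNS = ("participant_id", "question_id", "correct", "confidence")


@dataclass(frozen=True)
class ResponseRecord:
    """One participant's answer to one question."""

    participant_id: str
    question_id: str
    correct: int
    confidence: float

    def __post_init__(self):
        if self.correct not in (0, 1):
            raise ValidationError(
                f"correct must be 0 or 1, got {self.correct!r} "
                f"({self.participant_id}, {self.question_id})"
            )
        if not 0.0 <= self.confidence <= 100.0:
            raise ValidationError(
                f"confidence must lie in [0, 100], got {self.confidence!r} "
                f"({self.participant_id}, {self.question_id})"
            )


@dataclass(frozen=True)
class BehavioralDataset:
    """A complete participants x questions table for one binary-choice task.

    Attributes
    ----------
    task_name
        Free-form label (e.g. ``"population_inference"``).
    correct
        DataFrame of 0/1 correctness, participants on the index,
        questions on the columns.
    confidence
        DataFrame of confidence ratings in [0, 100], aligned with
        ``correct``.
    """

    task_name: str
    correct: pd.DataFrame = field(repr=False)
    confidence: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        c, k = self.correct, self.confidence
        if list(c.index) != list(k.index) or list(c.columns) != list(k.columns):
            raise ValidationError("correct and confidence matrices are not aligned")
        if c.index.has_duplicates:
            raise ValidationError("duplicate participant ids")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate question ids")
        if c.shape[0] < 1 or c.shape[1] < 1:
            raise ValidationError("dataset must contain at least one cell")
        cv = c.to_numpy()
        if c.isna().any().any() or not np.isin(cv, (0, 1)).all():
            raise ValidationError("correct entries must all be 0 or 1")
        kv = k.to_numpy(dtype=float)
        if np.isnan(kv).any() or (kv < 0).any() or (kv > 100).any():
            raise ValidationError("confidence entries must all lie in [0, 100]")

    # -- introspection -------------------------------------------------
    @property
    def participants(self) -> list[str]:
        return list(self.correct.index)

    @property
    def questions(self) -> list[str]:
        return list(self.correct.columns)

    @property
    def n_participants(self) -> int:
        return self.correct.shape[0]

    @property
    def n_questions(self) -> int:
        return self.correct.shape[1]

    # -- conversions ---------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Flatten to the canonical long layout, one row per cell."""
        long = (
            self.correct.stack()
            .rename("correct")
            .to_frame()
            .join(self.confidence.stack().rename("confidence"))
            .reset_index()
        )
        long.columns = list(LONG_COLUMNS)
        return long

    def records(self) -> Iterable[ResponseRecord]:
        for row in self.to_long().itertuples(index=False):
            yield ResponseRecord(*row)

    @classmethod
    def from_long(cls, frame: pd.DataFrame, task_name: str = "task") -> "BehavioralDataset":
        """Build a dataset from a long-format frame, validating completeness.

        Participant and question ids are opaque strings; rows may arrive in
        any order.  Ordering of the result is lexicographic in both ids so
        the same file always yields the same dataset.
        """
        missing = [c for c in LONG_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        frame = frame.loc[:, list(LONG_COLUMNS)].copy()
        frame["participant_id"] = frame["participant_id"].astype(str)
        frame["question_id"] = frame["question_id"].astype(str)

        dup = frame.duplicated(["participant_id", "question_id"])
        if dup.any():
            p, q = frame.loc[dup.idxmax(), ["participant_id", "question_id"]]
            raise ValidationError(f"duplicate cell for participant {p!r}, question {q!r}")

        participants = sorted(frame["participant_id"].unique())
        questions = sorted(frame["question_id"].unique())
        if len(frame) != len(participants) * len(questions):
            have = set(zip(frame["participant_id"], frame["question_id"]))
            for p in participants:
                for q in questions:
                    if (p, q) not in have:
                        raise IncompleteDesignError(p, q)

        correct = frame.pivot(
            index="participant_id", columns="question_id", values="correct"
        ).loc[participants, questions]
        conf = frame.pivot(
            index="participant_id", columns="question_id", values="confidence"
        ).loc[participants, questions]
        correct.index.name = conf.index.name = None
        correct.columns.name = conf.columns.name = None
        return cls(task_name=task_name, correct=correct.astype(np.int8), confidence=conf.astype(float))


def read_dataset(path: str | Path, layout: str = "long", task_name: str | None = None) -> BehavioralDataset:
    """Read a behavioral dataset from disk.

    Only the ``long`` layout is supported: a UTF-8 CSV with header
    ``participant_id,question_id,correct,confidence``.  The file must form
    a complete participants x questions design.
    """
    if layout != "long":
        raise ValidationError(f"unknown layout {layout!r}; only 'long' is supported")
    path = Path(path)
    frame = pd.read_csv(path)
    name = task_name if task_name is not None else path.stem
    return BehavioralDataset.from_long(frame, task_name=name)


def write_dataset(dataset: BehavioralDataset, path: str | Path) -> None:
    """Write a dataset in the canonical long layout."""
    dataset.to_long().to_csv(path, index=False)


def write_summary(table: pd.DataFrame, path: str | Path) -> None:
    """Write a summary table as CSV with 6-significant-digit floats.

    If the table carries interval columns (``ci_low``/``ci_high`` flanking a
    ``mean`` or ``value`` column), the interval ordering is validated first.
    """
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty summary table")
    point_col = next((c for c in ("mean", "value", "mean_rate") if c in table.columns), None)
    if point_col and {"ci_low", "ci_high"}.issubset(table.columns):
        bad = (table["ci_low"] > table[point_col]) | (table[point_col] > table["ci_high"])
        if bad.any():
            raise ValidationError("confidence interval does not bracket its point estimate")
    table.to_csv(path, index=False, float_format="%.6g")
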