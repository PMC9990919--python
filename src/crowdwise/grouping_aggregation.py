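"""Confidence-based member selection and vote-aggregation rules.

This module houses the building blocks of the two resampling simulations:
ranking participants by their confidence on training questions, selecting
group members from that ranking ("highest" / "higher" / "mixed"
categories, in deterministic-stride or random mode), the three aggregation
rules (majority, confidence-weighted, transmission chain), and the
pairwise accordance rate used to quantify judgment diversity.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np

from .data_model import BehavioralDataset
from .errors import TieError, ValidationError

CATEGORIES = ("highest", "higher", "mixed")


@dataclass(frozen=True)
class ConfidenceRanking:
    """Participants sorted by descending mean training confidence."""

    participants: tuple[str, ...]
    mean_confidence: tuple[float, ...]
    tie_seed: int

    def __post_init__(self):
        if any(
            a < b for a, b in zip(self.mean_confidence, self.mean_confidence[1:])
        ):
            raise ValidationError("ranking confidence must be non-increasing")

    def __len__(self) -> int:
        return len(self.participants)


@dataclass(frozen=True)
class SelectionScheme:
    """How to pick group members from a confidence ranking.

    category
        ``highest`` — top ranks; ``higher`` — above-median ranks
        (1..ceil(N/2)); ``mixed`` — all ranks.
    mode
        ``stride`` — deterministic, evenly spaced rank positions across the
        category pool; ``random`` — uniform sample without replacement from
        the pool (``highest`` stays the deterministic top block).
    """

    category: str
    mode: str
    group_size: int

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.mode not in ("stride", "random"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.group_size < 1:
            raise ValidationError("group_size must be >= 1")


def rank_by_confidence(
    data: BehavioralDataset,
    training_questions: Iterable[str],
    tie_seed: int = 0,
) -> ConfidenceRanking:
    """Sort participants by mean confidence over the training questions.

    Exact ties are broken uniformly at random, reproducibly via
    ``tie_seed`` (ratings are continuous, so ties essentially only occur
    in constructed data).
    """
    training = list(training_questions)
    if not training:
        raise ValidationError("training_questions must be non-empty")
    unknown = set(training) - set(data.questions)
    if unknown:
        raise ValidationError(f"unknown question id(s): {sorted(unknown)}")
    means = data.confidence.loc[:, training].mean(axis=1).to_numpy()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((tie_seed, 17))))
    jitter = rng.random(means.size)
    # descending by mean confidence, random secondary key
    order = np.lexsort((jitter, -means))
    participants = tuple(np.asarray(data.participants, dtype=object)[order])
    return ConfidenceRanking(
        participants=participants,
        mean_confidence=tuple(means[order]),
        tie_seed=tie_seed,
    )


def _pool_size(category: str, n: int, group_size: int) -> int:
    if category == "highest":
        return group_size
    if category == "higher":
        return math.ceil(n / 2)
    return n


def stride_positions(category: str, n_participants: int, group_size: int) -> list[int]:
    """Deterministic 1-based rank positions for stride selection.

    Positions are evenly spaced over the category pool with step
    pool/group_size: with 150 participants and groups of 15 this gives
    ranks 1..15 (highest), 1, 6, ..., 71 (higher) and 1, 11, ..., 141
    (mixed).
    """
    pool = _pool_size(category, n_participants, group_size)
    if group_size > pool:
        raise ValidationError(
            f"group_size {group_size} exceeds the {category!r} pool of {pool}"
        )
    if category == "highest":
        return list(range(1, group_size + 1))
    return [1 + round(i * pool / group_size) for i in range(group_size)]


def select_members(
    ranking: ConfidenceRanking,
    scheme: SelectionScheme,
    rng_seed: int | np.random.Generator = 0,
) -> list[str]:
    """Pick ``scheme.group_size`` participants from the ranking."""
    n = len(ranking)
    pool = _pool_size(scheme.category, n, scheme.group_size)
    if scheme.group_size > pool or pool > n:
        raise ValidationError(
            f"group_size {scheme.group_size} not feasible for category "
            f"{scheme.category!r} with {n} participants"
        )
    if scheme.mode == "stride":
        positions = stride_positions(scheme.category, n, scheme.group_size)
    elif scheme.category == "highest":
        # degenerate: the top block is the only size-g subset of its pool
        positions = list(range(1, scheme.group_size + 1))
    else:
        rng = (
            rng_seed
            if isinstance(rng_seed, np.random.Generator)
            else np.random.Generator(np.random.PCG64(np.random.SeedSequence((rng_seed, 29))))
        )
        positions = list(
            1 + rng.choice(pool, size=scheme.group_size, replace=False)
        )
    return [ranking.participants[p - 1] for p in positions]


def _resolve_tie(alternatives: Sequence[Hashable], tie_seed, context: str):
    if tie_seed is None:
        raise TieError(f"exact tie in {context} between {sorted(map(str, alternatives))}")
    rng = (
        tie_seed
        if isinstance(tie_seed, np.random.Generator)
        else np.random.Generator(np.random.PCG64(np.random.SeedSequence((tie_seed, 31))))
    )
    ordered = sorted(alternatives, key=str)
    return ordered[rng.integers(len(ordered))]


def majority_vote(choices: Sequence[Hashable], tie_seed: int | None = None) -> Hashable:
    """Strict-majority winner; an exact tie needs ``tie_seed`` or raises."""
    if len(choices) == 0:
        raise ValidationError("majority_vote requires at least one choice")
    counts = Counter(choices)
    top = counts.most_common()
    best = top[0][1]
    leaders = [alt for alt, c in top if c == best]
    if len(leaders) == 1:
        return leaders[0]
    return _resolve_tie(leaders, tie_seed, "majority vote")


def weighted_confidence_vote(
    choices: Sequence[Hashable], confidences: Sequence[float]
) -> tuple[Hashable, float]:
    """Alternative with the larger summed confidence, plus that sum."""
    if len(choices) != len(confidences):
        raise ValidationError("choices and confidences must have equal length")
    if len(choices) == 0:
        raise ValidationError("weighted_confidence_vote requires at least one choice")
    if any(c < 0 for c in confidences):
        raise ValidationError("confidences must be >= 0")
    sums: dict[Hashable, float] = {}
    for alt, conf in zip(choices, confidences):
        sums[alt] = sums.get(alt, 0.0) + float(conf)
    best = max(sums.values())
    leaders = [alt for alt, s in sums.items() if s == best]
    if len(leaders) > 1:
        raise TieError(f"equal confidence sums for {sorted(map(str, leaders))}")
    return leaders[0], best


def transmission_chain(
    choices: Sequence[Hashable],
    confidences: Sequence[float],
    threshold: float,
) -> Hashable:
    """Sequential rule: the running solution is overwritten only by members
    whose confidence is at or above ``threshold``.

    The first member's choice is adopted unconditionally (their confidence
    is never consulted, so it may be NaN).
    """
    if len(choices) == 0:
        raise ValidationError("transmission_chain requires at least one member")
    if len(choices) != len(confidences):
        raise ValidationError("choices and confidences must have equal length")
    solution = choices[0]
    for alt, conf in zip(choices[1:], confidences[1:]):
        if conf >= threshold:
            solution = alt
    return solution


def accordance_rate(responses_x, responses_y) -> float:
    """Fraction of positions on which two response vectors agree.

    Equals 1 minus the normalized Hamming distance; symmetric in its
    arguments.
    """
    x = np.asarray(responses_x)
    y = np.asarray(responses_y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("responses must be equal-length vectors")
    if x.size == 0:
        raise ValidationError("responses must be non-empty")
    return float(np.mean(x == y))


def group_accuracy(
    data: BehavioralDataset,
    members: Sequence[str],
    questions: Sequence[str],
    rule: str = "majority",
    tie_seed: int | np.random.Generator | None = None,
    chain_threshold: float = 50.0,
) -> float:
    """Mean over ``questions`` of whether the aggregated group judgment is
    correct.

    ``correct == 1`` marks the true alternative, so each member's choice on
    a question is their correctness indicator and the group judgment is
    correct iff the aggregate equals 1.  ``rule`` is one of ``majority``,
    ``weighted`` (confidence-weighted vote) or ``chain`` (transmission
    chain in the order of ``members``, updating at confidence >=
    ``chain_threshold``).
    """
    members = list(members)
    questions = list(questions)
    if not members or not questions:
        raise ValidationError("members and questions must be non-empty")
    unknown_m = set(members) - set(data.participants)
    unknown_q = set(questions) - set(data.questions)
    if unknown_m or unknown_q:
        raise ValidationError(
            f"unknown ids: participants {sorted(unknown_m)}, questions {sorted(unknown_q)}"
        )
    choices = data.correct.loc[members, questions].to_numpy()
    confs = data.confidence.loc[members, questions].to_numpy()
    g = len(members)
    if tie_seed is not None and not isinstance(tie_seed, np.random.Generator):
        tie_seed = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence((int(tie_seed), 31)))
        )

    if rule == "majority":
        ones = choices.sum(axis=0)
        correct = ones * 2 > g
        ties = ones * 2 == g
        if ties.any():
            outcomes = np.array(
                [_resolve_tie((0, 1), tie_seed, "majority vote") for _ in range(int(ties.sum()))]
            )
            correct = correct.astype(float)
            correct[ties] = outcomes == 1
        return float(np.mean(correct))
    if rule == "weighted":
        sum_true = (confs * choices).sum(axis=0)
        sum_false = (confs * (1 - choices)).sum(axis=0)
        correct = sum_true > sum_false
        ties = sum_true == sum_false
        if ties.any():
            outcomes = np.array(
                [_resolve_tie((0, 1), tie_seed, "weighted vote") for _ in range(int(ties.sum()))]
            )
            correct = correct.astype(float)
            correct[ties] = outcomes == 1
        return float(np.mean(correct))
    if rule == "chain":
        hits = [
            transmission_chain(choices[:, j], confs[:, j], chain_threshold) == 1
            for j in range(len(questions))
        ]
        return float(np.mean(hits))
    raise ValidationError(f"unknown rule {rule!r}")
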