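"""The two training-test resampling simulations.

Simulation 1 (:func:`run_accordance_simulation`) asks how similar the
judgments of confidence-selected individuals are: each iteration draws a
handful of questions, ranks participants by confidence on the first
(training) question, assembles a panel per confidence category by
deterministic stride positions, and averages the pairwise accordance rate
of panel members over the remaining (test) questions.

Simulation 2 (:func:`run_group_simulation`) asks whether group accuracy on
training questions predicts accuracy on held-out test questions: each
iteration draws disjoint training/test question sets, ranks participants
by mean training confidence, samples a group within the category pool, and
scores majority-rule group accuracy separately on both sets.

Both are seed-reproducible; per-iteration random substreams are keyed by
(seed, iteration), optionally shared across conditions (common random
numbers).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import BehavioralDataset
from .errors import ValidationError
from .grouping_aggregation import CATEGORIES, stride_positions
from .stats import EffectSize, cliffs_delta, mean_ci


@dataclass(frozen=True)
class SplitDesign:
    """Disjoint training/test question subsets for one iteration."""

    training_questions: tuple[str, ...]
    test_questions: tuple[str, ...]

    def __post_init__(self):
        if set(self.training_questions) & set(self.test_questions):
            raise ValidationError("training and test questions must be disjoint")


@dataclass(frozen=True)
class AccordanceResult:
    """Mean pairwise accordance for one confidence category."""

    category: str
    mean_rate: float
    ci_low: float
    ci_high: float
    n_iterations: int
    rates: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if not self.ci_low <= self.mean_rate <= self.ci_high:
            raise ValidationError("CI must bracket the mean rate")


@dataclass(frozen=True)
class GroupCondition:
    n_train: int
    group_size: int
    category: str
    n_test: int

    def label(self) -> str:
        return (
            f"{self.category}/size{self.group_size}/train{self.n_train}"
        )


@dataclass(frozen=True)
class GroupSimResult:
    """Per-iteration training and test accuracies for one condition."""

    condition: GroupCondition
    train_accuracies: np.ndarray = field(repr=False)
    test_accuracies: np.ndarray = field(repr=False)
    splits: tuple[SplitDesign, ...] = field(repr=False, default=())

    def __post_init__(self):
        tr, te = self.train_accuracies, self.test_accuracies
        if tr.shape != te.shape:
            raise ValidationError("train/test accuracy vectors must align")
        for v in (tr, te):
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValidationError("accuracies must lie in [0, 1]")

    @property
    def n_iterations(self) -> int:
        return self.train_accuracies.size

    def mean_train(self) -> float:
        return float(self.train_accuracies.mean())

    def mean_test(self) -> float:
        return float(self.test_accuracies.mean())


@dataclass(frozen=True)
class TestWorseSummary:
    """Decomposition of iterations whose test accuracy fell below training."""

    condition: GroupCondition
    test_worse_proportion: float
    mean_diff_in_test_worse: float
    has_test_worse: bool

    def __post_init__(self):
        if not 0.0 <= self.test_worse_proportion <= 1.0:
            raise ValidationError("proportion must lie in [0, 1]")
        if self.mean_diff_in_test_worse > 0:
            raise ValidationError("mean test-worse difference must be <= 0")


def _iter_rng(seed: int, iteration: int, tag: int = 0) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((seed, iteration, tag)))
    )


def run_accordance_simulation(
    data: BehavioralDataset,
    n_iterations: int = 5000,
    n_sample_questions: int = 10,
    panel_size: int = 15,
    seed: int = 0,
) -> list[AccordanceResult]:
    """Simulation 1: mean pairwise accordance per confidence category.

    Per iteration, ``n_sample_questions`` questions are drawn without
    replacement; the first serves as the training question and the rest as
    test questions.  Panels of ``panel_size`` are formed by stride
    positions within each category pool, and the accordance rate is
    averaged over all panel_size*(panel_size-1)/2 unordered member pairs.
    The returned interval is a t-based 95% CI for the mean over
    iterations.
    """
    n_p, n_q = data.n_participants, data.n_questions
    if n_q < n_sample_questions:
        raise ValidationError("not enough questions to sample from")
    if n_p < 2 * panel_size:
        raise ValidationError("stride selection needs at least 2*panel_size participants")
    conf = data.confidence.to_numpy()
    corr = data.correct.to_numpy()
    positions = {
        cat: np.array(stride_positions(cat, n_p, panel_size)) - 1 for cat in CATEGORIES
    }
    iu, ju = np.triu_indices(panel_size, k=1)

    rates = {cat: np.empty(n_iterations) for cat in CATEGORIES}
    for i in range(n_iterations):
        rng = _iter_rng(seed, i)
        qs = rng.choice(n_q, size=n_sample_questions, replace=False)
        train, test = qs[0], qs[1:]
        order = np.lexsort((rng.random(n_p), -conf[:, train]))
        for cat in CATEGORIES:
            panel = order[positions[cat]]
            resp = corr[np.ix_(panel, test)]
            agree = (resp[iu] == resp[ju]).mean(axis=1)
            rates[cat][i] = agree.mean()

    results = []
    for cat in CATEGORIES:
        m, lo, hi = mean_ci(rates[cat], 0.95)
        results.append(
            AccordanceResult(
                category=cat, mean_rate=m, ci_low=lo, ci_high=hi,
                n_iterations=n_iterations, rates=rates[cat],
            )
        )
    return results


def run_group_simulation(
    data: BehavioralDataset,
    n_train: int,
    group_size: int,
    category: str,
    n_test: int,
    n_iterations: int = 5000,
    seed: int = 0,
    common_random_numbers: bool = False,
    store_splits: bool = False,
) -> GroupSimResult:
    """Simulation 2: majority-rule group accuracy on training vs. test
    questions for one (n_train, group_size, category) condition.

    Member selection is the random mode of the category pools: ``highest``
    takes the top ``group_size`` ranks, ``higher`` samples uniformly from
    the above-median ranks, ``mixed`` from all ranks.  With
    ``common_random_numbers`` the per-iteration substream is shared across
    conditions run at the same seed, pairing their question splits.
    """
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    n_p, n_q = data.n_participants, data.n_questions
    if n_train < 1 or n_test < 1 or n_train + n_test > n_q:
        raise ValidationError("need n_train >= 1, n_test >= 1, n_train + n_test <= #questions")
    if group_size > n_p:
        raise ValidationError("group_size exceeds the number of participants")
    pool = group_size if category == "highest" else (
        -(-n_p // 2) if category == "higher" else n_p
    )
    if group_size > pool:
        raise ValidationError(f"group_size {group_size} exceeds the {category!r} pool")

    condition = GroupCondition(n_train, group_size, category, n_test)
    tag = 0 if common_random_numbers else (
        1 + CATEGORIES.index(category) + 10 * group_size + 1000 * n_train
    )
    conf = data.confidence.to_numpy()
    corr = data.correct.to_numpy()
    questions = np.asarray(data.questions, dtype=object)

    train_acc = np.empty(n_iterations)
    test_acc = np.empty(n_iterations)
    splits = []
    for i in range(n_iterations):
        rng = _iter_rng(seed, i, tag)
        qs = rng.choice(n_q, size=n_train + n_test, replace=False)
        train, test = qs[:n_train], qs[n_train:]
        mean_conf = conf[:, train].mean(axis=1)
        order = np.lexsort((rng.random(n_p), -mean_conf))
        if category == "highest":
            members = order[:group_size]
        else:
            members = order[rng.choice(pool, size=group_size, replace=False)]
        for qset, out in ((train, train_acc), (test, test_acc)):
            ones = corr[np.ix_(members, qset)].sum(axis=0)
            wins = ones * 2 > group_size
            ties = ones * 2 == group_size
            if ties.any():  # even group sizes only
                wins = wins | (ties & (rng.random(qset.size) < 0.5))
            out[i] = wins.mean()
        if store_splits:
            splits.append(
                SplitDesign(tuple(questions[train]), tuple(questions[test]))
            )
    return GroupSimResult(
        condition=condition,
        train_accuracies=train_acc,
        test_accuracies=test_acc,
        splits=tuple(splits),
    )


def summarize_test_worse(result: GroupSimResult) -> TestWorseSummary:
    """Proportion of test-worse iterations (test < train) and the mean
    test-minus-train difference within them (0 when none occurred)."""
    if result.n_iterations == 0:
        raise ValidationError("empty simulation result")
    diff = result.test_accuracies - result.train_accuracies
    worse = diff < 0
    has = bool(worse.any())
    return TestWorseSummary(
        condition=result.condition,
        test_worse_proportion=float(worse.mean()),
        mean_diff_in_test_worse=float(diff[worse].mean()) if has else 0.0,
        has_test_worse=has,
    )


def compare_conditions(
    result_a: GroupSimResult, result_b: GroupSimResult, on: str = "test"
) -> EffectSize:
    """Cliff's delta of condition a's accuracies versus condition b's."""
    if on not in ("test", "train"):
        raise ValidationError("on must be 'test' or 'train'")
    attr = f"{on}_accuracies"
    return cliffs_delta(getattr(result_a, attr), getattr(result_b, attr))


def accordance_summary_table(results) -> pd.DataFrame:
    """SummaryTable view of Simulation 1 results."""
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "mean_rate": r.mean_rate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_iterations": r.n_iterations,
            }
            for r in results
        ]
    )


def group_summary_table(results) -> pd.DataFrame:
    """SummaryTable view of Simulation 2 results with test-worse columns."""
    rows = []
    for r in results:
        tw = summarize_test_worse(r)
        rows.append(
            {
                "category": r.condition.category,
                "group_size": r.condition.group_size,
                "n_train": r.condition.n_train,
                "n_test": r.condition.n_test,
                "mean_train_accuracy": r.mean_train(),
                "mean_test_accuracy": r.mean_test(),
                "test_worse_proportion": tw.test_worse_proportion,
                "mean_diff_in_test_worse": tw.mean_diff_in_test_worse,
                "n_iterations": r.n_iterations,
            }
        )
    return pd.DataFrame(rows)


def run_group_conditions(
    data: BehavioralDataset,
    n_trains=(1, 5, 10),
    group_sizes=(3, 15),
    categories=CATEGORIES,
    n_test: int = 25,
    n_iterations: int = 5000,
    seed: int = 0,
    common_random_numbers: bool = False,
) -> list[GroupSimResult]:
    """Run Simulation 2 over the full condition grid."""
    return [
        run_group_simulation(
            data, n_train, group_size, category, n_test,
            n_iterations=n_iterations, seed=seed,
            common_random_numbers=common_random_numbers,
        )
        for n_train, group_size, category in itertools.product(
            n_trains, group_sizes, categories
        )
    ]
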