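import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from crowdwise import (
    SelectionScheme,
    TieError,
    ValidationError,
    accordance_rate,
    group_accuracy,
    majority_vote,
    rank_by_confidence,
    select_members,
    stride_positions,
    transmission_chain,
    weighted_confidence_vote,
)
from conftest import make_dataset


class TestRankByConfidence:
    def test_single_training_question(self):
        ds = make_dataset([[1], [1], [1]], [[90.0], [50.0], [70.0]])
        ranking = rank_by_confidence(ds, ["Q001"])
        assert list(ranking.participants) == ["P001", "P003", "P002"]

    def test_mean_over_two_training_questions(self):
        ds = make_dataset([[1, 1], [1, 1]], [[80.0, 40.0], [70.0, 60.0]])
        ranking = rank_by_confidence(ds, ["Q001", "Q002"])  # means 60 vs 65
        assert list(ranking.participants) == ["P002", "P001"]

    def test_pure_ties_random_but_reproducible(self):
        ds = make_dataset(np.ones((8, 1)), np.full((8, 1), 50.0))
        r1 = rank_by_confidence(ds, ["Q001"], tie_seed=3)
        r2 = rank_by_confidence(ds, ["Q001"], tie_seed=3)
        r3 = rank_by_confidence(ds, ["Q001"], tie_seed=4)
        assert r1.participants == r2.participants
        assert sorted(r1.participants) == ds.participants
        assert r1.participants != r3.participants  # almost surely under 8! orders

    def test_unknown_question_rejected(self):
        ds = make_dataset([[1], [0]])
        with pytest.raises(ValidationError):
            rank_by_confidence(ds, ["nope"])


class TestSelectMembers:
    @pytest.mark.parametrize(
        "category,expected",
        [
            ("highest", list(range(1, 16))),
            ("higher", [1, 6, 11, 16, 21, 26, 31, 36, 41, 46, 51, 56, 61, 66, 71]),
            ("mixed", [1, 11, 21, 31, 41, 51, 61, 71, 81, 91, 101, 111, 121, 131, 141]),
        ],
    )
    def test_published_stride_positions_at_150(self, category, expected):
        assert stride_positions(category, 150, 15) == expected

    def test_higher_pool_is_ceil_half(self):
        # 149 participants: above-median pool is ranks 1..75
        assert max(stride_positions("higher", 149, 15)) <= 75

    def test_highest_size_3_is_top_three(self):
        assert stride_positions("highest", 149, 3) == [1, 2, 3]

    def test_stride_returns_rank_ordered_participants(self):
        conf = np.linspace(99, 1, 30).reshape(-1, 1)
        ds = make_dataset(np.ones((30, 1)), conf)
        ranking = rank_by_confidence(ds, ["Q001"])
        members = select_members(ranking, SelectionScheme("highest", "stride", 3))
        assert members == ["P001", "P002", "P003"]

    def test_random_mode_samples_within_pool(self):
        conf = np.linspace(99, 1, 30).reshape(-1, 1)
        ds = make_dataset(np.ones((30, 1)), conf)
        ranking = rank_by_confidence(ds, ["Q001"])
        members = select_members(ranking, SelectionScheme("higher", "random", 5), rng_seed=2)
        assert len(set(members)) == 5
        ranks = [ranking.participants.index(m) + 1 for m in members]
        assert max(ranks) <= 15  # ceil(30/2)

    def test_random_mode_reproducible(self):
        ds = make_dataset(np.ones((30, 1)), np.linspace(99, 1, 30).reshape(-1, 1))
        ranking = rank_by_confidence(ds, ["Q001"])
        scheme = SelectionScheme("mixed", "random", 10)
        assert select_members(ranking, scheme, 5) == select_members(ranking, scheme, 5)

    def test_oversized_group_rejected(self):
        ds = make_dataset(np.ones((10, 1)), np.linspace(99, 1, 10).reshape(-1, 1))
        ranking = rank_by_confidence(ds, ["Q001"])
        with pytest.raises(ValidationError):
            select_members(ranking, SelectionScheme("higher", "stride", 6))


class TestVoteRules:
    def test_majority_worked_example(self):
        assert majority_vote(list("AAABB")) == "A"

    def test_majority_singleton(self):
        assert majority_vote(["A"]) == "A"

    def test_majority_tie_requires_seed(self):
        with pytest.raises(TieError):
            majority_vote(["A", "B"])
        assert majority_vote(["A", "B"], tie_seed=1) in ("A", "B")

    def test_weighted_worked_example(self):
        # three A votes (20+30+40=90) lose to two B votes (80+90=170)
        winner, total = weighted_confidence_vote(list("AAABB"), [20, 30, 40, 80, 90])
        assert (winner, total) == ("B", 170)

    def test_weighted_unanimous(self):
        winner, total = weighted_confidence_vote(["A", "A"], [10, 15])
        assert (winner, total) == ("A", 25)

    def test_weighted_tie_raises(self):
        with pytest.raises(TieError):
            weighted_confidence_vote(["A", "B"], [10, 10])

    def test_weighted_agrees_with_majority_under_equal_confidence(self):
        choices = list("ABAAB")
        winner, _ = weighted_confidence_vote(choices, [7.0] * 5)
        assert winner == majority_vote(choices)

    def test_chain_worked_example(self):
        # X chose A (adopted unconditionally), Y overwrites with B at 80,
        # Z's A at 30 is below the threshold of 50
        assert transmission_chain(list("ABA"), [np.nan, 80, 30], threshold=50) == "B"

    def test_chain_all_below_threshold_keeps_first(self):
        assert transmission_chain(list("ABB"), [np.nan, 10, 20], threshold=50) == "A"

    def test_chain_single_member(self):
        assert transmission_chain(["B"], [5.0], threshold=50) == "B"

    def test_chain_empty_rejected(self):
        with pytest.raises(ValidationError):
            transmission_chain([], [], threshold=50)


class TestAccordanceRate:
    def test_published_example(self):
        x = [1, 0, 0, 0, 1, 1, 1, 0, 1]
        y = [1, 1, 0, 1, 1, 0, 1, 0, 0]
        assert accordance_rate(x, y) == pytest.approx(5 / 9)

    def test_identical_and_complementary(self):
        x = np.array([1, 0, 1, 1])
        assert accordance_rate(x, x) == 1.0
        assert accordance_rate(x, 1 - x) == 0.0

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_hamming_complement(self, xs, data):
        ys = data.draw(st.lists(st.integers(0, 1), min_size=len(xs), max_size=len(xs)))
        x, y = np.array(xs), np.array(ys)
        r = accordance_rate(x, y)
        assert r == accordance_rate(y, x)
        assert r == pytest.approx(1 - np.mean(x != y))

    def test_independent_responders_match_product_formula(self):
        """E[accordance] = pq + (1-p)(1-q) for independent accuracies p, q."""
        p, q, n = 0.7, 0.55, 4000
        rng = np.random.default_rng(0)
        x = (rng.random(n) < p).astype(int)
        y = (rng.random(n) < q).astype(int)
        expected = p * q + (1 - p) * (1 - q)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(accordance_rate(x, y) - expected) < 3 * se


class TestGroupAccuracy:
    def test_unanimously_correct_group(self):
        ds = make_dataset(np.ones((3, 5)))
        acc = group_accuracy(ds, ds.participants, ds.questions)
        assert acc == 1.0

    def test_direct_majority_count(self):
        # question 1: 2/3 correct -> group correct; question 2: 1/3 -> wrong
        ds = make_dataset([[1, 1], [1, 0], [0, 0]])
        assert group_accuracy(ds, ds.participants, ds.questions) == 0.5

    def test_identical_members_equal_individual_accuracy(self):
        row = np.array([[1, 0, 1, 1, 0]])
        ds = make_dataset(np.repeat(row, 5, axis=0))
        acc = group_accuracy(ds, ds.participants, ds.questions)
        assert acc == row.mean()

    def test_condorcet_binomial_oracle(self):
        """15 iid members at p=0.6 on 200 questions: majority accuracy must
        sit within 3 SE of the closed-form binomial tail (~0.787)."""
        m, p, nq = 15, 0.6, 200
        rng = np.random.default_rng(3)
        ds = make_dataset((rng.random((m, nq)) < p).astype(int))
        expected = 1 - binom.cdf(m // 2, m, p)
        se = np.sqrt(expected * (1 - expected) / nq)
        acc = group_accuracy(ds, ds.participants, ds.questions)
        assert abs(acc - expected) < 3 * se

    def test_weighted_rule_follows_confident_minority(self):
        ds = make_dataset(
            [[1, 1], [0, 1], [0, 1]],
            [[90.0, 50.0], [10.0, 50.0], [20.0, 50.0]],
        )
        # Q1: correct member holds 90 vs 30 -> weighted says correct
        assert group_accuracy(ds, ds.participants, ds.questions, rule="weighted") == 1.0
        assert group_accuracy(ds, ds.participants, ds.questions, rule="majority") == 0.5

    def test_chain_rule_last_confident_wins(self):
        ds = make_dataset(
            [[0], [1], [0]],
            [[99.0], [80.0], [30.0]],
        )
        # chain: adopt P1's wrong answer, P2 overwrites (80 >= 50), P3 too low
        acc = group_accuracy(ds, ds.participants, ds.questions, rule="chain")
        assert acc == 1.0

    def test_unknown_member_rejected(self):
        ds = make_dataset([[1], [0]])
        with pytest.raises(ValidationError):
            group_accuracy(ds, ["ghost"], ds.questions)
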