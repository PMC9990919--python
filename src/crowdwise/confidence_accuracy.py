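"""Within- and between-question prediction of accuracy from confidence.

For every question (within) or ordered question pair (between), a logistic
regression predicts the 0/1 correctness of each participant from their
confidence rating: within uses confidence on the same question, between
uses confidence on a different question.  If confidence carries real
information about knowledge, within-question slopes should exceed
between-question slopes — the core behavioral signature this package
simulates around.

Estimation is maximum likelihood with Wald 95% intervals.  Degenerate
likelihoods (constant outcome, complete or quasi separation, failed
optimization) are flagged via ``converged=False`` rather than raised, and
such fits are dropped by :func:`apply_exclusions`, mirroring the exclusion
of non-converged estimates in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data_model import BehavioralDataset
from .errors import ValidationError

#: |slope| above this (per confidence unit on a 0-100 scale) is treated as
#: a separation artifact, not a credible estimate.
BETA_CAP = 50.0


@dataclass(frozen=True)
class CoefficientEstimate:
    """Logistic slope of accuracy on confidence for one (i, j) pairing.

    ``independent_question`` supplies the confidence (question i);
    ``dependent_question`` supplies the correctness outcome (question j).
    The two coincide in within-question fits.
    """

    independent_question: str
    dependent_question: str
    beta: float
    ci_low: float
    ci_high: float
    converged: bool

    def __post_init__(self):
        if self.converged and not (self.ci_low <= self.beta <= self.ci_high):
            raise ValidationError("confidence interval must bracket beta")

    @property
    def ci_excludes_zero(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


@dataclass(frozen=True)
class CoefficientSummary:
    n_estimates: int
    mean_beta: float
    sd_beta: float
    prop_ci_excluding_zero: float

    def __post_init__(self):
        if not 0.0 <= self.prop_ci_excluding_zero <= 1.0:
            raise ValidationError("proportion must lie in [0, 1]")


def fit_confidence_logistic(
    confidence,
    correct,
    independent_question: str = "",
    dependent_question: str = "",
) -> CoefficientEstimate:
    """ML logistic fit of P(correct) on confidence, with a 95% Wald CI."""
    confidence = np.asarray(confidence, dtype=float).ravel()
    correct = np.asarray(correct, dtype=float).ravel()
    if confidence.size != correct.size:
        raise ValidationError("confidence and correct must have equal length")
    if confidence.size < 2:
        raise ValidationError("need at least 2 observations")

    failed = CoefficientEstimate(
        independent_question, dependent_question,
        beta=np.nan, ci_low=np.nan, ci_high=np.nan, converged=False,
    )
    if correct.min() == correct.max():  # degenerate likelihood, not an error
        return failed

    exog = sm.add_constant(confidence, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(correct, exog).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return failed

    beta = float(res.params[1])
    se = float(res.bse[1])
    ok = (
        bool(res.mle_retvals.get("converged", False))
        and np.isfinite(beta)
        and np.isfinite(se)
        and abs(beta) <= BETA_CAP
    )
    if not ok:
        return failed
    lo, hi = (float(v) for v in res.conf_int(alpha=0.05)[1])
    return CoefficientEstimate(
        independent_question, dependent_question,
        beta=beta, ci_low=lo, ci_high=hi, converged=True,
    )


def within_question_analysis(data: BehavioralDataset) -> list[CoefficientEstimate]:
    """One fit per question: confidence on q predicting correctness on q."""
    return [
        fit_confidence_logistic(
            data.confidence[q], data.correct[q],
            independent_question=q, dependent_question=q,
        )
        for q in data.questions
    ]


def between_question_pairs(questions) -> list[tuple[str, str]]:
    """All ordered pairs (i, j), i != j, in dataset question order."""
    qs = list(questions)
    return [(qi, qj) for qi in qs for qj in qs if qi != qj]


def between_question_analysis(data: BehavioralDataset) -> list[CoefficientEstimate]:
    """One fit per ordered question pair: confidence on i predicting
    correctness on j (i != j); n*(n-1) estimates."""
    return [
        fit_confidence_logistic(
            data.confidence[qi], data.correct[qj],
            independent_question=qi, dependent_question=qj,
        )
        for qi, qj in between_question_pairs(data.questions)
    ]


def apply_exclusions(
    estimates,
    excluded_questions=frozenset(),
    excluded_pairs=frozenset(),
) -> list[CoefficientEstimate]:
    """Drop excluded questions/pairs and non-converged fits.

    An excluded question removes every estimate that uses it on either
    side; an excluded ordered pair (i, j) removes exactly that pairing.
    """
    excluded_questions = set(excluded_questions)
    excluded_pairs = set(tuple(p) for p in excluded_pairs)
    return [
        e
        for e in estimates
        if e.converged
        and e.independent_question not in excluded_questions
        and e.dependent_question not in excluded_questions
        and (e.independent_question, e.dependent_question) not in excluded_pairs
    ]


def summarize_coefficients(estimates) -> CoefficientSummary:
    """Mean/SD of slopes and the share of 95% CIs excluding zero."""
    estimates = list(estimates)
    if not estimates:
        raise ValidationError("cannot summarize an empty estimate list")
    if not all(e.converged for e in estimates):
        raise ValidationError("summaries require converged estimates only")
    betas = np.array([e.beta for e in estimates])
    return CoefficientSummary(
        n_estimates=len(estimates),
        mean_beta=float(betas.mean()),
        sd_beta=float(betas.std(ddof=1)) if len(estimates) > 1 else 0.0,
        prop_ci_excluding_zero=float(np.mean([e.ci_excludes_zero for e in estimates])),
    )
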