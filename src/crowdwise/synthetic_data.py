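"""Seeded generator of synthetic binary-choice behavioral data.

The generator is a latent-trait (item-response-style) model.  Each
participant p has a general ability a_p ~ N(0, ability_sd); each question q
an easiness e_q ~ N(0, easiness_sd); each cell an item-specific knowledge
term k_pq ~ N(0, item_knowledge_sd).  The latent evidence

    s_pq = a_p + e_q + k_pq

drives both the response, correct_pq ~ Bernoulli(sigmoid(s_pq)), and the
confidence report,

    confidence_pq = 100 * sigmoid(calib_intercept + calib_slope * s_pq + eps_pq),

with reporting noise eps_pq ~ N(0, confidence_noise_sd).  Because k_pq is
informative only about question q, the confidence-accuracy association is
stronger within a question than between questions — the empirical
signature the downstream analyses look for.  Setting calib_slope <= 0
produces a "wicked" environment in which confidence does not track (or
anti-tracks) accuracy.

Reproducibility contract: one integer seed; independent substreams are
derived per stream name and per question column, so the same seed yields a
bit-identical dataset, and growing ``n_questions`` leaves the draws for
earlier questions (and all participant abilities) unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import BehavioralDataset
from .errors import ValidationError

# substream tags, fixed forever for reproducibility
_ABILITY, _EASINESS, _CELL = 1, 2, 3

DEFAULT_TASK_SHAPES = {
    "population_inference": (150, 70),
    "relationships_comparison": (149, 25),
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the latent-trait response/confidence model.

    Defaults mirror the shape of a ~150-participant, 70-question
    two-alternative task with moderate between-person ability spread,
    sizeable question difficulty spread, and item-specific knowledge as
    the dominant evidence source.
    """

    n_participants: int = 150
    n_questions: int = 70
    ability_sd: float = 0.3
    easiness_sd: float = 0.7
    item_knowledge_sd: float = 1.0
    calib_intercept: float = 0.0
    calib_slope: float = 1.0
    confidence_noise_sd: float = 0.5
    seed: int = 0
    task_name: str = "synthetic"

    def __post_init__(self):
        if self.n_participants < 2 or self.n_questions < 2:
            raise ValidationError("need at least 2 participants and 2 questions")
        for name in ("ability_sd", "easiness_sd", "item_knowledge_sd", "confidence_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, *key))))


def generate_dataset(config: GeneratorConfig) -> BehavioralDataset:
    """Draw one complete synthetic BehavioralDataset from the model."""
    n_p, n_q = config.n_participants, config.n_questions
    ability = _stream(config.seed, _ABILITY).normal(0.0, config.ability_sd or 0.0, n_p) \
        if config.ability_sd > 0 else np.zeros(n_p)
    easiness_rng = _stream(config.seed, _EASINESS)

    correct = np.empty((n_p, n_q), dtype=np.int8)
    confidence = np.empty((n_p, n_q), dtype=float)
    for q in range(n_q):
        e_q = easiness_rng.normal(0.0, config.easiness_sd) if config.easiness_sd > 0 else 0.0
        rng = _stream(config.seed, _CELL, q)
        k = rng.normal(0.0, config.item_knowledge_sd, n_p) if config.item_knowledge_sd > 0 else np.zeros(n_p)
        u = rng.random(n_p)
        eps = rng.normal(0.0, config.confidence_noise_sd, n_p) if config.confidence_noise_sd > 0 else np.zeros(n_p)
        s = ability + e_q + k
        correct[:, q] = (u < _sigmoid(s)).astype(np.int8)
        confidence[:, q] = 100.0 * _sigmoid(config.calib_intercept + config.calib_slope * s + eps)

    width_p = len(str(n_p))
    width_q = len(str(n_q))
    participants = [f"P{i + 1:0{width_p}d}" for i in range(n_p)]
    questions = [f"Q{j + 1:0{width_q}d}" for j in range(n_q)]
    return BehavioralDataset(
        task_name=config.task_name,
        correct=pd.DataFrame(correct, index=participants, columns=questions),
        confidence=pd.DataFrame(confidence, index=participants, columns=questions),
    )
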