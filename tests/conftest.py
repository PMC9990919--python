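import numpy as np
import pandas as pd
import pytest

from crowdwise import BehavioralDataset, GeneratorConfig, generate_dataset


def make_dataset(correct, confidence=None, task_name="task"):
    """Build a BehavioralDataset from raw arrays (participants x questions)."""
    correct = np.asarray(correct)
    if confidence is None:
        confidence = np.full(correct.shape, 50.0)
    n_p, n_q = correct.shape
    participants = [f"P{i+1:03d}" for i in range(n_p)]
    questions = [f"Q{j+1:03d}" for j in range(n_q)]
    return BehavioralDataset(
        task_name=task_name,
        correct=pd.DataFrame(np.asarray(correct, dtype=np.int8), index=participants, columns=questions),
        confidence=pd.DataFrame(np.asarray(confidence, dtype=float), index=participants, columns=questions),
    )


@pytest.fixture
def tiny_long_frame():
    """Smallest complete design: 2 participants x 2 questions."""
    return pd.DataFrame(
        {
            "participant_id": ["p1", "p1", "p2", "p2"],
            "question_id": ["q1", "q2", "q1", "q2"],
            "correct": [1, 0, 0, 1],
            "confidence": [80.0, 20.0, 55.0, 60.0],
        }
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One 150x20 draw from the generator defaults (shared, read-only)."""
    return generate_dataset(GeneratorConfig(n_questions=20, seed=7))
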