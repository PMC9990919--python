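"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class IncompleteDesignError(ValidationError):
    """A participants-by-questions table is missing at least one cell.

    Every participant must answer every question (two-alternative forced
    choice with no skipping), so a missing cell is a data defect, not a
    value to impute.
    """

    def __init__(self, participant_id: str, question_id: str):
        self.participant_id = participant_id
        self.question_id = question_id
        super().__init__(
            f"incomplete design: no record for participant "
            f"{participant_id!r}, question {question_id!r}"
        )


class TieError(ValueError):
    """An aggregation rule produced an exact tie and no tie-break seed was given."""
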