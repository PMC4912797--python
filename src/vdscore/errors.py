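"""Exception types shared across the package."""


class DegenerateInputError(ValueError):
    """Raised when an operation receives input it is undefined for.

    Typical causes: a label vector with only one outcome class, fewer
    points than a smoother needs, or a non-positive biomarker level.
    """


class DegenerateVarianceError(RuntimeError):
    """Paired AUC contrast has zero estimated variance but a non-zero delta."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to converge within its iteration budget."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"[{stage}] {cause}")
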