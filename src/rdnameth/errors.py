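"""Exception hierarchy shared across the package."""


class RdnamethError(Exception):
    """Base class for all package-specific errors."""


class InvalidPresetError(RdnamethError):
    """A mixture preset's parameters are infeasible or out of domain."""


class ReferenceSpecError(RdnamethError):
    """An amplicon reference violates its structural invariants."""


class CohortTooSmallError(RdnamethError):
    """A cohort has too few samples for the requested operation."""


class UndefinedStatisticError(RdnamethError):
    """A statistic is undefined for the given input (empty, constant, ...)."""


class DegenerateCovariateError(RdnamethError):
    """Covariate matrix is rank-deficient or swallows a variable entirely."""


class ImputationError(RdnamethError):
    """KNN imputation cannot proceed (bad k, fully-missing CpG, ...)."""


class ClockFitError(RdnamethError):
    """Clock fitting preconditions violated (constant response, folds > n)."""


class PipelineError(RdnamethError):
    """End-to-end pipeline failure, carrying stage and sample context."""

    def __init__(self, stage: str, sample: str | None, message: str):
        self.stage = stage
        self.sample = sample
        where = f"stage={stage}" + (f", sample={sample}" if sample else "")
        super().__init__(f"[{where}] {message}")
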