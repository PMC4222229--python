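"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, InputFormatError -> 3,
any other PipelineError -> 4.
"""


class PipelineError(Exception):
    """Base class for all package-specific failures."""


class ConfigError(PipelineError):
    """Invalid configuration or infeasible simulation parameters."""


class InputFormatError(PipelineError):
    """An input file could not be parsed or violates its format contract."""


class ReferenceMismatchError(InputFormatError):
    """A variant's REF allele disagrees with the transcript reference base."""

    def __init__(self, expected: str, observed: str, context: str = ""):
        self.expected = expected
        self.observed = observed
        msg = f"reference base mismatch: transcript has {expected!r}, variant REF is {observed!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class InsufficientDataError(PipelineError):
    """Too few observations for the requested statistic."""


class StageError(PipelineError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
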