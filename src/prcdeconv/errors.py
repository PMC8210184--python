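"""Exception types shared across the pipeline."""


class PrcDeconvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PrcDeconvError):
    """A simulation or pipeline configuration field is invalid.

    The message always names the offending field.
    """


class SchemaError(PrcDeconvError):
    """An input table violates its declared schema."""


class EmptyDesignError(PrcDeconvError):
    """A sample selection matched no runs."""


class BaitMismatchError(PrcDeconvError):
    """Two interactor sets that must share a bait do not."""


class PipelineError(PrcDeconvError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
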