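"""Exception hierarchy for the dopplervti pipeline."""


class DopplerVtiError(Exception):
    """Base class for all dopplervti errors."""


class ParameterError(DopplerVtiError, ValueError):
    """A physical or shape parameter is non-finite or out of its valid range."""


class ConfigurationError(DopplerVtiError, ValueError):
    """A configuration is internally inconsistent (Nyquist violation, bad phases, ...)."""


class InputFormatError(DopplerVtiError, ValueError):
    """An input file or array does not satisfy the documented format contract."""


class InsufficientSignalError(DopplerVtiError, RuntimeError):
    """Too little usable signal to segment beats or trace an envelope."""


class MissingWindowError(DopplerVtiError, RuntimeError):
    """A protocol window contains no kept beats or samples."""


class DegenerateTestError(DopplerVtiError, RuntimeError):
    """A statistical test is undefined for the given data (zero-variance differences)."""


class StageError(DopplerVtiError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")
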