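"""Exception types shared across the package."""


class PhreshError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PhreshError, ValueError):
    """A parameter violates an operation's contract."""


class NoReferenceError(PhreshError, ValueError):
    """A stack has no unconverted region to normalise against."""


class ContractViolationError(PhreshError, ValueError):
    """Inputs are individually valid but mutually inconsistent."""


class ConfigError(PhreshError, ValueError):
    """A run configuration is incomplete or self-contradictory."""


class StageError(PhreshError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
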