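"""Exception types shared across the pipeline."""


class PlateletPanelError(Exception):
    """Base class for package errors."""


class ConfigError(PlateletPanelError):
    """Invalid generator or pipeline configuration."""


class SchemaError(PlateletPanelError):
    """A tabular input is missing required columns or has the wrong shape."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = list(missing or [])


class OutOfWindowError(PlateletPanelError):
    """A calendar date falls outside the configured observation window."""


class JoinError(PlateletPanelError):
    """Donation records reference donor ids absent from the donor table."""

    def __init__(self, message: str, orphan_ids: list | None = None):
        super().__init__(message)
        self.orphan_ids = list(orphan_ids or [])


class RankError(PlateletPanelError):
    """Fixed-effect design matrix is rank deficient."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = list(aliased or [])


class ConvergenceError(PlateletPanelError):
    """Variance-component optimisation failed to converge."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = list(trace or [])
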