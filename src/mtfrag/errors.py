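"""Exception types shared across the package."""


class MtfragError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MtfragError):
    """Invalid configuration: bad parameter ranges, duplicate contigs, unknown keys.

    ``errors`` carries the full list of violations when several were found.
    """

    def __init__(self, message, errors=None):
        super().__init__(message)
        self.errors = list(errors) if errors is not None else [message]


class StageError(MtfragError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
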