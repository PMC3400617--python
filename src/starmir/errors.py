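"""Exception hierarchy for the starmir toolkit."""


class StarmirError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(StarmirError, ValueError):
    """A sequence contains a symbol outside its declared alphabet."""


class BoundsError(StarmirError, ValueError):
    """A position or window falls outside a sequence."""


class ConfigError(StarmirError, ValueError):
    """A request or vector profile is malformed or incomplete."""


class DesignFailure(StarmirError, RuntimeError):
    """No design satisfying the stated constraints exists.

    Carries the list of constraints that could not be satisfied so that
    callers (and the CLI) can report actionable diagnostics.
    """

    def __init__(self, message: str, violated: list[str] | None = None):
        super().__init__(message)
        self.violated = violated or []
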