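"""Exception hierarchy.

Configuration problems (unknown variants, missing parameters, bad config
files) are distinguished from numerical failures (non-convergent steady
states) so the command line can map them to distinct exit codes.
"""


class ThermoglycError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThermoglycError):
    """A model, variant or run configuration is invalid or incomplete."""


class DomainError(ThermoglycError, ValueError):
    """An input lies outside the physically meaningful domain."""


class ConvergenceError(ThermoglycError):
    """A steady-state solve failed; carries the last residual report."""

    def __init__(self, message, residual=None, state=None):
        super().__init__(message)
        self.residual = residual
        self.state = state
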