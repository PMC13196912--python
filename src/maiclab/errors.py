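"""Exception taxonomy shared across the package.

Validation problems (bad data files, inconsistent configuration) are kept
distinct from numerical failures (non-convergent weights, separation,
undefined contrasts) so callers — and the command-line interface exit
codes — can tell "fix your inputs" apart from "this analysis is not
estimable on these inputs".
"""


class MaicError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MaicError):
    """A data or config file could not be read at all."""


class ValidationError(MaicError):
    """Inputs were readable but violate a domain invariant."""


class ConfigurationError(ValidationError):
    """The analysis configuration is internally inconsistent."""


class EstimationError(MaicError):
    """A numerical procedure could not produce a defined estimate."""


class SeparationError(EstimationError):
    """A weighted outcome proportion hit 0 or 1; the log-odds contrast is undefined."""


class ConvergenceError(EstimationError):
    """The weight solver stopped without meeting its tolerance.

    Carries the partial :class:`~maiclab.maic_core.WeightSolution` as
    ``diagnostics`` so the failure can be inspected.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
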