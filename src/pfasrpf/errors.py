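"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PfasRpfError` so the CLI can map
failures to a stage-named message and a nonzero exit status.
"""


class PfasRpfError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PfasRpfError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(PfasRpfError):
    """A parsed value violates a domain invariant (e.g. mean <= 0)."""


class DomainError(PfasRpfError):
    """A function argument is outside its mathematical domain."""


class ConsistencyError(PfasRpfError):
    """Cross-object references do not line up (unknown compound/study)."""


class InsufficientDataError(PfasRpfError):
    """Too few points to estimate the requested quantity."""


class InvalidCurveError(PfasRpfError):
    """A standard curve with non-negative slope (no amplification signal)."""


class PairingError(PfasRpfError):
    """A sample lacks its reference-gene measurement."""


class NormalizationError(PfasRpfError):
    """The control group is empty or has non-positive mean signal."""


class NonConvergenceError(PfasRpfError):
    """No optimizer start reached the convergence tolerance."""


class IdentifiabilityError(PfasRpfError):
    """The design cannot identify the requested parameters."""


class UnreachableEffectError(DomainError):
    """The requested effect size lies beyond the curve's plateau."""


class DirectionError(DomainError):
    """Sign of the effect size disagrees with the curve direction."""


class ConfigError(PfasRpfError):
    """Invalid pipeline configuration."""
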