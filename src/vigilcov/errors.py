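"""Typed exceptions raised across the pipeline.

Every stage raises a subclass of :class:`VigilcovError` so orchestration code
can abort with a stage-tagged message rather than a bare ValueError.
"""


class VigilcovError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(VigilcovError):
    """A configuration value or function argument is invalid."""


class BoundaryError(VigilcovError):
    """A window or TR interval extends past the available recording."""


class QualityError(VigilcovError):
    """A physiological signal is too corrupted to use."""


class InsufficientDataError(VigilcovError):
    """Too few windows / samples / events for the requested statistic."""


class DegenerateInputError(VigilcovError):
    """Zero-variance, all-tied, or otherwise undefined statistical input."""


class CoverageError(VigilcovError):
    """An input series does not cover the span an operation requires."""
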