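"""Exception hierarchy.

All package errors derive from :class:`PpgCalibError` so callers can catch
one base type; most also derive from ``ValueError`` since they signal bad
inputs rather than internal faults.
"""


class PpgCalibError(Exception):
    """Base class for all errors raised by ppgcalib."""


class DomainError(PpgCalibError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(PpgCalibError, ValueError):
    """Invalid camera / tone-curve / run configuration."""


class ProtocolError(PpgCalibError, ValueError):
    """A bench protocol cannot be constructed or sampled."""


class CalibrationError(PpgCalibError, ValueError):
    """A sweep recording cannot support a line fit."""


class PipelineError(PpgCalibError, ValueError):
    """Trace segmentation / feature extraction / selection failure."""


class UndefinedRatioError(PipelineError):
    """A ratio-of-ratios denominator is zero or non-positive."""


class FormatError(PpgCalibError, ValueError):
    """Malformed on-disk trace / sweep / table file."""


class ReportError(PpgCalibError, ValueError):
    """Report inputs are incomplete or inconsistent."""
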