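"""Exception hierarchy for the peristartle pipeline.

All errors raised deliberately by the package derive from
:class:`PeristartleError`, so callers can catch pipeline failures without
also swallowing programming errors.
"""


class PeristartleError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PeristartleError):
    """A file does not conform to the documented CSV dialect (e.g. a
    required column is missing)."""


class ParseError(PeristartleError):
    """A row could not be parsed (e.g. non-numeric coordinate); carries
    the offending line number in the message."""


class VocabularyError(PeristartleError):
    """A label is outside the accepted vocabulary (keypoint names,
    status labels, intensity classes)."""


class ReferentialError(PeristartleError):
    """A record references a bout or male that does not exist in the
    joined dataset."""


class BoundsError(PeristartleError):
    """An event or exit lies outside the frame range of its bout."""


class ConfigurationError(PeristartleError):
    """A simulation or run configuration is invalid or infeasible."""


class MissingKeypointError(PeristartleError):
    """A bout lacks a keypoint required by the computation (beak tip or
    at least one inter-tarsal joint)."""


class ParameterError(PeristartleError):
    """An analysis parameter is out of its valid range (e.g. hard
    cleaning threshold not above the soft threshold)."""


class DegenerateGeometryError(PeristartleError):
    """The per-bout mean body height is zero or undefined, so relative
    displacement cannot be normalised."""


class EmptyGroupError(PeristartleError):
    """A status group contains no usable individuals."""


class InsufficientClustersError(PeristartleError):
    """Too few exchangeable units (males) for a cluster permutation
    test."""


class EmptyComparisonError(PeristartleError):
    """Automatic and manual annotations share no (bout, frame, keypoint)
    keys."""
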