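"""Exception hierarchy shared across the package.

Every error raised on a user-facing path derives from :class:`RegulocusError`
so the CLI can turn any of them into a one-line diagnostic and a nonzero
exit code.
"""


class RegulocusError(Exception):
    """Base class for all package errors."""


class InvalidAlphabetError(RegulocusError):
    """A DNA string contains symbols outside the allowed alphabet."""


class InvalidMotifError(RegulocusError):
    """A restriction motif is empty or malformed."""


class ViewpointResolutionError(RegulocusError):
    """A viewpoint interval overlaps zero or more than one restriction fragment."""


class ConfigError(RegulocusError):
    """A simulation or run configuration violates its invariants."""


class ParameterError(RegulocusError, ValueError):
    """An operation parameter is out of its valid domain (e.g. even window)."""


class PipelineOrderError(RegulocusError):
    """A track operation was called on a profile at the wrong stage."""


class InconsistencyError(RegulocusError):
    """Two inputs that must share a fragment map / sequence do not."""


class DegenerateProfileError(RegulocusError):
    """A profile has no usable signal in the normalization reference."""


class DegenerateTableError(RegulocusError):
    """A contingency table has a zero margin; the comparison is uninformative."""


class RegionError(RegulocusError):
    """Region containment or well-formedness violated."""


class RegionParseError(RegulocusError, ValueError):
    """A region string could not be parsed; message names the offending token."""


class BedFormatError(RegulocusError):
    """A BED/bedGraph file failed validation; message cites the line number."""


class DegenerateLandscapeWarning(UserWarning):
    """All stitched signals equal (or exactly linear); no cutoff exists."""
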