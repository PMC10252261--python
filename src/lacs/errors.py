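"""Exception hierarchy for the lacs package.

All package-specific failures derive from :class:`LacsError` so that callers
(and the CLI) can distinguish validation problems (:class:`ValidationError`)
from I/O problems (:class:`IOFailure`).
"""


class LacsError(Exception):
    """Base class for all lacs errors."""


class ValidationError(LacsError, ValueError):
    """Invalid inputs, parameters or domain-object state."""


class IOFailure(LacsError, OSError):
    """File could not be read or written."""


class FormatError(IOFailure):
    """A file exists but cannot be parsed as the expected image format."""


class AmbiguousSeriesError(FormatError):
    """A DICOM directory mixes slices from more than one series."""


class MissingRescaleError(FormatError):
    """DICOM slices lack the rescale slope/intercept needed to obtain HU."""


class BoundsError(ValidationError):
    """A region of interest or index lies outside the volume extent."""


class DegenerateROIError(ValidationError):
    """A region of interest covers fewer than two voxels (SD undefined)."""


class DegenerateTestError(ValidationError):
    """A statistical test is undefined for the given data (e.g. all-zero
    paired differences in the Wilcoxon signed-rank test)."""


class UndefinedICCError(ValidationError):
    """The intraclass correlation is undefined (zero between-subject
    variance)."""
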