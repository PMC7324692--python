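"""Exception hierarchy for phantom QA analysis failures.

Every error a QA stage can raise derives from :class:`QAError`, so the
orchestrator can catch per-stage failures without masking programming errors.
"""


class QAError(Exception):
    """Base class for all QA analysis errors."""


class DicomReadError(QAError):
    """A DICOM series folder could not be assembled into a volume."""


class NoDicomFoundError(DicomReadError):
    """The folder contains no readable DICOM image files."""


class MultipleSeriesError(DicomReadError):
    """The folder mixes files from more than one series."""


class InconsistentGeometryError(DicomReadError):
    """PixelSpacing or SliceThickness differ between slices of one series."""


class DuplicateSliceError(DicomReadError):
    """Two files in the series share the same InstanceNumber."""


class MarkerDetectionError(QAError):
    """Fiducial marker detection failed."""


class MarkersNotFoundError(MarkerDetectionError):
    """Fewer than three plausible marker components were found."""


class AmbiguousMarkersError(MarkerDetectionError):
    """More than four plausible marker components were found."""


class DegenerateMarkersError(MarkerDetectionError):
    """Two detected marker centroids (near-)coincide."""


class SurfaceNotInScanError(QAError):
    """Neither phantom end surface lies inside the scanned range."""


class RoiError(QAError):
    """A region of interest is invalid (too small, outside the phantom...)."""


class SliceOutOfRangeError(QAError):
    """A required analysis slice falls outside the scanned range."""


class AmbiguousPlugLocationError(QAError):
    """The resolution plug could not be located unambiguously.

    Recoverable: the user may supply the hole index / slice offset manually.
    """


class LayoutConflictError(QAError):
    """The resolution plug was assigned to a hole already holding a plug."""


class BaselineFormatError(QAError):
    """A baseline file is unreadable or has an unsupported format version."""
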