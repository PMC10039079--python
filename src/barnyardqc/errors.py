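"""Exception hierarchy shared across the pipeline stages."""


class BarnyardQCError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(BarnyardQCError):
    """A file on disk violates the expected format (names file/line where possible)."""


class LayoutError(BarnyardQCError):
    """A read layout is inconsistent with itself or with the reads it is applied to."""


class SynchronizationError(BarnyardQCError):
    """R1/R2 FASTQ files have unequal record counts or drifted out of order."""


class InsufficientDataError(BarnyardQCError):
    """Too few observations for the requested operation (e.g. cell calling)."""


class NoKneeError(BarnyardQCError):
    """The barcode rank curve has no detectable knee; advise a manual threshold."""


class ConsistencyError(BarnyardQCError):
    """Cross-object invariant violated (e.g. gene missing from the feature table)."""


class UnsupportedDesignError(BarnyardQCError):
    """Experimental design outside the supported scope (e.g. >2 species)."""


class EmptyResultError(BarnyardQCError):
    """An operation removed every cell/gene; carries the filter report as ``report``."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
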