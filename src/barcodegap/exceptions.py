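"""Exception hierarchy shared across the package.

Usage/configuration mistakes and malformed data raise distinct branches so
that callers (notably the CLI) can map them to different exit codes.
"""


class BarcodeGapError(Exception):
    """Base class for all package errors."""


class UsageError(BarcodeGapError):
    """The caller violated an operation's precondition."""


class ConfigError(UsageError):
    """A run configuration is internally inconsistent."""


class DataError(BarcodeGapError):
    """The input data is malformed or inconsistent."""


class FormatError(DataError):
    """A file does not parse as the expected format."""


class AlignmentError(DataError):
    """Sequences that must be aligned have unequal lengths or bad symbols."""


class MetadataError(DataError):
    """Specimen metadata is missing, duplicated, or inconsistent."""


class TopologyError(DataError):
    """A tree operation is impossible on the given topology."""


class DetectionError(DataError):
    """Peak detection could not find the requested number of peaks."""
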