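"""Exception hierarchy.

All anticipated bad inputs raise a named subclass of :class:`InputError` so
callers (and the CLI) can distinguish user mistakes from bugs.
"""


class BarseqfitError(Exception):
    """Base class for all package errors."""


class InputError(BarseqfitError, ValueError):
    """Invalid user-supplied data or configuration."""


class MissingColumnError(InputError):
    """A required column is absent from an input table."""


class DuplicateBarcodeError(InputError):
    """A barcode occurs more than once in a pool file."""


class NegativeCountError(InputError):
    """A count-table entry is negative."""


class SampleSheetError(InputError):
    """Sample sheet violates its invariants (e.g. two reference groups)."""


class FastqFormatError(InputError):
    """Malformed FASTQ record; message names the record index."""


class BarcodeSpaceExhaustedError(BarseqfitError, RuntimeError):
    """Could not draw a fresh unique barcode after repeated attempts."""


class PipelineError(BarseqfitError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
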